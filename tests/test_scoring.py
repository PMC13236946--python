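import dataclasses

import numpy as np
import pytest

from dentale.model import (
    ALL_TOOTH_IDS,
    WeightConfig,
    normal_assessment,
    sextant_of,
    sextant_teeth,
)
from dentale.scoring import (
    InvalidAssessmentError,
    referral_decision,
    score_assessment,
    score_cohort,
)
from dentale.synthetic import CohortParams, generate_cohort
from tests._oracles import brute_force_score
from tests.conftest import random_valid_assessment, with_bony, with_sextant, with_tooth


class TestScoreExamples:
    def test_all_normal_scores_zero(self, normal):
        bd = score_assessment(normal)
        assert bd.base_total == 0
        assert bd.final_total == 0
        assert bd.adjustment_points == 0
        assert not bd.refer
        assert all(v == 0 for v in bd.per_sextant_totals.values())

    def test_worst_case_scores_158(self, worst):
        bd = score_assessment(worst)
        assert bd.base_total == 158
        assert bd.presence_points == 144
        assert bd.condyle_points == 6
        assert bd.ramus_points == 2
        assert bd.alveolar_points == 6
        assert bd.wear_points == 0
        assert bd.refer

    def test_single_missing_canine(self, normal):
        bd = score_assessment(with_tooth(normal, tooth=13, status="missing"))
        assert bd.base_total == 8
        assert bd.per_sextant_totals[2] == 8
        assert bd.adjustment_points == 0
        assert bd.final_total == 8
        assert not bd.refer

    def test_missing_canine_and_incisor_triggers_adjustment_and_referral(self, normal):
        a = with_tooth(normal, tooth=13, status="missing")
        a = with_tooth(a, tooth=11, status="missing")
        bd = score_assessment(a)
        assert bd.base_total == 14
        assert bd.per_sextant_totals[2] == 14
        assert bd.adjustment_points == 5
        assert bd.final_total == 19
        assert bd.refer  # 19 >= 16

    def test_invalid_assessment_rejected_with_violations(self, normal):
        bad = with_tooth(normal, tooth=11, status="gone")
        with pytest.raises(InvalidAssessmentError) as exc:
            score_assessment(bad)
        assert exc.value.violations


class TestUnitDeltas:
    """Each single abnormal item shifts the total by exactly its weight."""

    @pytest.mark.parametrize(
        "code,delta", [(13, 8), (23, 8), (11, 6), (42, 6), (14, 4), (25, 4), (36, 4), (47, 4)]
    )
    def test_missing_tooth_delta(self, normal, code, delta):
        bd = score_assessment(with_tooth(normal, tooth=code, status="missing"))
        assert bd.final_total == delta

    @pytest.mark.parametrize(
        "field,delta",
        [
            ("condyle_left_abnormal", 3),
            ("condyle_right_abnormal", 3),
            ("ramus_left_abnormal", 1),
            ("ramus_right_abnormal", 1),
        ],
    )
    def test_bony_delta(self, normal, field, delta):
        bd = score_assessment(with_bony(normal, **{field: True}))
        assert bd.final_total == delta

    @pytest.mark.parametrize(
        "flag",
        [
            "crown_abnormal",
            "root_abnormal",
            "crown_root_ratio_abnormal",
            "eruption_not_age_appropriate",
        ],
    )
    def test_aspect_delta_one_point(self, normal, flag):
        bd = score_assessment(with_tooth(normal, tooth=16, **{flag: True}))
        assert bd.final_total == 1

    def test_alveolar_and_wear_one_point_per_sextant(self, normal):
        assert score_assessment(with_sextant(normal, sextant=3, alveolar_reduced=True)).final_total == 1
        assert score_assessment(with_sextant(normal, sextant=3, tooth_wear=True)).final_total == 1


class TestAdjustmentRule:
    def _sextant1_at(self, normal, points):
        """Build exactly `points` in sextant 1 (teeth 14-17, weight 4 each)."""
        a = normal
        if points >= 4:
            a = with_tooth(a, tooth=14, status="missing")
        if points >= 8:
            a = with_tooth(a, tooth=15, status="missing")
        rest = points % 4
        if rest >= 1:
            a = with_sextant(a, sextant=1, alveolar_reduced=True)
        if rest >= 2:
            a = with_sextant(a, sextant=1, alveolar_reduced=True, tooth_wear=True)
        if rest >= 3:
            a = with_tooth(a, tooth=16, crown_abnormal=True)
        return a

    def test_exactly_ten_no_bonus(self, normal):
        a = self._sextant1_at(normal, 10)
        bd = score_assessment(a)
        assert bd.per_sextant_totals[1] == 10
        assert bd.adjustment_points == 0
        assert bd.final_total == 10

    def test_eleven_gets_bonus_once(self, normal):
        a = self._sextant1_at(normal, 11)
        bd = score_assessment(a)
        assert bd.per_sextant_totals[1] == 11
        assert bd.adjustment_points == 5
        assert bd.final_total == 16
        assert bd.refer

    def test_two_qualifying_sextants_bonus_applied_once(self, normal):
        a = normal
        for code in (13, 11, 23, 21):  # 14 points in sextant 2
            a = with_tooth(a, tooth=code, status="missing")
        for code in (34, 35, 36):  # 12 points in sextant 4
            a = with_tooth(a, tooth=code, status="missing")
        bd = score_assessment(a)
        assert bd.per_sextant_totals[2] == 28
        assert bd.per_sextant_totals[4] == 12
        assert bd.adjustment_points == 5

    def test_per_sextant_bonus_switch(self, normal):
        a = normal
        for code in (13, 11, 34, 35, 36):
            a = with_tooth(a, tooth=code, status="missing")
        w = WeightConfig(per_sextant_bonus=True)
        bd = score_assessment(a, w)
        assert bd.per_sextant_totals[2] == 14
        assert bd.per_sextant_totals[4] == 12
        assert bd.adjustment_points == 10

    def test_condyle_points_not_attributed_to_sextants(self, normal):
        a = with_bony(
            normal,
            condyle_left_abnormal=True,
            condyle_right_abnormal=True,
            ramus_left_abnormal=True,
            ramus_right_abnormal=True,
        )
        bd = score_assessment(a)
        assert bd.base_total == 8
        assert all(v == 0 for v in bd.per_sextant_totals.values())
        assert bd.adjustment_points == 0


class TestExclusionNotes:
    def test_excluded_missing_tooth_contributes_zero(self, normal):
        a = with_tooth(
            normal, tooth=13, status="missing", exclusion_note="orthodontic extraction"
        )
        bd = score_assessment(a)
        assert bd.final_total == 0
        assert bd.per_sextant_totals[2] == 0

    def test_excluded_present_tooth_aspects_not_counted(self, normal):
        a = with_tooth(normal, tooth=16, crown_abnormal=True, exclusion_note="artifact")
        assert score_assessment(a).final_total == 0


class TestReferralDecision:
    @pytest.mark.parametrize("total,expected", [(16, True), (15, False), (0, False), (158, True)])
    def test_inclusive_threshold(self, total, expected):
        assert referral_decision(total) is expected

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            referral_decision(-1)

    def test_custom_threshold(self):
        w = WeightConfig(referral_threshold=20)
        assert referral_decision(16, w) is False
        assert referral_decision(20, w) is True


class TestScoreCohort:
    def test_empty(self):
        df = score_cohort([])
        assert len(df) == 0
        assert list(df.columns) == [
            "subject_id", "rater_id", "base_total", "adjustment_points",
            "final_total", "refer",
        ]

    def test_range_endpoints(self, normal, worst):
        # base range is the printed 0-158; the worst case also trips the
        # localized-pathology adjustment, so its final total is 163
        df = score_cohort([normal, worst])
        assert list(df["base_total"]) == [0, 158]
        assert list(df["final_total"]) == [0, 163]

    def test_83_synthetic_rows_order_preserving(self):
        cohort = generate_cohort(CohortParams(n_subjects=83, seed=5))
        assessments = [r.assessment for r in cohort]
        df = score_cohort(assessments)
        assert len(df) == 83
        assert list(df["subject_id"]) == [a.subject_id for a in assessments]
        for a, total in zip(assessments, df["final_total"]):
            assert score_assessment(a).final_total == total

    def test_invalid_assessment_aborts_with_index(self, normal):
        bad = with_tooth(normal, tooth=11, status="gone")
        with pytest.raises(InvalidAssessmentError) as exc:
            score_cohort([normal, bad])
        assert exc.value.index == 1


class TestProperties:
    def test_oracle_equivalence_random_assessments(self):
        rng = np.random.default_rng(42)
        for i in range(1000):
            a = random_valid_assessment(rng, with_notes=(i % 3 == 0))
            bd = score_assessment(a)
            base, adj, final, per_sextant = brute_force_score(a)
            assert bd.base_total == base
            assert bd.adjustment_points == adj
            assert bd.final_total == final
            assert bd.per_sextant_totals == per_sextant

    def test_base_total_bounds(self):
        rng = np.random.default_rng(43)
        for _ in range(500):
            bd = score_assessment(random_valid_assessment(rng))
            assert 0 <= bd.base_total <= 158

    def test_breakdown_sums(self):
        rng = np.random.default_rng(44)
        for _ in range(200):
            bd = score_assessment(random_valid_assessment(rng))
            assert bd.base_total == (
                bd.presence_points + bd.aspect_points + bd.alveolar_points
                + bd.wear_points + bd.condyle_points + bd.ramus_points
            )
            assert bd.final_total == bd.base_total + bd.adjustment_points
            assert bd.refer == (bd.final_total >= 16)

    def test_monotonicity_single_flip_never_decreases(self):
        rng = np.random.default_rng(45)
        aspect_flags = (
            "crown_abnormal",
            "root_abnormal",
            "crown_root_ratio_abnormal",
            "eruption_not_age_appropriate",
        )
        for _ in range(300):
            a = random_valid_assessment(rng)
            before = score_assessment(a).final_total
            kind = rng.integers(4)
            if kind == 0:  # present tooth -> missing (clears aspects + maybe wear)
                present = [t.tooth for t in a.teeth if t.status == "present"]
                if not present:
                    continue
                code = int(rng.choice(present))
                b = with_tooth(
                    a, tooth=code, status="missing",
                    crown_abnormal=False, root_abnormal=False,
                    crown_root_ratio_abnormal=False,
                    eruption_not_age_appropriate=False,
                )
                sx = sextant_of(code)
                if not any(
                    t.status == "present" for t in b.teeth
                    if t.tooth in sextant_teeth(sx)
                ):
                    b = with_sextant(b, sextant=sx, tooth_wear=False)
            elif kind == 1:  # flip an aspect on a present tooth
                present = [t for t in a.teeth if t.status == "present"]
                if not present:
                    continue
                t = present[rng.integers(len(present))]
                flag = aspect_flags[rng.integers(4)]
                if getattr(t, flag):
                    continue
                b = with_tooth(a, tooth=t.tooth, **{flag: True})
            elif kind == 2:  # flag alveolar reduction
                s = a.sextants[rng.integers(6)]
                if s.alveolar_reduced:
                    continue
                b = with_sextant(a, sextant=s.sextant, alveolar_reduced=True)
            else:  # flag a bony item
                field = (
                    "condyle_left_abnormal", "condyle_right_abnormal",
                    "ramus_left_abnormal", "ramus_right_abnormal",
                )[rng.integers(4)]
                if getattr(a.bony, field):
                    continue
                b = with_bony(a, **{field: True})
            assert score_assessment(b).final_total >= before

    def test_missing_aspect_exclusivity(self):
        # a tooth contributes its presence weight or its aspect points, never both
        rng = np.random.default_rng(46)
        w = WeightConfig()
        for _ in range(200):
            a = random_valid_assessment(rng)
            bd = score_assessment(a)
            expected_presence = sum(
                w.presence_weight(t.tooth)
                for t in a.teeth
                if t.status == "missing" and not t.exclusion_note
            )
            expected_aspects = sum(
                sum(t.aspect_flags())
                for t in a.teeth
                if t.status == "present" and not t.exclusion_note
            )
            assert bd.presence_points == expected_presence
            assert bd.aspect_points == expected_aspects


def test_all_missing_chart_wear_cannot_push_above_158(worst):
    # wear is structurally unscorable when every tooth is missing, so the
    # worst case is exactly the printed maximum
    assert score_assessment(worst).base_total == WeightConfig().max_base_score()


def test_custom_weight_config(normal):
    w = WeightConfig(
        presence_weights={cls: 2 for cls in WeightConfig().presence_weights},
        condyle_point=10,
    )
    a = with_tooth(normal, tooth=13, status="missing")
    a = with_bony(a, condyle_left_abnormal=True)
    bd = score_assessment(a, w)
    assert bd.base_total == 12


def test_score_is_deterministic(normal):
    a = with_tooth(normal, tooth=13, status="missing")
    assert score_assessment(a) == score_assessment(a)


def test_dataclass_frozen(normal):
    bd = score_assessment(normal)
    with pytest.raises(dataclasses.FrozenInstanceError):
        bd.final_total = 99
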