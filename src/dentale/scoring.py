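"""Score computation: itemized breakdown, localized-pathology adjustment and
referral decision."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from dentale.model import (
    SEXTANT_IDS,
    Assessment,
    WeightConfig,
    sextant_of,
    validate_assessment,
)


class InvalidAssessmentError(ValueError):
    """Raised when an assessment fails structural validation."""

    def __init__(self, violations: list[str], index: int | None = None):
        self.violations = violations
        self.index = index
        where = f"assessment {index}: " if index is not None else ""
        super().__init__(where + "; ".join(violations))


@dataclass(frozen=True)
class ScoreBreakdown:
    """Itemized score for one assessment.

    ``base_total`` is the plain weighted sum (0-158 under default weights);
    ``final_total`` adds the localized-pathology adjustment, and ``refer``
    applies the inclusive referral threshold to it.
    """

    presence_points: int
    aspect_points: int
    alveolar_points: int
    wear_points: int
    condyle_points: int
    ramus_points: int
    per_sextant_totals: dict[int, int] = field(default_factory=dict)
    base_total: int = 0
    adjustment_points: int = 0
    final_total: int = 0
    refer: bool = False


def referral_decision(total: int, weights: WeightConfig | None = None) -> bool:
    """True iff ``total`` meets the referral threshold (inclusive)."""
    if total < 0:
        raise ValueError(f"score total must be non-negative, got {total}")
    w = weights if weights is not None else WeightConfig()
    return total >= w.referral_threshold


def score_assessment(a: Assessment, weights: WeightConfig | None = None) -> ScoreBreakdown:
    """Compute the full score breakdown for one assessment.

    Per-tooth contribution: the class presence weight if the tooth is
    missing, otherwise one aspect point per flagged aspect.  Teeth carrying
    an ``exclusion_note`` (e.g. orthodontic extraction) contribute nothing.
    Alveolar reduction and wear score one point per sextant; abnormal
    condyles 3 points per side, rami 1 per side.

    Sextant totals attribute a tooth's points to its sextant plus that
    sextant's alveolar and wear points; condyle/ramus points belong to no
    sextant.  If any sextant total strictly exceeds the adjustment
    threshold, the bonus is added once (or once per qualifying sextant when
    ``weights.per_sextant_bonus`` is set).

    Raises
    ------
    InvalidAssessmentError
        If the assessment fails :func:`validate_assessment`.
    """
    w = weights if weights is not None else WeightConfig()
    violations = validate_assessment(a)
    if violations:
        raise InvalidAssessmentError(violations)

    presence = 0
    aspect = 0
    per_sextant = {s: 0 for s in SEXTANT_IDS}
    for t in a.teeth:
        if t.exclusion_note:
            continue
        if t.status == "missing":
            pts = w.presence_weight(t.tooth)
            presence += pts
        else:
            pts = w.aspect_point * sum(t.aspect_flags())
            aspect += pts
        per_sextant[sextant_of(t.tooth)] += pts

    alveolar = 0
    wear = 0
    for s in a.sextants:
        pts = 0
        if s.alveolar_reduced:
            pts += w.alveolar_point
            alveolar += w.alveolar_point
        if s.tooth_wear:
            pts += w.wear_point
            wear += w.wear_point
        per_sextant[s.sextant] += pts

    b = a.bony
    condyle = w.condyle_point * (int(b.condyle_left_abnormal) + int(b.condyle_right_abnormal))
    ramus = w.ramus_point * (int(b.ramus_left_abnormal) + int(b.ramus_right_abnormal))

    base_total = presence + aspect + alveolar + wear + condyle + ramus

    n_over = sum(1 for v in per_sextant.values() if v > w.sextant_adjustment_threshold)
    if n_over == 0:
        adjustment = 0
    elif w.per_sextant_bonus:
        adjustment = n_over * w.sextant_adjustment_bonus
    else:
        adjustment = w.sextant_adjustment_bonus

    final_total = base_total + adjustment
    return ScoreBreakdown(
        presence_points=presence,
        aspect_points=aspect,
        alveolar_points=alveolar,
        wear_points=wear,
        condyle_points=condyle,
        ramus_points=ramus,
        per_sextant_totals=per_sextant,
        base_total=base_total,
        adjustment_points=adjustment,
        final_total=final_total,
        refer=final_total >= w.referral_threshold,
    )


def score_cohort(
    assessments: list[Assessment], weights: WeightConfig | None = None
) -> pd.DataFrame:
    """Score a list of assessments into a tidy table.

    Returns one row per input assessment, in input order, with columns
    ``subject_id, rater_id, base_total, adjustment_points, final_total,
    refer``.  Any invalid assessment aborts the whole call, reporting its
    index and all violations.
    """
    w = weights if weights is not None else WeightConfig()
    rows = []
    for i, a in enumerate(assessments):
        violations = validate_assessment(a)
        if violations:
            raise InvalidAssessmentError(violations, index=i)
        bd = score_assessment(a, w)
        rows.append(
            {
                "subject_id": a.subject_id,
                "rater_id": a.rater_id,
                "base_total": bd.base_total,
                "adjustment_points": bd.adjustment_points,
                "final_total": bd.final_total,
                "refer": bd.refer,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "rater_id",
            "base_total",
            "adjustment_points",
            "final_total",
            "refer",
        ],
    )
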