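import dataclasses

import numpy as np
import pytest

from dentale.model import (
    ALL_TOOTH_IDS,
    SEXTANT_IDS,
    Assessment,
    BonyFinding,
    SextantFinding,
    ToothFinding,
    normal_assessment,
    sextant_of,
    worst_case_assessment,
)


@pytest.fixture
def normal():
    return normal_assessment()


@pytest.fixture
def worst():
    return worst_case_assessment()


def random_valid_assessment(rng: np.random.Generator, with_notes: bool = False) -> Assessment:
    """Build a random valid assessment directly from the constraints,
    independent of the synthetic module's generative model."""
    teeth = []
    present_by_sextant = {s: False for s in SEXTANT_IDS}
    for code in ALL_TOOTH_IDS:
        if rng.random() < 0.25:
            note = "orthodontic extraction" if with_notes and rng.random() < 0.2 else None
            teeth.append(ToothFinding(tooth=code, status="missing", exclusion_note=note))
        else:
            present_by_sextant[sextant_of(code)] = True
            teeth.append(
                ToothFinding(
                    tooth=code,
                    crown_abnormal=bool(rng.random() < 0.2),
                    root_abnormal=bool(rng.random() < 0.2),
                    crown_root_ratio_abnormal=bool(rng.random() < 0.2),
                    eruption_not_age_appropriate=bool(rng.random() < 0.2),
                )
            )
    sextants = tuple(
        SextantFinding(
            sextant=s,
            alveolar_reduced=bool(rng.random() < 0.3),
            tooth_wear=bool(present_by_sextant[s] and rng.random() < 0.3),
        )
        for s in SEXTANT_IDS
    )
    bony = BonyFinding(
        condyle_left_abnormal=bool(rng.random() < 0.2),
        condyle_right_abnormal=bool(rng.random() < 0.2),
        ramus_left_abnormal=bool(rng.random() < 0.2),
        ramus_right_abnormal=bool(rng.random() < 0.2),
    )
    return Assessment(
        subject_id=f"S{rng.integers(1_000_000)}",
        rater_id="R1",
        age_at_opg_years=float(rng.uniform(6, 21)),
        teeth=tuple(teeth),
        sextants=sextants,
        bony=bony,
    )


def with_tooth(a: Assessment, **tooth_changes) -> Assessment:
    """Copy an assessment replacing one tooth finding (keyed by 'tooth')."""
    code = tooth_changes.pop("tooth")
    teeth = tuple(
        dataclasses.replace(t, **tooth_changes) if t.tooth == code else t
        for t in a.teeth
    )
    return dataclasses.replace(a, teeth=teeth)


def with_sextant(a: Assessment, **sx_changes) -> Assessment:
    code = sx_changes.pop("sextant")
    sextants = tuple(
        dataclasses.replace(s, **sx_changes) if s.sextant == code else s
        for s in a.sextants
    )
    return dataclasses.replace(a, sextants=sextants)


def with_bony(a: Assessment, **bony_changes) -> Assessment:
    return dataclasses.replace(a, bony=dataclasses.replace(a.bony, **bony_changes))
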