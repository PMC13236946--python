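"""Domain model: FDI tooth chart, sextant map, findings and weight configuration.

Tooth identity uses FDI two-digit notation (quadrant digit 1-4, position
digit 1-7).  Third molars (position 8) are excluded from the instrument and
rejected everywhere.  The six sextants follow the standard periodontal
convention: two anterior sextants canine-to-canine (6 teeth each) and four
posterior sextants first premolar to second molar (4 teeth each).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional


class ToothClass(enum.Enum):
    """Morphological class of a permanent tooth, keyed by FDI position digit."""

    CENTRAL_INCISOR = "central_incisor"
    LATERAL_INCISOR = "lateral_incisor"
    CANINE = "canine"
    FIRST_PREMOLAR = "first_premolar"
    SECOND_PREMOLAR = "second_premolar"
    FIRST_MOLAR = "first_molar"
    SECOND_MOLAR = "second_molar"


_POSITION_TO_CLASS = {
    1: ToothClass.CENTRAL_INCISOR,
    2: ToothClass.LATERAL_INCISOR,
    3: ToothClass.CANINE,
    4: ToothClass.FIRST_PREMOLAR,
    5: ToothClass.SECOND_PREMOLAR,
    6: ToothClass.FIRST_MOLAR,
    7: ToothClass.SECOND_MOLAR,
}

#: Default presence weights: losing a canine scores 8, an incisor 6, a
#: premolar or molar 4.  Sum over the 28-tooth chart = 144.
DEFAULT_PRESENCE_WEIGHTS: dict[ToothClass, int] = {
    ToothClass.CENTRAL_INCISOR: 6,
    ToothClass.LATERAL_INCISOR: 6,
    ToothClass.CANINE: 8,
    ToothClass.FIRST_PREMOLAR: 4,
    ToothClass.SECOND_PREMOLAR: 4,
    ToothClass.FIRST_MOLAR: 4,
    ToothClass.SECOND_MOLAR: 4,
}

#: The 28 valid FDI codes of the permanent dentition excluding third molars,
#: in canonical chart order (quadrant 1..4, position 1..7).
ALL_TOOTH_IDS: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 8)
)

_VALID_CODES = frozenset(ALL_TOOTH_IDS)
_THIRD_MOLARS = frozenset({18, 28, 38, 48})

#: Names of the four per-tooth aspect findings, each worth one point when
#: flagged on a present tooth.
ASPECT_FIELDS: tuple[str, ...] = (
    "crown_abnormal",
    "root_abnormal",
    "crown_root_ratio_abnormal",
    "eruption_not_age_appropriate",
)

SEXTANT_IDS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


def _check_code(fdi_code: int) -> None:
    if fdi_code in _THIRD_MOLARS:
        raise ValueError(
            f"tooth {fdi_code} is a third molar: third molars are excluded "
            "from the instrument and must not be charted"
        )
    if fdi_code not in _VALID_CODES:
        raise ValueError(
            f"invalid FDI code {fdi_code}: expected quadrant digit 1-4 and "
            "position digit 1-7"
        )


def tooth_class_of(fdi_code: int) -> ToothClass:
    """Map a valid FDI code to its tooth class.

    Raises
    ------
    ValueError
        If the code is not one of the 28 scorable permanent teeth; third
        molars get a message naming the exclusion rule.
    """
    _check_code(fdi_code)
    return _POSITION_TO_CLASS[fdi_code % 10]


def sextant_of(fdi_code: int) -> int:
    """Map a valid FDI code to its sextant (1-6).

    Sextant 1 = upper right posterior (14-17), 2 = upper anterior (13-23),
    3 = upper left posterior (24-27), 4 = lower left posterior (34-37),
    5 = lower anterior (33-43), 6 = lower right posterior (44-47).
    """
    _check_code(fdi_code)
    quadrant, position = divmod(fdi_code, 10)
    anterior = position <= 3
    if quadrant in (1, 2):
        if anterior:
            return 2
        return 1 if quadrant == 1 else 3
    if anterior:
        return 5
    return 4 if quadrant == 3 else 6


def sextant_teeth(sextant: int) -> tuple[int, ...]:
    """The FDI codes belonging to a sextant, in chart order."""
    if sextant not in SEXTANT_IDS:
        raise ValueError(f"invalid sextant {sextant}: expected 1-6")
    return tuple(t for t in ALL_TOOTH_IDS if sextant_of(t) == sextant)


@dataclass(frozen=True)
class ToothFinding:
    """One permanent tooth's radiographic status.

    ``status`` is ``"present"`` or ``"missing"``.  Aspect flags are
    scorable only on a present tooth; on a missing tooth they must be
    false.  A crown-root ratio >= 1:1 is charted as
    ``crown_root_ratio_abnormal``.  ``exclusion_note`` marks a tooth whose
    absence is not a late effect (e.g. orthodontic extraction); excluded
    teeth contribute no points.
    """

    tooth: int
    status: str = "present"
    crown_abnormal: bool = False
    root_abnormal: bool = False
    crown_root_ratio_abnormal: bool = False
    eruption_not_age_appropriate: bool = False
    exclusion_note: Optional[str] = None

    def aspect_flags(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.crown_abnormal,
            self.root_abnormal,
            self.crown_root_ratio_abnormal,
            self.eruption_not_age_appropriate,
        )


@dataclass(frozen=True)
class SextantFinding:
    """Region-level findings for one sextant: alveolar bone reduction and
    tooth wear, one point each.  Wear is unscorable in an edentulous
    sextant."""

    sextant: int
    alveolar_reduced: bool = False
    tooth_wear: bool = False


@dataclass(frozen=True)
class BonyFinding:
    """Bilateral condyle (3 points/side) and ascending ramus (1 point/side)
    contour findings."""

    condyle_left_abnormal: bool = False
    condyle_right_abnormal: bool = False
    ramus_left_abnormal: bool = False
    ramus_right_abnormal: bool = False


@dataclass(frozen=True)
class Assessment:
    """One rater's complete scoring form for one survivor."""

    subject_id: str
    rater_id: str
    age_at_opg_years: float
    teeth: tuple[ToothFinding, ...]
    sextants: tuple[SextantFinding, ...]
    bony: BonyFinding = field(default_factory=BonyFinding)

    def tooth(self, fdi_code: int) -> ToothFinding:
        _check_code(fdi_code)
        for t in self.teeth:
            if t.tooth == fdi_code:
                return t
        raise KeyError(f"tooth {fdi_code} not charted")

    def sextant(self, sextant: int) -> SextantFinding:
        for s in self.sextants:
            if s.sextant == sextant:
                return s
        raise KeyError(f"sextant {sextant} not charted")


@dataclass(frozen=True)
class WeightConfig:
    """Item weights, adjustment-rule parameters and the referral threshold.

    Defaults reproduce the published instrument: base score range 0-158,
    a +5 adjustment when any single sextant strictly exceeds 10 points,
    and referral at a total of 16 points or more (inclusive).
    ``per_sextant_bonus`` switches the adjustment from once-per-assessment
    to once-per-qualifying-sextant (sensitivity analysis only).
    """

    presence_weights: dict[ToothClass, int] = field(
        default_factory=lambda: dict(DEFAULT_PRESENCE_WEIGHTS)
    )
    aspect_point: int = 1
    condyle_point: int = 3
    ramus_point: int = 1
    alveolar_point: int = 1
    wear_point: int = 1
    sextant_adjustment_threshold: int = 10
    sextant_adjustment_bonus: int = 5
    referral_threshold: int = 16
    per_sextant_bonus: bool = False

    def presence_weight(self, fdi_code: int) -> int:
        return self.presence_weights[tooth_class_of(fdi_code)]

    def max_base_score(self) -> int:
        """Worst-case base total: every tooth missing plus all bony and
        alveolar items (wear unscorable then).  158 under defaults."""
        teeth = sum(self.presence_weight(t) for t in ALL_TOOTH_IDS)
        return teeth + 2 * self.condyle_point + 2 * self.ramus_point + 6 * self.alveolar_point

    def replace(self, **changes) -> "WeightConfig":
        return dataclasses.replace(self, **changes)


def validate_assessment(a: Assessment) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the assessment is scorable.  Violations are
    returned, never raised, so callers can report them all at once.
    """
    violations: list[str] = []

    seen: dict[int, int] = {}
    for t in a.teeth:
        if t.tooth in _THIRD_MOLARS:
            violations.append(
                f"tooth {t.tooth}: third molars are excluded from the instrument"
            )
            continue
        if t.tooth not in _VALID_CODES:
            violations.append(f"tooth {t.tooth}: not a valid FDI code")
            continue
        seen[t.tooth] = seen.get(t.tooth, 0) + 1
        if t.status not in ("present", "missing"):
            violations.append(
                f"tooth {t.tooth}: status must be 'present' or 'missing', got {t.status!r}"
            )
        if t.status == "missing" and any(t.aspect_flags()):
            violations.append(
                f"tooth {t.tooth}: aspect findings flagged on a missing tooth "
                "(aspects are unscorable on an absent tooth)"
            )
    for code, n in seen.items():
        if n > 1:
            violations.append(f"tooth {code}: charted {n} times")
    absent = sorted(set(ALL_TOOTH_IDS) - set(seen))
    if absent:
        violations.append(
            f"incomplete chart: {len(seen)} of 28 teeth charted, missing {absent}"
        )

    charted_sextants = [s.sextant for s in a.sextants]
    if sorted(charted_sextants) != list(SEXTANT_IDS):
        violations.append(
            f"sextants must be exactly 1-6, got {sorted(charted_sextants)}"
        )
    else:
        present_by_sextant = {s: False for s in SEXTANT_IDS}
        for t in a.teeth:
            if t.tooth in _VALID_CODES and t.status == "present":
                present_by_sextant[sextant_of(t.tooth)] = True
        for s in a.sextants:
            if s.tooth_wear and not present_by_sextant[s.sextant]:
                violations.append(
                    f"sextant {s.sextant}: tooth wear flagged but no tooth is "
                    "present (wear scoring is inapplicable in an edentulous sextant)"
                )

    if not (a.age_at_opg_years >= 0):
        violations.append(f"age_at_opg_years must be non-negative, got {a.age_at_opg_years}")

    return violations


def normal_assessment(
    subject_id: str = "S0", rater_id: str = "R0", age: float = 12.0
) -> Assessment:
    """A fully normal assessment (every tooth present, no findings);
    scores 0 under any sane weight configuration."""
    return Assessment(
        subject_id=subject_id,
        rater_id=rater_id,
        age_at_opg_years=age,
        teeth=tuple(ToothFinding(tooth=t) for t in ALL_TOOTH_IDS),
        sextants=tuple(SextantFinding(sextant=s) for s in SEXTANT_IDS),
        bony=BonyFinding(),
    )


def worst_case_assessment(
    subject_id: str = "S0", rater_id: str = "R0", age: float = 18.0
) -> Assessment:
    """The maximal-score assessment: all 28 teeth missing, both condyles and
    rami abnormal, all six sextants alveolar-reduced; wear unscorable."""
    return Assessment(
        subject_id=subject_id,
        rater_id=rater_id,
        age_at_opg_years=age,
        teeth=tuple(ToothFinding(tooth=t, status="missing") for t in ALL_TOOTH_IDS),
        sextants=tuple(
            SextantFinding(sextant=s, alveolar_reduced=True) for s in SEXTANT_IDS
        ),
        bony=BonyFinding(
            condyle_left_abnormal=True,
            condyle_right_abnormal=True,
            ramus_left_abnormal=True,
            ramus_right_abnormal=True,
        ),
    )
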