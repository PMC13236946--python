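"""Advisory reference table of permanent-tooth eruption ages.

Median eruption ages (years) per FDI position, maxillary vs mandibular,
from standard dental-development references (Lunt & Law-style values).
These are package reference data, used only by advisory helpers and the
synthetic cohort generator -- never by the scorer, where age-appropriate
eruption is a rater judgment.  Override via the ``table`` argument.
"""

from __future__ import annotations

from dentale.model import _check_code  # noqa: F401  (shared code validation)

#: (arch, position) -> median eruption age in years.  Arch "upper" covers
#: quadrants 1-2, "lower" quadrants 3-4.
DEFAULT_ERUPTION_AGES: dict[tuple[str, int], float] = {
    ("upper", 1): 7.25,
    ("upper", 2): 8.25,
    ("upper", 3): 11.5,
    ("upper", 4): 10.25,
    ("upper", 5): 11.0,
    ("upper", 6): 6.25,
    ("upper", 7): 12.25,
    ("lower", 1): 6.25,
    ("lower", 2): 7.5,
    ("lower", 3): 10.25,
    ("lower", 4): 10.75,
    ("lower", 5): 11.5,
    ("lower", 6): 6.0,
    ("lower", 7): 11.75,
}


def reference_eruption_age(
    fdi_code: int, table: dict[tuple[str, int], float] | None = None
) -> float:
    """Median eruption age for a tooth, from the reference table."""
    _check_code(fdi_code)
    t = table if table is not None else DEFAULT_ERUPTION_AGES
    quadrant, position = divmod(fdi_code, 10)
    arch = "upper" if quadrant in (1, 2) else "lower"
    return t[(arch, position)]


def expected_erupted(
    fdi_code: int,
    age_years: float,
    tolerance_years: float = 1.5,
    table: dict[tuple[str, int], float] | None = None,
) -> bool:
    """Advisory: would this tooth normally have erupted by ``age_years``?

    True once the survivor's age exceeds the reference eruption age minus
    ``tolerance_years``.  Informational only; the scorer never calls this.
    """
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    return age_years >= reference_eruption_age(fdi_code, table) - tolerance_years
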