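"""Readers and writers for the assessment schema, weight configs and reports.

JSON is the canonical interchange format (one document per subject-rater
pair, nested per-tooth structure).  CSV is a convenience dialect with a
fixed, documented column order: identifier columns, then six columns per
tooth in chart order (``t11_status, t11_crown, t11_root, t11_crown_root,
t11_eruption, t11_note``), twelve sextant columns (``s1_alveolar, s1_wear,
...``) and four bony columns (``condyle_L, condyle_R, ramus_L, ramus_R``).
Booleans are 0/1 in CSV, tooth status is ``present``/``missing``, encoding
is UTF-8.  Weight configs load from TOML or JSON.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from dentale.model import (
    ALL_TOOTH_IDS,
    SEXTANT_IDS,
    Assessment,
    BonyFinding,
    SextantFinding,
    ToothClass,
    ToothFinding,
    WeightConfig,
    validate_assessment,
)
from dentale.scoring import ScoreBreakdown
from dentale.validation import AccuracyResult, ConfusionCounts, IccResult


class SchemaError(ValueError):
    """A file does not conform to the assessment or report schema."""


_BONY_FIELDS = (
    "condyle_left_abnormal",
    "condyle_right_abnormal",
    "ramus_left_abnormal",
    "ramus_right_abnormal",
)
_BONY_CSV = {"condyle_L": "condyle_left_abnormal", "condyle_R": "condyle_right_abnormal",
             "ramus_L": "ramus_left_abnormal", "ramus_R": "ramus_right_abnormal"}
_TOOTH_CSV_SUFFIXES = ("status", "crown", "root", "crown_root", "eruption", "note")

CSV_COLUMNS: tuple[str, ...] = (
    ("subject_id", "rater_id", "age_at_opg_years")
    + tuple(f"t{t}_{sfx}" for t in ALL_TOOTH_IDS for sfx in _TOOTH_CSV_SUFFIXES)
    + tuple(f"s{s}_{kind}" for s in SEXTANT_IDS for kind in ("alveolar", "wear"))
    + tuple(_BONY_CSV)
)


# ---------------------------------------------------------------- assessments

def assessment_to_dict(a: Assessment) -> dict[str, Any]:
    return {
        "subject_id": a.subject_id,
        "rater_id": a.rater_id,
        "age_at_opg_years": a.age_at_opg_years,
        "teeth": {
            str(t.tooth): {
                "status": t.status,
                "crown_abnormal": t.crown_abnormal,
                "root_abnormal": t.root_abnormal,
                "crown_root_ratio_abnormal": t.crown_root_ratio_abnormal,
                "eruption_not_age_appropriate": t.eruption_not_age_appropriate,
                "exclusion_note": t.exclusion_note,
            }
            for t in sorted(a.teeth, key=lambda t: t.tooth)
        },
        "sextants": {
            str(s.sextant): {
                "alveolar_reduced": s.alveolar_reduced,
                "tooth_wear": s.tooth_wear,
            }
            for s in sorted(a.sextants, key=lambda s: s.sextant)
        },
        "bony": {f: getattr(a.bony, f) for f in _BONY_FIELDS},
    }


def assessment_from_dict(d: dict[str, Any]) -> Assessment:
    try:
        teeth = tuple(
            ToothFinding(
                tooth=int(code),
                status=rec["status"],
                crown_abnormal=bool(rec.get("crown_abnormal", False)),
                root_abnormal=bool(rec.get("root_abnormal", False)),
                crown_root_ratio_abnormal=bool(rec.get("crown_root_ratio_abnormal", False)),
                eruption_not_age_appropriate=bool(
                    rec.get("eruption_not_age_appropriate", False)
                ),
                exclusion_note=rec.get("exclusion_note"),
            )
            for code, rec in d["teeth"].items()
        )
        sextants = tuple(
            SextantFinding(
                sextant=int(code),
                alveolar_reduced=bool(rec.get("alveolar_reduced", False)),
                tooth_wear=bool(rec.get("tooth_wear", False)),
            )
            for code, rec in d["sextants"].items()
        )
        bony = BonyFinding(**{f: bool(d["bony"].get(f, False)) for f in _BONY_FIELDS})
        return Assessment(
            subject_id=str(d["subject_id"]),
            rater_id=str(d["rater_id"]),
            age_at_opg_years=float(d["age_at_opg_years"]),
            teeth=teeth,
            sextants=sextants,
            bony=bony,
        )
    except (KeyError, TypeError, ValueError) as e:
        raise SchemaError(f"malformed assessment record: {e}") from e


def _check_batch(assessments: list[Assessment], where: str) -> list[Assessment]:
    problems = []
    seen = set()
    for i, a in enumerate(assessments):
        key = (a.subject_id, a.rater_id)
        if key in seen:
            problems.append(f"record {i}: duplicate subject-rater pair {key}")
        seen.add(key)
        for v in validate_assessment(a):
            problems.append(f"record {i} ({a.subject_id}/{a.rater_id}): {v}")
    if problems:
        raise SchemaError(f"{where}: " + "; ".join(problems))
    return assessments


def read_assessments(path: str | Path, format: Optional[str] = None) -> list[Assessment]:
    """Read assessments from JSON or CSV; every record must validate or the
    whole read aborts listing all violations with record indices."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty file (expected at least one record)")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        records = doc["assessments"] if isinstance(doc, dict) else doc
        if not isinstance(records, list) or not records:
            raise SchemaError(f"{path}: expected a non-empty list of assessments")
        assessments = [assessment_from_dict(r) for r in records]
    elif fmt == "csv":
        assessments = _read_assessments_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}: expected 'json' or 'csv'")
    return _check_batch(assessments, str(path))


def write_assessments(
    assessments: list[Assessment], path: str | Path, format: Optional[str] = None
) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        doc = {"assessments": [assessment_to_dict(a) for a in assessments]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif fmt == "csv":
        _write_assessments_csv(assessments, path)
    else:
        raise ValueError(f"unknown format {fmt!r}: expected 'json' or 'csv'")


def _read_assessments_csv(path: Path) -> list[Assessment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in df.columns:
        if col.startswith("t") and col[1:3].isdigit():
            code = int(col[1:3])
            if code % 10 == 8:
                raise SchemaError(
                    f"{path}: column {col!r} refers to a third molar; third "
                    "molars are excluded from the instrument"
                )
            if code not in ALL_TOOTH_IDS:
                raise SchemaError(f"{path}: column {col!r} is not a valid FDI code")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns and not c.endswith("_note")]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols[:8]}...")

    def as_bool(row, col):
        return str(row[col]).strip() in ("1", "true", "True")

    out = []
    for _, row in df.iterrows():
        teeth = []
        for t in ALL_TOOTH_IDS:
            status = str(row[f"t{t}_status"]).strip()
            note = str(row.get(f"t{t}_note", "")).strip() or None
            teeth.append(
                ToothFinding(
                    tooth=t,
                    status=status,
                    crown_abnormal=as_bool(row, f"t{t}_crown"),
                    root_abnormal=as_bool(row, f"t{t}_root"),
                    crown_root_ratio_abnormal=as_bool(row, f"t{t}_crown_root"),
                    eruption_not_age_appropriate=as_bool(row, f"t{t}_eruption"),
                    exclusion_note=note,
                )
            )
        sextants = tuple(
            SextantFinding(
                sextant=s,
                alveolar_reduced=as_bool(row, f"s{s}_alveolar"),
                tooth_wear=as_bool(row, f"s{s}_wear"),
            )
            for s in SEXTANT_IDS
        )
        bony = BonyFinding(**{f: as_bool(row, c) for c, f in _BONY_CSV.items()})
        out.append(
            Assessment(
                subject_id=str(row["subject_id"]),
                rater_id=str(row["rater_id"]),
                age_at_opg_years=float(row["age_at_opg_years"]),
                teeth=tuple(teeth),
                sextants=sextants,
                bony=bony,
            )
        )
    return out


def _write_assessments_csv(assessments: list[Assessment], path: Path) -> None:
    rows = []
    for a in assessments:
        row: dict[str, Any] = {
            "subject_id": a.subject_id,
            "rater_id": a.rater_id,
            "age_at_opg_years": a.age_at_opg_years,
        }
        by_code = {t.tooth: t for t in a.teeth}
        for code in ALL_TOOTH_IDS:
            t = by_code[code]
            row[f"t{code}_status"] = t.status
            row[f"t{code}_crown"] = int(t.crown_abnormal)
            row[f"t{code}_root"] = int(t.root_abnormal)
            row[f"t{code}_crown_root"] = int(t.crown_root_ratio_abnormal)
            row[f"t{code}_eruption"] = int(t.eruption_not_age_appropriate)
            row[f"t{code}_note"] = t.exclusion_note or ""
        by_sx = {s.sextant: s for s in a.sextants}
        for sx in SEXTANT_IDS:
            row[f"s{sx}_alveolar"] = int(by_sx[sx].alveolar_reduced)
            row[f"s{sx}_wear"] = int(by_sx[sx].tooth_wear)
        for col, fname in _BONY_CSV.items():
            row[col] = int(getattr(a.bony, fname))
        rows.append(row)
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


# -------------------------------------------------------------- weight config

def weight_config_to_dict(w: WeightConfig) -> dict[str, Any]:
    d = asdict(w)
    d["presence_weights"] = {cls.value: pts for cls, pts in w.presence_weights.items()}
    return d


def weight_config_from_dict(d: dict[str, Any]) -> WeightConfig:
    d = dict(d)
    if "presence_weights" in d:
        d["presence_weights"] = {
            ToothClass(name): int(pts) for name, pts in d["presence_weights"].items()
        }
    try:
        return WeightConfig(**d)
    except TypeError as e:
        raise SchemaError(f"malformed weight config: {e}") from e


def read_weight_config(path: str | Path) -> WeightConfig:
    """Load a weight config from TOML or JSON (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return weight_config_from_dict(tomllib.load(fh))
    with open(path, encoding="utf-8") as fh:
        return weight_config_from_dict(json.load(fh))


def write_weight_config(w: WeightConfig, path: str | Path) -> None:
    """Write a weight config as TOML (key-value) or JSON, by extension."""
    path = Path(path)
    d = weight_config_to_dict(w)
    if path.suffix.lower() == ".toml":
        lines = []
        for key, val in d.items():
            if key == "presence_weights":
                continue
            lines.append(f"{key} = {str(val).lower() if isinstance(val, bool) else val}")
        lines.append("")
        lines.append("[presence_weights]")
        for cls, pts in d["presence_weights"].items():
            lines.append(f"{cls} = {pts}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        path.write_text(json.dumps(d, indent=1) + "\n", encoding="utf-8")


# ------------------------------------------------------------------- reports

@dataclass(frozen=True)
class ReportDocument:
    """Serializable run report: tool version, weight echo, per-subject score
    rows and an optional validation block.  Round-trips losslessly."""

    version: str
    weights: WeightConfig
    scores: list[dict[str, Any]] = field(default_factory=list)
    validation: Optional[dict[str, Any]] = None
    timestamp: Optional[str] = None


def score_row(subject_id: str, rater_id: str, bd: ScoreBreakdown) -> dict[str, Any]:
    d = asdict(bd)
    d["per_sextant_totals"] = {str(k): v for k, v in bd.per_sextant_totals.items()}
    return {"subject_id": subject_id, "rater_id": rater_id, **d}


def accuracy_block(c: ConfusionCounts, acc: AccuracyResult) -> dict[str, Any]:
    def m(metric):
        if not metric.applicable:
            return {"applicable": False}
        return {
            "applicable": True,
            "proportion": metric.proportion,
            "percent": metric.percent,
            "ci95": [metric.ci_low, metric.ci_high],
        }

    return {
        "counts": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn, "n": c.total},
        "sensitivity": m(acc.sensitivity),
        "specificity": m(acc.specificity),
        "ppv": m(acc.ppv),
        "npv": m(acc.npv),
    }


def icc_block(r: IccResult) -> dict[str, Any]:
    return {
        "estimate": r.estimate,
        "ci95": [r.ci_low, r.ci_high],
        "model": r.model,
        "p_value": r.p_value,
        "mean_squares": r.mean_squares,
    }


def write_report(r: ReportDocument, path: str | Path) -> None:
    """Deterministic JSON serialization (stable key order, percentages at
    one decimal inside accuracy blocks)."""
    doc = {
        "version": r.version,
        "weights": weight_config_to_dict(r.weights),
        "scores": r.scores,
        "validation": r.validation,
        "timestamp": r.timestamp,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> ReportDocument:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        return ReportDocument(
            version=doc["version"],
            weights=weight_config_from_dict(doc["weights"]),
            scores=doc["scores"],
            validation=doc.get("validation"),
            timestamp=doc.get("timestamp"),
        )
    except KeyError as e:
        raise SchemaError(f"{path}: missing report field {e}") from e
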