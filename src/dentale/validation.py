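"""Reliability and diagnostic-accuracy statistics.

Interobserver reliability is the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1), computed from the two-way
ANOVA mean squares with F-based 95% confidence bounds (McGraw & Wong).
Diagnostic accuracy is the standard 2x2 battery (sensitivity, specificity,
PPV, NPV) with Wilson score intervals, plus a threshold sweep implementing
the selection rule "smallest threshold with sensitivity 1".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

ICC_MODELS = ("icc2_1", "icc2_k", "icc3_1", "icc3_k")


@dataclass(frozen=True)
class RaterMatrix:
    """Complete crossed subjects x raters grid of totals (no missing cells)."""

    values: np.ndarray
    subscale: str = "total"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError(f"rater matrix must be 2-D, got shape {v.shape}")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError(
                f"need at least 2 subjects and 2 raters, got {n} x {k}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(
                "rater matrix has missing or non-finite cells; the design "
                "must be complete (no imputation is performed)"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    p_value: float
    mean_squares: dict[str, float]


def _anova_mean_squares(v: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way crossed ANOVA mean squares (rows=subjects, cols=raters)."""
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((v - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way(
    m: RaterMatrix, model: str = "icc2_1", alpha: float = 0.05
) -> IccResult:
    """Two-way intraclass correlation with F-based confidence bounds.

    ``model`` selects among ``icc2_1`` (two-way random, absolute agreement,
    single measure -- the default and the form used throughout), ``icc2_k``
    (average measure), and the consistency forms ``icc3_1`` / ``icc3_k``.
    The p-value tests ICC = 0 via F = MSR/MSE on (n-1, (n-1)(k-1)) df.

    Raises
    ------
    ValueError
        On an unknown model, or when the matrix has no variance at all
        (every cell identical), which leaves the ICC undefined.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"unknown ICC model {model!r}; expected one of {ICC_MODELS}")
    v = m.values
    msr, msc, mse, n, k = _anova_mean_squares(v)
    if msr <= 1e-14 and msc <= 1e-14 and mse <= 1e-14:
        raise ValueError(
            "zero variance across both subjects and raters: ICC is undefined "
            "for a constant matrix"
        )

    df1, df2 = n - 1, (n - 1) * (k - 1)
    fq = stats.f.ppf(1 - alpha / 2, df1, df2)
    fq_rev = stats.f.ppf(1 - alpha / 2, df2, df1)

    if model in ("icc2_1", "icc2_k"):
        est1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # Satterthwaite df for the absolute-agreement bounds
        if abs(1.0 - est1) < 1e-14:
            vdf = np.nan
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (k * est1) / (n * (1.0 - est1))
                b = 1.0 + (k * est1 * (n - 1)) / (n * (1.0 - est1))
                vdf = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df2
                )
        if not np.isfinite(vdf) or vdf <= 0:
            lo1 = hi1 = est1
        else:
            f_lo = stats.f.ppf(1 - alpha / 2, df1, vdf)
            f_hi = stats.f.ppf(1 - alpha / 2, vdf, df1)
            lo1 = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi1 = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr
            )
        if model == "icc2_1":
            est, lo, hi = est1, lo1, hi1
        else:
            sb = lambda r: k * r / (1.0 + (k - 1) * r)
            est, lo, hi = sb(est1), sb(lo1), sb(hi1)
    else:
        if mse <= 0:
            est = 1.0
            lo = hi = 1.0
        else:
            f_obs = msr / mse
            fl = f_obs / fq
            fu = f_obs * fq_rev
            if model == "icc3_1":
                est = (msr - mse) / (msr + (k - 1) * mse)
                lo = (fl - 1.0) / (fl + k - 1.0)
                hi = (fu - 1.0) / (fu + k - 1.0)
            else:
                est = (msr - mse) / msr
                lo = 1.0 - 1.0 / fl
                hi = 1.0 - 1.0 / fu

    if mse <= 0:
        p = 0.0
        lo, hi = est, est
    else:
        p = float(stats.f.sf(msr / mse, df1, df2))
    lo = float(min(lo, est))
    hi = float(max(hi, est))
    labels = {
        "icc2_1": "two-way random, absolute agreement, single measure",
        "icc2_k": "two-way random, absolute agreement, average measure",
        "icc3_1": "two-way mixed, consistency, single measure",
        "icc3_k": "two-way mixed, consistency, average measure",
    }
    return IccResult(
        estimate=float(est),
        ci_low=lo,
        ci_high=hi,
        model=labels[model],
        p_value=p,
        mean_squares={"msr": msr, "msc": msc, "mse": mse},
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts of referral decisions against the expert reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            c = getattr(self, name)
            if not isinstance(c, (int, np.integer)) or c < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {c!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_percent(proportion: float | None) -> float | None:
    """Render a proportion as a percentage rounded to one decimal,
    half away from zero (so 0.94642 -> 94.6, 0.9465 -> 94.7)."""
    if proportion is None:
        return None
    return float(
        Decimal(repr(proportion * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class Metric:
    """One accuracy metric: proportion, Wilson 95% interval and the
    one-decimal percentage.  All fields are None when the defining ratio
    has a zero denominator (not-applicable, never coerced to 0 or 1)."""

    proportion: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def percent(self) -> float | None:
        return round_percent(self.proportion)

    @property
    def applicable(self) -> bool:
        return self.proportion is not None


def _metric(numerator: int, denominator: int) -> Metric:
    if denominator == 0:
        return Metric(None, None, None)
    p = numerator / denominator
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    # guard against float noise at the boundaries (e.g. 53/53 -> hi 1 - 1e-16)
    return Metric(p, min(float(lo), p), max(float(hi), p))


@dataclass(frozen=True)
class AccuracyResult:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    counts: ConfusionCounts


def diagnostic_accuracy(c: ConfusionCounts) -> AccuracyResult:
    """Sensitivity, specificity, PPV and NPV with Wilson 95% intervals.

    Zero-denominator metrics come back not-applicable (``Metric`` of
    Nones) rather than 0 or 1.
    """
    return AccuracyResult(
        sensitivity=_metric(c.tp, c.tp + c.fn),
        specificity=_metric(c.tn, c.tn + c.fp),
        ppv=_metric(c.tp, c.tp + c.fp),
        npv=_metric(c.tn, c.tn + c.fn),
        counts=c,
    )


def confusion_at_threshold(
    scores: list[tuple[float, bool]], threshold: float
) -> ConfusionCounts:
    """Count referrals (score >= threshold, inclusive) against expert labels."""
    tp = fp = fn = tn = 0
    for total, label in scores:
        refer = total >= threshold
        if label:
            tp, fn = tp + int(refer), fn + int(not refer)
        else:
            fp, tn = fp + int(refer), tn + int(not refer)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ThresholdSweep:
    table: pd.DataFrame
    results: dict[float, tuple[ConfusionCounts, AccuracyResult]]
    selected_threshold: float | None  # safety-first selection, see sweep_thresholds


def sweep_thresholds(
    scores: list[tuple[float, bool]],
    thresholds: list[float] = (14, 16, 18, 20),
) -> ThresholdSweep:
    """Evaluate referral accuracy over candidate thresholds.

    ``scores`` pairs each subject's final total with the expert referral
    label.  One row per threshold (inclusive comparison).  The selected
    threshold implements the safety-first rule -- never miss an
    expert-positive while minimizing over-referral: since sensitivity is
    non-increasing and specificity non-decreasing in the threshold, that is
    the LARGEST candidate still achieving sensitivity 1 (None when no
    candidate does).

    Raises
    ------
    ValueError
        If the labels are degenerate (all positive or all negative), which
        leaves sensitivity or specificity undefined at every threshold.
    """
    if not scores:
        raise ValueError("empty score list")
    labels = [bool(lbl) for _, lbl in scores]
    if all(labels) or not any(labels):
        raise ValueError(
            "degenerate expert labels (all one class): need at least one "
            "positive and one negative"
        )
    if len(thresholds) == 0:
        raise ValueError("no thresholds supplied")

    rows = []
    results: dict[float, tuple[ConfusionCounts, AccuracyResult]] = {}
    selected = None
    for t in sorted(thresholds):
        c = confusion_at_threshold(scores, t)
        acc = diagnostic_accuracy(c)
        results[t] = (c, acc)
        sens = acc.sensitivity.proportion
        if sens is not None and sens == 1.0:
            selected = t  # thresholds ascend, so this ends at the largest
        rows.append(
            {
                "threshold": t,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "tn": c.tn,
                "sensitivity": sens,
                "specificity": acc.specificity.proportion,
                "ppv": acc.ppv.proportion,
                "npv": acc.npv.proportion,
            }
        )
    return ThresholdSweep(
        table=pd.DataFrame(rows), results=results, selected_threshold=selected
    )
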