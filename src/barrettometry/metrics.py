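"""Evaluation statistics for automated vs reference Barrett's measurements:
absolute difference, relative error, RMSE, Cohen's kappa on Prague categories,
Spearman correlation and paired t-tests, plus a dataset-level report."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .quantification import to_prague_category


@dataclass
class PairedSeries:
    """Reference (ground truth / expert) vs automated values for one unit."""

    reference: np.ndarray
    automated: np.ndarray
    unit: str = ""
    categories_reference: list[str] | None = None
    categories_automated: list[str] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.automated = np.asarray(self.automated, dtype=np.float64)
        if self.reference.shape != self.automated.shape or self.reference.size < 1:
            raise ValueError("reference and automated series must match, n >= 1")

    @property
    def differences(self) -> np.ndarray:
        return self.automated - self.reference


def relative_error(auto: float | np.ndarray, ref: float | np.ndarray,
                   as_percent: bool = False):
    """|auto - ref| / ref; NaN where ref == 0 (zero-length markers are
    excluded from aggregates and counted separately)."""
    auto = np.asarray(auto, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ref > 0, np.abs(auto - ref) / ref, np.nan)
    if as_percent:
        out = out * 100.0
    return float(out) if out.ndim == 0 else out


def rmse(series: PairedSeries | np.ndarray) -> float:
    """Root mean square of the paired differences."""
    d = series.differences if isinstance(series, PairedSeries) else np.asarray(series)
    return float(np.sqrt(np.mean(np.square(d))))


def cohen_kappa(categories_ref, categories_auto) -> tuple[float, bool]:
    """Unweighted Cohen's kappa; ``(value, degenerate)``.

    When both raters use a single category, chance agreement is 1 and kappa is
    undefined; it is reported as 1 for perfect agreement else 0, flagged.
    """
    ref = list(categories_ref)
    auto = list(categories_auto)
    if len(ref) != len(auto) or not ref:
        raise ValueError("category sequences must be equal length, n >= 1")
    if len(set(ref)) == 1 and len(set(auto)) == 1:
        return (1.0 if ref == auto else 0.0), True
    return float(cohen_kappa_score(ref, auto)), False


def spearman(series: PairedSeries) -> tuple[float, bool]:
    """Spearman rank correlation; ``(value, degenerate)`` (NaN when constant)."""
    if series.reference.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(series.reference) == 0 or np.ptp(series.automated) == 0:
        return float("nan"), True
    r = sps.spearmanr(series.reference, series.automated).statistic
    return float(r), False


def paired_t(series: PairedSeries) -> tuple[float, float, bool]:
    """Two-sided paired t-test on (automated - reference): ``(t, p, degenerate)``."""
    if series.reference.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = series.differences
    if np.allclose(d, d[0]):
        return float("nan"), float("nan"), True
    res = sps.ttest_rel(series.automated, series.reference)
    return float(res.statistic), float(res.pvalue), False


@dataclass
class EvalReport:
    """Per-marker and aggregate agreement statistics, Table-style."""

    labels: list[str]
    reference: np.ndarray
    automated: np.ndarray
    abs_difference: np.ndarray
    relative_error_pct: np.ndarray
    mean_abs_difference: float
    mean_relative_error_pct: float
    accuracy_pct: float
    rmse: float
    kappa: float | None = None
    kappa_degenerate: bool = False
    spearman_r: float | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    n: int = 0
    n_excluded_zero_ref: int = 0
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Per-marker table mirroring the ground-truth / automated / error layout."""
        df = pd.DataFrame(
            {
                "marker": self.labels,
                "ground_truth": self.reference,
                "automated": self.automated,
                "abs_difference": self.abs_difference,
                "relative_error_pct": self.relative_error_pct,
            }
        )
        overall = pd.DataFrame(
            {
                "marker": ["overall"],
                "ground_truth": [np.mean(self.reference)],
                "automated": [np.mean(self.automated)],
                "abs_difference": [self.mean_abs_difference],
                "relative_error_pct": [self.mean_relative_error_pct],
            }
        )
        return pd.concat([df, overall], ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_abs_difference": self.mean_abs_difference,
            "mean_relative_error_pct": self.mean_relative_error_pct,
            "accuracy_pct": self.accuracy_pct,
            "rmse": self.rmse,
            "kappa": self.kappa,
            "spearman_r": self.spearman_r,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_excluded_zero_ref": self.n_excluded_zero_ref,
            "flags": list(self.flags),
        }


def evaluate_dataset(
    automated,
    reference,
    labels: list[str] | None = None,
    unit: str = "",
    category_scale: float = 1.0,
) -> EvalReport:
    """Full evaluation of paired automated vs reference measurements.

    ``category_scale`` converts values to cm before Prague binning (e.g. 0.1
    for mm inputs); categories feed Cohen's kappa.  Markers with zero
    reference are excluded from relative-error means and counted separately.
    """
    auto = np.asarray(automated, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if auto.shape != ref.shape or auto.size < 1:
        raise ValueError("automated and reference lengths differ or empty")
    labels = labels or [f"marker_{i}" for i in range(auto.size)]
    if len(labels) != auto.size:
        raise ValueError("label count mismatch")

    flags: list[str] = []
    absdiff = np.abs(auto - ref)
    relerr = relative_error(auto, ref, as_percent=True)
    zero_ref = ~np.isfinite(relerr)
    mean_rel = float(np.nanmean(relerr)) if (~zero_ref).any() else float("nan")

    series = PairedSeries(ref, auto, unit=unit)
    kappa = spearman_r = t_stat = p_val = None
    kappa_degen = False
    if auto.size >= 2:
        cats_ref = [to_prague_category(max(v, 0.0) * category_scale) for v in ref]
        cats_auto = [to_prague_category(max(v, 0.0) * category_scale) for v in auto]
        kappa, kappa_degen = cohen_kappa(cats_ref, cats_auto)
        if kappa_degen:
            flags.append("kappa_degenerate")
        t_stat, p_val, t_degen = paired_t(series)
        if t_degen:
            flags.append("t_test_degenerate")
            t_stat = p_val = None
    else:
        flags.append("n_too_small_for_agreement")
    if auto.size >= 3:
        spearman_r, sp_degen = spearman(series)
        if sp_degen:
            flags.append("spearman_degenerate")
            spearman_r = None

    return EvalReport(
        labels=list(labels),
        reference=ref,
        automated=auto,
        abs_difference=absdiff,
        relative_error_pct=relerr,
        mean_abs_difference=float(absdiff.mean()),
        mean_relative_error_pct=mean_rel,
        accuracy_pct=100.0 - mean_rel if np.isfinite(mean_rel) else float("nan"),
        rmse=rmse(series),
        kappa=kappa,
        kappa_degenerate=kappa_degen,
        spearman_r=spearman_r,
        t_statistic=t_stat,
        p_value=p_val,
        n=int(auto.size),
        n_excluded_zero_ref=int(zero_ref.sum()),
        flags=flags,
    )
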