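"""Differential expression, correlation utilities and qPCR quantification.

DE follows the chipset convention: features are log2 intensities, the effect
size is the difference of group means (log2 fold change), significance comes
from Welch's unequal-variance two-sample t test, and a feature is called
up/down when |log2FC| exceeds log2(fold-change threshold) AND the raw P is
below the P threshold (fold change > 2, P < 0.05 by default).  BH-adjusted
q values are reported alongside but do not drive the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionBundle, SampleDesign  # noqa: F401  (re-export context)


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a zero-variance vector."""


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(matrix: pd.DataFrame, design: SampleDesign, group_a: str,
             group_b: str, fc_thresh: float = 2.0,
             p_thresh: float = 0.05) -> pd.DataFrame:
    """Per-feature Welch DE of ``group_a`` versus ``group_b``.

    ``log2fc`` is mean(A) − mean(B) of the log2 values, so with the default
    fold-change threshold 2.0 a call requires |log2fc| > 1.  Zero-variance
    features with equal group means get p = 1 (no evidence, not an error).
    """
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ValueError("thresholds must be positive")
    a = matrix[design.samples_in(group_a)].to_numpy(dtype=float)
    b = matrix[design.samples_in(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >=2 samples")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    # zero variance in both groups: identical means -> p=1; else p -> 0 limit
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    lfc_cut = np.log2(fc_thresh)
    status = np.where((log2fc > lfc_cut) & (p < p_thresh), "up",
                      np.where((log2fc < -lfc_cut) & (p < p_thresh), "down", "ns"))
    return pd.DataFrame({
        "feature_id": matrix.index,
        "log2fc": log2fc,
        "p": p,
        "q": bh_adjust(p),
        "status": status,
    }).set_index("feature_id")


def de_counts(de: pd.DataFrame) -> dict[str, int]:
    """Counts of up/down/ns calls in a DE table."""
    vc = de["status"].value_counts()
    return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates (log2fc, −log10 p) plus status, one row per feature.

    p = 0 (test underflow) is clamped to the smallest positive float for the
    display axis only, with a warning; the DE table's p is left untouched.
    """
    p = de["p"].to_numpy(dtype=float).copy()
    if (p == 0).any():
        warnings.warn("p=0 clamped to the smallest positive float for -log10 display")
        p[p == 0] = np.nextafter(0, 1)
    return pd.DataFrame({
        "log2fc": de["log2fc"],
        "neg_log10_p": -np.log10(p),
        "status": de["status"],
    }, index=de.index)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n: int
    method: str

    def __post_init__(self):
        if abs(self.r_squared - self.r ** 2) > 1e-12:
            raise ValueError("r_squared must equal r**2")


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p value.

    Spearman is Pearson on average ranks (scipy convention).  Zero variance
    in either vector raises ``UndefinedCorrelationError`` rather than passing
    a NaN downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a finite p value")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), len(x), method)


@dataclass(frozen=True)
class QPCRMeasurement:
    """Paired cycle thresholds for one target/reference gene in case vs control."""

    ct_target_case: float
    ct_ref_case: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self):
        for v in (self.ct_target_case, self.ct_ref_case,
                  self.ct_target_control, self.ct_ref_control):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("all Ct values must be finite and > 0")


def delta_delta_ct(m: QPCRMeasurement) -> float:
    """Relative expression 2^(−ΔΔCt).

    ΔΔCt = (Ct_target − Ct_reference)_case − (Ct_target − Ct_reference)_control;
    the reference is a housekeeping gene such as β-actin.  Always positive.
    """
    ddct = (m.ct_target_case - m.ct_ref_case) - (m.ct_target_control - m.ct_ref_control)
    return float(2.0 ** (-ddct))
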