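"""Signature-based immune-fraction deconvolution.

Estimates the cell-type composition of a bulk expression profile as a
non-negative combination of reference signatures, solved by non-negative
least squares (NNLS) on the genes shared between bulk and signature, then
renormalised to the simplex (absolute abundances are not identifiable
without a scale anchor).  This is the standard transparent surrogate for
signature-deconvolution tools built on ν-SVR; the method tag records it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .diffexp import CorrelationResult, correlate
from .simulate import SampleDesign, SignatureMatrix

MIN_SHARED_GENES = 10


@dataclass(frozen=True)
class DeconvolutionResult:
    """Per-sample cell-type fractions (rows sum to 1) plus fit residuals."""

    fractions: pd.DataFrame      # samples × cell types
    residual_norm: pd.Series     # per sample, on the shared-gene subspace
    method: str = "nnls"

    def __post_init__(self):
        if (self.fractions.to_numpy() < 0).any():
            raise ValueError("fractions must be non-negative")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("fractions must sum to 1 per sample")


def deconvolve(bulk, signature: SignatureMatrix) -> DeconvolutionResult:
    """NNLS deconvolution of one or more bulk profiles.

    ``bulk`` is a Series (one sample) or DataFrame (genes × samples) indexed
    by gene id; at least 10 genes must intersect the signature.  Fractions
    are scale-invariant in the bulk: multiplying a profile by c > 0 leaves
    them unchanged.
    """
    if isinstance(bulk, pd.Series):
        bulk = bulk.to_frame(name="sample_1")
    shared = bulk.index.intersection(signature.data.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared with the signature "
            f"(need >= {MIN_SHARED_GENES})")
    B = bulk.loc[shared].to_numpy(dtype=float)
    if (B < 0).any():
        raise ValueError("bulk expression must be non-negative")
    A = signature.data.loc[shared].to_numpy(dtype=float)
    fracs, resids = [], []
    for j in range(B.shape[1]):
        coef, rnorm = nnls(A, B[:, j])
        total = coef.sum()
        if total == 0:
            raise ValueError(
                f"degenerate bulk profile {bulk.columns[j]!r}: NNLS fit is zero")
        fracs.append(coef / total)
        resids.append(rnorm)
    fractions = pd.DataFrame(fracs, index=list(bulk.columns),
                             columns=signature.cell_types)
    return DeconvolutionResult(fractions,
                               pd.Series(resids, index=list(bulk.columns)))


def fractions_vs_severity(result: DeconvolutionResult, design: SampleDesign,
                          cell_type: str, clinical_score) -> tuple[CorrelationResult, pd.DataFrame]:
    """Spearman association of one cell type's fraction with a clinical score.

    ``clinical_score`` is aligned to the design's samples (e.g. a GCS-like
    score, which *decreases* with severity).  Also returns the per-group
    mean fraction table for all cell types.
    """
    if cell_type not in result.fractions.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    frac = result.fractions.loc[list(design.sample_ids), cell_type]
    score = np.asarray(clinical_score, dtype=float)
    if len(score) != len(design.sample_ids):
        raise ValueError("clinical_score must align with the design samples")
    corr = correlate(frac.to_numpy(), score, method="spearman")
    means = (result.fractions.loc[list(design.sample_ids)]
             .groupby(pd.Series(design.groups, index=list(design.sample_ids)))
             .mean())
    return corr, means
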