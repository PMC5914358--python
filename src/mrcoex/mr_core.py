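"""Mutual-rank coexpression index and its logit transformation.

The pipeline is: Pearson correlation matrix -> per-guide-gene correlation
ranks -> mutual rank MR_ij = sqrt(R_ij * R_ji). Rank 1 is the most
positively correlated partner and rank N-1 the most negatively correlated
one, so small MR means strong (positive) coexpression. MR lies in
[1, N-1] for a network of N genes.

The range-standardized MR, p = MR / N, lies strictly inside (0, 1) and its
logit, log(p / (1 - p)), plays the role the Fisher z-transform plays for
the correlation coefficient: on the logit scale the bootstrap error of MR
is approximately normal with a constant SD across the whole MR range,
which is what makes averaging and confidence intervals for MR tractable.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _logit
from scipy.stats import rankdata

from .types import ExpressionMatrix, MRMatrix

__all__ = [
    "pearson_matrix",
    "correlation_ranks",
    "mutual_rank",
    "mr_from_expression",
    "logit_mr",
    "inverse_logit_mr",
]


def pearson_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """All-pairs Pearson correlation (genes x genes; diagonal 1).

    Requires >= 3 samples and no zero-variance genes (PCC undefined).
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {expr.n_samples}")
    sd = expr.values.std(axis=1)
    bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
    if bad:
        raise ValueError(f"zero-variance genes (drop them first): {bad[:10]}")
    r = np.corrcoef(expr.values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_ranks(corr: np.ndarray) -> np.ndarray:
    """Rank each guide gene's partners by descending correlation.

    Row i ranks the non-self entries of corr[i]: the most positive
    correlation gets rank 1, the most negative rank N-1. Ties receive the
    average of the tied positions (fractional ranks), so the result is
    deterministic and permutation-invariant. The diagonal is NaN.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n):
        raise ValueError(f"correlation matrix must be square, got {corr.shape}")
    if n >= 2 and not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix is not symmetric")
    work = corr.copy()
    # Self-correlation is excluded from the ranking: pin it past every
    # real entry so the remaining ranks run 1..N-1.
    np.fill_diagonal(work, -np.inf)
    ranks = rankdata(-work, axis=1, method="average")
    np.fill_diagonal(ranks, np.nan)
    return ranks


def mutual_rank(ranks: np.ndarray) -> np.ndarray:
    """MR_ij = sqrt(R_ij * R_ji): geometric mean of the reciprocal ranks.

    Symmetric by construction; each entry lies between min(R_ij, R_ji)
    and max(R_ij, R_ji), hence in [1, N-1]. Diagonal is NaN.
    """
    ranks = np.asarray(ranks, dtype=float)
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, np.nan)
    return mr


def mr_from_expression(expr: ExpressionMatrix) -> MRMatrix:
    """Convenience composition: PCC -> ranks -> mutual rank."""
    mr = mutual_rank(correlation_ranks(pearson_matrix(expr)))
    return MRMatrix(gene_ids=list(expr.gene_ids), values=mr, n_genes=expr.n_genes)


def logit_mr(mr, n_genes: int):
    """logit(MR / N) = log(p / (1 - p)) with p = MR / N.

    Strictly increasing in MR; defined for 0 < MR < N. With the
    standardization p = (r + 1) / 2 of a correlation coefficient the same
    formula gives log((1 + r) / (1 - r)) = 2 * artanh(r), i.e. twice the
    Fisher transform — the MR version applies the identical mechanism to
    the rank scale.
    """
    if n_genes < 3:
        raise ValueError(f"need N >= 3 genes, got {n_genes}")
    mr = np.asarray(mr, dtype=float)
    with np.errstate(invalid="ignore"):
        inside = (mr > 0) & (mr < n_genes)
    if not np.all(inside | np.isnan(mr)):
        bad = mr[~(inside | np.isnan(mr))]
        raise ValueError(f"MR values outside (0, N={n_genes}): {bad.flat[:5]}")
    out = _logit(mr / n_genes)
    return float(out) if out.ndim == 0 else out


def inverse_logit_mr(z, n_genes: int):
    """Back-transform a logit value to the MR scale: N * sigmoid(z)."""
    out = n_genes * expit(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out
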