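"""Integration of multiple MR values and MR confidence intervals.

Because the logit-transformed MR error is approximately normal with a
constant SD, a set of MR values is combined by averaging on the logit
scale and back-transforming. For k MR values MR_1..MR_k with weights
w_1..w_k (sum 1) on a platform of N genes the weighted logit average is

    MR_avg = N * prod(MR_i^w_i) / (prod((N - MR_i)^w_i) + prod(MR_i^w_i)),

which is identical to sigmoid(sum_i w_i * logit(MR_i / N)) * N. For
MR_i << N the denominator's first product dominates and the expression
approaches the plain weighted geometric mean prod(MR_i^w_i). The
equal-weight special case (w_i = 1/k) is the average used to merge the
coexpression lists of several query genes.

Confidence intervals use the logit-normal error model: the interval for
an observed MR with logit-scale SD sigma is the back-transform of
logit(MR/N) +/- z * sigma with a standard normal quantile z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .mr_core import inverse_logit_mr, logit_mr

logger = logging.getLogger(__name__)

__all__ = [
    "MRQuery",
    "MRInterval",
    "weighted_logit_average",
    "geometric_mean_mr",
    "coexsearch_average",
    "mr_confidence_interval",
    "interval_contains_top_edges",
]


@dataclass
class MRQuery:
    """k MR values with normalized positive weights, on an N-gene platform."""

    mr_values: np.ndarray
    weights: np.ndarray
    n_genes: int

    def __init__(self, mr_values, weights=None, n_genes: int = 0):
        self.mr_values = np.atleast_1d(np.asarray(mr_values, dtype=float))
        k = self.mr_values.size
        if k < 1:
            raise ValueError("need at least one MR value")
        if n_genes < 3:
            raise ValueError(f"need N >= 3 genes, got {n_genes}")
        self.n_genes = int(n_genes)
        if np.any(self.mr_values <= 0) or np.any(self.mr_values >= n_genes):
            raise ValueError(f"MR values must lie strictly in (0, N={n_genes})")
        if weights is None:
            self.weights = np.full(k, 1.0 / k)
        else:
            w = np.atleast_1d(np.asarray(weights, dtype=float))
            if w.size != k:
                raise ValueError(f"{w.size} weights for {k} MR values")
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            total = w.sum()
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"weights must sum to 1, got {total}")
            if total != 1.0:
                logger.warning("renormalizing weights (sum %.2e away from 1)", total - 1)
                w = w / total
            self.weights = w


@dataclass
class MRInterval:
    """Point MR with its logit-normal confidence bounds."""

    mr: float
    sigma: float
    level: float
    lower: float
    upper: float


def weighted_logit_average(query: MRQuery) -> float:
    """Weighted logit average of MR values (fixed point at equal inputs).

    Evaluated in log space: with L = sum w_i*log(MR_i) and
    M = sum w_i*log(N - MR_i), the result is N * sigmoid(L - M), which
    never overflows however large k is.
    """
    mr, w, n = query.mr_values, query.weights, query.n_genes
    log_num = float(np.dot(w, np.log(mr)))
    log_den = float(np.dot(w, np.log(n - mr)))
    return float(n * expit(log_num - log_den))


def geometric_mean_mr(query: MRQuery) -> float:
    """Weighted geometric mean prod(MR_i^w_i): the MR << N limit of the
    logit average."""
    return float(np.exp(np.dot(query.weights, np.log(query.mr_values))))


def coexsearch_average(mr_values, n_genes: int) -> float:
    """Equal-weight logit average, used to merge several query genes'
    coexpression lists into one ranking. Order-invariant."""
    mr_values = np.atleast_1d(np.asarray(mr_values, dtype=float))
    if mr_values.size == 0:
        raise ValueError("empty MR list")
    return weighted_logit_average(MRQuery(mr_values, None, n_genes))


def mr_confidence_interval(
    mr: float,
    sigma: float,
    n_genes: int,
    level: float = 0.90,
    quantile: float | None = None,
) -> MRInterval:
    """Two-sided MR interval under the logit-normal error model.

    ``sigma`` is the bootstrap SD of logit-MR (the logit-MR error). The
    multiplier is the standard normal quantile z_{(1+level)/2} (1.6449
    for the default 90% level) unless ``quantile`` overrides it.
    sigma = 0 collapses the interval to the point value.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if not (0 < mr < n_genes):
        raise ValueError(f"MR must lie in (0, N={n_genes}), got {mr}")
    z = norm.ppf(0.5 * (1.0 + level)) if quantile is None else float(quantile)
    center = logit_mr(mr, n_genes)
    lower = inverse_logit_mr(center - z * sigma, n_genes)
    upper = inverse_logit_mr(center + z * sigma, n_genes)
    return MRInterval(mr=float(mr), sigma=float(sigma), level=float(level),
                      lower=float(lower), upper=float(upper))


def interval_contains_top_edges(
    level: float,
    sigma: float,
    n_genes: int,
    mr: float = 100.0,
    edge_threshold: float = 300.0,
) -> dict:
    """Report whether an MR=100 gene's CI stays inside the default edge list.

    Coexpression browsers typically display the top ``edge_threshold``
    (default 300) partners; this checks whether the upper confidence
    bound of a gene at ``mr`` (default 100) still falls within that list.
    """
    ci = mr_confidence_interval(mr, sigma, n_genes, level)
    return {
        "mr": ci.mr,
        "sigma": ci.sigma,
        "level": ci.level,
        "lower": ci.lower,
        "upper": ci.upper,
        "edge_threshold": float(edge_threshold),
        "contained": bool(ci.upper <= edge_threshold),
    }
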