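"""Bootstrap analysis of the mutual-rank index over experimental units.

A coexpression compendium is a collection of experiments (batches), so the
natural resampling unit is the experiment: each bootstrap replicate draws
experiments with replacement, re-centers each draw as its own batch (two
draws of the same experiment are independent pseudo-experiments), and
recomputes the full correlation -> rank -> MR pipeline. Accumulating
per-pair moments across replicates yields, for every gene pair, the mean
and SD of MR and of logit-MR ("logit-MR error"), plus skewness/kurtosis
diagnostics of the error distribution on both scales.

Three downstream products:

* :func:`error_profile` — the SD field binned by MR percentile: on the raw
  MR scale the error peaks mid-range (uncorrelated pairs) and vanishes at
  both extremes, while on the logit scale it is approximately flat.
* :func:`bagged_mr` — the bagging estimate: the equal-weight logit average
  of the replicate MR matrices, a variance-reduced coexpression index.
* :func:`fit_error_model` — across platforms, mean logit-MR error falls
  linearly in log(sample count), so the error level of a platform can be
  predicted from its sample size alone. :data:`PLATFORM_SUMMARY` ships the
  published summary statistics of 16 public plant coexpression platforms
  (nine species; microarray and RNAseq compendia) used to anchor that
  relationship.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .mr_core import logit_mr, mr_from_expression
from .preprocess import batch_center, eb_batch_adjust
from .types import (
    BatchDesign,
    BootstrapSummary,
    ErrorModel,
    ErrorProfile,
    ExpressionMatrix,
    MRMatrix,
)

__all__ = [
    "bootstrap_mr",
    "bagged_mr",
    "error_profile",
    "error_moments",
    "fit_error_model",
    "PLATFORM_SUMMARY",
]

# Published per-platform summary statistics: 16 plant coexpression
# platforms (<species>-m = microarray, <species>-r = RNAseq compendium).
# Columns: total genes, samples, mean bootstrap SD of logit-MR, and the
# KEGG-based function score (partial AUROC at FPR 0.01, scaled by 1e4).
_PLATFORM_TSV = """\
platform	genes	samples	logit_mr_error	function_score
Ath-m	20819	16033	0.37	5.43
Ath-r	22760	2120	0.71	5.17
Bra-r	28978	188	1.04	4.77
Gma-m	15746	1131	0.74	3.37
Gma-r	8373	599	1.02	7.64
Mtr-m	20376	975	1.04	4.43
Mtr-r	3753	41	1.46	2.65
Osa-m	19867	2250	0.76	4.98
Osa-r	24437	336	1.07	4.06
Ppo-m	21910	765	1.10	3.82
Sly-m	5721	401	1.04	4.08
Sly-r	20564	282	1.01	3.87
Vvi-m	9421	314	1.14	4.47
Vvi-r	18587	346	0.90	3.10
Zma-m	10777	806	1.11	4.62
Zma-r	32274	1794	0.88	4.42
"""

PLATFORM_SUMMARY: pd.DataFrame = pd.read_csv(
    io.StringIO(_PLATFORM_TSV), sep="\t", index_col="platform"
)


def _resample(
    expr: ExpressionMatrix,
    design: BatchDesign,
    rng: np.random.Generator,
    unit: str,
) -> tuple[ExpressionMatrix, BatchDesign]:
    """One bootstrap draw of the compendium.

    ``unit="experiments"``: experiments drawn with replacement until the
    original experiment count is reached; each draw becomes a distinct
    batch. ``unit="samples"``: plain sample bootstrap keeping each
    sample's original batch label.
    """
    if unit == "experiments":
        exps = design.experiments
        draws = rng.integers(0, len(exps), size=len(exps))
        sample_ids: list[str] = []
        assignment: dict[str, str] = {}
        order: list[str] = []
        for d, ei in enumerate(draws):
            batch = f"b{d}"
            order.append(batch)
            for s in design.samples_of(exps[ei]):
                # subset_samples renames the k-th repeat of a sample to s#k
                k = sample_ids.count(s)
                sample_ids.append(s)
                name = s if k == 0 else f"{s}#{k}"
                assignment[name] = batch
        sub = expr.subset_samples(sample_ids)
        return sub, BatchDesign(assignment=assignment, experiments=order)
    if unit == "samples":
        draws = rng.integers(0, expr.n_samples, size=expr.n_samples)
        sample_ids = [expr.sample_ids[i] for i in draws]
        sub = expr.subset_samples(sample_ids)
        assignment = {
            s: design.experiment_of(s.split("#", 1)[0]) for s in sub.sample_ids
        }
        return sub, BatchDesign(assignment=assignment)
    raise ValueError(f"unknown resampling unit {unit!r}")


def _replicate_mr(
    expr: ExpressionMatrix,
    design: BatchDesign,
    rng: np.random.Generator,
    unit: str,
    batch_mode: str,
) -> np.ndarray:
    sub, sub_design = _resample(expr, design, rng, unit)
    if batch_mode == "center":
        adjusted = batch_center(sub, sub_design)
    elif batch_mode == "eb":
        adjusted = eb_batch_adjust(sub, sub_design)
    else:
        raise ValueError(f"unknown batch mode {batch_mode!r}")
    return mr_from_expression(adjusted).values


class _MomentAccumulator:
    """Streaming central moments M1..M4 of a stack of equal-shape arrays
    (Pebay's single-pass update), so B replicate matrices never need to
    be held at once."""

    def __init__(self, shape: tuple[int, ...]):
        self.n = 0
        self.m1 = np.zeros(shape)
        self.m2 = np.zeros(shape)
        self.m3 = np.zeros(shape)
        self.m4 = np.zeros(shape)

    def add(self, x: np.ndarray) -> None:
        n1 = self.n
        self.n = n = n1 + 1
        delta = x - self.m1
        d_n = delta / n
        d_n2 = d_n * d_n
        term1 = delta * d_n * n1
        self.m1 += d_n
        self.m4 += (
            term1 * d_n2 * (n * n - 3 * n + 3)
            + 6 * d_n2 * self.m2
            - 4 * d_n * self.m3
        )
        self.m3 += term1 * d_n * (n - 2) - 3 * d_n * self.m2
        self.m2 += term1

    @property
    def mean(self) -> np.ndarray:
        return self.m1

    def sd(self, ddof: int = 1) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(self.m2 / max(self.n - ddof, 1))

    def skewness(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(float(self.n)) * self.m3 / np.power(self.m2, 1.5)

    def excess_kurtosis(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.n * self.m4 / (self.m2 * self.m2) - 3.0


def bootstrap_mr(
    expr: ExpressionMatrix,
    design: BatchDesign,
    n_replicates: int = 100,
    seed: int = 0,
    resample_unit: str = "experiments",
    batch_mode: str = "center",
) -> BootstrapSummary:
    """Bootstrap the MR network over experimental units.

    Each of the ``n_replicates`` (paper-scale default 100) replicates
    resamples the compendium, re-runs batch correction and the full
    PCC -> rank -> MR pipeline, and feeds the MR matrix (and its logit)
    into streaming moment accumulators. Deterministic given ``seed``;
    per-replicate substreams are spawned from one SeedSequence.
    """
    design.validate_against(expr)
    if len(design.experiments) < 2 and resample_unit == "experiments":
        raise ValueError("bootstrap over experiments needs >= 2 experiments")
    if n_replicates < 2:
        raise ValueError(f"need >= 2 replicates, got {n_replicates}")

    n = expr.n_genes
    acc_mr = _MomentAccumulator((n, n))
    acc_logit = _MomentAccumulator((n, n))
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for ss in streams:
        mr = _replicate_mr(expr, design, np.random.default_rng(ss), resample_unit,
                           batch_mode)
        np.fill_diagonal(mr, 1.0)  # placeholder; diagonal re-masked below
        acc_mr.add(mr)
        acc_logit.add(logit_mr(mr, n))

    def _mask(mat: np.ndarray) -> np.ndarray:
        np.fill_diagonal(mat, np.nan)
        return mat

    has_moments = n_replicates >= 4
    return BootstrapSummary(
        gene_ids=list(expr.gene_ids),
        n_genes=n,
        n_replicates=n_replicates,
        seed=seed,
        mean_mr=_mask(acc_mr.mean.copy()),
        sd_mr=_mask(acc_mr.sd()),
        mean_logit_mr=_mask(acc_logit.mean.copy()),
        sd_logit_mr=_mask(acc_logit.sd()),
        skew_mr=_mask(acc_mr.skewness()) if has_moments else None,
        kurtosis_mr=_mask(acc_mr.excess_kurtosis()) if has_moments else None,
        skew_logit_mr=_mask(acc_logit.skewness()) if has_moments else None,
        kurtosis_logit_mr=_mask(acc_logit.excess_kurtosis()) if has_moments else None,
    )


def bagged_mr(
    expr: ExpressionMatrix,
    design: BatchDesign,
    n_replicates: int = 100,
    seed: int = 0,
    resample_unit: str = "experiments",
    batch_mode: str = "center",
    aggregate: str = "logit",
) -> MRMatrix:
    """Bagging MR: aggregate of the replicate MR matrices.

    ``aggregate="logit"`` (default) takes the equal-weight logit average —
    the mean of logit-MR back-transformed to the MR scale — consistent
    with how MR values are integrated elsewhere; ``"mean"`` gives the
    plain arithmetic mean for comparison. Values lie in (0, N); a single
    replicate returns that replicate unchanged.
    """
    design.validate_against(expr)
    if len(design.experiments) < 2 and resample_unit == "experiments":
        raise ValueError("bagging over experiments needs >= 2 experiments")
    if n_replicates < 1:
        raise ValueError(f"need >= 1 replicate, got {n_replicates}")
    if aggregate not in ("logit", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    n = expr.n_genes
    total = np.zeros((n, n))
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for ss in streams:
        mr = _replicate_mr(expr, design, np.random.default_rng(ss), resample_unit,
                           batch_mode)
        np.fill_diagonal(mr, 1.0)
        total += logit_mr(mr, n) if aggregate == "logit" else mr
    total /= n_replicates
    from .mr_core import inverse_logit_mr

    values = inverse_logit_mr(total, n) if aggregate == "logit" else total
    np.fill_diagonal(values, np.nan)
    return MRMatrix(gene_ids=list(expr.gene_ids), values=values, n_genes=n)


def _percentile_bins(summary: BootstrapSummary, bin_width: float):
    mean = summary.offdiag("mean_mr")
    order = np.argsort(np.argsort(mean, kind="stable"), kind="stable")
    pct = (order + 1) / mean.size  # percentile in (0, 1]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.ceil(pct / bin_width).astype(int) - 1, 0, n_bins - 1)
    return pct, idx, edges, n_bins


def error_profile(
    summary: BootstrapSummary,
    bin_width: float = 0.01,
    scale: str = "logit",
) -> ErrorProfile:
    """Bin the bootstrap SD by the percentile of the mean bootstrap MR.

    Non-overlapping bins of width ``bin_width`` (default 0.01, i.e. 100
    bins) partition the percentile axis; each bin reports the median and
    first/third quartiles of the SD of MR (``scale="mr"``) or of logit-MR
    (``scale="logit"``). Empty bins carry NaN.
    """
    if scale not in ("mr", "logit"):
        raise ValueError(f"unknown scale {scale!r}")
    if not (0 < bin_width <= 1):
        raise ValueError(f"bin width must be in (0, 1], got {bin_width}")
    sd = summary.offdiag("sd_mr" if scale == "mr" else "sd_logit_mr")
    _, idx, edges, n_bins = _percentile_bins(summary, bin_width)

    median = np.full(n_bins, np.nan)
    q1 = np.full(n_bins, np.nan)
    q3 = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vals = sd[idx == b]
        counts[b] = vals.size
        if vals.size:
            q1[b], median[b], q3[b] = np.percentile(vals, [25, 50, 75])
    return ErrorProfile(bin_edges=edges, median=median, q1=q1, q3=q3,
                        counts=counts, scale=scale, bin_width=bin_width)


def error_moments(
    summary: BootstrapSummary,
    scale: str = "logit",
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Per-bin skewness and excess kurtosis of the bootstrap deviations.

    Aggregates the per-pair sample skewness and excess kurtosis of the
    replicate values by MR-percentile bin (median across pairs). Near 0
    on the logit scale — where the error is approximately normal — but
    not on the raw MR scale. Requires B >= 4 replicates.
    """
    if scale not in ("mr", "logit"):
        raise ValueError(f"unknown scale {scale!r}")
    if summary.skew_mr is None:
        raise ValueError("moment diagnostics need >= 4 bootstrap replicates")
    skew = summary.offdiag("skew_mr" if scale == "mr" else "skew_logit_mr")
    kurt = summary.offdiag(
        "kurtosis_mr" if scale == "mr" else "kurtosis_logit_mr"
    )
    _, idx, edges, n_bins = _percentile_bins(summary, bin_width)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_pairs": int(mask.sum()),
                "skewness": float(np.nanmedian(skew[mask])) if mask.any() else np.nan,
                "excess_kurtosis": float(np.nanmedian(kurt[mask])) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_error_model(points) -> ErrorModel:
    """Least-squares line of logit-MR error on log(sample count).

    ``points`` is an iterable of (sample_count, mean logit-MR error)
    pairs, one per platform; needs >= 3 points with distinct counts. The
    stored ``pearson_r`` is the correlation between log(count) and error.
    Fitted on :data:`PLATFORM_SUMMARY` the relationship predicts an error
    near 1 for a 500-sample compendium.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (sample_count, error) points")
    x = np.log(pts[:, 0])
    y = pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("sample counts are all identical; cannot fit")
    slope, intercept = np.polyfit(x, y, 1)
    r = pearsonr(x, y).statistic
    return ErrorModel(intercept=float(intercept), slope=float(slope),
                      pearson_r=float(r))
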