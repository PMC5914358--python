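"""Expression preprocessing: log transform, batch centering, empirical-Bayes
batch adjustment, and probe-to-gene resolution.

Coexpression compendia aggregate many independent experiments, so the
experiment is treated as the batch unit throughout. Batch handling comes in
two strengths:

* :func:`batch_center` — subtract each gene's per-experiment mean
  (zero-centering), the classical correction.
* :func:`eb_batch_adjust` — a one-step parametric empirical-Bayes
  location/scale adjustment in the spirit of ComBat: per-gene per-batch
  location and scale effects are shrunk toward across-gene priors (normal
  for location, inverse-gamma for scale) before removal. A full external
  ComBat implementation can be substituted wherever this function is used,
  since only the adjusted matrix flows downstream.

Both return per-gene centered matrices; Pearson correlation is invariant to
per-gene location, so this choice does not affect the coexpression network.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import BatchDesign, ExpressionMatrix, ProbeMap

logger = logging.getLogger(__name__)

__all__ = [
    "log_transform",
    "batch_center",
    "eb_batch_adjust",
    "drop_zero_variance",
    "select_probe",
    "average_probes",
]

DEFAULT_PSEUDOCOUNT = 0.125


def log_transform(
    expr: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ExpressionMatrix:
    """log2(v + pseudocount) of a raw-scale matrix.

    The pseudocount (default 0.125, i.e. log2 -> -3 at zero) keeps zero
    counts finite while leaving moderate expression values essentially
    unchanged.
    """
    if expr.scale != "raw":
        raise ValueError(f"log_transform expects a raw-scale matrix, got {expr.scale!r}")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    neg = np.argwhere(expr.values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            "negative expression value "
            f"{expr.values[i, j]} at gene {expr.gene_ids[i]!r}, "
            f"sample {expr.sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=np.log2(expr.values + pseudocount),
        scale="log2",
    )


def _batch_columns(expr: ExpressionMatrix, design: BatchDesign) -> dict[str, np.ndarray]:
    """Experiment -> column-index array, in design experiment order.

    Samples whose IDs carry a ``#k`` suffix (bootstrap-duplicated
    experiments) are resolved through their own design entry.
    """
    design.validate_against(expr)
    cols: dict[str, list[int]] = {e: [] for e in design.experiments}
    for j, s in enumerate(expr.sample_ids):
        cols[design.experiment_of(s)].append(j)
    return {e: np.asarray(ix, dtype=int) for e, ix in cols.items() if ix}


def batch_center(expr: ExpressionMatrix, design: BatchDesign) -> ExpressionMatrix:
    """Subtract each gene's mean within each experiment (batch zero-centering)."""
    if expr.scale != "log2":
        raise ValueError("batch_center expects log2-scale expression")
    out = expr.values.copy()
    for _, ix in _batch_columns(expr, design).items():
        out[:, ix] -= out[:, ix].mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=out,
        scale="log2",
    )


def eb_batch_adjust(
    expr: ExpressionMatrix,
    design: BatchDesign,
    mode: str = "location_scale",
    shrink: bool = True,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment (simplified ComBat).

    Per gene the matrix is standardized by its pooled residual SD; per
    batch the location effect gamma and (in ``location_scale`` mode) the
    squared scale effect delta^2 are estimated and shrunk toward priors
    fitted across genes by the method of moments — normal for gamma,
    inverse-gamma for delta^2 — then removed:
    ``z* = (z - gamma*) / delta*``.

    With ``shrink=False`` and ``mode="location_only"`` the adjustment
    reduces exactly to :func:`batch_center`. Batches with a single sample
    cannot support a scale estimate and silently fall back to
    location-only (with a logged warning). Zero-variance genes are passed
    through unchanged.
    """
    if mode not in ("location_scale", "location_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if expr.scale != "log2":
        raise ValueError("eb_batch_adjust expects log2-scale expression")
    if not shrink and mode == "location_only":
        # No-shrinkage location adjustment is plain batch zero-centering.
        return batch_center(expr, design)
    cols = _batch_columns(expr, design)
    x = expr.values
    n_genes = x.shape[0]

    # Per-gene pooled residual SD after removing batch means.
    resid = x.copy()
    for ix in cols.values():
        resid[:, ix] -= x[:, ix].mean(axis=1, keepdims=True)
    pooled_sd = resid.std(axis=1, ddof=0)
    constant = pooled_sd <= 0
    safe_sd = np.where(constant, 1.0, pooled_sd)

    grand = x.mean(axis=1, keepdims=True)
    z = (x - grand) / safe_sd[:, None]

    out = np.empty_like(z)
    for batch, ix in cols.items():
        zb = z[:, ix]
        gamma_hat = zb.mean(axis=1)
        if shrink and n_genes > 1:
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
        else:
            gamma_bar, tau2 = 0.0, np.inf

        nb = len(ix)
        scale_here = mode == "location_scale" and nb >= 2
        if mode == "location_scale" and nb < 2:
            logger.warning(
                "batch %r has a single sample; falling back to location-only",
                batch,
            )

        if scale_here:
            delta2_hat = ((zb - gamma_hat[:, None]) ** 2).sum(axis=1) / (nb - 1)
            delta2_hat = np.maximum(delta2_hat, 1e-12)
            if shrink and n_genes > 2:
                # Inverse-gamma prior by moments: mean m, variance v across genes.
                m = delta2_hat.mean()
                v = delta2_hat.var(ddof=1)
                if v > 0:
                    lam = m * m / v + 2.0  # shape
                    theta = m * (lam - 1.0)  # scale
                else:
                    lam, theta = np.inf, m
            else:
                lam, theta = np.inf, 0.0
        else:
            delta2_hat = np.ones(n_genes)
            lam, theta = np.inf, 0.0

        if np.isfinite(tau2) and tau2 > 0:
            gamma_star = (nb * tau2 * gamma_hat + delta2_hat * gamma_bar) / (
                nb * tau2 + delta2_hat
            )
        elif np.isfinite(tau2):  # tau2 == 0: all genes share one location effect
            gamma_star = np.full(n_genes, gamma_bar)
        else:
            gamma_star = gamma_hat

        if scale_here:
            if np.isfinite(lam):
                ss = ((zb - gamma_star[:, None]) ** 2).sum(axis=1)
                delta2_star = (theta + 0.5 * ss) / (nb / 2.0 + lam - 1.0)
            else:
                delta2_star = delta2_hat
            delta_star = np.sqrt(np.maximum(delta2_star, 1e-12))
        else:
            delta_star = np.ones(n_genes)

        out[:, ix] = (zb - gamma_star[:, None]) / delta_star[:, None]

    out *= safe_sd[:, None]
    if shrink:
        # Shrinkage leaves a small per-gene offset; report on a per-gene
        # centered scale (PCC-invariant). Without shrinkage the matrix is
        # already exactly batch-centered.
        out -= out.mean(axis=1, keepdims=True)
    out[constant, :] = 0.0  # zero-variance genes: centered, nothing to adjust
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=out,
        scale="log2",
    )


def drop_zero_variance(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero variance across samples (PCC undefined)."""
    keep = expr.values.std(axis=1) > 0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        sample_ids=list(expr.sample_ids),
        values=expr.values[keep],
        scale=expr.scale,
    )


def _corr_vectors(values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``values`` with each row of ``targets``."""
    a = values - values.mean(axis=1, keepdims=True)
    b = targets - targets.mean(axis=1, keepdims=True)
    an = np.linalg.norm(a, axis=1)
    bn = np.linalg.norm(b, axis=1)
    an[an == 0] = np.inf
    bn[bn == 0] = np.inf
    return (a @ b.T) / np.outer(an, bn)


def _pearson_1d(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def select_probe(
    probe_expr: ExpressionMatrix,
    probe_map: ProbeMap,
    reference_corr,  # pd.DataFrame, gene x gene correlations from another platform
) -> ProbeMap:
    """Choose one probe per gene by coexpression agreement with a reference.

    For each multi-probe gene, every candidate probe's coexpression
    profile — its correlation vector against the probes of unambiguous
    (single-probe) genes — is compared (Pearson) with the reference
    platform's profile for the same gene over the same gene set; the
    best-agreeing probe wins, ties broken by probe ID. Genes absent from
    the reference keep all their probes (caller should average them).
    """
    if reference_corr is None:
        raise ValueError("select_probe requires a reference correlation matrix; "
                         "use average_probes when none is available")
    probe_index = {p: i for i, p in enumerate(probe_expr.gene_ids)}
    for p in probe_map.mapping:
        if p not in probe_index:
            raise ValueError(f"probe {p!r} missing from expression matrix")

    genes = probe_map.genes()
    single = [g for g in genes if len(probe_map.probes_of(g)) == 1]
    anchor_genes = [g for g in single if g in reference_corr.index]
    if not anchor_genes:
        raise ValueError("no single-probe genes shared with the reference")
    anchor_rows = np.array(
        [probe_index[probe_map.probes_of(g)[0]] for g in anchor_genes]
    )
    anchors = probe_expr.values[anchor_rows]

    chosen: dict[str, str] = {}
    for gene in genes:
        probes = probe_map.probes_of(gene)
        if len(probes) == 1:
            chosen[probes[0]] = gene
            continue
        if gene not in reference_corr.index:
            logger.info("gene %r absent from reference; keeping all probes", gene)
            for p in probes:
                chosen[p] = gene
            continue
        others = [g for g in anchor_genes if g != gene]
        ref_profile = reference_corr.loc[gene, others].to_numpy(dtype=float)
        mask = np.array([g != gene for g in anchor_genes])
        cand = probe_expr.values[[probe_index[p] for p in probes]]
        profiles = _corr_vectors(cand, anchors)[:, mask]
        sims = [_pearson_1d(profiles[i], ref_profile) for i in range(len(probes))]
        # ties: smallest probe ID among the maxima
        top = max(sims)
        winners = sorted(p for p, s in zip(probes, sims) if s == top)
        chosen[winners[0]] = gene
    return ProbeMap(mapping=chosen)


def average_probes(probe_expr: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse probes to genes by averaging each gene's probe rows."""
    probe_index = {p: i for i, p in enumerate(probe_expr.gene_ids)}
    for p in probe_map.mapping:
        if p not in probe_index:
            raise ValueError(f"probe {p!r} missing from expression matrix")
    genes = probe_map.genes()
    out = np.empty((len(genes), probe_expr.n_samples))
    for gi, gene in enumerate(genes):
        rows = [probe_index[p] for p in probe_map.probes_of(gene)]
        out[gi] = probe_expr.values[rows].mean(axis=0)
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=list(probe_expr.sample_ids),
        values=out,
        scale=probe_expr.scale,
    )
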