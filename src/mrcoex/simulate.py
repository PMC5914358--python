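"""Synthetic expression compendia with planted coexpression modules.

The generator emulates the structure of a multi-experiment expression
compendium at desk scale:

* genes are grouped into rank-1 coexpression modules driven by one latent
  factor per module and sample, so the expected within-module correlation
  has the closed form loading^2 / (loading^2 + noise_sd^2);
* samples come in experiments (batches) with per-(gene, experiment)
  location offsets and optional multiplicative noise-scale distortion,
  applied on the log2 scale — where batch correction operates;
* the log-scale signal is exponentiated to base 2, so the raw matrix is
  strictly positive and the standard log transform recovers the linear
  model (up to the pseudocount);
* annotations mirror the modules with configurable fidelity, plus random
  decoy terms, so the function score has a planted signal and a null.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AnnotationSet, BatchDesign, ExpressionMatrix, GroundTruth

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_annotations",
    "simulate_platform_pair",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic compendium.

    Defaults give 500 genes, 10 modules of 20 genes (the rest background),
    20 experiments of 5 samples each (100 samples), loading 1.0 against
    residual SD 1.0 (expected within-module PCC 0.5), batch location SD
    0.5 and no scale distortion — a mid-sized, moderately noisy
    compendium with visible but imperfect module structure.
    """

    n_genes: int = 500
    n_modules: int = 10
    genes_per_module: int = 20
    n_experiments: int = 20
    samples_per_experiment: int | list[int] = 5
    loading: float = 1.0
    noise_sd: float = 1.0
    batch_location_sd: float = 0.5
    batch_scale_sd: float = 0.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    annotation_fidelity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_modules, self.genes_per_module,
               self.n_experiments) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules x {self.genes_per_module} genes "
                f"exceed n_genes={self.n_genes}"
            )
        if self.loading < 0 or self.noise_sd < 0 or self.batch_location_sd < 0 \
                or self.batch_scale_sd < 0:
            raise ValueError("loadings and SDs must be >= 0")
        if not (0.0 <= self.annotation_fidelity <= 1.0):
            raise ValueError("annotation fidelity must lie in [0, 1]")

    def experiment_sizes(self) -> list[int]:
        if isinstance(self.samples_per_experiment, int):
            return [self.samples_per_experiment] * self.n_experiments
        sizes = list(self.samples_per_experiment)
        if len(sizes) != self.n_experiments:
            raise ValueError(
                f"{len(sizes)} experiment sizes for {self.n_experiments} experiments"
            )
        return sizes


def _loading_matrix(config: SimulationConfig) -> np.ndarray:
    """Genes x modules loading matrix of the planted block structure."""
    lam = np.zeros((config.n_genes, config.n_modules))
    for m in range(config.n_modules):
        lo = m * config.genes_per_module
        lam[lo : lo + config.genes_per_module, m] = config.loading
    return lam


def _ids(config: SimulationConfig):
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    sizes = config.experiment_sizes()
    samples, assignment = [], {}
    for e, size in enumerate(sizes):
        for s in range(size):
            sid = f"e{e:02d}s{s:02d}"
            samples.append(sid)
            assignment[sid] = f"e{e:02d}"
    return genes, samples, assignment


def _assemble(
    config: SimulationConfig,
    lam: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, BatchDesign, GroundTruth]:
    genes, samples, assignment = _ids(config)
    n_samples = len(samples)
    sizes = config.experiment_sizes()

    factors = rng.standard_normal((config.n_modules, n_samples))
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    log_expr = baseline[:, None] + lam @ factors

    noise = rng.standard_normal((config.n_genes, n_samples)) * config.noise_sd
    col = 0
    for e, size in enumerate(sizes):
        sl = slice(col, col + size)
        if config.batch_location_sd > 0:
            log_expr[:, sl] += rng.normal(
                0.0, config.batch_location_sd, config.n_genes
            )[:, None]
        if config.batch_scale_sd > 0:
            scale = np.exp(rng.normal(0.0, config.batch_scale_sd, config.n_genes))
            noise[:, sl] *= scale[:, None]
        col += size
    log_expr += noise

    expr = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=samples,
        values=np.exp2(log_expr),
        scale="raw",
    )
    design = BatchDesign(assignment=assignment)
    gene_module: dict[str, int | None] = {}
    for i, g in enumerate(genes):
        m = i // config.genes_per_module
        gene_module[g] = m if m < config.n_modules else None
    truth = GroundTruth(gene_module=gene_module, module_terms={},
                        latent_factors=factors)
    return expr, design, truth


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, BatchDesign, GroundTruth]:
    """Draw one synthetic compendium: raw expression, batch design, truth."""
    rng = np.random.default_rng(config.seed)
    return _assemble(config, _loading_matrix(config), rng)


def simulate_annotations(
    truth: GroundTruth,
    fidelity: float = 1.0,
    n_random_terms: int = 0,
    seed: int = 0,
    min_term_size: int = 2,
) -> AnnotationSet:
    """Annotations mirroring the planted modules.

    One term per module covers a random ``fidelity`` fraction of its
    genes (at least ``min_term_size`` so the term is informative); decoy
    terms draw the same number of genes uniformly from all genes. At
    fidelity 0 the module terms are dropped entirely, leaving decoys (if
    any) independent of the modules.
    """
    if not (0.0 <= fidelity <= 1.0):
        raise ValueError("fidelity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    all_genes = sorted(truth.gene_module)
    modules = sorted({m for m in truth.gene_module.values() if m is not None})

    terms: dict[str, frozenset[str]] = {}
    sizes = []
    for m in modules:
        members = truth.module_genes(m)
        size = int(round(fidelity * len(members)))
        sizes.append(max(size, min_term_size))
        if size >= min_term_size:
            pick = rng.choice(len(members), size=size, replace=False)
            terms[f"module_{m:02d}"] = frozenset(members[i] for i in pick)
    for d in range(n_random_terms):
        size = sizes[d % len(sizes)] if sizes else min_term_size
        pick = rng.choice(len(all_genes), size=min(size, len(all_genes)),
                          replace=False)
        terms[f"decoy_{d:02d}"] = frozenset(all_genes[i] for i in pick)
    if not terms:
        raise ValueError("no annotation terms generated (fidelity too low, no decoys)")
    return AnnotationSet(term_to_genes=terms, filtered=False)


def simulate_platform_pair(
    config: SimulationConfig,
    divergence: float = 0.0,
    seed: int = 0,
) -> tuple[
    tuple[ExpressionMatrix, BatchDesign],
    tuple[ExpressionMatrix, BatchDesign],
    GroundTruth,
]:
    """Two platforms measuring the same genes, with tunable divergence.

    Both datasets share the planted module structure but have independent
    samples, factors and noise — like a microarray/RNAseq pair for one
    species. ``divergence`` in [0, 1] mixes the second platform's loading
    matrix with a gene-permuted copy: 0 keeps the module structure
    identical, 1 makes it random with respect to the truth, and the
    Jaccard reproducibility of the two MR networks falls monotonically in
    between.
    """
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lam = _loading_matrix(config)
    expr_a, design_a, truth = _assemble(config, lam, rng)

    perm = rng.permutation(config.n_genes)
    lam_b = (1.0 - divergence) * lam + divergence * lam[perm]
    expr_b, design_b, _ = _assemble(config, lam_b, rng)
    return (expr_a, design_a), (expr_b, design_b), truth
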