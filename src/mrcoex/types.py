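"""Core data containers shared across the coexpression pipeline.

Conventions:

* Expression matrices are genes x samples.
* Gene-by-gene matrices (correlation, rank, mutual rank) carry the gene
  order of the expression matrix they were derived from; the diagonal of
  rank/MR matrices is NaN (a gene is never its own coexpression partner).
* ``n_genes`` (``N``) on :class:`MRMatrix` is the total gene count used for
  the logit range standardization p = MR / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BatchDesign",
    "ProbeMap",
    "MRMatrix",
    "BootstrapSummary",
    "ErrorProfile",
    "ErrorModel",
    "AnnotationSet",
    "GroundTruth",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {what} ID: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag.

    ``scale`` is ``"raw"`` for intensities/counts on the linear scale and
    ``"log2"`` after log transformation.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.scale == "log2" and not np.all(np.isfinite(self.values)):
            raise ValueError("log2 expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "raw") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            scale=scale,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset/reorder; duplicates in ``sample_ids`` are disambiguated."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        counts: dict[str, int] = {}
        new_ids = []
        for s in sample_ids:
            k = counts.get(s, 0)
            counts[s] = k + 1
            new_ids.append(s if k == 0 else f"{s}#{k}")
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=new_ids,
            values=self.values[:, cols].copy(),
            scale=self.scale,
        )


@dataclass
class BatchDesign:
    """Sample -> experiment assignment.

    The experiment (experimental unit) is the unit of both batch
    correction and bootstrap resampling.
    """

    assignment: dict[str, str]
    experiments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.experiments:
            seen: list[str] = []
            for e in self.assignment.values():
                if e not in seen:
                    seen.append(e)
            self.experiments = seen
        missing = set(self.assignment.values()) - set(self.experiments)
        if missing:
            raise ValueError(f"experiments missing from order list: {sorted(missing)}")
        for e in self.experiments:
            if not any(v == e for v in self.assignment.values()):
                raise ValueError(f"experiment {e!r} has no samples")

    def samples_of(self, experiment: str) -> list[str]:
        return [s for s, e in self.assignment.items() if e == experiment]

    def experiment_of(self, sample: str) -> str:
        try:
            return self.assignment[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} missing from batch design") from None

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples missing from batch design: {missing[:10]}")


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping."""

    mapping: dict[str, str]

    def genes(self) -> list[str]:
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return seen

    def probes_of(self, gene: str) -> list[str]:
        return sorted(p for p, g in self.mapping.items() if g == gene)


@dataclass
class MRMatrix:
    """Symmetric gene x gene mutual-rank values; diagonal is NaN.

    ``n_genes`` is the total gene count N of the source network, which
    bounds MR in [1, N-1] and defines the logit standardization.
    Bagged/integrated MR values are real-valued in (0, N).
    """

    gene_ids: list[str]
    values: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"MR matrix shape {self.values.shape} != ({n}, {n})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i<j) MR values as a flat array."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.values[iu]


@dataclass
class BootstrapSummary:
    """Per-pair moments of MR across bootstrap replicates.

    All matrices are symmetric with NaN diagonals. ``skew_*`` and
    ``kurtosis_*`` hold per-pair sample skewness and excess kurtosis of
    the replicate values on each scale (available when B >= 4).
    """

    gene_ids: list[str]
    n_genes: int
    n_replicates: int
    seed: int
    mean_mr: np.ndarray
    sd_mr: np.ndarray
    mean_logit_mr: np.ndarray
    sd_logit_mr: np.ndarray
    skew_mr: np.ndarray | None = None
    kurtosis_mr: np.ndarray | None = None
    skew_logit_mr: np.ndarray | None = None
    kurtosis_logit_mr: np.ndarray | None = None

    def offdiag(self, which: str) -> np.ndarray:
        mat = getattr(self, which)
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return mat[iu]


@dataclass
class ErrorProfile:
    """Binned summary of the bootstrap SD against the MR percentile axis.

    Bins partition (0, 1] of the percentile of the mean bootstrap MR;
    empty bins carry NaN medians/quartiles.
    """

    bin_edges: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    counts: np.ndarray
    scale: str
    bin_width: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ErrorModel:
    """Least-squares line of logit-MR error on log(sample count)."""

    intercept: float
    slope: float
    pearson_r: float

    def predict(self, n_samples: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.log(n_samples)


@dataclass
class AnnotationSet:
    """Term -> genes map after size filtering, with the derived inverse."""

    term_to_genes: dict[str, frozenset[str]]
    filtered: bool = False

    def __post_init__(self) -> None:
        self.term_to_genes = {
            t: frozenset(g) for t, g in self.term_to_genes.items()
        }

    @property
    def gene_to_terms(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for term, genes in self.term_to_genes.items():
            for g in genes:
                out.setdefault(g, set()).add(term)
        return {g: frozenset(ts) for g, ts in out.items()}

    @property
    def gene_universe(self) -> frozenset[str]:
        u: set[str] = set()
        for genes in self.term_to_genes.values():
            u |= genes
        return frozenset(u)

    def shuffled(self, rng: np.random.Generator) -> "AnnotationSet":
        """Randomly reassign gene labels, preserving every term's size.

        This is the randomized gene-function association null: module
        structure in the expression data is untouched while the
        annotation becomes independent of it.
        """
        universe = sorted(self.gene_universe)
        perm = {g: universe[i] for g, i in zip(universe, rng.permutation(len(universe)))}
        return AnnotationSet(
            term_to_genes={
                t: frozenset(perm[g] for g in genes)
                for t, genes in self.term_to_genes.items()
            },
            filtered=self.filtered,
        )


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    gene_module: dict[str, int | None]
    module_terms: dict[str, frozenset[str]]
    latent_factors: np.ndarray  # modules x samples

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module]
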