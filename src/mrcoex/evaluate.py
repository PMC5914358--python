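"""Quality measures for coexpression networks.

Two complementary measures:

* **Reproducibility** — build each platform's edge set from the top three
  coexpression partners of every gene (the convention used for network
  drawing), restrict both sets to the genes the two platforms share, and
  report the Jaccard coefficient of the edge sets.

* **Function score** — guilt-by-association discriminative power. All
  pairs of annotated genes are split into positives (sharing at least one
  annotation term) and negatives (no common term), ranked by ascending MR
  (strong coexpression first), and scored by the partial AUROC up to a
  false-positive rate of 0.01, multiplied by (1/0.01)^2 = 10,000. The
  scaling makes a random ranking score 0.5 in expectation and a perfect
  one 100. Annotation terms are size-filtered first (informative terms
  only): strict "< max" for GO-style use, "<= max" for pathway-style use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AnnotationSet, MRMatrix

__all__ = [
    "EdgeSet",
    "FunctionScoreResult",
    "top_k_edges",
    "jaccard_reproducibility",
    "filter_annotations",
    "function_score",
    "effect_ratio",
]


@dataclass
class EdgeSet:
    """Undirected gene pairs (canonical lexicographic order) plus the gene
    universe they were drawn from."""

    edges: frozenset[tuple[str, str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            if a > b:
                raise ValueError(f"non-canonical pair ({a!r}, {b!r})")

    def restricted_to(self, genes: frozenset[str]) -> "EdgeSet":
        return EdgeSet(
            edges=frozenset(
                (a, b) for a, b in self.edges if a in genes and b in genes
            ),
            universe=self.universe & genes,
        )


@dataclass
class FunctionScoreResult:
    """Partial-AUROC function score with its bookkeeping."""

    partial_auroc: float
    fpr_cutoff: float
    scale: float
    score: float
    n_positive: int
    n_negative: int


def top_k_edges(mr: MRMatrix, k: int = 3) -> EdgeSet:
    """Each gene contributes its k smallest-MR partners; union as
    undirected pairs.

    Ties at the k-th position are broken by (MR, partner gene ID), so the
    selection is deterministic. Edge count lies between N*k/2 (all
    selections reciprocal) and N*k (none).
    """
    n = len(mr.gene_ids)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    ids = np.array(mr.gene_ids)
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        row = mr.values[i]
        partners = np.delete(np.arange(n), i)
        # lexsort: last key primary -> sort by (MR, gene ID)
        order = np.lexsort((ids[partners], row[partners]))
        for j in partners[order[:k]]:
            a, b = ids[i], ids[j]
            edges.add((a, b) if a < b else (b, a))
    return EdgeSet(edges=frozenset(edges), universe=frozenset(mr.gene_ids))


def jaccard_reproducibility(a: EdgeSet, b: EdgeSet) -> float:
    """Jaccard coefficient of two edge sets over their common genes.

    Both sets are first restricted to pairs whose genes occur in both
    universes; 1 means complete overlap, 0 none.
    """
    common = a.universe & b.universe
    ea = a.restricted_to(common).edges
    eb = b.restricted_to(common).edges
    union = ea | eb
    if not union:
        raise ValueError("no edges among the common genes; Jaccard undefined")
    return len(ea & eb) / len(union)


def filter_annotations(
    raw: dict[str, set[str] | frozenset[str]],
    max_genes: int,
    mode: str = "strict_lt",
) -> AnnotationSet:
    """Keep informative annotation terms by size.

    ``strict_lt`` keeps terms with fewer than ``max_genes`` genes (GO
    convention, e.g. < 50); ``exclude_gt`` drops terms with more than
    ``max_genes`` genes, keeping equality (pathway convention, e.g.
    terms > 100 excluded). Empty terms are always dropped, and the gene
    universe becomes the genes with at least one surviving term.
    """
    if mode not in ("strict_lt", "exclude_gt"):
        raise ValueError(f"unknown mode {mode!r}")
    kept: dict[str, frozenset[str]] = {}
    for term, genes in raw.items():
        genes = frozenset(genes)
        if not genes:
            continue
        size = len(genes)
        if (mode == "strict_lt" and size < max_genes) or (
            mode == "exclude_gt" and size <= max_genes
        ):
            kept[term] = genes
    if not kept:
        raise ValueError("no annotation terms survive the size filter")
    return AnnotationSet(term_to_genes=kept, filtered=True)


def _roc_vertices(scores: np.ndarray, labels: np.ndarray):
    """ROC polyline vertices for ranking by ascending score.

    Tied scores advance as one block (the diagonal segment of the tie
    group), making the curve — and any area under it — invariant to the
    order in which tied pairs are listed.
    """
    order = np.argsort(scores, kind="stable")
    scores = scores[order]
    labels = labels[order]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    # group boundaries of tied scores
    boundary = np.flatnonzero(np.diff(scores)) + 1
    starts = np.concatenate(([0], boundary))
    stops = np.concatenate((boundary, [labels.size]))
    tp = fp = 0
    fpr = [0.0]
    tpr = [0.0]
    for s, e in zip(starts, stops):
        block = labels[s:e]
        tp += int(block.sum())
        fp += int(block.size - block.sum())
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
    return np.array(fpr), np.array(tpr), n_pos, n_neg


def _partial_auc(fpr: np.ndarray, tpr: np.ndarray, cutoff: float) -> float:
    """Trapezoidal area under the ROC polyline on [0, cutoff], with linear
    interpolation at the cutoff."""
    area = 0.0
    for i in range(1, fpr.size):
        x0, x1 = fpr[i - 1], fpr[i]
        y0, y1 = tpr[i - 1], tpr[i]
        if x0 >= cutoff:
            break
        if x1 > cutoff:  # clip the segment at the cutoff
            y1 = y0 + (y1 - y0) * (cutoff - x0) / (x1 - x0) if x1 > x0 else y0
            x1 = cutoff
        area += 0.5 * (y0 + y1) * (x1 - x0)
    return area


def function_score(
    mr: MRMatrix,
    annotations: AnnotationSet,
    fpr_cutoff: float = 0.01,
) -> FunctionScoreResult:
    """Partial-AUROC function score of an MR network.

    Considers all pairs of annotated genes present in the matrix;
    positives share >= 1 term. Pairs are ranked by ascending MR and the
    area under the ROC up to ``fpr_cutoff`` is scaled by
    (1/fpr_cutoff)^2, so a random ranking scores 0.5 (area
    cutoff^2 / 2) and a perfect one 1/fpr_cutoff.
    """
    if not (0 < fpr_cutoff < 1):
        raise ValueError(f"FPR cutoff must be in (0, 1), got {fpr_cutoff}")
    gene_terms = annotations.gene_to_terms
    idx = [i for i, g in enumerate(mr.gene_ids) if g in gene_terms]
    if len(idx) < 2:
        raise ValueError("fewer than two annotated genes in the MR matrix")
    genes = [mr.gene_ids[i] for i in idx]
    sub = mr.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    scores = sub[iu]
    labels = np.zeros(scores.size, dtype=bool)
    terms = [gene_terms[g] for g in genes]
    for p, (i, j) in enumerate(zip(*iu)):
        labels[p] = bool(terms[i] & terms[j])

    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need both classes non-empty, got {n_pos} positives / {n_neg} negatives"
        )
    fpr, tpr, n_pos, n_neg = _roc_vertices(scores, labels)
    pauc = _partial_auc(fpr, tpr, fpr_cutoff)
    scale = (1.0 / fpr_cutoff) ** 2
    return FunctionScoreResult(
        partial_auroc=pauc,
        fpr_cutoff=fpr_cutoff,
        scale=scale,
        score=pauc * scale,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def effect_ratio(score_a: float, score_b: float) -> float:
    """Ratio score_a / score_b, e.g. adjusted-vs-baseline or
    bagged-vs-single normalization gains."""
    if score_b == 0:
        raise ValueError("zero denominator score")
    return score_a / score_b
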