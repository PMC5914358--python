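"""Readers and writers for the pipeline's plain-text interchange formats.

TSV is the primary interchange (expression matrices, batch designs, probe
maps, MR matrices, edge lists, bootstrap summaries) for diff-ability; GMT
carries annotations; JSON carries ground truth and reports; YAML carries
run configuration. Every writer round-trips through its paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnnotationSet,
    BatchDesign,
    BootstrapSummary,
    ExpressionMatrix,
    GroundTruth,
    MRMatrix,
    ProbeMap,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_batch_design",
    "write_batch_design",
    "read_probe_map",
    "read_gmt",
    "write_gmt",
    "read_mr_matrix",
    "write_mr_matrix",
    "write_edges",
    "read_edges",
    "write_bootstrap_summary",
    "write_ground_truth",
    "read_ground_truth",
    "read_config",
]

DEFAULT_EDGE_THRESHOLD = 300.0  # default depth of a displayed coexpression list


def _read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row ID {dup!r}")
    if pd.Index(frame.columns).has_duplicates:
        raise ValueError(f"{path}: duplicate column IDs")
    return frame


def read_expression(path, scale: str = "raw") -> ExpressionMatrix:
    """Expression TSV: header of sample IDs, first column gene/probe IDs."""
    frame = _read_table(path)
    body = frame.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        rows, cols = np.where(body.isna())
        r, c = rows[0], cols[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    return ExpressionMatrix.from_frame(body, scale=scale)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def read_batch_design(path) -> BatchDesign:
    """Two-column TSV sample_id <TAB> experiment_id, header required."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: batch design needs two columns")
    samples = frame.iloc[:, 0]
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise ValueError(f"{path}: sample {dup!r} assigned more than once")
    return BatchDesign(assignment=dict(zip(samples, frame.iloc[:, 1])))


def write_batch_design(design: BatchDesign, path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.assignment), "experiment_id": list(design.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> ProbeMap:
    """Two-column TSV probe_id <TAB> gene_id."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns")
    probes = frame.iloc[:, 0]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ValueError(f"{path}: probe {dup!r} mapped more than once")
    return ProbeMap(mapping=dict(zip(probes, frame.iloc[:, 1])))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: term <TAB> description <TAB> gene [<TAB> gene ...] per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            out[fields[0]] = set(g for g in fields[2:] if g)
    if not out:
        raise ValueError(f"{path}: empty GMT file")
    return out


def write_gmt(annotations: AnnotationSet | dict, path, description: str = "na") -> None:
    terms = (
        annotations.term_to_genes
        if isinstance(annotations, AnnotationSet)
        else annotations
    )
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def read_mr_matrix(path) -> MRMatrix:
    frame = _read_table(path)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: MR matrix row/column gene IDs differ")
    return MRMatrix(
        gene_ids=[str(g) for g in frame.index],
        values=frame.to_numpy(dtype=float),
        n_genes=len(frame.index),
    )


def write_mr_matrix(mr: MRMatrix, path) -> None:
    mr.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def write_edges(mr: MRMatrix, path, threshold: float = DEFAULT_EDGE_THRESHOLD) -> None:
    """Edge list gene_a <TAB> gene_b <TAB> mr for MR <= threshold.

    Each undirected pair appears once, sorted by MR ascending then IDs.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    ids = mr.gene_ids
    iu = np.triu_indices(len(ids), k=1)
    vals = mr.values[iu]
    keep = np.flatnonzero(vals <= threshold)
    rows = sorted(
        ((vals[k], ids[iu[0][k]], ids[iu[1][k]]) for k in keep),
        key=lambda t: (t[0], t[1], t[2]),
    )
    pd.DataFrame(
        [(a, b, v) for v, a, b in rows], columns=["gene_a", "gene_b", "mr"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edges(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "mr"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    return frame


def write_bootstrap_summary(summary: BootstrapSummary, path) -> None:
    """Edge-list TSV of the per-pair bootstrap moments."""
    ids = summary.gene_ids
    iu = np.triu_indices(len(ids), k=1)
    pd.DataFrame(
        {
            "gene_a": [ids[i] for i in iu[0]],
            "gene_b": [ids[j] for j in iu[1]],
            "mean_mr": summary.mean_mr[iu],
            "sd_mr": summary.sd_mr[iu],
            "mean_logit_mr": summary.mean_logit_mr[iu],
            "sd_logit_mr": summary.sd_logit_mr[iu],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "gene_module": truth.gene_module,
        "module_terms": {t: sorted(g) for t, g in truth.module_terms.items()},
        "latent_factors": np.asarray(truth.latent_factors).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        gene_module={g: m for g, m in payload["gene_module"].items()},
        module_terms={
            t: frozenset(g) for t, g in payload["module_terms"].items()
        },
        latent_factors=np.asarray(payload["latent_factors"], dtype=float),
    )


def read_config(path) -> dict:
    """Flat YAML key space mirroring the CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
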