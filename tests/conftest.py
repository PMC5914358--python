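import numpy as np
import pytest

import mrcoex as mx


@pytest.fixture(scope="session")
def small_compendium():
    """150 genes / 10 planted modules / 15 experiments of 4 samples."""
    cfg = mx.SimulationConfig(
        n_genes=150, n_modules=10, genes_per_module=10,
        n_experiments=15, samples_per_experiment=4,
        loading=0.8, noise_sd=1.0, batch_location_sd=0.5, seed=7,
    )
    expr, design, truth = mx.simulate_expression(cfg)
    return cfg, expr, design, truth


@pytest.fixture(scope="session")
def small_logged(small_compendium):
    _, expr, design, truth = small_compendium
    return mx.log_transform(expr), design, truth


@pytest.fixture(scope="session")
def small_mr(small_logged):
    """MR network of the small compendium after batch centering."""
    logged, design, truth = small_logged
    centered = mx.batch_center(logged, design)
    return mx.mr_from_expression(mx.drop_zero_variance(centered)), truth


def naive_mr_pipeline(values: np.ndarray) -> np.ndarray:
    """Brute-force PCC -> ranks -> MR with explicit per-pair loops and
    sorts; the independent oracle for the vectorized pipeline."""
    n = values.shape[0]
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = values[i], values[j]
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum())
            corr[i, j] = corr[j, i] = r
    ranks = np.full((n, n), np.nan)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        by_corr = sorted(others, key=lambda j: -corr[i, j])
        pos = {j: p + 1 for p, j in enumerate(by_corr)}
        # average ties
        for j in others:
            tied = [k for k in others if corr[i, k] == corr[i, j]]
            ranks[i, j] = float(np.mean([pos[k] for k in tied]))
    mr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                mr[i, j] = np.sqrt(ranks[i, j] * ranks[j, i])
    return mr
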