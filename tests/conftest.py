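import numpy as np
import pytest

from dcoex import RunConfig, SimulationDesign, run_pipeline, simulate_collection


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic design (shared across tests).

    5 tissues, 7-15 datasets each, 600 genes, 20 planted links per class,
    fixed seed — the reference study conditions for parameter recovery.
    """
    design = SimulationDesign(rng_seed=11)
    datasets, truth = simulate_collection(design)
    result = run_pipeline(datasets, RunConfig(rng_seed=11))
    return design, truth, result


@pytest.fixture(scope="session")
def small_collection():
    """A fast, reduced collection for module-level tests."""
    design = SimulationDesign(
        n_tissues=3,
        datasets_per_tissue=[5, 5, 5],
        samples_per_dataset=(30, 60),
        n_genes=120,
        n_planted_pure=4,
        n_planted_induced1=4,
        n_planted_induced2=4,
        rng_seed=7,
    )
    datasets, truth = simulate_collection(design)
    return design, datasets, truth


def brute_force_pearson(matrix: np.ndarray) -> dict[tuple[int, int], float]:
    """Per-pair Pearson loop (oracle for the correlation store)."""
    n = matrix.shape[0]
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            x, y = matrix[i], matrix[j]
            xm, ym = x - x.mean(), y - y.mean()
            denom = np.sqrt((xm**2).sum() * (ym**2).sum())
            out[(i, j)] = float((xm * ym).sum() / denom)
    return out


def brute_force_sb(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Pair-by-pair rank/ceil binning (oracle for the SB transform)."""
    out = np.empty(len(values))
    N = len(values)
    for k, r in enumerate(values):
        if r < 0:
            out[k] = 0.5
            continue
        count_le = np.sum(values <= r)
        b = np.ceil(count_le / N * n_bins) / n_bins
        out[k] = max(b, 0.5)
    return out


def brute_force_tss(target_sb, other_sb) -> float:
    """Explicit double sum of positive differences (oracle for TSS)."""
    total = 0.0
    for p in target_sb:
        for q in other_sb:
            d = p - q
            if d > 0:
                total += d
    return total / (len(target_sb) * len(other_sb))
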