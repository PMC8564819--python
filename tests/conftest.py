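import numpy as np
import pandas as pd
import pytest

from trdecomp import synthetic as syn


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """Two replicates with different library sizes: S0=300, S1=120, tr=0.4."""
    return pd.DataFrame(
        {
            "gene_id": "g1",
            "condition": "c",
            "replicate": [1, 1, 2, 2],
            "site": ["TSS", "TES", "TSS", "TES"],
            "count": [100, 30, 200, 90],
            "library_size_millions": [1.0, 1.0, 2.0, 2.0],
        }
    )


@pytest.fixture
def expectation_config() -> syn.SimConfig:
    return syn.SimConfig(seed=0, noise_mode="expectation")


def random_count_table(rng: np.random.Generator) -> pd.DataFrame:
    """A small random but valid (non-degenerate) one-gene count table."""
    nrep = int(rng.integers(1, 6))
    m = rng.uniform(0.5, 8.0, size=nrep)
    lam0 = rng.uniform(2.0, 200.0)
    tr = rng.uniform(0.05, 3.0)
    y0 = rng.poisson(m * lam0) + 1  # +1 guarantees non-degenerate sums
    y1 = rng.poisson(m * lam0 * tr) + 1
    return pd.DataFrame(
        {
            "site": ["TSS"] * nrep + ["TES"] * nrep,
            "count": np.concatenate([y0, y1]),
            "library_size_millions": np.concatenate([m, m]),
        }
    )


def grid_mle(counts: pd.DataFrame, tol: float = 1e-9) -> tuple[float, float]:
    """Independent grid maximization of the Poisson log-likelihood.

    The likelihood separates into beta0 (TSS rows) and gamma = beta0 + beta1
    (TES rows); each 1-D term is maximized by iterative grid refinement.
    """

    def refine(y: np.ndarray, e: np.ndarray) -> float:
        def loglik(b: np.ndarray) -> np.ndarray:
            return (y[:, None] * b[None, :] - e[:, None] * np.exp(b)[None, :]).sum(axis=0)

        center = np.log((y.sum() + 0.5) / e.sum())
        width = 4.0
        while width > tol:
            grid = np.linspace(center - width, center + width, 2001)
            center = grid[int(np.argmax(loglik(grid)))]
            width /= 100.0
        return float(center)

    is0 = counts["site"].to_numpy() == "TSS"
    y = counts["count"].to_numpy(dtype=float)
    e = counts["library_size_millions"].to_numpy(dtype=float)
    beta0 = refine(y[is0], e[is0])
    gamma = refine(y[~is0], e[~is0])
    return beta0, gamma - beta0
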