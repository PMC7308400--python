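import numpy as np
import pandas as pd
import pytest

from rogue import CountMatrix, Platform


def make_matrix(values, platform=Platform.UMI):
    values = np.asarray(values)
    genes = np.array([f"g{i+1:03d}" for i in range(values.shape[0])], dtype=object)
    cells = np.array([f"c{j+1:03d}" for j in range(values.shape[1])], dtype=object)
    return CountMatrix(values, genes, cells, platform)


def make_profile(log_mean, obs_entropy, ds=None, p_adj=None):
    """Minimal S-E profile frame for operations that consume one."""
    n = len(log_mean)
    df = pd.DataFrame(
        {
            "mean_expr": np.exp(np.clip(np.asarray(log_mean, float), None, 50.0)) - 1,
            "log_mean": np.asarray(log_mean, float),
            "obs_entropy": np.asarray(obs_entropy, float),
            "fit_entropy": np.nan,
            "ds": np.nan if ds is None else np.asarray(ds, float),
            "p": np.nan,
            "p_adj": np.nan if p_adj is None else np.asarray(p_adj, float),
        },
        index=pd.Index([f"g{i+1:05d}" for i in range(n)], name="gene"),
    )
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_nb():
    """A modest pure NB population reused across tests (one draw)."""
    from rogue import SimSpec, simulate_nb

    return simulate_nb(SimSpec(n_genes=2500, n_cells=400, seed=11))
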