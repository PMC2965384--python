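import numpy as np
import pandas as pd
import pytest

from arraycna import EmissionParams, Hyperparams, build_state_table
from arraycna.io import ProbeSet


@pytest.fixture(scope="session")
def states():
    return build_state_table()


@pytest.fixture(scope="session")
def states_by_id(states):
    return {s.id: s for s in states}


@pytest.fixture
def params_k2():
    return EmissionParams.default(K=2)


@pytest.fixture
def hyper_small():
    """Fast settings: two heterogeneity levels, coarse pi0 grid."""
    return Hyperparams(pi_grid=(0.0, 0.2),
                       pi0_grid=tuple(np.round(np.arange(0.0, 0.91, 0.05), 2)))


def toy_probeset(n=8, chrom="1", spacing=500_000, seed=0, lrr_scale=0.5):
    """A tiny sorted probe set with arbitrary LRR/BAF values."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "name": [f"p{i}" for i in range(n)],
        "chrom": chrom,
        "pos": spacing * (np.arange(n) + 1),
        "lrr": rng.normal(0.0, lrr_scale, n),
        "baf": rng.uniform(0.0, 1.0, n),
        "gc": 0.5 + 0.05 * rng.standard_normal(n),
    })
    return ProbeSet(df)


@pytest.fixture
def tiny_probes():
    return toy_probeset()
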