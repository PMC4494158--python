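import numpy as np
import pandas as pd
import pytest

from darkrep import SignalMatrix, SyntheticSpec, generate_dataset
from darkrep.containers import LIGHT, make_sample_id


def random_signal_matrix(rng, n_genes=None, n_exp=None, conditions=None,
                         times=(0, 30, 60)):
    """A structurally valid random fixture with arbitrary positive signals."""
    n_genes = n_genes or int(rng.integers(20, 120))
    n_exp = n_exp or int(rng.integers(2, 4))
    conditions = conditions or [LIGHT, "dark"]
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene")
    cols, meta = {}, []
    for n in range(1, n_exp + 1):
        for cond in conditions:
            for t in times:
                sid = make_sample_id(cond, t, n)
                cols[sid] = rng.gamma(2.0, 50.0, size=n_genes) + 1e-3
                meta.append((sid, cond, t, n))
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(
        meta, columns=["sample_id", "condition", "time_min", "experiment"]
    ).set_index("sample_id")
    return SignalMatrix(values, samples)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced problem size for unit tests; same planted structure."""
    return SyntheticSpec(n_genes=400, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale default study design (one per session)."""
    return generate_dataset(SyntheticSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
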