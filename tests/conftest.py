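import numpy as np
import pytest

from cmcqspr.dataset import DescriptorTable, ModelingDataset, SampleRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(n=6, p=3, seed=0):
    """Small hand-checkable modeling dataset."""
    rng = np.random.default_rng(seed)
    ids = [f"C{i}" for i in range(n)]
    names = [f"D{j}" for j in range(p)]
    values = rng.standard_normal((n, p))
    records = [
        SampleRecord(compound_id=ids[i], T=300.0 + i, pH=7.0 + 0.1 * i,
                     S_eq=100.0 * i, log_cmc=float(values[i].sum()))
        for i in range(n)
    ]
    return ModelingDataset(records=records,
                           descriptors=DescriptorTable(ids, names, values))


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def planted_pool(rng):
    """Noise-free planted 2-subset in a 20-column pool."""
    X = rng.standard_normal((60, 20))
    y = 2.0 * X[:, 3] - 1.5 * X[:, 17] + 0.5
    return X, y, (3, 17)
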