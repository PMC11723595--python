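import numpy as np
import pytest

from orchard import VafDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(var_reads, total_reads, omega=0.5) -> VafDataset:
    """Build a small in-memory dataset from count matrices."""
    b = np.atleast_2d(np.asarray(var_reads, dtype=np.int64))
    N = np.atleast_2d(np.asarray(total_reads, dtype=np.int64))
    om = np.broadcast_to(np.asarray(omega, dtype=np.float64), b.shape).copy()
    n, m = b.shape
    return VafDataset(
        mutation_ids=[f"s{j}" for j in range(n)],
        mutation_names=[f"M{j}" for j in range(n)],
        var_reads=b,
        ref_reads=N - b,
        omega=om,
        sample_names=[f"sample{s}" for s in range(m)],
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
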