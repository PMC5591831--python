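import numpy as np
import pytest

from mmgraph.containers import TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eeg_ts(rng):
    """Small broadband EEG-like recording: 8 channels, 60 s at 250 Hz."""
    return TimeSeriesMatrix(
        values=rng.standard_normal((8, 15000)),
        sampling_rate=250.0,
        modality="eeg",
        subject_id="S01",
    )


def random_symmetric_matrix(n, rng):
    """Random correlation-like symmetric matrix with zero diagonal."""
    a = rng.uniform(-1, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def random_adjacency(n, p, rng):
    """Erdos-Renyi 0/1 adjacency."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a | a.T
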