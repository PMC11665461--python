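import numpy as np
import pytest

from peaknet.io import Peak, PeakMatrix


def make_matrix(values, sample_ids=None, peak_ids=None, sample_group=None):
    """Small PeakMatrix with canonical-width peaks from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_peaks, n_samples = values.shape
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    if peak_ids is None:
        peak_ids = [f"p{i + 1:03d}" for i in range(n_peaks)]
    peaks = [
        Peak(pid, "chr1", 1000 * (i + 1), 1000 * (i + 1) + 501)
        for i, pid in enumerate(peak_ids)
    ]
    return PeakMatrix(
        peaks=peaks, sample_ids=list(sample_ids), values=values, sample_group=sample_group
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
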