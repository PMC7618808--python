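import numpy as np
import pytest

from kisssync.config import PipelineConfig
from kisssync.model import TraceMatrix


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_bump_trace(
    peaks, amps, widths, duration_s=600.0, fs=2.0, baseline=0.0, noise=0.0, seed=0
):
    """Single-cell trace with Gaussian bumps at given peak times."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    x = np.full_like(t, baseline)
    for p, a, w in zip(peaks, amps, widths):
        x += a * np.exp(-0.5 * ((t - p) / w) ** 2)
    if noise > 0:
        x += np.random.default_rng(seed).normal(0, noise, len(t))
    return t, x


@pytest.fixture
def z_matrix_factory():
    """Build a z-unit multi-cell TraceMatrix with bumps per cell."""

    def build(cell_bumps, duration_s=600.0, fs=10.0, modality="miniscope"):
        t = np.arange(0.0, duration_s, 1.0 / fs)
        rows = []
        ids = []
        for cid, bumps in cell_bumps.items():
            x = np.zeros_like(t)
            for peak, amp, width in bumps:
                x += amp * np.exp(-0.5 * ((t - peak) / width) ** 2)
            rows.append(x)
            ids.append(cid)
        return TraceMatrix(ids, t, np.vstack(rows), modality=modality, units="z")

    return build
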