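import numpy as np
import pytest

from specpipe.montage import CHANNELS_19, montage_positions
from specpipe.cluster import build_adjacency


@pytest.fixture(scope="session")
def fit_grid():
    """The 2–40 Hz, 0.25 Hz analysis grid."""
    return np.arange(2.0, 40.0 + 1e-9, 0.25)


def model_spectrum(freqs, offset, exponent, peaks=(), noise_sd=0.0, rng=None):
    """Linear-power spectrum from the generative model; peaks are
    (cf, height, sd) triples and noise is Gaussian on log10 power."""
    logp = offset - exponent * np.log10(freqs)
    for cf, pw, sd in peaks:
        logp = logp + pw * np.exp(-((freqs - cf) ** 2) / (2.0 * sd ** 2))
    if noise_sd > 0:
        logp = logp + rng.normal(0.0, noise_sd, size=freqs.size)
    return 10.0 ** logp


@pytest.fixture(scope="session")
def adjacency_19():
    pos = montage_positions(CHANNELS_19)
    return build_adjacency(pos["label"].tolist(), pos[["x", "y"]].to_numpy())


@pytest.fixture(scope="session")
def grid16_adjacency():
    """Deterministic 16-channel lattice adjacency (4x4, slightly jittered so
    the triangulation is non-degenerate)."""
    xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    coords += 0.01 * np.sin(np.arange(32, dtype=float)).reshape(16, 2)
    labels = [f"g{i}" for i in range(16)]
    return build_adjacency(labels, coords)
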