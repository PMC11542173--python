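"""Total and parameterized (peak-model) band power.

Two band measures per channel:

* **total power** — arithmetic mean of linear power (μV²/Hz) over the band's
  grid points, computed on the raw spectrum with the aperiodic component left
  in; analyzed in linear space.
* **parameterized power** — mean over the same grid points of the fitted
  Gaussian peak model only (log10 units), i.e. power attributable to
  oscillations once the aperiodic component is removed. Defined (as zero)
  even when no discrete peak falls in the band, which paired statistics need.

Band edges are lower-inclusive and upper-exclusive, except the final band's
upper edge, so that a shared boundary (alpha 8–13, beta 13–30) is counted
once, in the higher band.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .parameterization import SpectralModel


class BandDefinition(NamedTuple):
    name: str
    fmin: float
    fmax: float
    upper_inclusive: bool = False


DEFAULT_BANDS = (
    BandDefinition("alpha", 8.0, 13.0, upper_inclusive=False),
    BandDefinition("beta", 13.0, 30.0, upper_inclusive=True),
)


class BandError(ValueError):
    pass


def band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    if not band.fmin < band.fmax:
        raise BandError(f"band {band.name!r} must have fmin < fmax")
    eps = 1e-9
    freqs = np.asarray(freqs, dtype=float)
    mask = freqs >= band.fmin - eps
    if band.upper_inclusive:
        mask &= freqs <= band.fmax + eps
    else:
        mask &= freqs < band.fmax - eps
    return mask


def total_band_power(freqs: np.ndarray, power_linear: np.ndarray,
                     band: BandDefinition) -> float:
    """Mean linear power over the band's grid points."""
    mask = band_mask(freqs, band)
    if not np.any(mask):
        raise BandError(f"band {band.name!r} does not intersect the grid")
    return float(np.mean(np.asarray(power_linear, dtype=float)[..., mask]))


def parameterized_band_power(model: SpectralModel, band: BandDefinition,
                             freqs: np.ndarray | None = None) -> float:
    """Mean of the fitted peak model over the band's grid points (log10 units)."""
    f = model.freqs if freqs is None else np.asarray(freqs, dtype=float)
    eps = 1e-9
    if band.fmin < f[0] - eps or band.fmax > f[-1] + eps:
        raise BandError(
            f"band {band.name!r} [{band.fmin}, {band.fmax}] outside the fitted "
            f"range [{f[0]}, {f[-1]}]")
    mask = band_mask(f, band)
    if not np.any(mask):
        raise BandError(f"band {band.name!r} does not intersect the grid")
    return float(np.mean(model.peak_log_power(f)[mask]))
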