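"""Epoching, amplitude-based artifact rejection, and averaged-periodogram PSD.

The estimation chain mirrors a standard resting-EEG pipeline: the continuous
recording is cut into 2000 ms segments with 50% overlap, segments in which any
channel deviates by more than ±150 μV from its within-segment mean are dropped,
recordings retaining fewer than half of their segments flag the subject for
exclusion, and the power spectral density is the across-segment average of
Hamming-windowed periodograms. Each windowed segment is zero-padded twofold
before the FFT so that 2000 ms segments yield a 0.25 Hz frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window


@dataclass
class Recording:
    """Multichannel time series in μV.

    data is (channels, samples); ``channel_labels`` matches the row order.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject: str = ""
    session: str = "NA"
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochSet:
    """Segmented recording: (epochs, channels, samples_per_epoch), μV."""

    epochs: np.ndarray
    fs: float
    epoch_onsets: np.ndarray  # seconds
    rejected_mask: np.ndarray  # True where rejected
    channel_labels: list[str]
    subject: str = ""
    session: str = "NA"
    condition: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def retention_fraction(self) -> float:
        if self.n_epochs == 0:
            return 0.0
        return float(np.sum(~self.rejected_mask)) / self.n_epochs


@dataclass
class PowerSpectrumSet:
    """Per-channel linear power (μV²/Hz) on a shared frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (channels, freqs)
    channel_labels: list[str]
    subject: str = ""
    session: str = "NA"
    condition: str = ""
    n_epochs_used: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.channel_labels), self.freqs.size):
            raise ValueError("power must be (channels, freqs)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


class EstimationError(RuntimeError):
    pass


def segment_recording(rec: Recording, epoch_len_ms: float = 2000.0,
                      overlap: float = 0.5) -> EpochSet:
    """Cut a recording into fixed-length epochs with fractional overlap.

    Epoch onsets are at k·L·(1−overlap); only epochs fully inside the
    recording are kept. A recording shorter than one epoch yields an empty
    EpochSet carrying a warning rather than an error.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    n_per = int(round(epoch_len_ms / 1000.0 * rec.fs))
    step = n_per * (1.0 - overlap)
    n_samples = rec.data.shape[1]
    if n_samples < n_per:
        return EpochSet(
            epochs=np.empty((0, rec.data.shape[0], n_per)),
            fs=rec.fs, epoch_onsets=np.empty(0), rejected_mask=np.empty(0, bool),
            channel_labels=rec.channel_labels, subject=rec.subject,
            session=rec.session, condition=rec.condition,
            warnings=["recording shorter than one epoch"],
        )
    n_epochs = int(np.floor((n_samples - n_per) / step)) + 1
    onsets = np.round(np.arange(n_epochs) * step).astype(int)
    epochs = np.stack([rec.data[:, o:o + n_per] for o in onsets])
    return EpochSet(
        epochs=epochs, fs=rec.fs, epoch_onsets=onsets / rec.fs,
        rejected_mask=np.zeros(n_epochs, dtype=bool),
        channel_labels=rec.channel_labels, subject=rec.subject,
        session=rec.session, condition=rec.condition,
    )


def reject_epochs(es: EpochSet, threshold_uv: float = 150.0) -> EpochSet:
    """Mark epochs in which any channel deviates from its within-epoch mean
    by more than ``threshold_uv`` (absolute value, strict inequality)."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if es.n_epochs == 0:
        return es
    dev = np.abs(es.epochs - es.epochs.mean(axis=2, keepdims=True))
    rejected = dev.max(axis=(1, 2)) > threshold_uv
    return EpochSet(
        epochs=es.epochs, fs=es.fs, epoch_onsets=es.epoch_onsets,
        rejected_mask=rejected, channel_labels=es.channel_labels,
        subject=es.subject, session=es.session, condition=es.condition,
        warnings=list(es.warnings),
    )


def check_retention(es: EpochSet, min_fraction: float = 0.5) -> bool:
    """True when the recording retains at least ``min_fraction`` of its epochs.

    The exclusion rule is strict: a retention fraction exactly at the bound is
    included. A False flag propagates to subject-level exclusion (a subject is
    excluded if any of their recordings fails).
    """
    if es.n_epochs == 0:
        raise EstimationError("cannot assess retention of an empty epoch set")
    return es.retention_fraction >= min_fraction


def compute_psd(es: EpochSet, pad_factor: int = 2,
                window: str = "hamming") -> PowerSpectrumSet:
    """Average one-sided periodogram over retained epochs.

    Each retained epoch is mean-detrended per channel, multiplied by the
    window, zero-padded by ``pad_factor``, and Fourier transformed. The
    periodogram is scaled to density units (μV²/Hz) by the window power
    ``fs·Σw²``, with the usual one-sided doubling of all bins except DC and
    Nyquist. At the defaults (2000 ms Hamming epochs, pad ×2) the grid step
    is 0.25 Hz.
    """
    keep = ~es.rejected_mask
    if es.n_epochs == 0 or not np.any(keep):
        raise EstimationError(
            f"no retained epochs for subject={es.subject!r} session={es.session!r} "
            f"condition={es.condition!r}")
    data = es.epochs[keep]
    n_per = data.shape[2]
    w = get_window(window, n_per, fftbins=True) if window != "boxcar" \
        else np.ones(n_per)
    nfft = n_per * int(pad_factor)
    demeaned = data - data.mean(axis=2, keepdims=True)
    spec = np.fft.rfft(demeaned * w, n=nfft, axis=2)
    psd = (np.abs(spec) ** 2) / (es.fs * np.sum(w ** 2))
    psd[..., 1:] *= 2.0
    if nfft % 2 == 0:  # Nyquist bin present and not doubled
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / es.fs)
    return PowerSpectrumSet(
        freqs=freqs, power=psd.mean(axis=0), channel_labels=es.channel_labels,
        subject=es.subject, session=es.session, condition=es.condition,
        n_epochs_used=int(keep.sum()),
    )


def restrict_range(psd: PowerSpectrumSet, fmin: float = 2.0,
                   fmax: float = 40.0) -> PowerSpectrumSet:
    """Inclusive trim of the frequency grid to [fmin, fmax]."""
    eps = 1e-9
    mask = (psd.freqs >= fmin - eps) & (psd.freqs <= fmax + eps)
    if not np.any(mask):
        raise EstimationError(
            f"range [{fmin}, {fmax}] Hz does not intersect the grid")
    return PowerSpectrumSet(
        freqs=psd.freqs[mask], power=psd.power[:, mask],
        channel_labels=psd.channel_labels, subject=psd.subject,
        session=psd.session, condition=psd.condition,
        n_epochs_used=psd.n_epochs_used,
    )


def estimate_psd(rec: Recording, epoch_len_ms: float = 2000.0,
                 overlap: float = 0.5, threshold_uv: float = 150.0,
                 pad_factor: int = 2, fmin: float = 2.0, fmax: float = 40.0,
                 window: str = "hamming") -> tuple[PowerSpectrumSet, EpochSet]:
    """Full estimation chain for one recording; returns (psd, epoch set)."""
    es = reject_epochs(segment_recording(rec, epoch_len_ms, overlap), threshold_uv)
    psd = restrict_range(compute_psd(es, pad_factor, window), fmin, fmax)
    return psd, es
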