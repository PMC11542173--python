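"""Synthetic resting-EEG cohorts with known aperiodic and oscillatory ground truth.

Each simulated subject has a log10 power spectrum that is linear in log10
frequency (the fixed-mode aperiodic component, offset ``b`` and exponent ``χ``)
plus Gaussian oscillatory peaks, with additive Gaussian noise on log10 power:

    log10 P(f) = b − χ·log10 f + Σ_k pw_k · exp(−(f − cf_k)² / (2·sd_k²)) + ε

Cohorts follow a Parkinson's-disease case–control design: healthy controls
(CTL, one session) and PD patients measured twice in a paired medication
factor (ON dopaminergic medication vs. OFF after overnight withdrawal), each
recorded eyes-closed (EC) and eyes-open (EO). Default group effects place the
PD aperiodic offset ~1 pooled SD and the exponent ~0.7 pooled SD above CTL
with identical oscillatory peaks, and a null ON/OFF contrast — the regime in
which total band power differs between groups while peak-attributable
(parameterized) band power does not.

Subjects can be materialized either directly as power spectra or as
time-domain recordings whose expected PSD follows the same model (white noise
shaped in the frequency domain), optionally with injected high-amplitude
transients to exercise artifact rejection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import PowerSpectrumSet, Recording
from .montage import CHANNELS_64, montage_positions, posterior_weights

ALPHA_RANGE = (8.0, 13.0)  # peaks in this range receive the topographic gradient


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PeakTemplate:
    """Population distribution of one oscillatory peak.

    cf/pw/sd are the population means (Hz, log10 units, Hz); the *_sd fields
    are between-subject standard deviations.
    """

    cf: float
    pw: float
    sd: float
    cf_sd: float = 0.0
    pw_sd: float = 0.0
    sd_sd: float = 0.0


@dataclass(frozen=True)
class GroupParams:
    """Between-subject distributions of the aperiodic parameters and peaks.

    ``aperiodic_corr`` is the between-subject correlation of offset and
    exponent. Empirically the two are strongly positively correlated —
    individual spectra pivot around a low anchor frequency rather than
    shifting independently in height and tilt — and this correlation is what
    keeps between-subject band-power variance compatible with the
    band-power consequences of group-level aperiodic shifts.
    """

    offset_mean: float
    offset_sd: float
    exponent_mean: float
    exponent_sd: float
    peaks: tuple[PeakTemplate, ...] = ()
    aperiodic_corr: float = 0.95


@dataclass(frozen=True)
class ConditionEffects:
    """Additive EC-minus-EO shifts (applied in the EC condition).

    Each effect has a population mean and a between-subject SD so that paired
    EC−EO contrasts have finite, controllable effect sizes.
    """

    offset: float = 0.0
    offset_sd: float = 0.0
    exponent: float = 0.0
    exponent_sd: float = 0.0
    alpha_height: float = 0.0
    alpha_height_sd: float = 0.0


@dataclass(frozen=True)
class MedicationEffects:
    """Additive ON-minus-OFF shifts (applied in the ON session)."""

    offset: float = 0.0
    exponent: float = 0.0
    alpha_height: float = 0.0


def _default_groups() -> dict[str, GroupParams]:
    # Identical oscillatory structure in both groups; PD differs only in the
    # aperiodic parameters. The decomposition Δoffset = +0.25, Δexponent =
    # +0.12 with SDs 0.24 / 0.17 gives between-group d ≈ 1.04 (offset) and
    # ≈ 0.71 (exponent) and rotates the group-mean spectra around ~120 Hz,
    # so PD log power exceeds CTL throughout 2–40 Hz — the regime in which
    # total alpha AND total beta rise while peak parameters are unchanged.
    peaks = (
        PeakTemplate(cf=10.0, pw=0.6, sd=1.5, cf_sd=0.5, pw_sd=0.08, sd_sd=0.10),
        PeakTemplate(cf=20.0, pw=0.25, sd=2.5, cf_sd=1.0, pw_sd=0.05, sd_sd=0.20),
    )
    ctl = GroupParams(offset_mean=0.5, offset_sd=0.24,
                      exponent_mean=1.0, exponent_sd=0.17, peaks=peaks,
                      aperiodic_corr=0.95)
    pd_ = replace(ctl, offset_mean=0.75, exponent_mean=1.12)
    return {"CTL": ctl, "PD": pd_}


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort."""

    n_ctl: int = 26
    n_pd: int = 26
    channel_labels: tuple[str, ...] = CHANNELS_64
    freq_grid: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 40.0 + 1e-9, 0.25))
    group_params: dict[str, GroupParams] = field(default_factory=_default_groups)
    condition_effects: ConditionEffects = field(default_factory=lambda: ConditionEffects(
        offset=0.10, offset_sd=0.02, exponent=0.05, exponent_sd=0.015,
        alpha_height=0.20, alpha_height_sd=0.05))
    medication_effects: MedicationEffects = field(default_factory=MedicationEffects)
    topography_weights: np.ndarray | None = None  # default: posterior gradient
    spectral_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if self.n_ctl < 2 or self.n_pd < 2:
            raise CohortConfigError("need at least 2 subjects per group")
        if np.any(self.freq_grid <= 0) or np.any(np.diff(self.freq_grid) <= 0):
            raise CohortConfigError("freq_grid must be positive and strictly increasing")
        if self.spectral_noise_sd < 0:
            raise CohortConfigError("spectral_noise_sd must be >= 0")
        for name, gp in self.group_params.items():
            if gp.offset_sd < 0 or gp.exponent_sd < 0:
                raise CohortConfigError(f"negative SD in group {name!r}")
        if self.topography_weights is not None:
            w = np.asarray(self.topography_weights, dtype=float)
            if w.shape != (len(self.channel_labels),):
                raise CohortConfigError("topography_weights length must equal channel count")
            if np.any(w < 0):
                raise CohortConfigError("topography_weights must be non-negative")
            self.topography_weights = w

    def resolved_topography(self) -> np.ndarray:
        if self.topography_weights is not None:
            return self.topography_weights
        return posterior_weights(montage_positions(self.channel_labels))


@dataclass
class SubjectParams:
    """Ground-truth per-channel model parameters for one spectrum."""

    subject_id: str
    group: str
    session: str  # ON / OFF / NA
    condition: str  # EC / EO
    offset: np.ndarray  # per channel, log10 power units
    exponent: np.ndarray  # per channel
    peaks: list[list[tuple[float, float, float]]]  # per channel: (cf, pw, sd)

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.exponent = np.asarray(self.exponent, dtype=float)
        if np.any(self.exponent < 0):
            raise CohortConfigError("exponent must be non-negative")
        for chan_peaks in self.peaks:
            for _, _, sd in chan_peaks:
                if sd <= 0:
                    raise CohortConfigError("peak sd must be positive")


@dataclass(frozen=True)
class ArtifactSpec:
    """High-amplitude transient injection for artifact-rejection tests."""

    amplitude_uv: float = 300.0
    count_per_channel: int = 1
    width_s: float = 0.02


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def _base_draw(spec: CohortSpec, group: str, rng: np.random.Generator) -> dict:
    """Draw subject-level base parameters and condition-shift realizations.

    A single draw covers every session/condition of the subject so the paired
    design is honored: shifts, not independent resamples.
    """
    if group not in spec.group_params:
        raise CohortConfigError(
            f"unknown group {group!r}; known: {sorted(spec.group_params)}")
    gp = spec.group_params[group]
    ce = spec.condition_effects
    # Correlated aperiodic draw: exponent first, then offset conditional on
    # it, preserving the marginal SDs and the configured correlation.
    z_chi, z_b = rng.standard_normal(2)
    rho = float(np.clip(gp.aperiodic_corr, -1.0, 1.0))
    exponent = gp.exponent_mean + gp.exponent_sd * z_chi
    offset = gp.offset_mean + gp.offset_sd * (
        rho * z_chi + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z_b)
    base = {
        "offset": offset,
        "exponent": exponent,
        "peaks": [(rng.normal(t.cf, t.cf_sd), rng.normal(t.pw, t.pw_sd),
                   rng.normal(t.sd, t.sd_sd)) for t in gp.peaks],
        "ec_offset": rng.normal(ce.offset, ce.offset_sd),
        "ec_exponent": rng.normal(ce.exponent, ce.exponent_sd),
        "ec_alpha": rng.normal(ce.alpha_height, ce.alpha_height_sd),
    }
    return base


def _compose(spec: CohortSpec, base: dict, subject_id: str, group: str,
             session: str, condition: str) -> SubjectParams:
    me = spec.medication_effects
    n_chan = len(spec.channel_labels)
    topo = spec.resolved_topography()
    fmin, fmax = spec.freq_grid[0], spec.freq_grid[-1]

    offset = base["offset"]
    exponent = base["exponent"]
    if condition == "EC":
        offset += base["ec_offset"]
        exponent += base["ec_exponent"]
    if session == "ON":
        offset += me.offset
        exponent += me.exponent
    exponent = max(exponent, 0.0)

    peaks_per_channel: list[list[tuple[float, float, float]]] = []
    for c in range(n_chan):
        chan_peaks = []
        for cf, pw, sd in base["peaks"]:
            is_alpha = ALPHA_RANGE[0] <= cf <= ALPHA_RANGE[1]
            height = pw
            if is_alpha:
                if condition == "EC":
                    height += base["ec_alpha"]
                if session == "ON":
                    height += me.alpha_height
                height *= topo[c]
            cf = float(np.clip(cf, fmin, fmax))
            sd = max(sd, 1e-3)
            if height > 0:
                chan_peaks.append((cf, float(height), float(sd)))
        peaks_per_channel.append(chan_peaks)

    return SubjectParams(
        subject_id=subject_id, group=group, session=session,
        condition=condition, offset=np.full(n_chan, offset),
        exponent=np.full(n_chan, exponent), peaks=peaks_per_channel,
    )


def sample_subject_params(spec: CohortSpec, group: str, session: str,
                          condition: str, rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's parameters for a given session and condition."""
    if condition not in ("EC", "EO"):
        raise CohortConfigError(f"unknown condition {condition!r}")
    if session not in ("ON", "OFF", "NA"):
        raise CohortConfigError(f"unknown session {session!r}")
    base = _base_draw(spec, group, rng)
    return _compose(spec, base, subject_id=f"{group}_subj", group=group,
                    session=session, condition=condition)


# ---------------------------------------------------------------------------
# Spectrum / time-series synthesis
# ---------------------------------------------------------------------------

def _model_log_power(freqs: np.ndarray, offset: float, exponent: float,
                     peaks: list[tuple[float, float, float]]) -> np.ndarray:
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive (log10 domain)")
    logp = offset - exponent * np.log10(freqs)
    for cf, pw, sd in peaks:
        logp = logp + pw * np.exp(-((freqs - cf) ** 2) / (2.0 * sd ** 2))
    return logp


def synthesize_psd(params: SubjectParams, spec: CohortSpec,
                   rng: np.random.Generator) -> PowerSpectrumSet:
    """Evaluate the generative model on the spec's frequency grid.

    Noise is additive Gaussian on log10 power (the space in which the model is
    fitted); the returned spectra are in linear power units.
    """
    freqs = spec.freq_grid
    n_chan = len(spec.channel_labels)
    logp = np.empty((n_chan, freqs.size))
    for c in range(n_chan):
        logp[c] = _model_log_power(freqs, params.offset[c], params.exponent[c],
                                   params.peaks[c])
    if spec.spectral_noise_sd > 0:
        logp += rng.normal(0.0, spec.spectral_noise_sd, size=logp.shape)
    return PowerSpectrumSet(
        freqs=freqs.copy(), power=10.0 ** logp,
        channel_labels=list(spec.channel_labels), subject=params.subject_id,
        session=params.session, condition=params.condition,
    )


def synthesize_timeseries(params: SubjectParams, duration_s: float = 60.0,
                          fs_hz: float = 500.0,
                          artifact_spec: ArtifactSpec | None = None,
                          rng: np.random.Generator | None = None,
                          channel_labels: list[str] | None = None,
                          scale: float = 1.0) -> Recording:
    """Generate a time series whose expected one-sided PSD follows the model.

    White Gaussian noise is shaped in the frequency domain by the square root
    of the target PSD (evaluated on the recording's own rFFT grid) and
    inverse-transformed, giving direct control over the spectrum without
    filter design. ``scale`` multiplies the output (0 gives an all-zero
    recording).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    max_cf = max((cf for chan in params.peaks for cf, _, _ in chan), default=0.0)
    if fs_hz <= 2.0 * max_cf:
        raise CohortConfigError(
            f"sampling rate {fs_hz} Hz below Nyquist for peak at {max_cf} Hz")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * fs_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    n_chan = params.offset.size
    data = np.empty((n_chan, n))
    for c in range(n_chan):
        target = np.zeros_like(freqs)
        pos = freqs > 0
        target[pos] = 10.0 ** _model_log_power(
            freqs[pos], params.offset[c], params.exponent[c], params.peaks[c])
        white = np.fft.rfft(rng.standard_normal(n))
        shaped = white * np.sqrt(target * fs_hz / 2.0)
        shaped[0] = 0.0
        data[c] = np.fft.irfft(shaped, n=n)
    data *= scale
    if artifact_spec is not None and artifact_spec.count_per_channel > 0:
        width = max(1, int(round(artifact_spec.width_s * fs_hz)))
        for c in range(n_chan):
            onsets = rng.integers(0, max(1, n - width),
                                  size=artifact_spec.count_per_channel)
            for o in onsets:
                data[c, o:o + width] += artifact_spec.amplitude_uv
    labels = channel_labels if channel_labels is not None else [
        f"ch{c}" for c in range(n_chan)]
    return Recording(data=data, fs=fs_hz, channel_labels=labels,
                     subject=params.subject_id, session=params.session,
                     condition=params.condition)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortRecord:
    params: SubjectParams
    spectra: PowerSpectrumSet | None = None
    recording: Recording | None = None


def _subject_cells(group: str) -> list[tuple[str, str]]:
    sessions = ["OFF", "ON"] if group == "PD" else ["NA"]
    return [(s, c) for s in sessions for c in ("EC", "EO")]


def generate_cohort(spec: CohortSpec, mode: str = "psd",
                    duration_s: float = 60.0, fs_hz: float = 500.0,
                    artifact_spec: ArtifactSpec | None = None,
                    ) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Generate the full cohort and its ground-truth manifest.

    PD subjects carry paired ON and OFF sessions; every subject carries EC and
    EO. ``mode`` selects power spectra ("psd") or time-domain recordings
    ("timeseries"). Fully reproducible from ``spec.seed``.
    """
    if mode not in ("psd", "timeseries"):
        raise CohortConfigError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    rows = []
    roster = [("CTL", i) for i in range(spec.n_ctl)] + \
             [("PD", i) for i in range(spec.n_pd)]
    for group, idx in roster:
        subject_id = f"{group}{idx + 1:03d}"
        base = _base_draw(spec, group, rng)
        for session, condition in _subject_cells(group):
            params = _compose(spec, base, subject_id, group, session, condition)
            rec = CohortRecord(params=params)
            if mode == "psd":
                rec.spectra = synthesize_psd(params, spec, rng)
            else:
                rec.recording = synthesize_timeseries(
                    params, duration_s=duration_s, fs_hz=fs_hz,
                    artifact_spec=artifact_spec, rng=rng,
                    channel_labels=list(spec.channel_labels))
            records.append(rec)
            for c, label in enumerate(spec.channel_labels):
                rows.append({
                    "subject_id": subject_id, "group": group,
                    "session": session, "condition": condition,
                    "channel": label,
                    "true_offset": params.offset[c],
                    "true_exponent": params.exponent[c],
                    "peaks": ";".join(
                        f"{cf:.6g},{pw:.6g},{sd:.6g}"
                        for cf, pw, sd in params.peaks[c]),
                })
    manifest = pd.DataFrame(rows)
    return records, manifest


def write_spectra_tsv(psd: PowerSpectrumSet, path) -> None:
    """One tab-separated matrix: frequency column plus per-channel linear power."""
    df = pd.DataFrame(psd.power.T, columns=psd.channel_labels)
    df.insert(0, "frequency_hz", psd.freqs)
    df.to_csv(path, sep="\t", index=False)


def load_cohort_dir(path) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Read a simulated cohort (manifest.tsv + per-cell *_psd.tsv tables)
    back into records, as written by the ``simulate`` stage."""
    from pathlib import Path

    base = Path(path)
    # keep_default_na: the CTL session label is the literal string "NA"
    manifest = pd.read_csv(base / "manifest.tsv", sep="\t",
                           keep_default_na=False, na_values=[])
    records: list[CohortRecord] = []
    cells = manifest.drop_duplicates(["subject_id", "session", "condition"])
    for _, cell in cells.iterrows():
        stem = f"{cell.subject_id}_{cell.session}_{cell.condition}"
        table = pd.read_csv(base / f"{stem}_psd.tsv", sep="\t")
        labels = [c for c in table.columns if c != "frequency_hz"]
        sub = manifest[(manifest.subject_id == cell.subject_id)
                       & (manifest.session == cell.session)
                       & (manifest.condition == cell.condition)]
        sub = sub.set_index("channel").loc[labels]
        peaks = [[tuple(float(x) for x in trip.split(","))
                  for trip in (spec.split(";") if isinstance(spec, str) and spec
                               else [])]
                 for spec in sub["peaks"]]
        params = SubjectParams(
            subject_id=cell.subject_id, group=cell.group,
            session=cell.session, condition=cell.condition,
            offset=sub["true_offset"].to_numpy(),
            exponent=sub["true_exponent"].to_numpy(), peaks=peaks)
        psd = PowerSpectrumSet(
            freqs=table["frequency_hz"].to_numpy(),
            power=table[labels].to_numpy().T, channel_labels=labels,
            subject=cell.subject_id, session=cell.session,
            condition=cell.condition)
        records.append(CohortRecord(params=params, spectra=psd))
    return records, manifest


def write_recording_tsv(rec: Recording, path) -> None:
    """Time column (s) plus per-channel μV columns."""
    t = np.arange(rec.data.shape[1]) / rec.fs
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.insert(0, "time_s", t)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
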