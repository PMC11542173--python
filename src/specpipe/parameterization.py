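"""Spectral parameterization: aperiodic (offset, exponent) + Gaussian peaks.

Decomposes a power spectrum, in log10 power over linear frequency, into

    log10 P(f) = b − χ·log10 f + Σ_k pw_k · exp(−(f − cf_k)² / (2·sd_k²))

by the iterative procedure used throughout the aperiodic-activity literature:

1. robust straight-line fit of log10 power against log10 frequency (offset b,
   exponent χ), down-weighting points that sit above the line so oscillatory
   bumps do not tilt the slope;
2. subtraction of that line ("flattening");
3. iterative peak detection on the flattened spectrum — take the maximum,
   accept it if it clears both an absolute height floor and a relative
   threshold in SD units of the current residual, estimate its width from the
   half-height crossings, subtract the implied Gaussian, repeat;
4. joint bounded least-squares refinement of all accepted Gaussians;
5. refit of the aperiodic line on the peak-subtracted spectrum;
6. goodness of fit (R² as squared Pearson correlation between log10 data and
   log10 model, and mean absolute error in log10 units).

Fitting is per channel, independently; there is no spatial coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

_HALF_WIDTH = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = this × Gaussian SD


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitSettings:
    """Algorithm settings (defaults are the standard recommended values
    for resting EEG: width limits 1–8 Hz, up to 8 peaks, minimum height 0.1,
    2 SD relative threshold, fixed aperiodic mode, fit range 2–40 Hz)."""

    peak_width_limits: tuple[float, float] = (1.0, 8.0)
    max_n_peaks: int = 8
    min_peak_height: float = 0.1
    peak_threshold: float = 2.0
    aperiodic_mode: str = "fixed"
    fit_range: tuple[float, float] = (2.0, 40.0)
    # Robust first-pass fit: keep points whose positive-clipped residual is at
    # or below this percentile (0–100 scale) of the residual distribution.
    robust_percentile: float = 0.025
    # Pruning of peak guesses before the joint fit.
    edge_std_factor: float = 1.0
    overlap_std_factor: float = 0.75

    def __post_init__(self) -> None:
        lo, hi = self.peak_width_limits
        if not 0 < lo < hi:
            raise ValueError("peak_width_limits must satisfy 0 < min < max")
        if self.max_n_peaks < 0 or self.min_peak_height < 0 or self.peak_threshold < 0:
            raise ValueError("counts and thresholds must be non-negative")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the fixed (no-knee) aperiodic mode is supported")
        if not self.fit_range[0] < self.fit_range[1]:
            raise ValueError("fit_range must be increasing")


class AperiodicParams(NamedTuple):
    offset: float  # log10 power at log10 f = 0
    exponent: float  # slope magnitude in log–log space


class PeakParams(NamedTuple):
    cf: float  # center frequency, Hz
    pw: float  # height above the aperiodic component, log10 power units
    bw: float  # bandwidth, Hz (2 × Gaussian SD)


@dataclass
class SpectralModel:
    aperiodic: AperiodicParams
    peaks: list[PeakParams]
    r_squared: float
    mean_abs_error: float
    freqs: np.ndarray = field(repr=False)
    fit_warning: bool = False

    def aperiodic_log_power(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        return self.aperiodic.offset - self.aperiodic.exponent * np.log10(f)

    def peak_log_power(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        out = np.zeros_like(f, dtype=float)
        for cf, pw, bw in self.peaks:
            sd = bw / 2.0
            out += pw * np.exp(-((f - cf) ** 2) / (2.0 * sd ** 2))
        return out

    def model_log_power(self, freqs: np.ndarray | None = None) -> np.ndarray:
        return self.aperiodic_log_power(freqs) + self.peak_log_power(freqs)


def _as_log(freqs: np.ndarray, power_linear: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.asarray(freqs, dtype=float)
    power_linear = np.asarray(power_linear, dtype=float)
    if np.any(power_linear <= 0):
        raise FitError("power must be strictly positive to fit in log10 space")
    if np.any(freqs <= 0):
        raise FitError("frequencies must be positive")
    return np.log10(freqs), np.log10(power_linear)


def _line_fit(logf: np.ndarray, logp: np.ndarray) -> AperiodicParams:
    if logf.size < 2 or np.ptp(logf) == 0:
        raise FitError("aperiodic fit needs at least two distinct frequencies")
    slope, intercept = np.polyfit(logf, logp, 1)
    return AperiodicParams(offset=float(intercept), exponent=float(-slope))


def fit_aperiodic(freqs: np.ndarray, power_linear: np.ndarray,
                  settings: FitSettings = FitSettings(),
                  robust: bool = True) -> AperiodicParams:
    """First-pass aperiodic fit.

    The robust pass refits using only the points whose positive-clipped
    residual from the initial fit falls at or below ``robust_percentile`` —
    in practice the points on or below the initial line — so that narrowband
    peaks, which only ever add power, do not bias the slope.
    """
    logf, logp = _as_log(freqs, power_linear)
    first = _line_fit(logf, logp)
    if not robust:
        return first
    resid = logp - (first.offset - first.exponent * logf)
    resid = np.clip(resid, 0.0, None)
    thresh = np.percentile(resid, np.clip(settings.robust_percentile, 0.0, 100.0))
    mask = resid <= thresh
    if mask.sum() < 2 or np.ptp(logf[mask]) == 0:
        return first
    return _line_fit(logf[mask], logp[mask])


def flatten_spectrum(freqs: np.ndarray, power_linear: np.ndarray,
                     ap: AperiodicParams) -> np.ndarray:
    """log10 power minus the aperiodic model, elementwise."""
    logf, logp = _as_log(freqs, power_linear)
    return logp - (ap.offset - ap.exponent * logf)


def _gaussian(freqs: np.ndarray, cf: float, pw: float, sd: float) -> np.ndarray:
    return pw * np.exp(-((freqs - cf) ** 2) / (2.0 * sd ** 2))


def _guess_sd(freqs: np.ndarray, flat: np.ndarray, i_max: int,
              settings: FitSettings) -> float:
    """Gaussian SD from the half-height crossing nearest the maximum.

    The one-sided half-width on the shorter flank (doubled) estimates the
    FWHM; this tolerates overlapping peaks on the other flank. The result is
    clamped to the configured bandwidth limits (bw = 2·sd).
    """
    half = flat[i_max] / 2.0
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    left = np.flatnonzero(flat[:i_max] <= half)
    right = np.flatnonzero(flat[i_max + 1:] <= half)
    sides = []
    if left.size:
        sides.append(i_max - left[-1])
    if right.size:
        sides.append(right[0] + 1)
    if sides:
        fwhm = 2.0 * min(sides) * df
        sd = fwhm / _HALF_WIDTH
    else:
        sd = (settings.peak_width_limits[0] + settings.peak_width_limits[1]) / 4.0
    lo, hi = settings.peak_width_limits
    return float(np.clip(sd, lo / 2.0, hi / 2.0))


def detect_peaks(freqs: np.ndarray, flattened: np.ndarray,
                 settings: FitSettings = FitSettings()) -> list[tuple[float, float, float]]:
    """Iterative peak detection on a flattened spectrum.

    Returns (cf, height, sd) guesses in order of detection (descending
    height). The relative SD threshold is recomputed from the residual at
    each iteration, since each subtraction changes the noise estimate.
    """
    freqs = np.asarray(freqs, dtype=float)
    flat = np.array(flattened, dtype=float)
    guesses: list[tuple[float, float, float]] = []
    while len(guesses) < settings.max_n_peaks:
        i = int(np.argmax(flat))
        height = flat[i]
        required = max(settings.min_peak_height,
                       settings.peak_threshold * float(np.std(flat)))
        if height < required or height <= 0:
            break
        sd = _guess_sd(freqs, flat, i, settings)
        cf = float(freqs[i])
        guesses.append((cf, float(height), sd))
        flat -= _gaussian(freqs, cf, height, sd)
    return guesses


def _multi_gauss(freqs: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Sum of Gaussians; x is flat (cf, pw, sd) triples."""
    p = x.reshape(-1, 3)
    d = freqs[:, None] - p[:, 0]
    return np.exp(-(d ** 2) / (2.0 * p[:, 2] ** 2)) @ p[:, 1]


def _multi_gauss_jac(freqs: np.ndarray, x: np.ndarray) -> np.ndarray:
    p = x.reshape(-1, 3)
    d = freqs[:, None] - p[:, 0]
    g = np.exp(-(d ** 2) / (2.0 * p[:, 2] ** 2))
    jac = np.empty((freqs.size, x.size))
    jac[:, 0::3] = p[:, 1] * g * d / p[:, 2] ** 2
    jac[:, 1::3] = g
    jac[:, 2::3] = p[:, 1] * g * d ** 2 / p[:, 2] ** 3
    return jac


def _prune_guesses(guesses: Sequence[tuple[float, float, float]],
                   settings: FitSettings) -> list[tuple[float, float, float]]:
    fmin, fmax = settings.fit_range
    kept = [g for g in guesses
            if (g[0] - fmin) >= settings.edge_std_factor * g[2]
            and (fmax - g[0]) >= settings.edge_std_factor * g[2]]
    # Overlap rule: if two center frequencies are closer than a fraction of
    # the wider peak's SD, keep the taller.
    kept.sort(key=lambda g: g[0])
    drop: set[int] = set()
    for a in range(len(kept) - 1):
        b = a + 1
        if kept[b][0] - kept[a][0] < settings.overlap_std_factor * max(kept[a][2], kept[b][2]):
            drop.add(a if kept[a][1] < kept[b][1] else b)
    return [g for i, g in enumerate(kept) if i not in drop]


def fit_peaks_joint(freqs: np.ndarray, flattened: np.ndarray,
                    guesses: Sequence[tuple[float, float, float]],
                    settings: FitSettings = FitSettings(),
                    max_nfev: int = 100) -> tuple[list[PeakParams], bool]:
    """Simultaneous bounded least-squares fit of all guessed Gaussians.

    Edge and overlap pruning is applied to the guesses first. Returns the
    fitted peaks sorted by center frequency and a warning flag that is set if
    the optimizer failed (in which case the pruned guesses are returned
    verbatim).
    """
    freqs = np.asarray(freqs, dtype=float)
    flat = np.asarray(flattened, dtype=float)
    pruned = _prune_guesses(guesses, settings)
    if not pruned:
        return [], False
    x0 = np.array(pruned, dtype=float).ravel()  # (cf, pw, sd) triples
    sol, ok = _gauss_system_lsq(freqs, flat, x0, settings, with_aperiodic=False,
                                xtol=1e-8, ftol=1e-8, max_nfev=max_nfev)
    peaks = [PeakParams(cf=float(sol[3 * k]), pw=float(sol[3 * k + 1]),
                        bw=float(2.0 * sol[3 * k + 2]))
             for k in range(sol.size // 3)]
    peaks.sort(key=lambda p: p.cf)
    return peaks, not ok


def refit_aperiodic(freqs: np.ndarray, power_linear: np.ndarray,
                    peaks: Sequence[PeakParams],
                    settings: FitSettings = FitSettings()) -> AperiodicParams:
    """Ordinary (non-robust) aperiodic fit on the peak-subtracted spectrum."""
    logf, logp = _as_log(freqs, power_linear)
    peak_model = np.zeros_like(logp)
    for cf, pw, bw in peaks:
        peak_model += _gaussian(np.asarray(freqs, float), cf, pw, bw / 2.0)
    return _line_fit(logf, logp - peak_model)


def _gauss_system_lsq(freqs: np.ndarray, target: np.ndarray, x0: np.ndarray,
                      settings: FitSettings, with_aperiodic: bool,
                      xtol: float = 1e-10, ftol: float = 1e-10,
                      max_nfev: int = 100) -> tuple[np.ndarray, bool]:
    """Bounded least squares for the (optional line +) multi-Gaussian model.

    A projected Levenberg–Marquardt iteration on the normal equations with the
    analytic Jacobian: each trial step is clipped into the feasible box
    (center frequencies inside the fit range, heights ≥ 0, Gaussian SDs
    within the bandwidth limits) before acceptance. At this problem size
    (≤ 26 parameters, ~150 points) the per-iteration cost is a handful of
    small matrix products, so even peak-rich noisy spectra fit in
    milliseconds. ``x0`` is [offset, exponent,] (cf, pw, sd) triples; the
    second return value is a success flag.
    """
    head = 2 if with_aperiodic else 0
    logf = np.log10(freqs) if with_aperiodic else None
    fmin, fmax = settings.fit_range
    sd_lo, sd_hi = settings.peak_width_limits[0] / 2.0, settings.peak_width_limits[1] / 2.0

    if x0.size == head:  # no peaks: closed-form line fit (or nothing to do)
        if head:
            slope, intercept = np.polyfit(logf, target, 1)
            return np.array([intercept, -slope]), True
        return np.asarray(x0, dtype=float), True

    def project(x: np.ndarray) -> np.ndarray:
        t = x[head:].reshape(-1, 3)
        t[:, 0] = np.clip(t[:, 0], fmin, fmax)
        t[:, 1] = np.clip(t[:, 1], 0.0, None)
        t[:, 2] = np.clip(t[:, 2], sd_lo, sd_hi)
        return x

    def residuals(x: np.ndarray) -> np.ndarray:
        out = _multi_gauss(freqs, x[head:]) - target
        if head:
            out += x[0] - x[1] * logf
        return out

    def jacobian(x: np.ndarray) -> np.ndarray:
        jac = np.empty((freqs.size, x.size))
        if head:
            jac[:, 0] = 1.0
            jac[:, 1] = -logf
        jac[:, head:] = _multi_gauss_jac(freqs, x[head:])
        return jac

    x = project(np.array(x0, dtype=float))
    r = residuals(x)
    cost = float(r @ r)
    lam = 1e-3
    for _ in range(max_nfev):
        jac = jacobian(x)
        grad = jac.T @ r
        hess = jac.T @ jac
        diag = np.diag(hess).copy()
        diag[diag <= 0] = 1e-12
        n_par = x.size
        moved = False
        for _ in range(6):
            damped = hess.copy()
            damped.flat[:: n_par + 1] += lam * diag
            try:
                dx = np.linalg.solve(damped, -grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_new = project(x + dx)
            r_new = residuals(x_new)
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                step = float(np.linalg.norm(x_new - x))
                rel_drop = (cost - cost_new) / max(cost, 1e-300)
                x, r, cost = x_new, r_new, cost_new
                lam = max(lam * 0.3, 1e-12)
                moved = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not moved:
            break  # stationary (possibly at a bound): converged
        if step < xtol * (xtol + float(np.linalg.norm(x))) or rel_drop < ftol:
            break
    return x, True


def _joint_refine(freqs: np.ndarray, logp: np.ndarray, ap: AperiodicParams,
                  peaks: list[PeakParams], settings: FitSettings,
                  max_nfev: int = 100,
                  ) -> tuple[AperiodicParams, list[PeakParams], bool]:
    """Final simultaneous refinement of aperiodic and peak parameters.

    The staged passes (robust line → peaks → line refit) are excellent
    initializers but each conditions on the other component's previous
    estimate; one bounded least-squares polish of the full model removes the
    residual coupling bias, so noiseless in-class spectra are recovered to
    numerical precision.
    """
    n = len(peaks)
    triples = np.array([[p.cf, p.pw, p.bw / 2.0] for p in peaks]).ravel() \
        if n else np.empty(0)
    x0 = np.concatenate([[ap.offset, ap.exponent], triples])
    x, ok = _gauss_system_lsq(freqs, logp, x0, settings, with_aperiodic=True,
                              xtol=1e-10, ftol=1e-10, max_nfev=max_nfev)
    if not ok:
        return ap, peaks, True
    new_ap = AperiodicParams(offset=float(x[0]), exponent=float(x[1]))
    new_peaks = [PeakParams(cf=float(x[2 + 3 * k]), pw=float(x[3 + 3 * k]),
                            bw=float(2.0 * x[4 + 3 * k]))
                 for k in range((x.size - 2) // 3)]
    new_peaks.sort(key=lambda p: p.cf)
    return new_ap, new_peaks, False


def _r_squared(logp: np.ndarray, model: np.ndarray) -> float:
    resid = logp - model
    if np.allclose(resid, 0.0, atol=1e-12):
        return 1.0
    if np.std(logp) == 0 or np.std(model) == 0:
        return 0.0
    r = np.corrcoef(logp, model)[0, 1]
    return float(r ** 2)


def fit_spectrum(freqs: np.ndarray, power_linear: np.ndarray,
                 settings: FitSettings = FitSettings()) -> SpectralModel:
    """Full decomposition of one channel's spectrum.

    The input grid is trimmed to ``settings.fit_range`` first; all reported
    quantities refer to that range. Deterministic for fixed input.
    """
    freqs = np.asarray(freqs, dtype=float)
    power_linear = np.asarray(power_linear, dtype=float)
    eps = 1e-9
    mask = (freqs >= settings.fit_range[0] - eps) & (freqs <= settings.fit_range[1] + eps)
    if mask.sum() < 3:
        raise FitError("fit range covers fewer than 3 grid points")
    f, p = freqs[mask], power_linear[mask]

    ap0 = fit_aperiodic(f, p, settings, robust=True)
    flat = flatten_spectrum(f, p, ap0)
    guesses = detect_peaks(f, flat, settings)
    peaks, warn = fit_peaks_joint(f, flat, guesses, settings, max_nfev=12)
    ap = refit_aperiodic(f, p, peaks, settings)

    logp = np.log10(p)
    ap, peaks, refine_warn = _joint_refine(f, logp, ap, peaks, settings,
                                           max_nfev=20)
    warn = warn or refine_warn
    model = SpectralModel(aperiodic=ap, peaks=peaks, r_squared=0.0,
                          mean_abs_error=0.0, freqs=f, fit_warning=warn)
    mod = model.model_log_power()
    model.r_squared = _r_squared(logp, mod)
    model.mean_abs_error = float(np.mean(np.abs(logp - mod)))
    return model


def qc_fits(fits: pd.DataFrame, participant_col: str = "subject",
            condition_col: str = "condition", r2_col: str = "r_squared",
            n_sd: float = 3.0) -> pd.DataFrame:
    """Participant-level goodness-of-fit screening.

    For each participant × condition, the mean R² across channels (and
    sessions) is computed; a cell is flagged when its mean falls more than
    ``n_sd`` SDs below the grand mean of all cells. Flagged participants are
    reported, not dropped — exclusion is left to the caller.
    """
    if fits[participant_col].nunique() < 2:
        raise ValueError("QC needs at least 2 participants")
    cell = (fits.groupby([participant_col, condition_col])[r2_col]
            .mean().rename("mean_r2").reset_index())
    grand_mean = cell["mean_r2"].mean()
    grand_sd = cell["mean_r2"].std(ddof=1)
    cutoff = grand_mean - n_sd * grand_sd
    cell["flagged"] = False if (not np.isfinite(grand_sd)) or grand_sd == 0 \
        else cell["mean_r2"] < cutoff
    cell.attrs["cutoff"] = float(cutoff)
    return cell
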