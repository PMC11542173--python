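"""Configuration, orchestration, and tabular I/O for end-to-end runs.

A run goes: simulate (or load spectra) → estimate PSDs (time-series input
only) → parameterize every channel → band power → cluster-based permutation
contrasts → report. Configuration is a single TOML file with one block per
stage; absent keys fall back to the standard settings (2000 ms / 50% epochs,
±150 μV rejection, 2–40 Hz fit at the recommended parameterization settings,
alpha 8–13 / beta 13–30, 10,000 permutations). Unknown keys are rejected with
a suggestion rather than ignored. Reruns with the same config and inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .bands import BandDefinition, parameterized_band_power, total_band_power
from .cluster import (AdjacencyGraph, build_adjacency, cohens_d,
                      electrode_t_map, permutation_cluster_test)
from .cohort import ArtifactSpec, CohortRecord, CohortSpec, GroupParams, \
    generate_cohort, _default_groups
from .estimation import EstimationError, PowerSpectrumSet, check_retention, \
    estimate_psd, restrict_range
from .montage import montage_positions
from .parameterization import FitSettings, fit_spectrum, qc_fits

log = logging.getLogger("specpipe")

MEASURES = ("offset", "exponent", "total_alpha", "total_beta",
            "param_alpha", "param_beta")
PAIRS = ("OFF_vs_CTL", "ON_vs_CTL", "ON_vs_OFF", "EC_vs_EO")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastSpec:
    measure: str
    pair: str
    condition: str = "EC"  # for group/medication pairs
    group: str = "CTL"  # for EC_vs_EO: CTL, PD_ON or PD_OFF
    n_permutations: int = 10000
    cluster_alpha: float = 0.05
    seed: int | None = None  # default: derived from the run seed

    def __post_init__(self) -> None:
        if self.pair not in PAIRS:
            raise ConfigError(f"unknown pair {self.pair!r}; known: {PAIRS}")
        if self.condition not in ("EC", "EO"):
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.group not in ("CTL", "PD_ON", "PD_OFF"):
            raise ConfigError(f"unknown group {self.group!r}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0 < self.cluster_alpha < 1:
            raise ConfigError("cluster_alpha must be in (0, 1)")

    @property
    def label(self) -> str:
        tag = self.group if self.pair == "EC_vs_EO" else self.condition
        return f"{self.pair}:{self.measure}:{tag}"


@dataclass
class EstimationSettings:
    epoch_len_ms: float = 2000.0
    overlap: float = 0.5
    threshold_uv: float = 150.0
    min_retention: float = 0.5
    pad_factor: int = 2
    window: str = "hamming"
    fmin: float = 2.0
    fmax: float = 40.0


def _default_contrasts() -> list[ContrastSpec]:
    out = []
    for pair in ("OFF_vs_CTL", "ON_vs_CTL", "ON_vs_OFF"):
        for measure in MEASURES:
            out.append(ContrastSpec(measure=measure, pair=pair, condition="EC"))
    return out


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    input_dir: str | None = None  # previously simulated cohort to load
    log_level: str = "INFO"
    overwrite: bool = False
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    simulate_mode: str = "psd"
    duration_s: float = 60.0
    fs_hz: float = 500.0
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    fit_settings: FitSettings = field(default_factory=FitSettings)
    bands: tuple[BandDefinition, ...] = field(
        default_factory=lambda: (BandDefinition("alpha", 8.0, 13.0, False),
                                 BandDefinition("beta", 13.0, 30.0, True)))
    contrasts: list[ContrastSpec] = field(default_factory=_default_contrasts)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)

    def fingerprint(self) -> str:
        blob = json.dumps(self.echo(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def echo(self) -> dict:
        return {
            "version": _version,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "input_dir": self.input_dir,
            "simulate_mode": self.simulate_mode,
            "duration_s": self.duration_s,
            "fs_hz": self.fs_hz,
            "cohort": {k: v if isinstance(v, (int, float, str, bool, type(None)))
                       else repr(v) for k, v in self.cohort.items()},
            "estimation": dataclasses.asdict(self.estimation),
            "parameterization": dataclasses.asdict(self.fit_settings),
            "bands": [list(b) for b in self.bands],
            "contrasts": [dataclasses.asdict(c) for c in self.contrasts],
        }


def _check_keys(block: dict, known: set[str], context: str) -> None:
    for key in block:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1, cutoff=0.4)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{extra}")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Absent keys take their defaults; unknown keys and invalid values raise a
    ConfigError naming the key.
    """
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    top_known = {"run", "cohort", "simulate", "estimation", "parameterization",
                 "bands", "contrasts"}
    _check_keys(raw, top_known, "config")

    cfg = RunConfig()
    run = raw.get("run", {})
    _check_keys(run, {"seed", "out_dir", "input_dir", "log_level",
                      "overwrite"}, "[run]")
    cfg.seed = int(run.get("seed", cfg.seed))
    cfg.out_dir = str(run.get("out_dir", cfg.out_dir))
    if "input_dir" in run:
        cfg.input_dir = str(run["input_dir"])
    cfg.log_level = str(run.get("log_level", cfg.log_level))
    cfg.overwrite = bool(run.get("overwrite", cfg.overwrite))

    sim = raw.get("simulate", {})
    _check_keys(sim, {"mode", "duration_s", "fs_hz"}, "[simulate]")
    cfg.simulate_mode = str(sim.get("mode", cfg.simulate_mode))
    if cfg.simulate_mode not in ("psd", "timeseries"):
        raise ConfigError("simulate.mode must be 'psd' or 'timeseries'")
    cfg.duration_s = float(sim.get("duration_s", cfg.duration_s))
    cfg.fs_hz = float(sim.get("fs_hz", cfg.fs_hz))

    coh = dict(raw.get("cohort", {}))
    coh_known = {"n_ctl", "n_pd", "spectral_noise_sd", "seed",
                 "pd_offset_shift", "pd_exponent_shift"}
    _check_keys(coh, coh_known, "[cohort]")
    shifts = (coh.pop("pd_offset_shift", None), coh.pop("pd_exponent_shift", None))
    if any(s is not None for s in shifts):
        groups = _default_groups()
        ctl = groups["CTL"]
        groups["PD"] = dataclasses.replace(
            ctl,
            offset_mean=ctl.offset_mean + float(shifts[0] or 0.0),
            exponent_mean=ctl.exponent_mean + float(shifts[1] or 0.0))
        coh["group_params"] = groups
    cfg.cohort = coh

    est = raw.get("estimation", {})
    est_known = {f.name for f in dataclasses.fields(EstimationSettings)}
    _check_keys(est, est_known, "[estimation]")
    try:
        cfg.estimation = EstimationSettings(**{**dataclasses.asdict(cfg.estimation), **est})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [estimation] value: {exc}") from exc

    par = dict(raw.get("parameterization", {}))
    par_known = {f.name for f in dataclasses.fields(FitSettings)}
    _check_keys(par, par_known, "[parameterization]")
    for tup_key in ("peak_width_limits", "fit_range"):
        if tup_key in par:
            par[tup_key] = tuple(par[tup_key])
    try:
        cfg.fit_settings = FitSettings(**{**dataclasses.asdict(cfg.fit_settings), **par})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [parameterization] value: {exc}") from exc

    if "bands" in raw:
        bands = []
        items = list(raw["bands"].items())
        for i, (name, edges) in enumerate(items):
            if len(edges) != 2 or not edges[0] < edges[1]:
                raise ConfigError(f"band {name!r} must be [fmin, fmax] with fmin < fmax")
            bands.append(BandDefinition(name, float(edges[0]), float(edges[1]),
                                        upper_inclusive=(i == len(items) - 1)))
        cfg.bands = tuple(bands)

    if "contrasts" in raw:
        specs = []
        known = {f.name for f in dataclasses.fields(ContrastSpec)}
        for i, block in enumerate(raw["contrasts"]):
            _check_keys(block, known, f"[[contrasts]] #{i + 1}")
            if block.get("measure") not in MEASURES:
                raise ConfigError(
                    f"unknown measure {block.get('measure')!r}; known: {MEASURES}")
            specs.append(ContrastSpec(**block))
        cfg.contrasts = specs
    return cfg


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    seed: int
    fingerprint: str
    manifest: pd.DataFrame
    parameters: pd.DataFrame
    band_power: pd.DataFrame
    qc: pd.DataFrame
    clusters: pd.DataFrame
    exclusions: pd.DataFrame
    retention: pd.DataFrame
    config_echo: dict


def _spectra_from_records(records: list[CohortRecord],
                          est: EstimationSettings,
                          ) -> tuple[list[PowerSpectrumSet], pd.DataFrame, list[dict]]:
    """Estimation stage: produce restricted spectra + retention bookkeeping."""
    spectra: list[PowerSpectrumSet] = []
    retention_rows: list[dict] = []
    failed: list[dict] = []
    for rec in records:
        meta = rec.params
        if rec.spectra is not None:
            psd = restrict_range(rec.spectra, est.fmin, est.fmax)
            retention = 1.0
            included = True
        else:
            psd, es = estimate_psd(
                rec.recording, epoch_len_ms=est.epoch_len_ms, overlap=est.overlap,
                threshold_uv=est.threshold_uv, pad_factor=est.pad_factor,
                fmin=est.fmin, fmax=est.fmax, window=est.window)
            retention = es.retention_fraction
            included = check_retention(es, est.min_retention)
        retention_rows.append({
            "subject_id": meta.subject_id, "group": meta.group,
            "session": meta.session, "condition": meta.condition,
            "retention_fraction": retention, "included": included,
        })
        if not included:
            failed.append({"subject_id": meta.subject_id,
                           "rule": f"retention < {est.min_retention:.0%} "
                                   f"({meta.session}/{meta.condition})"})
        spectra.append(psd)
    # A subject is excluded outright if any of their recordings fails QC.
    excluded_ids = {f["subject_id"] for f in failed}
    keep_records, keep_spectra = [], []
    for rec, psd in zip(records, spectra):
        if rec.params.subject_id not in excluded_ids:
            keep_records.append(rec)
            keep_spectra.append(psd)
    exclusions = pd.DataFrame(failed, columns=["subject_id", "rule"]).drop_duplicates()
    retention = pd.DataFrame(retention_rows)
    retention.attrs["kept"] = keep_records
    return keep_spectra, retention, [dict(r) for _, r in exclusions.iterrows()]


def parameterize_spectra(records: list[CohortRecord],
                         spectra: list[PowerSpectrumSet],
                         settings: FitSettings,
                         bands: tuple[BandDefinition, ...],
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every channel and tabulate parameters plus band powers (tidy)."""
    param_rows, band_rows = [], []
    for rec, psd in zip(records, spectra):
        meta = rec.params
        for c, label in enumerate(psd.channel_labels):
            model = fit_spectrum(psd.freqs, psd.power[c], settings)
            param_rows.append({
                "subject_id": meta.subject_id, "group": meta.group,
                "session": meta.session, "condition": meta.condition,
                "channel": label,
                "offset": model.aperiodic.offset,
                "exponent": model.aperiodic.exponent,
                "r_squared": model.r_squared,
                "mean_abs_error": model.mean_abs_error,
                "n_peaks": len(model.peaks),
                "peaks": ";".join(f"{p.cf:.6g},{p.pw:.6g},{p.bw:.6g}"
                                  for p in model.peaks),
                "fit_warning": model.fit_warning,
            })
            for band in bands:
                band_rows.append({
                    "subject_id": meta.subject_id, "group": meta.group,
                    "session": meta.session, "condition": meta.condition,
                    "channel": label, "band": band.name,
                    "total_power": total_band_power(psd.freqs, psd.power[c], band),
                    "parameterized_power": parameterized_band_power(model, band),
                })
    return pd.DataFrame(param_rows), pd.DataFrame(band_rows)


def measure_frame(parameters: pd.DataFrame, band_power: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(subject, session, condition, channel) table of all measures."""
    keys = ["subject_id", "group", "session", "condition", "channel"]
    wide = parameters[keys + ["offset", "exponent"]].copy()
    for band in band_power["band"].unique():
        sub = band_power[band_power["band"] == band]
        total = sub[keys + ["total_power"]].rename(
            columns={"total_power": f"total_{band}"})
        param = sub[keys + ["parameterized_power"]].rename(
            columns={"parameterized_power": f"param_{band}"})
        wide = wide.merge(total, on=keys).merge(param, on=keys)
    return wide


def _matrix(frame: pd.DataFrame, measure: str, labels: list[str],
            group: str, session: str, condition: str) -> np.ndarray:
    sel = frame[(frame["group"] == group) & (frame["session"] == session)
                & (frame["condition"] == condition)]
    if sel.empty:
        raise ConfigError(
            f"no data for group={group} session={session} condition={condition}")
    pivot = sel.pivot(index="subject_id", columns="channel", values=measure)
    return pivot.sort_index()[labels].to_numpy()


def contrast_data(frame: pd.DataFrame, spec: ContrastSpec,
                  labels: list[str]) -> tuple[str, np.ndarray, np.ndarray | None]:
    """Assemble (kind, a, b) matrices for one contrast."""
    m = spec.measure
    if spec.pair in ("OFF_vs_CTL", "ON_vs_CTL"):
        session = "OFF" if spec.pair.startswith("OFF") else "ON"
        a = _matrix(frame, m, labels, "PD", session, spec.condition)
        b = _matrix(frame, m, labels, "CTL", "NA", spec.condition)
        return "independent", a, b
    if spec.pair == "ON_vs_OFF":
        on = _matrix(frame, m, labels, "PD", "ON", spec.condition)
        off = _matrix(frame, m, labels, "PD", "OFF", spec.condition)
        return "paired", on - off, None
    group = "CTL" if spec.group == "CTL" else "PD"
    session = {"CTL": "NA", "PD_ON": "ON", "PD_OFF": "OFF"}[spec.group]
    ec = _matrix(frame, m, labels, group, session, "EC")
    eo = _matrix(frame, m, labels, group, session, "EO")
    return "paired", ec - eo, None


def run_contrasts(frame: pd.DataFrame, contrasts: list[ContrastSpec],
                  adjacency: AdjacencyGraph, seed: int) -> pd.DataFrame:
    """Run every configured contrast; one row per cluster, or a single
    non-significant summary row (whole-scalp max |t| and mean d) when a
    contrast yields no clusters."""
    labels = adjacency.channel_labels
    rows = []
    for i, spec in enumerate(contrasts):
        kind, a, b = contrast_data(frame, spec, labels)
        contrast_seed = spec.seed if spec.seed is not None \
            else (seed * 100003 + 7919 * i) % (2 ** 31)
        rng = np.random.default_rng(contrast_seed)
        results = permutation_cluster_test(
            kind, a, b, adjacency, n_permutations=spec.n_permutations,
            cluster_alpha=spec.cluster_alpha, rng=rng)
        base = {"contrast": spec.label, "measure": spec.measure,
                "pair": spec.pair, "kind": kind}
        if results:
            for j, res in enumerate(results):
                rows.append({**base, "cluster_id": j + 1,
                             "channels": ",".join(res.channels),
                             "n_channels": len(res.channels),
                             "sign": res.sign, "mass": res.mass,
                             "t_max": res.t_max, "d_mean": res.d_mean,
                             "p_value": res.p_value,
                             "significant": res.significant})
        else:
            t_map, _ = electrode_t_map(kind, a, b)
            d = cohens_d(kind, a, b)
            rows.append({**base, "cluster_id": 0, "channels": "",
                         "n_channels": 0, "sign": 0, "mass": 0.0,
                         "t_max": float(np.max(np.abs(t_map))),
                         "d_mean": float(np.nanmean(d)),
                         "p_value": np.nan, "significant": False})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig,
                 cohort: tuple[list[CohortRecord], pd.DataFrame] | None = None,
                 artifact_spec: ArtifactSpec | None = None) -> RunReport:
    """Execute simulate → estimate → parameterize → band power → cluster tests.

    ``cohort`` may inject pre-generated records (e.g. loaded spectra), in
    which case the simulate stage is skipped.
    """
    if cohort is not None:
        records, manifest = cohort
    elif config.input_dir is not None:
        from .cohort import load_cohort_dir
        log.info("loading cohort from %s (simulate stage skipped)",
                 config.input_dir)
        records, manifest = load_cohort_dir(config.input_dir)
    else:
        spec = config.cohort_spec()
        log.info("simulating cohort (n_ctl=%d, n_pd=%d, mode=%s)",
                 spec.n_ctl, spec.n_pd, config.simulate_mode)
        records, manifest = generate_cohort(
            spec, mode=config.simulate_mode, duration_s=config.duration_s,
            fs_hz=config.fs_hz, artifact_spec=artifact_spec)

    spectra, retention, exclusion_rows = _spectra_from_records(records, config.estimation)
    kept = retention.attrs["kept"]
    log.info("estimation complete: %d spectra, %d subjects excluded",
             len(spectra), len(exclusion_rows))

    parameters, band_power = parameterize_spectra(
        kept, spectra, config.fit_settings, config.bands)
    qc = qc_fits(parameters, participant_col="subject_id")
    frame = measure_frame(parameters, band_power)

    positions = montage_positions(tuple(spectra[0].channel_labels))
    adjacency = build_adjacency(positions["label"].tolist(),
                                positions[["x", "y"]].to_numpy())
    clusters = run_contrasts(frame, config.contrasts, adjacency, config.seed)

    return RunReport(
        seed=config.seed, fingerprint=config.fingerprint(), manifest=manifest,
        parameters=parameters, band_power=band_power, qc=qc, clusters=clusters,
        exclusions=pd.DataFrame(exclusion_rows, columns=["subject_id", "rule"]),
        retention=retention,
        config_echo=config.echo(),
    )


def write_results(report: RunReport, out_dir, overwrite: bool = False) -> list[Path]:
    """Write all report tables as TSV plus a JSON run summary.

    Refuses to overwrite a directory that already holds a run summary unless
    ``overwrite`` is set. Column order and float formatting are stable so
    reruns are byte-identical.
    """
    out = Path(out_dir)
    marker = out / "run_summary.json"
    if marker.exists() and not overwrite:
        raise FileExistsError(
            f"{out} already contains results; pass overwrite=True (--overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "manifest.tsv": report.manifest,
        "parameters.tsv": report.parameters,
        "band_power.tsv": report.band_power,
        "qc_r2.tsv": report.qc,
        "clusters.tsv": report.clusters,
        "exclusions.tsv": report.exclusions,
        "retention.tsv": report.retention,
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    summary = {
        "seed": report.seed,
        "fingerprint": report.fingerprint,
        "n_spectra": int(len(report.parameters) and
                         report.parameters.groupby(
                             ["subject_id", "session", "condition"]).ngroups),
        "n_excluded": int(len(report.exclusions)),
        "n_significant_clusters": int(report.clusters["significant"].sum())
        if len(report.clusters) else 0,
        "config": report.config_echo,
    }
    marker.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(marker)
    return written
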