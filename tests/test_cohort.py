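"""Synthetic cohort generation: parameter sampling, spectra, time series."""

import dataclasses

import numpy as np
import pytest

from specpipe.cohort import (ArtifactSpec, CohortConfigError, CohortSpec,
                             ConditionEffects, GroupParams, PeakTemplate,
                             generate_cohort, sample_subject_params,
                             synthesize_psd, synthesize_timeseries)
from specpipe.estimation import estimate_psd, reject_epochs, segment_recording
from specpipe.parameterization import fit_spectrum


def zero_variance_spec(**overrides):
    groups = {
        "CTL": GroupParams(offset_mean=0.5, offset_sd=0.0, exponent_mean=1.0,
                           exponent_sd=0.0,
                           peaks=(PeakTemplate(cf=10.0, pw=0.5, sd=1.5),)),
        "PD": GroupParams(offset_mean=0.7, offset_sd=0.0, exponent_mean=1.1,
                          exponent_sd=0.0,
                          peaks=(PeakTemplate(cf=10.0, pw=0.5, sd=1.5),)),
    }
    kwargs = dict(n_ctl=2, n_pd=2, channel_labels=("c1", "c2"),
                  group_params=groups,
                  condition_effects=ConditionEffects(offset=0.1, exponent=0.05,
                                                     alpha_height=0.2),
                  topography_weights=np.array([1.0, 1.0]),
                  spectral_noise_sd=0.0, seed=0)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


class TestSampling:
    def test_zero_variance_draw_equals_distribution_means(self):
        spec = zero_variance_spec()
        rng = np.random.default_rng(0)
        p = sample_subject_params(spec, "CTL", "NA", "EC", rng)
        assert np.allclose(p.offset, 0.5 + 0.1)  # group mean + EC shift
        assert np.allclose(p.exponent, 1.0 + 0.05)
        for chan_peaks in p.peaks:
            assert chan_peaks == [(10.0, pytest.approx(0.7), 1.5)]

    def test_identical_rng_state_identical_params(self):
        spec = CohortSpec(n_ctl=2, n_pd=2)
        a = sample_subject_params(spec, "PD", "OFF", "EC",
                                  np.random.default_rng(42))
        b = sample_subject_params(spec, "PD", "OFF", "EC",
                                  np.random.default_rng(42))
        assert np.array_equal(a.offset, b.offset)
        assert np.array_equal(a.exponent, b.exponent)
        assert a.peaks == b.peaks

    def test_offset_gap_yields_expected_cohens_d(self):
        # Brute-force oracle: 1000 draws per group, pooled-SD d for a 0.2
        # offset gap with SD 0.1 is 0.2/0.1 = 2.0.
        groups = {
            "CTL": GroupParams(offset_mean=0.5, offset_sd=0.1,
                               exponent_mean=1.0, exponent_sd=0.0),
            "PD": GroupParams(offset_mean=0.7, offset_sd=0.1,
                              exponent_mean=1.0, exponent_sd=0.0),
        }
        spec = zero_variance_spec(group_params=groups,
                                  condition_effects=ConditionEffects())
        rng = np.random.default_rng(11)
        ctl = np.array([sample_subject_params(spec, "CTL", "NA", "EO", rng)
                        .offset[0] for _ in range(1000)])
        pd_ = np.array([sample_subject_params(spec, "PD", "OFF", "EO", rng)
                        .offset[0] for _ in range(1000)])
        pooled = np.sqrt((ctl.var(ddof=1) + pd_.var(ddof=1)) / 2)
        d = (pd_.mean() - ctl.mean()) / pooled
        assert d == pytest.approx(2.0, abs=0.1)

    def test_unknown_group_rejected(self):
        with pytest.raises(CohortConfigError):
            sample_subject_params(CohortSpec(), "PATIENT", "NA", "EC",
                                  np.random.default_rng(0))

    def test_aperiodic_correlation_preserves_marginals(self):
        spec = CohortSpec(n_ctl=2, n_pd=2)
        rng = np.random.default_rng(1)
        draws = [sample_subject_params(spec, "CTL", "NA", "EO", rng)
                 for _ in range(2000)]
        b = np.array([p.offset[0] for p in draws])
        chi = np.array([p.exponent[0] for p in draws])
        gp = spec.group_params["CTL"]
        assert b.std(ddof=1) == pytest.approx(gp.offset_sd, rel=0.1)
        assert chi.std(ddof=1) == pytest.approx(gp.exponent_sd, rel=0.1)
        assert np.corrcoef(b, chi)[0, 1] == pytest.approx(gp.aperiodic_corr,
                                                          abs=0.02)


class TestSynthesizePSD:
    def test_closed_form_aperiodic_values(self):
        spec = zero_variance_spec(
            channel_labels=("c1",),
            freq_grid=np.array([1.0, 10.0, 20.0]),
            group_params={"CTL": GroupParams(1.0, 0.0, 1.0, 0.0), "PD":
                          GroupParams(1.0, 0.0, 1.0, 0.0)},
            condition_effects=ConditionEffects(),
            topography_weights=np.array([1.0]))
        p = sample_subject_params(spec, "CTL", "NA", "EO",
                                  np.random.default_rng(0))
        psd = synthesize_psd(p, spec, np.random.default_rng(0))
        assert psd.power[0, 0] == pytest.approx(10.0, rel=1e-12)  # 1 Hz
        assert psd.power[0, 1] == pytest.approx(1.0, rel=1e-12)  # 10 Hz

    def test_gaussian_peak_values(self, fit_grid):
        spec = zero_variance_spec(
            channel_labels=("c1",), freq_grid=fit_grid,
            group_params={"CTL": GroupParams(0.0, 0.0, 0.0, 0.0,
                          peaks=(PeakTemplate(cf=10.0, pw=0.5, sd=1.5),)),
                          "PD": GroupParams(0.0, 0.0, 0.0, 0.0)},
            condition_effects=ConditionEffects(),
            topography_weights=np.array([1.0]))
        p = sample_subject_params(spec, "CTL", "NA", "EO",
                                  np.random.default_rng(0))
        psd = synthesize_psd(p, spec, np.random.default_rng(0))
        log10p = np.log10(psd.power[0])
        at = lambda f: log10p[np.argmin(np.abs(fit_grid - f))]
        assert at(10.0) == pytest.approx(0.5, abs=1e-12)
        assert at(13.0) == pytest.approx(0.5 * np.exp(-9 / 4.5), abs=1e-12)

    def test_offset_shift_doubles_linear_power(self):
        spec = zero_variance_spec()
        rng = np.random.default_rng(0)
        p1 = sample_subject_params(spec, "CTL", "NA", "EO", rng)
        p2 = dataclasses.replace(p1, offset=p1.offset + np.log10(2.0))
        s1 = synthesize_psd(p1, spec, np.random.default_rng(1))
        s2 = synthesize_psd(p2, spec, np.random.default_rng(1))
        assert np.allclose(s2.power, 2.0 * s1.power, rtol=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(CohortConfigError):
            zero_variance_spec(freq_grid=np.array([0.0, 1.0, 2.0]))

    def test_roundtrip_noiseless_aperiodic_recovery(self, fit_grid):
        spec = zero_variance_spec(
            channel_labels=("c1",), freq_grid=fit_grid,
            group_params={"CTL": GroupParams(0.8, 0.0, 1.2, 0.0),
                          "PD": GroupParams(0.8, 0.0, 1.2, 0.0)},
            condition_effects=ConditionEffects(),
            topography_weights=np.array([1.0]))
        p = sample_subject_params(spec, "CTL", "NA", "EO",
                                  np.random.default_rng(0))
        psd = synthesize_psd(p, spec, np.random.default_rng(0))
        m = fit_spectrum(psd.freqs, psd.power[0])
        assert m.aperiodic.offset == pytest.approx(0.8, abs=1e-6)
        assert m.aperiodic.exponent == pytest.approx(1.2, abs=1e-6)


class TestSynthesizeTimeseries:
    def params_one_channel(self, offset=1.0, exponent=1.0, peaks=()):
        from specpipe.cohort import SubjectParams
        return SubjectParams(subject_id="s", group="CTL", session="NA",
                             condition="EC", offset=np.array([offset]),
                             exponent=np.array([exponent]),
                             peaks=[list(peaks)])

    def test_roundtrip_exponent_recovery(self):
        errs = []
        for i in range(20):
            rec = synthesize_timeseries(self.params_one_channel(),
                                        rng=np.random.default_rng(100 + i))
            psd, _ = estimate_psd(rec)
            m = fit_spectrum(psd.freqs, psd.power[0])
            errs.append(m.aperiodic.exponent - 1.0)
        assert abs(np.mean(errs)) < 0.1

    def test_psd_matches_target_model(self):
        # Median absolute log10 error of the estimated spectrum against the
        # generating model, 2-40 Hz.
        meds = []
        for i in range(20):
            rec = synthesize_timeseries(self.params_one_channel(),
                                        rng=np.random.default_rng(200 + i))
            psd, _ = estimate_psd(rec)
            target = 1.0 - 1.0 * np.log10(psd.freqs)
            meds.append(np.median(np.abs(np.log10(psd.power[0]) - target)))
        assert np.median(meds) < 0.05

    def test_artifact_injection_forces_rejection(self):
        rec = synthesize_timeseries(
            self.params_one_channel(),
            artifact_spec=ArtifactSpec(amplitude_uv=300.0, count_per_channel=1),
            rng=np.random.default_rng(5))
        es = reject_epochs(segment_recording(rec))
        assert es.rejected_mask.any()

    def test_zero_scale_gives_all_zero_recording(self):
        rec = synthesize_timeseries(self.params_one_channel(), scale=0.0,
                                    rng=np.random.default_rng(0))
        assert np.all(rec.data == 0.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(CohortConfigError):
            synthesize_timeseries(
                self.params_one_channel(peaks=[(30.0, 0.5, 1.5)]), fs_hz=50.0,
                rng=np.random.default_rng(0))


class TestGenerateCohort:
    def test_paired_structure_and_counts(self):
        spec = CohortSpec(n_ctl=2, n_pd=2, seed=1)
        records, manifest = generate_cohort(spec)
        # Every subject carries EC and EO; PD additionally carries ON and OFF.
        assert len(records) == 2 * 2 + 2 * 2 * 2
        cells = manifest.groupby(["subject_id", "session", "condition"]).ngroups
        assert cells == len(records)
        for sid, sub in manifest.groupby("subject_id"):
            combos = set(zip(sub["session"], sub["condition"]))
            if sub["group"].iloc[0] == "PD":
                assert combos == {("ON", "EC"), ("ON", "EO"),
                                  ("OFF", "EC"), ("OFF", "EO")}
            else:
                assert combos == {("NA", "EC"), ("NA", "EO")}

    def test_default_cohort_size(self):
        spec = CohortSpec(seed=0)
        assert spec.n_ctl == 26 and spec.n_pd == 26

    def test_same_seed_byte_identical_manifests(self):
        a = generate_cohort(CohortSpec(n_ctl=2, n_pd=2, seed=9))[1]
        b = generate_cohort(CohortSpec(n_ctl=2, n_pd=2, seed=9))[1]
        assert a.to_csv(sep="\t") == b.to_csv(sep="\t")

    def test_on_off_sessions_share_subject_parameters(self):
        records, manifest = generate_cohort(CohortSpec(n_ctl=2, n_pd=2, seed=3))
        pd_rows = manifest[manifest["group"] == "PD"]
        for (_, cond), sub in pd_rows.groupby(["subject_id", "condition"]):
            on = sub[sub["session"] == "ON"]
            off = sub[sub["session"] == "OFF"]
            # Null medication effect: identical ground-truth parameters.
            assert np.allclose(on["true_offset"].values,
                               off["true_offset"].values)
            assert np.allclose(on["true_exponent"].values,
                               off["true_exponent"].values)

    def test_monotone_effect_injection(self, fit_grid):
        # Larger group offset gaps must produce larger empirical d of
        # fitted offsets (3 gap levels, 100 subjects per group, one channel).
        ds = []
        for gap in (0.1, 0.2, 0.3):
            groups = {
                "CTL": GroupParams(0.5, 0.15, 1.0, 0.0),
                "PD": GroupParams(0.5 + gap, 0.15, 1.0, 0.0),
            }
            spec = zero_variance_spec(
                n_ctl=2, n_pd=2, channel_labels=("c1",), freq_grid=fit_grid,
                group_params=groups, condition_effects=ConditionEffects(),
                topography_weights=np.array([1.0]), spectral_noise_sd=0.05)
            rng = np.random.default_rng(77)
            fitted = {g: [] for g in ("CTL", "PD")}
            for group in fitted:
                for _ in range(100):
                    p = sample_subject_params(spec, group, "NA", "EO", rng)
                    psd = synthesize_psd(p, spec, rng)
                    fitted[group].append(
                        fit_spectrum(psd.freqs, psd.power[0]).aperiodic.offset)
            ctl, pd_ = np.array(fitted["CTL"]), np.array(fitted["PD"])
            pooled = np.sqrt((ctl.var(ddof=1) + pd_.var(ddof=1)) / 2)
            ds.append((pd_.mean() - ctl.mean()) / pooled)
        assert ds[0] < ds[1] < ds[2]
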