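# specpipe

Resting-EEG spectral analysis for case–control studies in which group
differences in canonical band power may be driven by the *aperiodic* (1/f)
background rather than by oscillations. The package targets the Parkinson's
disease (PD) resting-EEG design — PD patients measured on (ON) and off (OFF)
dopaminergic medication, age-matched controls (CTL), eyes-closed (EC) and
eyes-open (EO) recordings — and ships a synthetic cohort generator with known
ground truth so the whole chain is testable without any data download.

## What it computes

Each channel's power spectrum is modeled in log10 power over frequency as

    log10 P(f) = b − χ·log10 f + Σ_k pw_k · exp(−(f − cf_k)² / (2·sd_k²))

where `b` is the aperiodic **offset**, `χ` the aperiodic **exponent** (the
1/f slope magnitude; a proxy for excitation–inhibition balance), and each
Gaussian is an oscillatory **peak** (center `cf`, height `pw` in log10 units,
bandwidth `2·sd`). The stages, in run order:

1. **`cohort`** — synthetic subjects with per-group distributions of `b`, `χ`
   (correlated between subjects) and peak templates, paired ON/OFF sessions,
   EC/EO conditions, posterior-weighted alpha topography; output as spectra
   or as time series whose expected PSD follows the model.
2. **`estimation`** — 2000 ms segments with 50% overlap; segments deviating
   more than ±150 μV from the within-segment channel mean are rejected;
   recordings retaining <50% of segments exclude the subject; Hamming-window
   averaged periodogram, zero-padded ×2 (0.25 Hz resolution), restricted to
   2–40 Hz.
3. **`parameterization`** — the iterative aperiodic + Gaussian-peak
   decomposition (robust line fit, flattening, iterative peak detection at
   max(0.1, 2 SD), joint bounded refit, aperiodic refit, full-model polish),
   with settings: peak width limits 1–8 Hz, ≤8 peaks, fixed (no-knee) mode;
   R² goodness-of-fit QC flags participants >3 SD below the grand mean.
4. **`bands`** — **total** band power (mean linear power, alpha 8–13 Hz,
   beta 13–30 Hz) vs **parameterized** band power (mean of the fitted peak
   model only, i.e. power attributable to oscillations).
5. **`cluster`** — cluster-based permutation tests over electrode space:
   per-channel t maps (independent or paired), supra-threshold same-signed
   clusters on a pruned Delaunay adjacency, max-|cluster-mass| null from
   10,000 label permutations or sign flips, with t_max and mean Cohen's d
   per cluster. An exhaustive enumerator provides exact p values on small
   designs.
6. **`pipeline` / CLI** — TOML configuration, orchestration, tidy TSV
   outputs, byte-identical reruns from a seed.

## Worked example

```python
import numpy as np
from specpipe import CohortSpec, FitSettings, fit_spectrum, generate_cohort

# One synthetic spectrum with known truth: b=0.8, χ=1.1, alpha peak 10/0.5/1.5
freqs = np.arange(2.0, 40.01, 0.25)
logp = 0.8 - 1.1 * np.log10(freqs) + 0.5 * np.exp(-(freqs - 10)**2 / (2 * 1.5**2))
model = fit_spectrum(freqs, 10.0**logp)
print(model.aperiodic)
print(model.peaks)
print(round(model.r_squared, 6))
```

prints (recovery to numerical precision on noiseless in-class spectra):

```
AperiodicParams(offset=0.8000000000000048, exponent=1.1000000000000036)
[PeakParams(cf=10.000000000000002, pw=0.49999999999999917, bw=2.9999999999999885)]
1.0
```

End-to-end from the shell (simulate a default 26+26 cohort, parameterize,
run the EC contrasts, write tidy tables):

```bash
specpipe run --seed 1 --out results/demo
```

which prints `wrote 8 files to results/demo; 4 significant clusters` and
fills `results/demo/` with `parameters.tsv` (one row per subject × session ×
condition × channel: offset, exponent, R², peaks), `band_power.tsv`,
`clusters.tsv` (contrast, member channels, cluster mass, t_max, mean d,
permutation p), retention/QC/exclusion tables, and a JSON run summary
echoing the seed and settings.

On the default synthetic cohort — groups differing **only** in aperiodic
offset (+0.25) and exponent (+0.12), identical oscillatory peaks, null
medication effect — the OFF vs CTL contrasts typically report significant
scalp-wide clusters for offset (d ≈ 1.0), exponent (d ≈ 0.7), total alpha
and total beta power (d ≈ 0.7–1.7), while parameterized alpha/beta show no
clusters (whole-scalp d scattered near 0) and no ON vs OFF contrast is
significant: total-band-power "oscillatory" group differences manufactured
entirely by the aperiodic background, and removed by parameterization.

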