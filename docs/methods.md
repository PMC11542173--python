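# Methods

## Spectral model and fitting

Every analysis is anchored to the fixed-mode (no-knee) spectral model

    log10 P(f) = b − χ·log10 f + Σ_k pw_k · exp(−(f − cf_k)² / (2·sd_k²)),

fitted per channel on 2–40 Hz at 0.25 Hz resolution. The fitting procedure
is the staged decomposition used throughout the aperiodic-activity
literature:

1. **Robust aperiodic fit.** Ordinary least squares of log10 power on log10
   frequency, then a second pass using only the points whose
   positive-clipped residual is at or below a low percentile of the residual
   distribution (default 0.025 on the 0–100 scale) — in practice the points
   on or below the first line. Because narrowband peaks only ever add power,
   this removes their pull on the slope. The percentile is configurable
   (`FitSettings.robust_percentile`).
2. **Flattening and iterative peak detection.** The line is subtracted; the
   global maximum of the residual is accepted as a peak guess if it clears
   both the absolute floor (0.1 log10 units) and the relative threshold
   (2 × the SD of the *current* residual, recomputed each iteration because
   successive subtractions shrink the noise estimate). The Gaussian SD guess
   comes from the nearer half-height crossing (the shorter flank tolerates
   an overlapping peak on the other side), clamped so the bandwidth
   `bw = 2·sd` stays within the 1–8 Hz limits. Detection stops at 8 peaks.
3. **Guess pruning.** Peaks whose center lies within 1 SD of a fit-range
   edge are dropped (boundary artifacts); when two centers are closer than
   0.75 × the wider SD, the taller is kept. Both factors are configurable.
4. **Joint bounded refit of all peaks,** then an ordinary aperiodic refit on
   the peak-subtracted spectrum.
5. **Full-model polish.** One simultaneous bounded least-squares pass over
   (b, χ, all peaks). The staged passes are excellent initializers but each
   conditions on the other component's previous estimate; the polish removes
   the residual coupling so that noiseless in-class spectra are recovered to
   numerical precision (the test suite checks < 1e−3; observed error is
   ~1e−12) rather than the ~5e−3 a single staged pass leaves.

### Numerical choices

The bounded solver is a projected Levenberg–Marquardt iteration on the
normal equations with the analytic Jacobian; trial steps are clipped into
the feasible box (centers inside the fit range, heights ≥ 0, SDs within the
width limits). At this problem size (≤ 26 parameters, ~150 points) each
iteration is a handful of small matrix products, so even peak-rich noisy
spectra fit in a few milliseconds — the property that makes the replicate
cohort studies below affordable. Iteration caps (12 for the peaks-only
stage, 20 for the polish) were chosen at the plateau of an accuracy/cost
sweep; recovery statistics are unchanged down to roughly half these values.
Goodness of fit is the squared Pearson correlation between log10 data and
log10 model; a perfectly matching constant spectrum is defined as R² = 1.

Under log10 noise of SD 0.05 the exponent is recovered with |bias| < 0.01
and RMSE ≈ 0.02 (200-spectrum calibration, recomputed by both the test
suite and `scripts/acceptance.py`).

## PSD estimation

2000 ms epochs with 50% overlap; epochs are rejected when any channel
deviates by more than ±150 μV in absolute value from its own within-epoch
mean. The mean-relative reading (rather than deviation from zero or peak-to
-peak) is robust to DC offsets and is configurable; rejection runs after
segmentation and before averaging, and retention is counted over all epochs
of the recording. A recording retaining less than half of its epochs flags
the subject for exclusion (a subject is excluded when *any* of their
recordings fails). Epochs are mean-detrended, Hamming-windowed, zero-padded
twofold (2000 ms windows natively give 0.5 Hz bins; padding yields the
0.25 Hz grid the parameterization expects), and scaled to one-sided density
units by the window power fs·Σw², so that band averages have μV²/Hz units.
With a rectangular window and no padding the estimator satisfies Parseval's
identity to 1e−6 relative, and a pure sinusoid's integrated band power
equals A²/2 within window leakage (both asserted in the tests).

## Band power

Total band power is the arithmetic mean of linear power over the band's
grid points; parameterized band power is the mean of the fitted peak model
(log10 units) over the same points. Band edges are lower-inclusive and
upper-exclusive except the last band's upper edge, so the shared 13 Hz
point belongs to beta only. Computing parameterized power from the peak
*model* (not from discrete detected peaks) keeps the measure defined — as
zero — when no peak lands in the band, which the paired statistics require.
The algebraic core of the package is the dissociation identity: scaling the
aperiodic component moves total band power and leaves parameterized band
power unchanged.

## Cluster-based permutation inference

Per-channel statistics are pooled-variance two-sample t (independent
contrasts: PD-OFF or PD-ON vs CTL) or one-sample t on per-subject
difference vectors (paired contrasts: ON vs OFF, EC vs EO). Channels with
|t| above the two-tailed critical value at the cluster-forming alpha (0.05)
are grouped into connected, same-signed clusters on the adjacency graph;
the cluster statistic is the mass (sum of member t values). The null is the
distribution of the maximum |mass| over label permutations (independent) or
whole-subject sign flips (paired) — permutations never mix channels within
a subject. Monte-Carlo p values use (1 + exceedances)/(n_permutations + 1),
so p is never zero; an exhaustive enumerator over all sign patterns or
group assignments provides exact p values on small designs and serves as
the oracle for the Monte-Carlo path. Under the two-sided max-|mass|
convention the all-flipped pattern always ties the observed mass, so the
attainable exhaustive floor is 2/2ⁿ. Cohen's d is the pooled-SD
standardized difference (independent) or the difference-score standardized
mean (paired; the difference-score convention is one of two defensible
readings and is switchable in principle via the data fed in). When a
contrast yields no cluster, the report row carries the whole-scalp max |t|
and mean d, flagged non-significant. No correction is applied across the
many contrasts (3 group pairs × conditions × 6 measures); this mirrors
common practice for this design and is a known caveat.

Adjacency is the Delaunay triangulation of azimuthal-equidistant projected
electrode positions with edges longer than 1.5 × the median pruned;
sub-temporal rim electrodes whose ring edges are long get their shortest
pruned edges restored until they have two neighbors, and collinear layouts
fall back to a nearest-neighbor chain. Familywise error is controlled by
construction: on 500 null cohorts (16 channels, 10 subjects per group) the
fraction with any significant cluster falls inside [0.025, 0.075].

## Synthetic cohort generator

The generator emulates the study design: n CTL subjects (one session) and n
PD subjects with paired ON/OFF sessions, each with EC and EO conditions.
Defaults (all configurable through `CohortSpec`):

| parameter | default | rationale |
|---|---|---|
| group sizes | 26 + 26 | the retained-cohort size of the design |
| offset b | CTL 0.5 ± 0.24; PD +0.25 | between-group d ≈ 1.04 |
| exponent χ | CTL 1.0 ± 0.17; PD +0.12 | between-group d ≈ 0.71 |
| offset–exponent correlation | 0.95 | see below |
| alpha peak | 10 ± 0.5 Hz, height 0.6 ± 0.08, SD 1.5 ± 0.1 | posterior-weighted (0.4→1.0 front-to-back) |
| beta peak | 20 ± 1.0 Hz, height 0.25 ± 0.05, SD 2.5 ± 0.2 | identical across groups |
| EC−EO shifts | b +0.10 ± 0.02; χ +0.05 ± 0.015; alpha height +0.20 ± 0.05 | EC > EO, alpha blocking |
| ON−OFF effects | 0 | the medication-invariance null |
| spectral noise | 0.05 log10 SD, iid | matches a ~59-epoch Welch average |

Two structural choices deserve explanation. First, the **between-subject
offset–exponent correlation (0.95)**: empirically the two aperiodic
parameters are strongly correlated — individual spectra pivot around a low
anchor frequency rather than varying in height and tilt independently.
Without this, independent draws put ~0.3 log10 units of between-subject
variance at every band frequency and no aperiodic group effect of plausible
size could ever surface in band power. Second, the **group-difference
decomposition (+0.25 offset, +0.12 exponent)**: an aperiodic-only group
difference changes log power at f by Δb − Δχ·log10 f, which stays positive
across the whole 2–40 Hz range only when Δb/Δχ > log10(40); the default
decomposition pivots near 120 Hz, which is the only regime in which total
alpha *and* total beta can both rise while every peak parameter is
identical — the headline dissociation. A decomposition with the same effect
sizes but a pivot inside the beta band (e.g. +0.2/+0.15, pivot ≈ 21.5 Hz)
necessarily produces a near-zero net total-beta effect; the acceptance
suite runs that variant as specified and documents the outcome rather than
adjusting it.

A consequence of the variance budget: the simulated EC−EO paired effects
are stronger (d ≈ 2–3) than is typical for real resting EEG (d ≈ 0.5–1.0),
because the between-subject SDs of the condition shifts must stay small for
the group contrasts in a single condition to retain their calibrated effect
sizes. The paired medication null and the group contrasts take priority.

Time-domain synthesis shapes white Gaussian noise in the frequency domain
by √(target PSD) and inverse-transforms — direct control of the expected
spectrum with no filter-design choices. Optional artifact transients
(default 300 μV) exercise the rejection stage. What the generator does
*not* emulate: real artifact morphology (blinks, line noise), volume
conduction, channel covariance, non-Gaussian spectra. Passing tests
demonstrate the correctness of the chain on the model class, not the
realism of any particular parameter estimate on human data.

## Problem sizes used in the automated studies

Replicate studies use the 19-channel classic 10/20 montage and eyes-closed
contrasts at 1,000 permutations (50 cohorts of 26+26 for the dissociation
experiment; 500 null cohorts of 16 channels for the error-rate study); the
single-cohort demonstration in `scripts/acceptance.py` uses the full
64-channel layout at the design's 10,000 permutations. These sizes keep the
full study set runnable on a laptop CPU in minutes while leaving every
statistical property intact.

## Known limitations

- Only the fixed aperiodic mode is implemented; spectra with a knee are out
  of scope, as are time-resolved parameterization and noise-floor modeling.
- Peak recovery guarantees hold for well-separated peaks (centers ≳8 Hz
  apart at these widths); heavily overlapping broad peaks can be merged or
  missed by the staged detection rule, which is inherent to the algorithm.
- The ±150 μV criterion's reference (epoch mean) and the bandwidth
  convention (bw = 2·SD, limits applied to bw) are explicit choices where
  the procedure is commonly left unstated; both are configurable.
- Cluster inference is spatial-only on scalar per-electrode measures; a
  channel × frequency-bin mode is not implemented.
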