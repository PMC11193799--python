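# Methods

## Overview

`circanap` implements the analysis chain used to derive the circadian
amplitude of REM sleep from a 40-h in-lab multiple-nap protocol and to
relate it to quantitative brain maps, together with a synthetic-cohort
generator that plants known ground truth so every estimator in the
chain can be validated end to end.

The chain is: (1) protocol schedule → (2) melatonin secretion-curve fit
and dim-light melatonin onset (DLMOn) → (3) per-nap sleep metrics,
circadian alignment, spline interpolation, constrained
line-plus-Gaussian fit → (4) voxel-based quantification (VBQ) with
permutation cluster-level inference.

## Protocol model

The schedule tiles a time axis of minutes since the scheduled wake-up
from the baseline night: an 8-h baseline night, a 130-min wake block,
ten cycles of an 80-min nap opportunity followed by 160 min of
scheduled wakefulness (the final wake block cut to 40 min), then an 8-h
recovery night. The nap day spans 2410 min under this convention; the
recovery night therefore begins 10 min after the nominal habitual sleep
time (16 h after wake-up for an 8-h night). The printed design
constants do not reconcile exactly with a 2400-min day, so the package
fixes this one consistent convention and uses it everywhere. Salivary
melatonin is sampled every 80 min starting 50 min after wake-up, giving
30 samples across the nap day.

## Melatonin model and DLMO

Secretion is modelled as a skewed baseline cosine: baseline `B` plus an
exponentiated half-cosine pulse of amplitude `H` peaking at the
acrophase `phi`,

    m(t) = B + H * max(0, cos(pi (t - phi) / (2 w)))^nu,

with `w = w_rise` before the peak and `w_fall` after it (the skewness)
and shape exponent `nu >= 1`. The pulse is extended 24-h periodically
(circular distance to the acrophase) so one parameter set explains both
evening rises inside a 40-h recording; the acrophase is bounded to the
first circadian period of the recording to keep it identifiable.

Fitting is bounded least squares over (B, H, phi, w_rise, w_fall, nu)
with multi-start over a grid of candidate acrophases every 2 h; the
starts are triaged by raw residual and only the best few are polished.
DLMOn is the rising-limb time at which the fitted curve reaches
`B + 0.25 H` (25% of the fitted peak-to-baseline amplitude), DLMOff the
corresponding falling-limb crossing; both are root-found by Brent's
method to 1e-4 min. DLMOff at the same 25% level is a choice — only the
onset threshold is conventionally fixed — and the fit is done on the
raw concentration scale.

## Nap phenotyping

Per sleep opportunity, sleep efficiency (SE) is the fraction of epochs
scored N1/N2/N3/REM over the whole opportunity, and REM% is REM time
over total sleep time. A window without sleep has REM% undefined and is
treated as missing, never as zero. Nap midpoints are re-expressed as
hours since DLMOn, and the per-nap values are interpolated with a cubic
B-spline (not-a-knot ends, `scipy.interpolate.make_interp_spline`) onto
the theoretical circadian grid −12, −8, −4, 0, 4, 8, 12, 16, 20, 24 h.
Grid points outside the observed span are evaluated at the span edge
and flagged. A subject needs at least four naps with defined REM%.

The circadian profile is fitted with

    f(t) = a + b t + h exp(-(t - mu)^2 / (2 sigma^2)),

where `h` is the circadian amplitude (the package's main phenotype) and
`b` the homeostatic accumulation slope in units per hour. The additive
line-plus-Gaussian form is deliberate: literally convolving a
first-order polynomial with a unit-mass Gaussian returns the same
polynomial (the test suite verifies this by quadrature), so an additive
combination is the only reading under which both a Gaussian height and
a polynomial slope exist.

The fit is anchored to circadian phase by constraining the curve's
pre-peak trough, `t_min = mu - 3 sigma` — the point where the Gaussian
surge departs baseline (the Gaussian is below 1.2% of its height
there) — to a ±2-h window around DLMOn ("a 4-h window surrounding the
onset"). The constraint is enforced exactly by reparameterizing the
least-squares problem over (a, b, h, t_min, sigma) with a box bound on
`t_min`; when the data pull the trough outside the window the estimate
sits on the window boundary. Multi-start over trough and width
initializations guards against local minima.

### Numerical identifiability of the Gaussian

Two bounds matter and are deliberate. The width is bounded to
sigma ∈ [2, 12] h: 2 h is half the grid spacing, and Gaussians narrower
than that are unresolvable by the 4-h sampling — without the floor the
global least-squares optimum is frequently a spike between grid points
with essentially arbitrary height (amplitude estimates several times
the data range). The height is capped at three times the observed data
range for the same reason. With these guards, at grid noise of
5 REM% the amplitude estimator has error SD ≈ 5 REM% and correlates at
≈ 0.6 with the generating amplitude.

### Known bias of the amplitude estimator

Nonlinear least squares on 10 points with 5 parameters is not unbiased.
At grid noise SD 2 REM% the amplitude bias is ≈ +2% of the true
amplitude; at noise SD 5 REM% (one nap per grid point, a realistic
level once epoch-level staging noise is included) it rises to ≈ +18%,
driven by the Jensen-type response of the fitted height to width
perturbations and by the h ≥ 0 bound. Users comparing amplitude
between groups are unaffected by a common multiplicative inflation;
users needing absolute amplitudes should be aware of it. The test suite
asserts the monotone degradation of recovery with noise and reports the
measured bias rather than hiding it.

## Cohort-level statistics

Day-vs-night session contrasts compare each non-night grid point
against the subject's mean over the two biological-night naps (+4 h and
+8 h since DLMOn), summarized as paired mean difference over the SD of
differences (negative = lower than night). The baseline-night
association is an OLS of circadian REM amplitude on baseline-night
REM% adjusted for age, sex and baseline-night SE (statsmodels).

## Voxel-based quantification

Subject maps (MTsat in percent units, R1 and R2* in 1/s) are smoothed
with a tissue-weighted Gaussian kernel, `s = G*(w x) / G*(w)` with a
6-mm FWHM and `w` the subject's tissue probability; voxels whose
smoothed weight falls below 0.05 are excluded. Cohort masks average
the tissue probabilities, assign each voxel to its argmax class (ties
to grey matter) and drop voxels where both means are ≤ 0.20.

The design matrix has one row per subject and columns intercept,
REM amplitude (the contrast), age, sex, education, SE amplitude, mean
REM%, mean SE, REM slope, SE slope, baseline-night REM% and SE.
Voxel-wise OLS t-maps are computed by QR projection; voxels with
missing values or zero variance are dropped with a log entry.

Cluster-level family-wise error is controlled by permutation rather
than random-field theory: suprathreshold clusters (one-sided voxel
threshold p < 1e-4, 26-connectivity) are ranked by extent, and the null
distribution of the maximal extent is built by Freedman–Lane
permutation — nuisance covariates are regressed out of the data, their
residuals permuted across subjects, the full model re-fitted — with
`p_fwe = (1 + #{perm max extent ≥ observed}) / (n_perm + 1)`. Positive
and negative contrasts are run separately. Coordinates are reported as
0-based voxel indices with mm offsets (index × voxel size); the
synthetic volumes share one grid, so no spatial normalization is
involved. The VBM variant runs the same engine on grey-matter volume
maps smoothed at 8 mm.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions. Per subject, nap- and night-level REM% targets follow

    REM%(t) = a + b t_elapsed + h exp(-(t_circ - mu)^2 / (2 sigma^2)),

clipped to [0, 95], with `t_circ` hours since the subject's true DLMOn;
SE follows the same shape on its own scale (50% + 0.3%/h + 35% ×
Gaussian, clipped to [5, 98]). For the two bracketing nights the
circadian distance is wrapped to the nearest 24-h cycle so night sleep
carries the circadian REM propensity of the night it falls in — this
is what makes baseline-night REM% correlate with the true amplitude.
Nap-level targets get truncated-Gaussian noise (SD 5 REM%/SE%), then
epochs are drawn independently from the implied stage distribution
(N1:N2:N3 = 0.18:0.60:0.22 within NREM). Melatonin samples are the
secretion curve times multiplicative lognormal noise (log-SD 0.20 by
default).

Subject truth distributions: trough t_min ~ TruncN(−1, 0.5²; [−2, 2])
and sigma ~ TruncN(3, 0.5²; [1.5, 6]) (so mu = t_min + 3 sigma ≈ 8 h
after DLMOn), amplitude h ~ TruncN(15, 5²; [0, 40]) REM%, baseline
a ~ TruncN(10, 2²), slope b ~ N(0.2, 0.1²) REM%/h; true DLMOn 2 h
before habitual sleep time ± 30 min; melatonin pulse B ≈ 2, H ≈ 10
pg/mL, w_rise ≈ 180, w_fall ≈ 240 min, nu ≈ 2; age ~ TruncN(69, 5²;
[59, 82]) years, 37% female, education ~ TruncN(14, 3²) years, 65%
habitual nappers.

Brain volumes use a smooth synthetic template (white-matter core,
grey-matter shell) with per-map tissue baselines (MTsat 0.9/1.8%,
R1 0.65/1.05 s⁻¹, R2* 16/21 s⁻¹ for GM/WM), a small age slope, i.i.d.
Gaussian voxel noise, and planted clusters whose voxels gain
`effect_beta × beta_scale × h_true` in the targeted map.

What the generator does **not** emulate: real EEG and scorer behaviour
(stages are conditionally independent across epochs, so hypnograms lack
bout structure), assay detection limits, MRI contrast physics, spatial
normalization error, and spatially correlated map noise. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every property of real recordings.

## Known limitations

- **Attenuation in the imaging association.** The imaging design
  includes covariates (baseline-night REM%, mean REM%) that are
  themselves proxies of the latent circadian amplitude. With a
  realistic measurement error of ~7 REM% on the estimated amplitude,
  the partial correlation of the estimate with the latent truth given
  those covariates is ≈ 0.4, which caps the voxel t at ≈ 3.7 for any
  planted effect size at n = 86 — below the cluster-forming threshold
  t(1e-4) ≈ 3.9. End-to-end recovery of truth-planted map effects is
  therefore not achievable at study scale through the estimated
  phenotype; imaging validation tests use the planted true amplitude
  as the regressor, which isolates the inference engine. This mirrors
  a genuine design issue in adjusting for phenotype proxies.
- The amplitude estimator's noise bias (above).
- Permutation inference assumes exchangeability of nuisance residuals
  across subjects; the calibration test verifies the FWE bound under
  i.i.d. noise only.

## Problem sizes used in validation

Validation experiments are sized for a desktop run: cohorts of 86
subjects for protocol fidelity and qualitative pattern checks, 200
subjects for fit-recovery statistics, 200 global-null imaging datasets
of 16³ voxels × 30 subjects with 500 permutations for the FWE
calibration, and a 40-subject cohort for planted-effect recovery.
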