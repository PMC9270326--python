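# Methods

`timingfit` re-implements, as a reusable and fully tested pipeline, a
voxel-level analysis that distinguishes two kinds of neural response to
brief (sub-second) visual events in fMRI data: *monotonic* responses,
which accumulate with event duration and frequency as in early visual
cortex, and *timing-tuned* responses, which peak at a preferred
(duration, period) combination as found in association cortices.  The
package never touches raw MRI data; every stage is exercised on
synthetic voxels whose ground truth is known.

## Stimulus model

Events are brief appearances of a visual stimulus characterized by a
duration (onset to offset) and a period (onset to next onset), both in
50-1000 ms in 50 ms steps, with duration ≤ period.  Four 56-TR blocks
(TR = 2100 ms, 117.6 s per block) cover the timing space in different
ways: duration = period (constant luminance), duration pinned at 50 ms
(constant duration), period pinned at 1000 ms (constant period), and
four short mixed progressions (gaps).  A run concatenates the four
blocks in one of 24 orders: 224 TRs, 470.4 s.

Each timing step nominally occupies one TR.  Events tile the timeline
contiguously; because most periods do not divide 2100 ms, the repeat
count for step *k* is chosen from {⌊2100/p⌋, ⌈2100/p⌉} to minimize the
cumulative deviation from the nominal TR grid (ties to the smaller
count; step changes occur at event onsets; trailing events that would
not finish inside the block are dropped).  Under contiguous tiling the
worst-case deviation is half the longest period — 500 ms, reached in
the constant-period block where nominal boundaries at multiples of
2100 ms can fall exactly between multiples of 1000 ms.  The measured
maximum drift is therefore reported (`max_onset_drift_ms`), not
asserted against a smaller bound.  Per-TR timing labels are assigned by
majority occupancy within each TR window, ties going to the later step.

## Response models

Both models predict a neural response amplitude *per event*, evaluated
at the event's offset (when the event's timing is fully known).

**Monotonic**: `A = β_dur · duration^expDur + β_freq · frequency^(expFreq − 1)`
with compressive exponents in (0, 1] and non-negative component
amplitudes.  The per-event frequency factor is `f^expFreq / f`; summed
over one second of events it gives `f^expFreq`, so the response *rate*
is non-decreasing in frequency even though the per-event amplitude
falls.  The ratio `β_dur/β_freq` (amplitude ratio) is a derived
quantity of interest.  Pinning one or both exponents at 1 yields the
simpler linear comparison models.

**Tuned**: an anisotropic 2-D Gaussian over (duration, period), with
preferred duration/period, extents σ_maj ≥ σ_min along rotated axes,
orientation θ (π-periodic), multiplied by the same compressive
frequency factor.  A form of the axis rotation circulates with
`Y = dDur·sinθ − dPer·cosθ`, whose rows are not orthogonal for general
θ — it does not describe an ellipse with perpendicular axes.  The
default `rotation_mode="corrected"` uses the proper rotation
(`Y = dDur·sinθ + dPer·cosθ`); `"as_printed"` reproduces the
non-orthogonal form literally.  Both are tested against independent
scalar oracles; all package-level analyses use the corrected mode.

Internal computation uses seconds and Hz; interfaces report ms.

## Hemodynamics

Neural impulse trains (one impulse per event, at its offset) are binned
on a 10 ms grid, convolved with a canonical two-gamma HRF (peak delay
6 s, undershoot delay 16 s, dispersions 1 s, peak:undershoot ratio 6;
unit peak amplitude; 30 s support) and sampled at TR onsets.  10 ms
bounds the discretization error well below other error sources since
event times are multiples of 50 ms.  A per-participant HRF can be
re-estimated by coordinate pattern search maximizing summed variance
explained over voxels whose fitted neural model explains more than 10%
of variance, after which neural parameters are refit once (a single
fit-neural → fit-HRF → refit-neural cycle).

Because every event in a block carries one of ~100 unique timings, a
block's predicted BOLD is linear in the vector of per-timing
amplitudes.  `SessionDesign` precomputes that linear map once per
schedule and HRF; candidate predictions for any parameter set then cost
one small matrix product.  The simulator uses the same map, so the
forward model cannot drift from the fitter.  Blocks are convolved
independently and concatenated in canonical condition order, matching
data that are per-condition averages over runs with counterbalanced
block orders (carry-over between blocks averages out across the 24
orders).

## Fitting, cross-validation, classification

Goodness of fit is variance explained (VE): the squared Pearson
correlation between prediction and data — equivalently 1 − RSS/TSS
after a free gain/offset refit — hence invariant to affine transforms
of either series.

*Monotonic*: exhaustive search over exponent candidates
({0.05, …, 1.0} in steps of 0.05), the two component amplitudes solved
per candidate by a two-regressor GLM with intercept under a
non-negativity fallback: a negative amplitude is zeroed and the other
refit alone; if the refit is also negative both are zero and VE is 0.

*Tuned*: grid search over six parameters.  The default grid uses
preferred timings 25-1475 ms in 75 ms steps (deliberately extending
beyond the presented 60-990 ms range so out-of-range optima are
expressible), six log-spaced extents 50-2000 ms with σ_min ≤ σ_maj, θ
in π/8 steps and ten frequency exponents; a reduced-density variant
(`GridSpec.coarse()`) serves quick exploration and the classification
study, where sub-grid precision is unnecessary.  The grid stage is
followed by a coordinate-wise pattern search seeded at the best grid
point, confined between that point's grid neighbors, with halving steps
down to a 1e-4 tolerance.  The objective is multimodal, so the search
restarts from the best grid point of each of the top three
frequency-exponent levels and keeps the best result.  Even so, on a
few percent of noiseless voxels the neighbor-confined search converges
marginally below VE 0.99 (typically 0.98+); this is an accepted
property of the confinement rule, and parameter-recovery checks
therefore use median absolute errors.

Cross-validation fits each model on one split-half average (odd-run or
even-run) and evaluates the regenerated prediction on the other half,
refitting only gain and offset.  Tuned fits whose preferred duration or
period falls below 60 ms or above 990 ms are flagged out-of-range and
receive zero cross-validated VE: such response functions change
monotonically over the presented range and must not masquerade as
evidence of tuning.  A voxel is *excluded* when neither model exceeds a
training-VE threshold (default 0.2) on any split; otherwise it is
labeled by the model with the higher mean cross-validated VE (ties and
fully out-of-range tuned fits go to monotonic).

## Map-level statistics

The measurement unit is one hemisphere × participant × cross-validation
split: per map it contributes the median cross-validated VE per model
over voxels passing the (split-specific) training threshold; empty
cells are dropped.  Model-vs-model and near-vs-far comparisons use
paired two-sided Wilcoxon signed-rank tests with Benjamini-Hochberg
FDR correction and effect size r = Z/√n, after a fixed-effects ANOVA
(Type III sums of squares, participant treated as fixed; partial η²
reported) and a Jarque-Bera normality gate on the paired differences.
Zero differences are dropped (classical convention) and the variance
term is tie-corrected.  For n ≤ 12 without ties the Wilcoxon p comes
from the exact null distribution — the discrete small-n null deviates
from any normal approximation by more than 0.01 — while Z always comes
from the continuity-corrected approximation, as it feeds the effect
size.  Medians carry percentile bootstrap CIs (default 1000
iterations, seeded).  Parameter comparisons across maps use Dunn's
rank-based pairwise test with Holm-Šidák step-down adjustment; for the
monotonic amplitude ratio, voxels with a zero or infinite ratio are
excluded.  Output tables carry a Bayes-factor column as a NaN
placeholder so their layout matches the published tables; Bayesian
paired comparisons are out of scope.

Eccentricity analyses bin voxels (pooled over hemispheres and splits)
into 0.2° half-open bins centered 0.1°-5.5°, dropping bins with fewer
than 50 entries, with a VE floor of 0 for inclusion.  Progressions are
displayed with whichever of a four-parameter cumulative-Gaussian
sigmoid (inflection, slope, maximum, minimum) or a quadratic correlates
better with the bin means (ties, including constant data, go to the
quadratic; sigmoid CIs are bootstrap, quadratic CIs analytic).  The
near/far contrast compares mean VE for eccentricities < 1° against
> 2° and < 5.6° per measurement and map.

## Synthetic data

Two generators exist, with different purposes.

The *validation* generator (`model_recovery`) draws deliberately broad,
homogeneous parameters — exponents U(0.05, 1); preferred timings
U(50, 1200) ms with duration < period; σ_maj U(100, 1500) ms,
σ_min U(50, σ_maj); θ U(0, π); amplitudes U(0.2, 1) — so that the
classification study also probes the degenerate corner where tuned
functions mimic monotonic ones.  Noiseless signals are z-normalized,
degraded twice with independent Gaussian noise (SD 0-6 in 0.5 steps,
i.e. SNR 1/6 to infinite), and rescaled to data-like units (mean 100,
SD 2 — arbitrary, since VE is affine-invariant; asserted by test).  In
our runs, misclassified ground-truth tuned voxels are dominated by
fitted out-of-range preferences and large extents; a separate monotone
trend of misclassification with the true frequency exponent did not
emerge under these distributions, so it is reported but not asserted.

The *cohort* generator (`synthetic_data`) emulates the structure the
map-level analyses assume: 8 participants × 2 hemispheres × 10 maps
ordered by a hierarchy index, 100 voxels per map/hemisphere (all
configurable).  The fraction of tuned voxels follows a logistic curve
in the hierarchy index from 0.1 to 0.9.  Tuned voxels draw realistic
in-range parameters (preferences inside 60-990 ms, moderate extents
150-800 ms, frequency exponents 0.1-0.6).  Eccentricities follow a
truncated exponential on [0, 5.6°] with 2° scale (denser near the
fovea, a cortical-magnification stand-in).  Per-voxel noise SD is
uniform in (0.5, 2.5) so VE distributions straddle the 0.2 exclusion
threshold; for monotonic voxels the effective noise is divided by an
eccentricity gain `exp(−ecc/2°)`, making their detectability decay away
from the stimulus location, while tuned components are
eccentricity-independent.  What passing tests show: the pipeline
recovers engineered population structure (a rising tuned−monotonic VE
difference along the hierarchy; eccentricity dependence only where
built in) under Gaussian, temporally white noise.  Real fMRI noise is
temporally autocorrelated and shares structure across voxels, and real
cohorts have far more heterogeneous response properties; the synthetic
results validate the machinery, not the neuroscience.

## Problem sizes

Default analysis scales were chosen to keep any single study minutes on
one core: parameter recovery uses 200 noiseless voxels per model; the
classification study 100 voxels per model at 13 noise levels (2600
voxel pairs through the full pipeline); the cohort analyses 4
participants × 2 hemispheres × 10 maps × 40 voxels (3200 voxels) on the
reduced-density grid.  All are parameters of the respective functions.

## Known limitations

* Per-block convolution ignores within-run carry-over; exact only in
  expectation over counterbalanced block orders.
* One HRF per participant; no voxel-wise HRF variation, no nonlinear
  BOLD saturation, no physiological noise model.
* The tuned search is confined between grid neighbors by design; very
  narrow response functions (σ well below the grid spacing) can be
  missed at coarse densities.
* Wilcoxon/Dunn machinery assumes exchangeable measurements across
  hemispheres and splits, as in the original analysis design.
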