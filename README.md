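# timingfit

Model-based analysis of fMRI responses to **sub-second visual event
timing**.  Early visual cortex responds to brief repeating visual
events with amplitudes that increase *monotonically* (and
sub-linearly) with event duration and frequency; association cortices
instead contain populations *tuned* to a preferred (duration, period)
combination.  `timingfit` implements both forward models, the
cross-validated voxel-wise fitting and classification pipeline that
distinguishes them, the map-level statistics that trace the transition
from monotonic to tuned responses along the cortical hierarchy, and a
simulation framework that validates the whole procedure on synthetic
data with known ground truth.

It is written for researchers in model-based (pRF-style) fMRI who want
a tested, scriptable re-implementation of this analysis — no MRI data
is required anywhere; every stage runs on simulated voxels.

## Models

Each model maps an event timing (duration *D* s, period *P* s,
frequency *f* = 1/*P* Hz) to a per-event neural amplitude, evaluated at
the event offset:

* **Monotonic:** `A = β_dur · D^expDur + β_freq · f^(expFreq−1)`, with
  compressive exponents expDur, expFreq ∈ (0, 1] and non-negative
  component amplitudes (ratio β_dur/β_freq reported).  Per second of
  stimulation the frequency component contributes `f^expFreq`, so the
  response rate grows monotonically with frequency.
* **Tuned:** an anisotropic 2-D Gaussian in (D, P) centered on a
  preferred timing, with extents σ_maj ≥ σ_min, orientation θ, scaled
  by the same compressive frequency factor `f^(expFreq−1)`.

Predicted amplitudes are placed at event offsets of a four-condition
stimulus schedule (duration and period swept over 50-1000 ms),
convolved with a two-gamma HRF, and compared to measured (or
simulated) per-TR time courses by variance explained (squared Pearson
correlation).  Fits are cross-validated across split-half averages;
tuned fits with preferred timings outside the presented range count as
monotonic-like.  See `docs/methods.md` for the full treatment.

## Worked example

Simulate a small cohort whose tuned-voxel fraction rises along a
ten-map hierarchy, fit both models to every voxel, and compare them
within each map:

```python
from timingfit import (SessionDesign, GridSpec, CohortConfig,
                       generate_cohort, fit_voxels)
from timingfit import statistics as st

design = SessionDesign()                      # stimulus + HRF forward model
cfg = CohortConfig(n_participants=2, voxels_per_map=20, seed=1)
ann, Ya, Yb, truth = generate_cohort(cfg, design)
fits = fit_voxels(Ya, Yb, design, GridSpec.coarse(),
                  voxel_ids=ann.voxel_id.values)
table, anova = st.compare_models_by_map(fits, ann, threshold=0.2)
prog, rho = st.hierarchy_progression(fits, ann, threshold=0.2)
```

Output (medians are cross-validated variance explained per
hemisphere × split measurement; Z from the paired Wilcoxon signed-rank
test, FDR-corrected p):

```
  map  n  median_monotonic  median_tuned     Z  effect_size_r  p_adj
   V1  8             0.314         0.000 -2.45         -0.866  0.022
   V2  8             0.309         0.000 -2.31         -0.817  0.022
   V3  8             0.238         0.000 -2.45         -0.866  0.022
  LO1  8             0.196         0.147 -1.47         -0.520  0.186
  TO1  8             0.176         0.180 -0.07         -0.025  0.945
  TO2  8             0.117         0.142  0.77          0.272  0.512
 IPS0  8             0.074         0.227  2.31          0.817  0.022
 IPS1  8             0.125         0.238  2.31          0.817  0.022
sPCS1  8             0.076         0.240  2.31          0.817  0.022
 iPCS  8             0.054         0.203  2.45          0.866  0.022
Spearman rho (hierarchy vs tuned-monotonic median VE difference): 0.939
```

Early (posterior) maps are dominated by the monotonic model (negative
Z: monotonic fits better), anterior maps by the tuned model (positive
Z), with a graded transition in between — the engineered hierarchy is
recovered end to end (ρ = 0.94).

A thin CLI wraps the same functions:

```sh
timingfit design --condition constant_period --out design.tsv
timingfit simulate --seed 1 --out fixtures/
timingfit fit --fixtures fixtures/ --out results/
timingfit recover --n-per-kind 50 --seed 7 --out recovery/
```

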