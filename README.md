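# dpasl

Quantification and lifespan analysis of blood-brain-barrier (BBB) water
exchange from diffusion-prepared pseudo-continuous arterial spin labeling
(DP-pCASL) MRI.

DP-pCASL labels arterial blood water and reads it out at two post-labeling
delays (PLDs) with and without diffusion weighting. Because diffusion
gradients crush the fast, pseudo-randomly oriented spins in vessels, the
ratio of crushed to uncrushed perfusion signal separates labeled water that
is still intravascular from water that has crossed the BBB into tissue.
From one scan the pipeline quantifies, per voxel:

* **ATT** (ms) — arterial transit time, by the FEAST method from the
  PLD = 0.9 s pair (b = 0 / 14 s/mm²);
* **CBF** (ml/100g/min) — cerebral blood flow, from the PLD = 1.8 s, b = 0
  signal via the single-compartment continuous-labeling (Buxton) model;
* **kw** (min⁻¹) — the BBB water-exchange rate, by inverting the
  two-compartment single-pass approximation (SPA) for the diffusion-weighted
  signal ratio A = ΔM_tissue / ΔM_total at PLD = 1.8 s (b = 0 / 50 s/mm²),
  optionally after total-variation regularization of the A-map.

The two-compartment model is the delivery/exchange/relaxation system

    dM_cap/dt = 2α f e^(-δ/T1b) · 1[δ ≤ t ≤ δ+τ] − (1/T1b + kw/60) M_cap
    dM_tis/dt = (kw/60) M_cap − (1/T1t) M_tis

with labeling duration τ = 1.5 s, transit time δ = ATT/1000, labeling
efficiency α = 0.72, blood/tissue T1 of 1.65/1.2 s and delivered flux
f = CBF/(6000·λ), λ = 0.9 ml/g. Closed-form piecewise solutions are used
throughout and verified against a Runge-Kutta oracle in the tests.

Around the kinetics sits the group-level machinery of a lifespan study of
186 subjects aged 8–92:

* ROI aggregation over an integer atlas and cohort-table assembly
  (`dpasl.roi`);
* adaptive hinge-spline ("hockey-stick" basis, MARS-style) age-trajectory
  regression with sex interactions, GCV pruning, 10-fold cross-validated R²
  and refit slopes with 95% CIs (`dpasl.trajectory`);
* voxelwise GLMs for age and age×sex effects with the other two parameter
  maps as covariates, plus AlphaSim-style Monte-Carlo cluster-extent
  correction (`dpasl.voxelwise`);
* a synthetic cohort/image generator whose piecewise-linear mean
  trajectories (knees at 62 y for kw, 22 y for CBF, 36 y for ATT) are
  calibrated so the age-group × sex expectations equal the study's printed
  whole-brain group statistics exactly (`dpasl.synthetic`).

## Worked example

```python
import numpy as np
import dpasl as d
from dpasl import synthetic as syn

proto = d.AcquisitionProtocol()          # τ=1.5 s, PLDs 0.9/1.8 s, b pairs
fields = syn.generate_parameter_maps(    # toy 2-region subject, truth known
    {1: (45.0, 1300.0, 105.0), 2: (25.0, 1600.0, 60.0)},
    shape=(16, 16, 16), noise_frac=0.02, smoothness=1.0, seed=3)
series = syn.generate_dp_pcasl_signals(fields, proto, noise_sd=0.02, seed=1)
maps = d.quantify_series(series, proto)
print(np.nanmean(maps.kw[fields.atlas == 1]))   # 104.925  (truth 105 min⁻¹)
print(np.nanmean(maps.att[fields.atlas == 1]))  # 1299.87  (truth 1300 ms)
print(np.nanmean(maps.cbf[fields.atlas == 1]))  # 45.194   (truth 45 ml/100g/min)

cohort = syn.generate_cohort(syn.study_preset(), seed=11)   # 186 subjects
model = d.mars_fit(cohort, "kw_gm")     # gray-matter kw vs age
print(model.knots)                       # [55.0] — change point near 62 y
print(model.slope_at(77.0, "M")["slope"])  # -0.499 min⁻¹/yr in this replicate
```

The quantified region means recover the generating truth to a fraction of a
percent at this noise level. The hinge-spline fit finds a change point in
gray-matter kw in the seventh decade with a post-knee decline on the order
of the generating −0.82 min⁻¹ per year; individual replicates scatter
around those values (the change point is weakly identified at the study's
residual noise), which is why replicate aggregates are used for headline
numbers (see `docs/methods.md`).

A command-line interface mirrors the library:
`dpasl simulate cohort|imaging`, `dpasl quantify`, `dpasl roi`,
`dpasl trajectory`, `dpasl voxelwise` (see `--help` of each).

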