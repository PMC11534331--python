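# Methods

This note documents the models, numerical choices and design decisions
behind `dpasl`, and what the synthetic-data tests do and do not establish
about real data.

## Kinetic models

All signals are fractions of the equilibrium magnetization M0. Externally,
ATT is in ms, kw in min⁻¹ and CBF in ml/100g/min; internally times are
seconds and rates s⁻¹, with delivered flux f = CBF/(6000·λ).

**Single-compartment (Buxton) model.** Label created continuously over the
τ = 1.5 s labeling block arrives δ = ATT/1000 s later, attenuated by
e^(−δ/T1b), and decays at the blood rate 1/T1b throughout. At readout
t = τ + PLD the signal is

    ΔM = 2 α f T1b e^(−δ/T1b) (1 − e^(−min(τ, t−δ)/T1b)) e^(−max(t−δ−τ, 0)/T1b)

continuous in both t and δ, zero until label arrives, and reducing to the
consensus closed form 2 α f T1b (1 − e^(−τ/T1b)) e^(−PLD/T1b) once the whole
bolus has arrived (δ ≤ PLD). A consequence of the uniform blood-T1 decay is
that the signal is *independent* of δ for δ ≤ PLD; see FEAST below.

**Two-compartment single-pass (SPA) model.** The capillary pool receives
the same arterial input, relaxes at 1/T1b and drains into tissue at
k = kw/60 s⁻¹; the tissue pool relaxes at R1t = 1/T1t (default 1/1.2 s⁻¹,
overridable per voxel — the acquisition's control images can furnish a
tissue-relaxation map, and the module accepts one). The closed-form
piecewise solution is implemented with an explicit limit branch where the
two clearance rates coincide (kw = 60·(1/T1t − 1/T1b) ≈ 13.6 min⁻¹), and is
validated against fixed-step RK4 integration of the ODEs to 1e-5 relative
error. When T1t = T1b the two compartments sum exactly to the Buxton
signal: exchange conserves label under equal relaxation, a property the
tests assert to 1e-9.

**Diffusion weighting is idealized** (this is the operative assumption of
the ratio method): b = 50 s/mm² at PLD 1.8 s is a perfect crusher of
capillary label, b = 0 is crusher-free, so the crushed/uncrushed ratio
A = ΔM_tis/ΔM_total depends only on (kw, ATT, R1t) and is strictly
increasing in kw and exactly independent of CBF. Partial attenuation at
intermediate b is out of scope.

**kw inversion** is monotone bracketing/bisection of A over kw ∈ [0, 1000]
min⁻¹ to |ΔA| ≤ 1e-8, vectorized over voxels; ratios at or above the value
at kw_max return kw_max with a saturation flag, nonpositive ratios return 0.

**FEAST.** The transit-time ratio is defined as
r(ATT) = ΔM_Buxton(ATT)/ΔM_Buxton(att_floor) with the uncrushed reference
assumed to arrive at the configurable floor (default 0.5 s). Under the
uniform blood-T1 decay above, r ≡ 1 for ATT ≤ PLD and decreases strictly on
(PLD, PLD+τ): at PLD = 0.9 s the method resolves transit times in
(900, 2400) ms, which covers the whole-brain range of the emulated study
(group means 1220–1527 ms). Inversion is by a precomputed 1 ms lookup table
with linear interpolation; r ≥ 1 maps to the floor (flagged when r > 1).

**CBF inversion** has two modes: "att-aware" (exact algebraic inverse of
the forward model, the model being linear in CBF) and "white-paper" (the
consensus closed form that ignores ATT). In the full pipeline the att-aware
mode additionally accepts the already-estimated kw map and inverts the
two-compartment *total* signal; this matters because with T1t < T1b the
exchanged label relaxes faster than the Buxton model assumes, and ignoring
it biases CBF by the exchange factor. With this correction the noise-free
end-to-end pipeline recovers (CBF, ATT, kw) truth fields to
(1e-3 ml/100g/min, 0.1 ms, 1e-4 min⁻¹).

## Map-level processing

**Differencing.** Control−label pairs per (PLD, b) condition, normalized by
M0; interleave order is declared in the series (control-first default).
Voxels with nonpositive or non-finite M0 are flagged missing, never
silently NaN-propagated. Every clamp, floor and saturation sets a bit in a
companion flag volume.

**PCA physiological-noise reduction.** The repeat-mean difference (the
perfusion signal) is removed; principal components of the residual
repeat × voxel matrix are ranked by variance and the minimal set of
highest-variance components whose removal leaves at most `retain_fraction`
(default 0.8) of the residual variance is discarded as structured
physiological noise. The repeat mean is restored exactly (re-centered), so
denoising never moves the mean difference map. A variance criterion is used
rather than correlation with the expected label time course.

**Total-variation regularization.** The published pipeline spatially
regularizes the ratio map (second-order TGV); here a first-order
anisotropic TV proximal problem ½‖u−f‖² + w·TV(u) is solved by ADMM with an
exact sparse factorization per u-update, masked to valid voxels. Weight 0
(the default, and the analytic test path) is the identity; the solution's
TV never exceeds the input's, and the 1-D solution matches a slack-variable
QP oracle to 1e-4. TGV's second-order behavior (piecewise-linear rather
than piecewise-constant recovery) is a known difference and out of scope.

## Group-level statistics

**ROI statistics.** Region means are plain (optionally GM-density-weighted)
means over finite voxels; aggregation is linear to 1e-12. Age groups are
half-open bins [8, 36), [36, 62), [62, 93), matching the study groups
8–35 / 36–61 / 62–92 with integer ages. SDs use the n−1 denominator; sex
comparisons within bins are one-way ANOVAs; relative sex differences are
reported as (F−M)/F·100 rounded half-away-from-zero to one decimal, the
convention that reproduces the printed 14.7 / 14.3 / 19.4 % values from the
printed group means.

**Hinge-spline trajectories.** Candidate knots are unique observed ages
with at least `min_knot_spacing` (5) observations strictly on each side;
candidate terms are the linear age term, the sex indicator (F = 0, M = 1),
the linear age×sex product, reflected hinge pairs max(0, ±(age−k)), and
sex×hinge pairs (interaction depth 2). The forward pass greedily adds the
candidate with the largest RSS reduction (ties to the earliest candidate;
additions below 1e-10 relative improvement stop the pass) up to `max_terms`
(8) basis functions; the backward pass deletes terms while the GCV
criterion (rss/n)/(1−C/n)², C = M + d(M−1)/2 with d = 3 and M counting the
intercept, does not worsen. The surviving basis is refit by OLS — with race
dummies (reference White) as additive covariates when present — giving
coefficient covariance for per-segment slope contrasts and 95% t-CIs.
Two cross-validation-like quantities are deliberately distinct: GCV prunes;
a genuine 10-fold CV on mutually exclusive folds (seeded, deterministic)
yields the reported R² = 1 − PRESS/TSS. On small instances (≤ 8 candidate
knots) the selected model attains the exhaustive minimum GCV over all
≤ 2-knot hinge models; this is a property of well-structured instances, not
a guarantee of greedy search in general.

**Reading the post-knee slope.** The fitted derivative is piecewise
constant between knots. Headline post-knee quantities are read from the
segment containing the center of the oldest age group (77 y): with a
weakly identified change point a replicate can place the knot early or
late, and a tiny terminal segment's slope is noise, whereas the slope at
the group center is an essentially unbiased estimator of the generating
post-knee slope (replicate-mean −0.82 at the preset's conditions).

**Voxelwise GLMs.** GLM1: response ~ intercept + age + sex + race + ICV +
GM density + the two non-response parameter maps (voxelwise columns);
contrast on age. GLM2 adds age×sex and tests it — the printed interaction
formula is read as including the age×sex product as the tested term with
additive covariates. Per-voxel OLS is vectorized via batched Gram matrices
with eigenvalue rank checks; T = cᵀβ̂ / √(cᵀ(XᵀX)⁻¹c·s²), df = n − p, and
equals explicit normal equations to 1e-10.

**Cluster-extent correction.** Residual smoothness is estimated per axis
from the variance of first differences of standardized residuals via the
Gaussian-kernel (Forman) relation FWHM = Δx·√(−2 ln 2 / ln r),
r = 1 − var(diff)/2, floored at one voxel — the sampling resolution limit:
a field rougher than one voxel cannot be distinguished from white noise on
the lattice, and the floor makes the white-noise case report exactly the
voxel size. The Monte-Carlo null simulates Gaussian fields at that
smoothness, thresholds two-sided at the Gaussian quantile matched to
P(|T_df| > t) (Student-to-normal quantile mapping), and takes the
(1−α) quantile of per-iteration maximum cluster sizes as the extent
threshold. Positive and negative clusters are labeled separately
(face connectivity 6 by default, 18/26 configurable). The published
501-voxel / |T| > 1.97 / 1.90 thresholds are shipped as presets
("paper-fig4"/"paper-fig5") because they depend on the original data's
smoothness, which is not recoverable; the default path recomputes the
extent threshold from the data at hand.

## Synthetic cohorts

The study preset reproduces the cohort structure exactly: 186 subjects
(89 M / 97 F), race 65/27/47/47, age groups of 56/55/75 with per-group sex
allocation (31/25, 28/27, 30/45) — the unique printed-marginal-consistent
allocation adopted here. Ages are integer years uniform within each group
(the per-year distribution is not published; integers keep every age inside
8–92 and make the 62 y knee an observable age). Mean trajectories are
continuous piecewise-linear with one knee per feature (kw 62 y, CBF 22 y,
ATT 36 y); per sex, the three parameters (level at knee, pre/post slopes)
solve a 3×3 linear system so the group expectations equal the printed
whole-brain means *exactly* under the generator's own age distribution.
Residual SDs per (sex, group) are set so total group SDs match the printed
ones (variance decomposition; floored at 10% of the printed SD). The
calibrated whole-brain post-knee kw slopes come out at −1.20 (M) vs
−0.18 (F) min⁻¹/yr — the male decline steeper, as reported. The
gray-matter kw curve is not printed as group means, so it uses a flat
pre-knee level of 121.2 min⁻¹ (midpoint of the printed young-group means),
the published post-knee slope −0.82 min⁻¹/yr for both sexes, and a residual
SD of 17 min⁻¹ (near the printed young-group whole-brain SDs); these GM
noise levels are extrapolations, not published values.

Imaging simulation places per-region truths on a toy slab atlas, perturbs
them with optionally smoothed Gaussian fields, forward-models the four
(PLD, b) conditions with the package's own kinetics at the acquisition's
repeat counts (15 pairs at 0.9 s, 20 at 1.8 s), and embeds them in
control/label volumes around a uniform M0. The noise parameter is the SD of
a single-pair difference *relative to the condition's mean difference
amplitude* (so "2% noise" means a per-pair difference SNR of 50). Noise is
calibrated against the difference signal rather than M0 because the
difference signal itself is only ~0.3–0.5% of M0 at the study's CBF values. Noise is
Gaussian, not Rician — adequate for difference images of high-SNR magnitude
data, a documented simplification.

**What the synthetic tests do not show.** The generator has no anatomy,
motion, slice profile, partial-volume mixing, or field inhomogeneity; its
noise is uncorrelated across conditions and its diffusion crushing is
binary. Passing recovery tests therefore validate the estimators against
the model's own assumptions, not against scanner reality.

## Known limitations and problem sizes

* The change point of the GM-kw trajectory is weakly identified at the
  preset's noise: the published slope CI ([−1.35, −0.28]) itself implies a
  residual SD ≈ 23 min⁻¹ at n = 186, at which single-replicate knee
  estimates scatter by ±10 y and post-selection slope CIs undercover.
  Headline recovery therefore uses replicate aggregates (median knot, mean
  slope at the oldest-group center over 200 seeded cohorts in
  `scripts/acceptance.py`; smaller replicate counts in the test suite).
* FEAST with a uniform blood-T1 single-compartment model cannot resolve
  transit times at or below the short PLD (0.9 s); such voxels report the
  configured floor.
* Default problem sizes (16³ grids, 30-subject imaging groups, 200
  trajectory replicates, 300–1000 Monte-Carlo null iterations) were chosen
  as the smallest at which sampling error is comfortably below the effects
  under study; all are arguments, not constants.
* Acquisition simulation of non-CPMG diffusion preparation, background
  suppression design, multi-PLD protocols, spatial normalization and
  partial-volume correction are out of scope; inputs are assumed aligned.
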