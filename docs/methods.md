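# Methods

This note documents the models, numerical choices and known limitations of
`chimetraits`. It describes what the code computes and why the defaults are
what they are; every number quoted here is produced by the package's own
tests or drivers.

## Forward model

The pipeline is designed around a pluggable forward model. The built-in
surrogate is *not* a physical leaf/canopy model: it is an analytic stand-in
with qualitatively correct absorption features, defined so that every
downstream stage (sensor simulation, LUT regression, active learning,
mapping) can be exercised and tested offline. An adapter slot for an
external PROSAIL-PRO implementation exposes the same signature and raises
a `ConfigurationError` when the library is unavailable.

Leaf level. Each constituent contributes a sum-of-Gaussians absorption
coefficient k(λ) (chlorophyll peaks at 430/665 nm, carotenoids 450/480 nm,
water 1450/1940 nm, protein 1510/2054/2172 nm, carbon-based constituents
1730/2100/2300 nm; amplitudes per native content unit are config defaults).
Total absorbance is

    a(λ) = [cab·k_cab + ccx·k_cx + cw·k_w + 1000·cp·k_p + 1000·cbc·k_cbc] / N

with N the leaf structure parameter. Reflectance and transmittance split
the Beer–Lambert-attenuated flux by a scattering fraction
s = clip(0.45 + 0.05·(N−1), 0, 0.6):

    R(λ) = s·e^(−a(λ)),   T(λ) = (1−s)·e^(−a(λ)),

so R+T = e^(−a) ≤ 1 everywhere, absorptance vanishes with the absorbers,
and reflectance decreases monotonically in every content — the three
properties the rest of the pipeline depends on (red-edge contrast, NDVI
ordering of soil vs vegetation, dark-soil/dense-canopy limits). A
formulation in which reflectance *grows* with absorbance was rejected
because it inverts the vegetation spectrum (NIR below red), breaking NDVI
masking and every monotonicity property.

Canopy level. A single-layer closure with extinction
k_ext = (0.5 + 0.4·cos ALA)/cos SZA:

    R_canopy = soil·e^(−k_ext·LAI·(1+T)) + R_leaf·(1 − e^(−k_ext·LAI)).

LAI = 0 returns the soil spectrum exactly; LAI → ∞ converges to the leaf
reflectance (within 1e−6 at LAI = 50). The hot-spot parameter and
observer/azimuth angles are accepted for the external adapter but unused
by the surrogate. The four soil backgrounds are linear brightness ramps
(b ∈ {0.6, 0.8, 1.0, 1.2}); all have NDVI ≈ 0.075, safely below the 0.3
bare-soil threshold.

## Sensor simulation

The CHIME-like configuration tiles 400–2500 nm with 210 bands of 10 nm
FWHM (centers 405 … 2495 nm; a center-at-400 convention would yield 211
edges and was rejected). Water-vapour windows [1340, 1470], [1750, 2000]
and [2350, 2500] nm drop 13+25+15 = 53 bands, retaining 157. The exact
removed-band list of the real mission is not public; these windows sit in
the canonical 1.4/1.9/2.4 μm absorption regions and are config-exposed.
Resampling integrates the 1 nm simulation grid against Gaussian SRFs
truncated at ±3σ and renormalized; on a 1 nm grid the worst-case error of
this quadrature against a linear spectrum is below 1e−3 of the band value.

## LUT sampling

Marginals follow the configured table of distributions (normals for
structure/pigments/water/angles, uniforms for protein, carbon-based
constituents, sun zenith and soil index). Truncation uses rejection, not
clipping, to avoid probability spikes at the bounds — important for LAI
(μ = 1.77, σ = 1.4, truncated at 0.05, which raises its effective mean to
≈ 1.95). A correlated block (default {cab, ccx, cw} with ρ = 0.8/0.4/0.4)
is drawn as a truncated multivariate normal (Gaussian copula over the
marginal normals); the actual field covariances behind the published
example figure are not printed, so the defaults are a plausible
pigment/water co-variation and fully configurable. Traits derive as
LCC = cab, LNC = 1000·cp/4.43, CCC = LCC·LAI/100, CNC = 10·LNC·LAI.
"5% Gaussian noise" is implemented as multiplicative relative noise —
each spectrum and trait value times (1+ε), ε ~ N(0, 0.05²) — the common
convention for hybrid-retrieval LUTs; reflectance re-clips to [0, 1] and
traits floor at 0.

## Gaussian process regression

Zero-mean GP on targets centered by the training mean (added back at
prediction), squared-exponential ARD kernel, evidence maximization in
log-hyperparameter space with analytic gradients and L-BFGS-B
(bounds ±20 in log space), 3 seeded restarts by default. Initialization:
σ_s² = var(y), σ_n² = 0.1·var(y), lengthscales = per-dimension input std.
The noise init is deliberately conservative: starting near interpolation
(σ_n² ≪ var(y)) reproducibly drives the optimizer into a degenerate
zero-lengthscale optimum on noisy targets (observed with the residual
regression used by RSAL: evidence −25.8 for the collapsed solution vs
−10.9 for the smooth one). Conditioning uses an escalating jitter
(10⁻¹⁰·mean diag K, ×10 steps up to 10⁻⁶) before declaring failure. The
trained solution is never allowed to fall below the evidence of the
initialization. Predictive variance is floored at 0 and bounded by
c* = σ_s² + σ_n²; the prediction CV is 100·√variance/|mean|.

## Active learning

The loop starts from 20 randomly chosen LUT samples, ranks the remaining
candidates with one of five heuristics, proposes the top candidate,
retrains, and keeps it only if validation RMSE strictly decreases; every
candidate is considered exactly once. Rankings are recomputed after every
acceptance (the pool changed) and reused after rejections (it did not).
Heuristic internals not fixed by the method description are config
defaults: CBD uses k-means with k = min(10, #candidates), PAL a 5-member
bootstrap GP ensemble, RSAL a 5-fold out-of-fold residual regression.
Cost/fidelity trade-off: trial candidates are evaluated by re-solving the
GP at the current hyperparameters (a Cholesky at pool size, cheap), and θ
is fully re-optimized after every 5th accepted sample; the refit is
adopted only when it does not worsen validation RMSE, so the accepted-step
RMSE sequence remains strictly decreasing by construction. Measured on the
synthetic campaign, per-acceptance refits triple the runtime without
improving accuracy, while refitting only every 10th acceptance degrades
it. The same validation set guides acceptance and reports the final
metrics, mirroring the method's reliance on in-situ data; a held-out split
can be configured for honest generalization checks.

The accepted-pool size is an outcome, not a target: on a 500-record LUT
with 5% noise the final pools span roughly 15–45% of the LUT depending on
heuristic, trait and seed, while every heuristic matches or beats the
full-LUT model on validation R². The learning curve is much steeper than
the final pool suggests — HYB-comparable accuracy is typically reached
within the first few dozen accepted samples, after which the strict
accept-if-better rule keeps absorbing marginal improvements.

## Synthetic campaign

The generator emulates a field campaign of 87 elementary sampling units
(10×10 m plots), 31 of which carry leaf-lab nitrogen, plus 11 chlorotic
leaf-only samples (LCC ∈ [8, 20] μg cm⁻²) that broaden the leaf-level
range. Latent traits are drawn per ESU: LCC normal (43.31 ± 6.29 μg cm⁻²),
LNC normal (0.15 ± 0.03 mg cm⁻²), CCC gamma with mean 0.75 and SD 0.61
g m⁻². The gamma is deliberate: a normal with these moments places ~11% of
its mass below zero, so truncating it would inflate the realized mean to
≈ 0.90 and break the generator's contract of reproducing the configured
moments; the gamma matches both exactly and has the right-skewed shape
canopy-level traits show in practice. LAI is then *derived* as
100·CCC/LCC (truncated to [0.05, 7], infeasible pairs resampled) so every
row satisfies the trait identities exactly, and CNC = 10·LNC·LAI follows.
Consequence, documented rather than resolved: the four configured means
are mutually inconsistent under the identities (LAI implied by CCC/LCC is
≈ 1.7, by CNC/LNC ≈ 2.6), so the generator reproduces the three *drawn*
means (LCC, LNC, CCC) while the derived CNC mean settles near 2.6 g m⁻²
rather than 3.87. Two campaign dates are emulated as symmetric ±8%
shifts of the leaf-trait means, with the between-date variance absorbed
into the within-date SD so the pooled moments still match. Observations
are latent values times (1 + instrument noise), 5% relative SD per
instrument by default; SPAD readings invert the exponential calibration.

Scenes are rectangular vegetation fields with smoothly varying latent
traits (seeded Gaussian random fields; cab ∈ [25, 60] μg cm⁻²,
LAI ∈ [0.8, 5], cp ∈ [4, 9]·10⁻⁴ g cm⁻²) over bare-soil regions from the
soil library, plus 1% radiometric noise by default. The LAI floor of 0.8
guarantees every vegetated pixel clears NDVI ≥ 0.3, so the bare-soil mask
equals the constructed soil layout exactly — which is what the map tests
assert.

What the synthetic data does *not* emulate: real leaf optics (the
surrogate's features are idealized Gaussians), atmospheric and
georectification effects, within-plot heterogeneity beyond optional LAI
jitter, instrument spectral calibration error, and the spatial PSF of a
real sensor. Passing tests therefore demonstrate the *pipeline's*
correctness and internal consistency — that the regression recovers traits
generated by its own forward model under noise — not retrieval accuracy on
real imagery.

## Problem sizes and runtimes

The test suite and analysis drivers use a 500-record LUT, an 87-ESU
campaign and 20×20–30×30-pixel scenes; the LUT builder's default remains
2000 records. These sizes keep the full suite within minutes on one CPU
while leaving every contract (counts, monotonicity, recovery thresholds)
at its stated strength. Sampler-recovery checks use 10⁵ draws; campaign
moment-recovery checks use 3000–4000 ESUs.

## Known limitations

- The surrogate's absorption amplitudes are not calibrated against any
  measured leaf spectra; absolute reflectance levels are only plausible.
- The GP is exact (dense Cholesky); training beyond ~3000 samples becomes
  slow and no sparse approximation is provided.
- Heteroscedastic noise is not modeled (the predictive variance is
  stationary in the kernel sense).
- The active-learning loop is single-candidate and single-pass; batch
  proposals and uncertainty-based stopping rules are out of scope.
- Map aggregation is block-mean; no convolutional resampling.
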