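# Methods

This note documents the statistical models implemented in `wolbkrig`, the
conventions and defaults behind them, and the choices made where the
design was genuinely open.

## Data model

The unit of observation is a sampled population: coordinates (decimal
degrees), sampling year, the number of individuals genotyped for wCer2
(`n`), the number infected (`k`), and optionally per-individual COI
haplotype calls (HT1/HT2). Surveys of this kind accumulate over decades,
so the same orchard may be sampled repeatedly; because variance-based
spatial analysis assumes independent observations per location,
`filter_duplicate_locations` thins coordinate groups that agree within a
tolerance (default 1e-3°, roughly 100 m — the precision of handheld GPS
field records) to a single randomly chosen representative. The choice is
driven by one integer seed threaded through the whole pipeline; the
operation is idempotent and order-preserving.

The packaged survey fixture carries the published counts and haplotype
calls of the 2018–2022 sampling (15 populations). Coordinates in the
fixture are approximate representative locations per named region
(synthetic stand-ins; the published table names regions, not
coordinates), which is sufficient for exercising the pipeline but not for
re-deriving real-geography results.

## Frequency estimation and comparison

Infection frequency is the observed proportion p̂ = k/n. Intervals are
Wilson score by default: with z the (1+γ)/2 normal quantile,

    center = (k + z²/2) / (n + z²),
    half-width = z √(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n),

clipped to [0, 1]. Wilson is the default of the standard `binconf`
implementation and reproduces the published per-population intervals at
their printed precision; Clopper–Pearson is available behind a method
flag for users who want the conservative "exact" interval. One printed
value (the 11/12 population's upper bound, 0.996) matches neither method
(Wilson ≈ 0.985, Clopper–Pearson ≈ 0.998) and is treated as a printing
error; the tests assert the computed values, not the printed one.

Fisher's exact test uses the two-sided probability-mass rule: conditional
on the margins, sum the hypergeometric probabilities of all tables no
more probable than the observed one (with a 1e-7 relative slack against
floating-point ties). This is the convention of the standard R
implementation and reproduces the published P-values (0.478, 0.045).
Comparisons are strictly pairwise; to compare against a region, pool its
counts first with `pool_groups`. The published pairwise result for the
partially infected French population only reproduces against a single
fully infected n = 12 population — not against the pooled 36/36 — which
is why `compare_populations` is pairwise by contract. No multiple-testing
correction is applied.

## Distances and grids

All distances are great-circle kilometres (haversine, sphere radius
6371.0088 km). The study region spans thousands of km, so planar
degree-based distances would distort east–west separations by up to ~40%
at the northern edge. Prediction grids are full lat/lon lattices; the
default covers Europe and western Russia (lat 34–71, lon −11–61) at 0.5°.
No land/sea masking is applied — predictions over water are reported and
it is up to the interpretation to ignore them.

## Variogram analysis

The empirical semivariogram bins site pairs by separation into intervals
((j−1)w, jw] of width w (default 60 km) up to a cutoff (default 2000 km,
with the full 6300 km sampling span available via configuration), and
averages half squared differences per bin:

    γ̂(h_j) = (1 / 2N_j) Σ_{pairs in bin j} (z_i − z_k)².

Anisotropy diagnostics: directional variograms restrict pairs to bearing
sectors (default axes 0°, 45°, 90°, 135° with ±22.5° tolerance — a
partition, so the omnidirectional estimate is exactly the pair-weighted
average of the sectors), and the variogram map bins pair separation
vectors (Δx, Δy) with exact central symmetry. Bearings use an
equirectangular local-tangent-plane approximation, adequate at sub-cutoff
scales and documented as approximate.

The theoretical model is exponential,

    γ(r) = C0 + C1 (1 − e^(−3r/b)),   γ(0) = 0,

with nugget C0 (spatially unstructured variance, which includes binomial
sampling noise of order E[p(1−p)/n]), partial sill C1 (spatially
structured variance), and b the practical range: γ(b) − C0 =
(1 − e⁻³) C1 ≈ 0.9502 C1. Fitting is weighted least squares over bins
with weights N_j/h_j² by default (the default of the reference
geostatistics stack; N_j and unweighted are options), bounds C0, C1 ≥ 0,
b > 0. Exponential WLS objectives are multimodal in b, so the bounded
trust-region solver is restarted from five deterministic initial values
of b ({¼, ½, 1, 2, 4} × the distance at which γ̂ first reaches 80% of its
maximum); ties resolve to lowest SSE, then smallest b, and the returned
SSE never exceeds that of the default initial guess. A flat variogram
fits C1 = 0 with the range flagged unidentifiable.

`practical_range` returns the exact distance at which γ reaches 95% of
the *total* sill C0 + C1 (closed form −(b/3) ln(0.05 (C0+C1)/C1)); this
equals ~0.9986 b when C0 = 0 but differs from b when C0 > 0. Both
quantities are exposed because the two conventions are often conflated.

No fitted (C0, C1, b) values are published for the real data, so the fit
is validated by noiseless-inversion tests, invariance properties, and
parameter-recovery simulations rather than against printed targets.

## Ordinary kriging

Prediction at x0 solves the standard (n+1) ordinary-kriging system

    [Γ 1; 1ᵀ 0][w; λ] = [γ0; 1],   Γ_ik = γ(d_ik) (zero diagonal),

giving z*(x0) = Σ w_i z_i and kriging variance Σ w_i γ0_i + λ, which
depends only on geometry and the model, never on observed values. Grid
prediction factorizes the system once (LU) and solves all grid
right-hand sides in one pass; 238 sites × ~10⁴ grid points takes seconds.
Kriging is global by default (the study's site count is small); a
nearest-k neighborhood mode exists for larger problems, with per-point
failures recorded as NaN rather than aborting the surface.

Numerical policy: coincident sites are an error directing the user to
the deduplication stage (they make the system singular); systems with
condition number above 1e12 receive a 1e-10 diagonal ridge and a logged
warning. Predicted values are frequencies, so they are clamped to [0, 1]
post hoc with the raw best-linear-unbiased value retained in a separate
column (ordinary kriging can overshoot the physical bounds near
extrapolation edges).

Validation is leave-one-out cross-validation: each site predicted from
the other n−1, reporting mean error, RMSE, 95% coverage of ±1.96√(kriging
variance), and the variance of standardized residuals (≈ 1 for a
well-specified model).

## Origin inference

The map-reading argument — "regions predicted wCer2-infected cannot have
sourced an uninfected invasive population" — is made quantitative with a
binomial compatibility score: for each grid cell, the exact probability
of the invasive observation (k_inv of n_inv infected; 0 of 40 in the
motivating case) given the cell's predicted frequency. Cells with score
≥ α (default 0.05) are candidate origins. This score is an explicit
extension of the qualitative argument, flagged as such in the run
summary; α is a configuration choice, not an estimate. The point mass is
the default (appropriate for k_inv = 0); a two-tailed exact binomial
p-value is available for interior counts.

Haplotype concordance cross-tabulates per-individual wCer2 status
against mitochondrial haplotype (HT2 hitch-hikes with wCer2 through
maternal co-transmission); the misassociation rate is the fraction of
infected/HT1 plus uninfected/HT2 individuals. The deterministic spread
criterion classifies (F, μ) — relative fecundity of infected females and
maternal transmission failure — as `spreads_from_rare` iff F(1−μ) > 1,
with the boundary classified bistable (strict inequality). The full
infection-frequency recursion and spatial-wave models are out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
sites over a European-scale bounding box (uniform, or a Thomas-like
clustered mode mimicking dense Central-European sampling), a latent
Gaussian field with covariance C0 I + C1 exp(−3d/b), a link to [0, 1],
and per-site binomial sampling. Sample sizes follow the empirical law of
the survey: resampled from the native-range survey sizes with a 5%
uniform tail on 1–68, giving mean ≈ 12 and range 1–68, matching field
protocols where a handful to a few dozen flies are genotyped per site.

Default truth parameters for simulation experiments are mean_p = 0.5,
C0 = 0.05, C1 = 0.20, b = 600 km — synthetic fixture choices shaped by
the qualitative features of the real surface (semivariance rising to
~200 km, strong autocorrelation below 1000 km), not published estimates.

The default `truncate` link is a NORTA-type (normal-to-anything)
construction: the clipped-normal marginal is moment-matched so the
field's mean and variance equal mean_p and C0 + C1, and the latent
correlation is pre-distorted through the numerically inverted
pair-correlation map of the clipping transform, so the generated field
itself carries the nominal exponential variogram. This matters because a
plain clipped Gaussian attenuates both variance and correlation range —
parameters would then describe a field nobody observes. Note that at
mean_p = 0.5 a variance of 0.25 is the Bernoulli maximum, so the matched
field is strongly bimodal — which is faithful to the real data, where
most populations are near 0% or 100% infected. A plain `clip` link (the
textbook variant), a variance-matched `logit` link (correlation
approximate), and an `identity` link (no transform, for Gaussian-scale
calibration studies such as LOOCV checks) are also provided. When the
identity link is used, frequencies are clipped to [0, 1] just before
binomial sampling.

What the generator does **not** emulate: temporal spread dynamics,
infection-frequency clines driven by cytoplasmic incompatibility waves,
non-stationarity of the mean, or the historical accumulation of surveys
across 25 years. Passing recovery tests therefore show the estimators
work under the assumed stationary model at realistic sampling intensity
— not that the real surface satisfies those assumptions.

## Problem sizes used in the test suite

Simulation-based tests use 238 sites (the real native-range count) with
~12 individuals per site for recovery experiments (100 replicates),
60–960 sites for consistency checks, and 90-site fields for LOOCV
calibration (20 replicates) — sizes chosen to mirror the study design
while keeping the default suite fast on one CPU.

## Known limitations

- Only the exponential variogram family is implemented (the model-family
  argument is a configuration hook); no REML/ML variogram estimation.
- Ordinary kriging only: no universal/regression kriging, no co-kriging
  with haplotype data, no Bayesian variants.
- No cartography: surfaces are tables of (lat, lon, prediction,
  variance), with no coastline clipping or sea masking.
- Directional bearings are planar-approximate; at separations well
  beyond ~2000 km sector assignment near sector edges can differ from a
  fully spherical treatment.
- The compatibility score treats the kriged prediction as known; it does
  not propagate kriging variance into the binomial probability.
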