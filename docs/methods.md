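# Methods

This note documents the models implemented in `seedshadow`, the defaults
and why, the numerical choices, and what the synthetic test bed does and
does not establish.

## Landscape covariates

Covariates live on a single projected, metre-based 10 m grid. Canopy gaps
are connected regions of cells with canopy height below 5 m; connectivity is
4-neighbour (rook), the conservative standard for treefall-gap delineation
(configurable). Gaps are detected at the canopy model's native resolution
and classed by area: small ≥ 50 m², large ≥ 500 m², so every large gap is by
construction also a small gap and the large-gap distance layer's zero set is
nested in the small-gap one. Distance layers are centre-to-centre Euclidean
distances at the 10 m covariate resolution after mapping gap cells to the
coarse grid by any-overlap; a gapless raster gets the raster diagonal as a
finite cap rather than an infinity that would poison standardisation.

The vertical complexity index is the normalised Shannon entropy
−Σ pᵢ ln pᵢ / ln(n_bins) of the per-cell vertical profile of LiDAR return
heights over fixed-width bins (default 1 m over 0–60 m). This is one of
several entropy-style VCI definitions in use; it is bounded in [0, 1],
invariant to total return count, and 0/1 at the degenerate extremes. Cells
with no returns are nodata. Nodata never enters means or entropies, and a
step whose endpoint lands on nodata invalidates its stratum rather than
being silently imputed.

Rasters are exchanged as plain-text ESRI ASCII grids with the CRS identifier
in a trailing comment; no reprojection is performed — inputs must already
share a projected metre CRS, and a mismatch is an error. The Movebank
reader accepts projected x/y directly, or lon/lat via a local
equirectangular projection about the track centroid, which is accurate to
well under a metre over a 25 km² study area near the equator but should not
be used for tracks spanning hundreds of kilometres.

## Track regularisation and strata

Tags record fixes every 5 min between 05:45 and 18:30 local time.
Resampling to the 30-min analysis rate is a greedy forward pass: from each
kept fix, the next kept fix is the one whose gap is closest to the target
within ±5 min (ties to the earlier record); gaps outside the window start a
new burst, and bursts shorter than three fixes are dropped because a turn
angle needs two consecutive steps. The ±5 min tolerance and the 60-min
temperature-matching window are declared defaults, not values inferred from
any source; both are configurable. Steps that would span the nightly GPS-off
window are excluded.

Headings use the mathematical convention (radians, counter-clockwise from
+x); turn angles are wrapped differences of successive headings in (−π, π].
Control steps (default K = 10) share the used step's origin and time, with
lengths from the fitted tentative gamma and turns from the fitted von Mises
applied to the previous observed heading. Covariates are the value of the
raster cell containing the endpoint, without interpolation. Continuous
covariates are centred and scaled per animal using the sample SD (n − 1)
over used and control steps together; binary swamp is never scaled, and the
swamp × temperature interaction is the product of standardised temperature
and raw swamp. `standardize_covariates` can instead apply externally fixed
parameters — used when scoring simulated locations with a fitted model, and
by the recovery tests so the refit estimand matches the generating scale.

## Conditional logistic regression

The conditional likelihood Σ_strata [βᵀx_used − log Σ_j exp(βᵀx_j)] is
maximised by Newton ascent with step halving; the gradient and Hessian are
the exact stratum-wise moment expressions, so the covariance is the inverse
observed information at the optimum. Convergence requires a gradient
max-norm below 1e-8. Strata with missing design values or no within-stratum
variation are dropped and counted in the diagnostics. Separation — a
coefficient escaping |β| > 15 on standardised covariates while the gradient
stays non-zero — is flagged and the fit reported non-converged rather than
returning a silent boundary estimate. The fitter is verified against
coarse-to-fine exhaustive grid search on small problems and against a
generic simplex optimiser on real strata, and satisfies the conditional-
likelihood invariance under stratum-constant covariate shifts.

The default formula is canopy height + VCI + distance to small gap +
distance to large gap + swamp + swamp × temperature + log(SL + 1) + cos(TA);
SL is in metres and the +1 keeps the term finite at zero length. Tentative
distributions are maximum-likelihood fits (gamma with location pinned at 0;
zero lengths offset by half a covariate cell, 5 m; von Mises with unit
scale). A concentration above 500 is pinned and flagged degenerate. The von
Mises mean is fitted rather than fixed at 0, but simulation defaults to
μ = 0.

## Population level

The primary population estimator is two-stage: per-individual conditional
logits pooled by inverse variance, β̂ = Σ(βᵢ/seᵢ²)/Σ(1/seᵢ²),
se = (Σ 1/seᵢ²)^(−1/2). A one-stage mixed-model (Poisson-reformulation,
random slopes) estimator was considered and deliberately not implemented:
`fit_population_model` performs the two-stage computation and warns, since
for the pipeline's purposes (a time-agnostic population kernel) the
two-stage estimator is sufficient and fully testable against closed forms.
Species contrasts are weighted least squares of individual coefficients on a
species indicator with weights 1/seᵢ², F-tested with df = (g − 1, n − g).

Temperature-binned swamp selection refits a reduced model (swamp + movement
terms) per individual within each bin of the used step's raw temperature and
pools. Bins are half-open and left-closed: (−∞, 22), [22, 25), [25, 27),
[27, ∞) °C — membership of exactly 27 °C in the hottest bin is this
package's decision, since "25–27 and >27" leaves the boundary ambiguous.

## ODBA and model ranking

ODBA is computed per burst as the sum over the three axes of the mean
absolute deviation from that axis's burst mean. The burst mean is the static
(gravity) estimate; no running mean is used because bursts are short (20 s).
This makes ODBA exactly invariant to per-axis constant offsets and linear in
dynamic amplitude. Count-to-g calibration is an explicit per-axis
slope/intercept (default identity for inputs already in g); the tag
manufacturer's internal transformation is not reproduced, so calibration is
a required user input for raw counts.

Candidate ODBA models are linear in any subset of the predictors with a
per-animal random intercept. The variance ratio σ²_u/σ²_e is profiled out —
each group's covariance has a closed-form inverse and determinant, and the
ratio is found by 1-D bounded search with the θ = 0 boundary checked
explicitly, so a single animal reduces exactly to OLS. Maximum likelihood
(not REML) is used so AICc is comparable across fixed-effect subsets;
k counts the fixed effects (with intercept) plus two variance parameters.
Note on ranking behaviour: when exactly one predictor has an effect, a
superset model still outranks the minimal one whenever a spurious term's
deviance gain exceeds the ≈2-point penalty (probability ≈ 0.157 per term),
so the minimal model is the modal winner, not a near-certain one; the tests
assert the statistically correct version of this claim.

## Gut passage and seed shadows

Gut-passage times are gamma by method of moments from a published
mean ± spread in minutes: shape = (mean/spread)², scale = spread²/mean. The
published ± values are described as standard errors without the trial size,
so converting them to SDs is impossible; this package uses them directly as
the SD of the passage-time distribution. This makes the fitted gamma
narrower than the true inter-seed distribution if the values really are
standard errors of a mean — a known, prominently flagged interpretation
choice that shifts deposition weights toward the mean passage time but does
not affect any conservation property.

Deposition weights are CDF increments over consecutive 20-min steps,
w_k = F(kΔt) − F((k−1)Δt), k = 1..50; the tail mass beyond the simulated
bout, 1 − F(50Δt), is reported and never silently renormalised.

Trajectory simulation draws, per step, 100 candidates from the tentative
distributions (count configurable; the value is a declared default),
scores each by exp(βᵀx) using the significant habitat coefficients, the
fitted movement-term coefficients, and the stored training
standardisation, and keeps one with probability proportional to its score.
Off-raster or nodata candidates score zero; a fully invalid candidate set is
redrawn up to 10 times before the trajectory is flagged stuck and truncated.
The initial heading is uniform on (−π, π]. The population kernel is
time-agnostic: interaction terms are dropped when building a kernel from a
fitted model.

Seed shadows bin weighted endpoints to the 10 m grid and smooth with an
isotropic Gaussian (default bandwidth 30 m = 3 pixels, truncated at 4σ; the
discrete kernel is normalised so smoothing conserves mass). The default
extent is the endpoint bounding box padded past the kernel support, so the
raster total equals the mean per-trajectory deposited weight to machine
precision; with a user-supplied extent the truncated mass is reported.
λ = total mass / pixel count, so λ is extent-dependent by definition —
comparisons require a common extent. Distance summaries are
deposition-weighted quantiles of endpoint distance from the source.
Seed-fall realisations draw per-pixel Poisson counts with intensity
deposition × total seeds and place points uniformly within pixels.

Movement-model adequacy is checked by comparing covariate distributions at
used, available, and simulated endpoints: shared-bin histograms, quantile
tables, and a total-variation divergence between used and simulated, which
is 0 for identical sets and demonstrably smaller for a fitted kernel than a
selection-free one on synthetic data.

## Synthetic test bed

The generators define the study conditions for every recovery test.
Landscapes are 300 × 300 cells at 10 m (3 × 3 km): canopy height is a
Gaussian random field (white noise convolved with a Gaussian of 50 m range)
with mean 25 m and SD 8 m, clipped at 8 m above the gap threshold so no
spurious gaps arise; gap patches are carved as connected blobs at requested
areas with buffered separation; swamps are disks; the VCI field shares a
fixed 0.3 correlation with canopy height, safely below the 0.6 collinearity
screen. Temperature is a sinusoid peaking at 14:00 (mean 23 °C, amplitude
5 °C, noise SD 0.5 °C) so the tags' daytime window spans all four analysis
bins.

Tracks simulate one selection decision per 30 min with candidate sets scored
by the true coefficients (tentative kernel: gamma shape 2, rate 0.01 —
mean step 200 m; von Mises κ = 0.5), then emit 5-min fixes by linear
interpolation on the daytime schedule, so resampling is genuinely exercised
while the decision-scale coefficients remain the estimand. The default
recovery condition is 5 animals × 500+ strata with canopy β = 0.3.
Replicated coverage experiments (200 fits of 500 strata) generate strata
directly from the same per-step selection process without trajectory
autocorrelation, which is the estimator-relevant structure at a fraction of
the cost. Accelerometer bursts get a random unit gravity vector per burst
and Gaussian dynamic noise scaled through the exact normal mean-absolute-
deviation factor so the expected ODBA equals the requested level.

What the synthetic bed does not emulate: real topography and inselberg
geometry, GPS measurement error, fix-quality loss, behavioural states
(roosting, nesting), inter-animal interactions, and habitat-dependent
temperature offsets (the station series is global, as in the field setup).
Passing recovery tests therefore shows the estimators are correct for the
assumed data-generating model, not that the model captures everything a real
tracking data set contains.

## Problem sizes and determinism

Default test and acceptance sizes — 3 × 3 km landscapes, 5 animals ×
800 decision steps, K = 10 controls, 200 coverage replicates, 100
trajectories × 50 steps — were chosen as the smallest sizes at which the
recovery tolerances are comfortably met; everything completes in a few
minutes on one CPU. Every stochastic component takes an explicit seed
(NumPy `default_rng`), and same-seed runs are bit-identical.
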