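# Methods

## Movement model

The state per planar axis is (position x, velocity v) in km and km/h,
with Ornstein–Uhlenbeck velocity `dv = −β v dt + σ dW`. Exact
discretization over an interval Δ (hours) uses

    v' = e^{−βΔ} v + η_v,                    Var(η_v) = σ²(1−e^{−2βΔ})/(2β)
    x' = x + v(1−e^{−βΔ})/β + η_x,           Var(η_x) = (σ²/β²)[Δ − 2(1−e^{−βΔ})/β + (1−e^{−2βΔ})/(2β)]
                                             Cov(η_x, η_v) = σ²(1−e^{−βΔ})²/(2β²)

For βΔ < 10⁻² these expressions cancel catastrophically in double
precision (the position variance is O((βΔ)³) built from O(βΔ) terms), so
Taylor series through the fourth relative order are used instead; the
branch point was chosen where the series truncation error and the
floating-point cancellation error are both below 10⁻⁹ relative, and a
test checks continuity across the switch. The two axes are independent
given the parameters. σ is the diffusion coefficient of the velocity
SDE, so the stationary velocity variance is σ²/(2β) per axis.

Parameters are piecewise constant per inter-fix interval and anchored at
the interval's **starting** fix (causal: the covariates an animal
experiences now drive its next displacement).

## Likelihood, initialization, smoothing

The marginal likelihood is the exact Kalman-filter prediction-error
decomposition, one scalar-observation filter per axis (numba kernels;
~10 µs per 150-fix track). The initial state has a diffuse position
prior (variance 10⁶ km², centred on the first observation — which makes
the likelihood exactly translation invariant) and a stationary velocity
prior at the first interval's (σ, β). `dense_loglik` rebuilds the same
joint Gaussian explicitly by composing transitions and serves as the
module's oracle on short tracks (agreement to 10⁻⁸ is enforced in
tests). State estimates come from the Rauch–Tung–Striebel smoother;
speed is the norm of the smoothed velocity.

## Covariate link and fitting

log σ_t and log β_t are linear in standardized covariates with optional
group-deviation terms. The link-noise SDs ε₁/ε₂ are fixed at 0.001 and
the default fit treats the link as deterministic (the ε→0 limit): at
that scale the latent jitter moves the log-parameters by ~0.1% and is
statistically invisible, while making the likelihood exact; a latent
mode (jittered predictors) exists for simulation fidelity.

Fitting maximizes the summed per-animal likelihood over all link
coefficients with L-BFGS-B using **central** finite-difference
gradients — one-sided differences proved too noisy along the curved
σ/β trade-off valley and produced optima violating model nesting.
Starts come from a coarse β grid (3·10⁻⁴…1 h⁻¹) with σ moment-matched
to the empirical velocity variance and zero slopes; the incumbent is
re-polished from a jittered restart and a Nelder–Mead pass because the
surface has a flat ridge where βΔ saturates (once velocity fully
decorrelates between fixes, larger β is indistinguishable). Standard
errors are square roots of the diagonal of the inverse
finite-difference Hessian. The convergence flag accepts the optimizer's
own success status or a gradient ∞-norm below 10⁻⁴·max(1, |logLik|);
an absolute 10⁻⁵ threshold is meaningless against finite-difference
noise at |logLik| ~ 10⁴. k in AIC = 2k − 2 logLik counts every
estimated link coefficient (the fixed ε are not counted; this cannot
affect ΔAIC rankings).

I-models are the same machinery on one animal with no grouping;
covariates with zero within-animal variance (e.g. ice presence for a
whale that never met ice) are dropped per animal with a warning.

## Geometry

Without a projection library in the stack, a spherical azimuthal
equidistant projection (centre 40°W 45°S, R = 6371.0088 km) is
implemented directly, with a secant scale factor k₀ = 0.9974 — the pure
projection stretches chords transverse to the centre direction by
c/sin c (+0.52% at the 55°S feeding-ground latitudes); shrinking the map
balances radial against transverse error so both stay within 0.5%
there. Great-circle distances use the haversine form; distance to a
front polyline densifies segments to ≤1 km chords.

## Argos error model

Error ellipses (semi-major M, semi-minor m metres, orientation c from
north) decompose to per-axis SDs by sd_x² = (M² sin²c + m² cos²c)/2,
sd_y² = (M² cos²c + m² sin²c)/2 — the axes treated as 1-sigma extents
split between axes; the convention is a module constant so a 95%-ellipse
convention can be swapped in. For ellipse-less (older) tags, per-class
gamma GLMs (log link, latitude covariate; statsmodels) are fitted to
ellipse-derived SDs, with the gamma shape by profile maximum likelihood
(statsmodels' default moment estimator is not the MLE); imputation draws
one SD per fix from the class/latitude gamma and applies it to both axes
(class-based Argos errors are reported isotropically). Classes with
<10 training fixes fall back to a pooled model.

## Descriptive analyses

Censoring removes on-shelf fixes before the first shelf exit
(configurable polygon; the shipped Brazilian-shelf polygon is a
hand-drawn synthetic proxy of the 200 m isobath) and rejects tracks that
never reach 50°S. The crossing date interpolates linearly in latitude
between the bracketing fixes; durations are floor whole days. Footer
statistics use the sample SD (n−1); on the shipped deployment table this
reproduces the printed tracking-duration SD exactly, and also shows that
the printed migratory-duration SD (13.9) is not derivable from the
printed column (it recomputes to 11.6) — the package reports the
recomputed value. The speed filter iteratively removes the later fix of
the first consecutive pair implying >5 m s⁻¹ until stable; it never
removes the first fix. Quartile/ARS classification pools all animals;
ties go to the lower quartile, so degenerate constant series are all-Q1.
The Wilcoxon rank-sum test reports the Mann–Whitney U (the statistic R
prints as W) with exact enumeration over group assignments for small
samples (tie-safe) and a tie-corrected, continuity-corrected normal
approximation otherwise. The 95% minimum convex polygon drops the 5% of
fixes farthest from the centroid in projected km before taking the hull
(standard home-range convention).

## Synthetic data: what it emulates and what it does not

`gen_covariate_fields` builds analytic fields plus Gaussian-smoothed
noise: SST with a 0.5 °C/deg latitudinal gradient, zero-mean SSTA
patches, a depth ramp with a meridional ridge, predominantly negative
curl south of 50°S, CHL linearly coupled to SST (|r| ≥ 0.5 by
construction, so the collinearity screen always has something to catch)
and daily ice fractions that are 1 south of a wiggly boundary in August
and October. `gen_fleet` then simulates each whale by reading covariates
at its current true position, applying the link, advancing with the
exact transition, and observing through a class-sampled error ellipse —
i.e. exactly the generative model the fit assumes, plus the ecological
structure (latitude gradients, an ice zone, group deviations).

Two stock conditions:

* **recovery** — 20 animals × 150 fixes, 1 h mean gap, groups
  interleaved along a −62…−30° start-latitude spread so group effects
  are not confounded with latitude and both groups sample the ice zone.
  True σ-side coefficients echo the magnitudes of the shipped best-model
  table; the β side is scaled (B0 = −1.5, slopes ≤ 0.5 in magnitude) so
  that β stays within the band resolvable at the sampling rate — a decay
  much faster than one inter-fix gap saturates the likelihood and no
  estimator could recover it. Covariates are standardized by the field
  climatology (the generating scale); the pipeline path re-estimates
  pooled moments empirically instead.
* **fleet** — a migration-shaped fleet (30 animals, 22 of which reach
  the Polar Front): very persistent transit dynamics (1/β of weeks) with
  a fast southward launch, fix counts spanning ~120–2000. It produces
  deployment-table-shaped summaries (crossing durations of ~3–6 weeks)
  but does not pretend to match real Southern Ocean oceanography or real
  whales' persistence time scales.

Passing recovery tests therefore demonstrates correctness of the
estimator under the model's own assumptions with informative covariate
contrast; they do not certify behaviour under model misspecification,
heavy-tailed Argos errors, duty-cycled gaps, or covariate fields with
realistic spectra.

## Problem sizes and numerical choices

The validation experiments use 20 replicates for SE coverage and 20
replicate fleets (12 animals × 120 fixes) for AIC selection — sizes at
which a full run of the suite completes in a few minutes on one core
while leaving Monte-Carlo error well inside the asserted bands.
Innovation variances must be strictly positive (a non-PSD innovation
names the offending fix); smoothed covariances are checked symmetric PSD
to −10⁻¹⁰. Zero error ellipses floor at 0.05 km with a warning. AIC ties
sort by model name for determinism. Seeds derive from
`numpy.random.SeedSequence` spawning, so every artifact is reproducible
from (config, master seed) — the pipeline manifest records the config
hash, seed and output checksums.

## Known limitations

* No heavy-tailed observation model; gross outliers must be removed by
  the speed filter upstream.
* Complete pooling or fully independent fits only — no partial-pooling
  random effects.
* The latent-link mode perturbs deterministically per draw; it does not
  integrate over the latent link (at ε = 0.001 the difference is far
  below estimation noise).
* Spatial prediction extrapolates beyond the training covariate range
  (flagged per cell) and inherits all uncertainty of the selected model
  without propagating coefficient SEs into the maps.
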