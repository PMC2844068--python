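# Methods

This note documents the models implemented in `polguide`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Geometry and angle conventions

All analysis happens in the plane of the medium surface (projected
confocal slices), in continuous micrometres with y increasing upward and
counter-clockwise angles positive. For a tube sampled at the imaging
cadence Δt, the current growth direction at time t is the chord
v_cur = r(t) − r(t−Δt) and the new direction v_new = r(t+Δt) − r(t). The
turn θ_tip is the signed angle from v_cur to v_new; the bearing θ_mp is
the signed angle from v_cur to the tip-to-micropyle vector of the nearest
micropyle (positive when the micropyle lies to the left, so a positive
turn steers toward it); Δθ = θ_mp − θ_tip, wrapped to (−π, π]. Nearest
micropyles are chosen by Euclidean distance at each time point, ties
broken by ovule order. Zero-length steps leave the turn undefined; such
samples are dropped with a warning.

## Attractant field

A micropyle is a point source releasing attractant at a constant rate
into a thin fluid film where it diffuses in 2D. In prefactor-stripped
units (the release-rate/diffusivity factor is absorbed into the turning
constant κ′):

    c(r, t) = (1/4π) E₁((r + r₀)²/4Dt),
    g(r, t) = −∂c/∂r = (1/2π) e^{−(r+r₀)²/4Dt} / (r + r₀).

The additive offset r₀ stands for diffusion over the ovule surface before
the attractant reaches the film, and regularises the point-source
divergence at r → 0. At long times g approaches the steady 1/(2π(r+r₀))
law — the gradient is maintained by the competition between release and
diffusion, which is why longer ovule incubation strengthens the response
at every distance. The diffusion age of each ovule at analysis time t is
t plus its incubation offset (30/150/270 min for the 0/2/4-hour
conditions). Fields of multiple ovules superpose linearly; the quantity a
tube senses is the across-tip difference Δc̄ = Σᵢ gᵢ sin θ_mp,i (tip width
absorbed into κ′).

Defaults (fitted values): κ′ = 40.11 rad/(conc·min), D = 66.72 µm²/min,
r₀ = 117.56 µm. A consistency check the suite exercises: the model's
instantaneous turning response κ′·g·Δt at 25 µm from a ~6-hour-old source
is ≈ 0.72 rad per 20-min interval, matching the regression response
observed closest to the micropyle at 4-hour incubation.

## Turning and slowing dynamics

Tip turning is an Euler–Maruyama discretisation of a Langevin equation:

    δθ = κ′ Δc̄ δt + sqrt(2 v δt / L) z,    z ~ N(0,1).

The diffusive term scales as sqrt(δt) so the tangent direction
accumulates variance 2·δs/L per arc length δs grown, making the
persistence length L independent of the integration step (halving dt
moves targeting fractions by less than one binomial SE; tested). With the
rate-coupled noise mode the variance tracks the instantaneous rate v; the
fixed-noise variant evaluates it at the initial rate throughout, to
separate the effect of slowing itself from the smaller random turns that
slowing would otherwise cause.

Growth slowing is modelled as relaxation toward a floor rate:

    dv/dt = −(1/τ) (v − v_min) · k_v|Δc̄| / (1 + k_v|Δc̄|),

integrated exactly over each step (v stays in [v_min, v_init] for any
dt). Over a 20-min sampling interval this reproduces the periodic update
v_new = v_min + (v_old − v_min)/(k_v Δc + 1); the saturating form is what
makes the fitted τ = 19.20 min, slightly below the interval, consistent
with that update (a non-saturating relaxation would force τ ≥ 20 min).
The drive uses |Δc̄|: a signed drive would accelerate tubes with the
gradient on one side, which neither the data nor stability permit.
Defaults: v_init = 2.76, v_min = 0.5 µm/min, k_v = 533.39, τ = 19.20 min,
L = 1042.70 µm.

The simulator advances each tube ballistically over dt = 0.1 min,
evaluates the superposed field at the advanced position and time, applies
the turn and the slowing update, and marks tubes captured within 10 µm of
a micropyle or escaped beyond 800 µm of the style-exit origin; resolved
tubes never move again. Targeting runs have no fixed horizon: they
iterate until every tube resolves (capped at 4000 min), because the
targeting fraction asks whether a tube is able to reach a micropyle, and
tubes that slow to ~0.5 µm/min need well over the 320-min imaging window
to close the final tens of micrometres.

## Estimators

**Radial frequencies.** Distances to the nearest micropyle are binned in
half-open 50-µm bins; each consecutive sample pair counts as closer
(farther) when the distance to that same micropyle at the later time
falls in a lower (higher) bin, same-bin transitions counting toward the
total only. Standard errors are Bernoulli; comparisons across conditions
use the uncorrected χ² test on the 2×k outcome table. Post-penetration
points are included by default (unbiased comparison against heat-treated
controls); a pre-penetration variant restricts to samples whose nearest
ovule is functional, eventually penetrated, and not yet penetrated
(strict t < penetration time). Note one symmetry subtlety: even for
undirected growth f_closer and f_farther need not match per bin (the
innermost bin has no lower bin; and a straight mover's closer/farther
step probabilities differ geometrically). The exact invariant — time
reversal swaps total closer and farther counts — is what the suite tests.

**Turning response.** Ordinary least squares of θ_tip on sin θ_mp within
a distance band, reporting slope A (the mean response, ∝ the local
gradient), intercept ε, their SEs, two-sided Pearson r and p, and the
residual SD (with an optional 2×IQR outlier-trimmed variant for the
innermost band where outliers dominate). Because the regressor and the
response are built from noisy 20-min chords, A is attenuated relative to
the instantaneous κ′·g·Δt; the same attenuation affects any tracked data
analysed this way.

**Circular statistics.** Angles map to unit vectors; the mean direction
is the resultant direction, and σ₀ = sqrt(−2 ln R) with R the mean
resultant length (wrapped-normal correspondence, no small-sample
correction — for the two-angle sample {1°, 359°} this gives exactly
1.000°). R below 1e−12 returns an infinite σ₀ sentinel. Bootstrap SEs use
1000 resamples (means are re-centred on the point estimate before taking
the spread, so wrap-around cannot inflate them); dispersion comparisons
use a one-sided permutation test of log(σ₀[1]/σ₀[2]) with a plus-one
correction. Measurement error on an angle between two tracked segments of
lengths l₁, l₂ with isotropic position noise σ is
sqrt((σ/l₁)² + (σ/l₂)²).

**Growth profile.** Step speed (chord length / Δt) is assigned to the
distance at the step's first point and averaged in ±5 µm windows on a
5-µm grid over 10–200 µm; SE uses the maximum-likelihood SD.

**Persistence length.** Paths are interpolated with a cubic spline in
cumulative chord length, resampled every 5 µm of arc length, and the mean
cosine of the turn over a lag δs is averaged over all point pairs and
tubes. The linear model ⟨cos θ⟩ = (1 + b) − δs/L is the small-δs
expansion of the exponential tangent decorrelation e^{−δs/L}, so the fit
is restricted to the initial regime (lags with ⟨cos θ⟩ ≥ 0.9, at least 4
lags): fitting the full 500-µm curve would overestimate L = 1000 µm by
~28%, while the restricted fit recovers it to ~5% (58 tubes of ~600 µm;
the intercept deviation b is then consistent with 0). Confidence
intervals come from re-estimating after jittering positions with the
tracking noise. Perfectly straight growth returns an infinite-L sentinel.
A related subtlety the suite documents: turns measured between successive
20-min chords carry only (2/3)·2vΔt/L of variance (successive window
means of a Brownian tangent), while the tangent itself carries the full
2vΔt/L.

**Turning-model fit.** χ² = Σ (θ_tip,i − κ′Δc̄ᵢΔt)²/σᵢ², with Δc̄
evaluated at the interval start (a midpoint variant was tried and is
substantially worse) and σᵢ² the sum of the propagated measurement
variance and the motility variance 2vᵢΔt/L. Minimisation uses Powell's
derivative-free method in log-parameter space with multi-start (restarts
log-uniform within a decade of the initial guess); gradient-based least
squares stalls in the local minima created by the E₁ kernel. κ′ is fitted
in place of the raw turning constant because the release-rate prefactor
makes the pair exactly non-identifiable (the objective is flat along
their product; demonstrated in the suite). Identifiability of (κ′, D, r₀)
requires pooling conditions with different source ages: a single
incubation time leaves the three parameters covariant along a valley
(median recovery errors drop from ~30–100% to 12–17% when the 0/2/4-hour
conditions are pooled).

**Confidence intervals.** Two resampling schemes are provided and they
answer different questions. `param_ci` perturbs tip positions with the
4-µm tracking noise and refits (5–95 percentiles) — it measures
sensitivity to measurement error only, and at synthetic-data scale it
undercovers severely because the Langevin process noise dominates.
`parametric_bootstrap_ci` re-simulates whole datasets at the fitted
parameters and refits; basic (pivotal) intervals are the default because
chord sampling and noise-in-regressors give the estimator a reproducible
bias that percentile intervals cannot absorb. Measured coverage of the
basic intervals is 8/9 over three replicate experiments × three
parameters, consistent with the nominal 90%.

**Slowing fit.** The update is linear in k_v after the transformation
(v_old − v_min)/(v_new − v_min) − 1 = k_v Δc, and is fitted through the
origin by iteratively-reweighted least squares with bisquare (Tukey)
weights; rows at or below the floor rate are excluded. τ follows from
matching the discrete update to the continuous relaxation over the
observation interval, averaged over the observed Δc (τ → Δt as Δc → 0).

**Z-drift registration.** Stack profiles are normalised by their maximum;
the mismatch Q between the adjacent-slice differences of two profiles is
the sum of squared differences over their overlap (out-of-overlap slices
excluded, not zero-padded), minimised over integer shifts with ties
preferring no correction. Q is invariant under positive scaling of either
profile, and noiseless integer shifts are recovered exactly.

## Synthetic data: what it emulates, what it does not

The generator reproduces the stated world of the 4-hour assay: ~3
functional ovules per replicate with micropyles at 430 ± 20 µm from the
style exit (uniform on a ±60° arc about the style axis), tubes starting
at the style exit with headings Gaussian-fanned (SD 15°) about the axis,
growth simulated at dt = 0.1 min, sampled every 20 min, with independent
isotropic 4-µm Gaussian noise added to recorded positions only
(measurement noise; the process noise is the Langevin term itself).
Trajectories truncate at capture or escape, as tracking ends at
penetration, and synthetic ovules inherit penetration times from first
captures.

It does not emulate: fluorescence images; staggered tube emergence (all
tubes start at t = 0); tube–tube interactions or post-fertilisation
repulsion; ovule-to-ovule biological variability beyond the incubation
offset; or the actual (unpublished) replicate geometries. A green test on
synthetic data therefore establishes that the estimators recover the
stated model, not that the model is the true data-generating process of
the assay.

That last caveat matters for one headline simulation number: with this
synthetic geometry the toggle experiment reproduces the random-targeting
baseline (T−S− ≈ 8%), the full-model fraction (T+S+ ≈ 93% > 60%), the
T+S+ > T+S− > T−S− ordering, and the negligible effect of fixing the
noise amplitude (< 1 pp), but the turning-only fraction T+S− comes out
near 50%, well above the ~20% reported from experiment-matched layouts.
The synthetic fan aims tubes at the ovule field more tightly than the
experimental arrangements did, and no admissible choice of duration
reconciles both the T+S+ and T+S− absolute values at once.

## Known limitations

* The 2D field ignores diffusion into the agar bulk and any degradation
  of the attractant; both would steepen the distance dependence.
* The regression response and the fitted κ′ are chord-attenuated;
  comparisons between model and data are made through the same 20-min
  sampling pipeline for that reason.
* The σ_θ error model treats the two chord directions as independent,
  but they share the middle tracked point; the χ² normalisation is
  therefore approximate (χ²/n ≈ 0.9–2 depending on the noise regime).
* Capture is purely geometric (10 µm); micropyle entry mechanics and
  funicular (3D) guidance are out of scope.
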