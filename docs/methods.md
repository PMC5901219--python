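# Methods

This note documents the model implemented by `riparia`, the numerical
choices behind it, the synthetic-data conditions used in the test suite,
and the limits of what the tests demonstrate.

## Model and assumptions

A same-aged cohort of a single riparian species is tracked from
germination (n(0) = ε, a small occasional-germination abundance, default
0.05) to extinction (first passage below n_e < ε, default 0.01). The
dynamics are stage-switched: noisy logistic growth during the formative
stage of duration T_f, noisy exponential decay afterwards. The only
environmental driver is the flood water table h(t), entering through the
quadratic divergence penalty (h − η)² around the plot-specific favorable
level η. The driver is a stationary Gaussian process; its correlation time
τ_h distinguishes white-noise forcing (τ_h = 0, flow fluctuating much
faster than the vegetation responds) from Ornstein–Uhlenbeck forcing.
Nonstationary flow is approximated piecewise: a sequence of stationary
segments, each with its own (μ, σ, τ_h), sampled at segment midpoints when
built from a prescribed drift.

Key modelling assumptions, inherited and kept:

- **Stratonovich reading** of the stochastic equation. After the
  logit/log transform the noise is additive, so the Itô/Stratonovich
  distinction disappears in the transformed dynamics and no Milstein-type
  correction is needed in the exact sampler.
- **White-noise treatment of the decline stage** regardless of τ_h:
  mature-population dynamics are orders of magnitude slower than
  water-table fluctuation, so correlation-time corrections are only
  carried in the formative stage.
- **No inter-cohort competition.** Cohorts of different ages at a plot
  evolve independently and community totals are plain sums in "cohort
  units" (they may exceed 1).

## Parameters

| name | units | default | meaning |
| --- | --- | --- | --- |
| λ | yr⁻¹ | 3.24 | maximum formative growth rate at h = η |
| a_f | yr⁻¹ m⁻² | 0.49 | formative sensitivity to divergence |
| A, B, C, D | yr⁻¹m⁻², m⁻², yr⁻¹m⁻², yr⁻¹ | −0.024, 0.513, 7·10⁻⁴, 0.04 | decline sensitivity a_d(t) = A + B/t + C e^{Dt} |
| T_f | yr | 1 | formative-stage duration |
| ε | – | 0.05 | initial (germination) abundance |
| n_e | – | 0.01 | extinction threshold (< ε) |
| t_ip, t_maxage | yr | 49.9, 60 | inflection age and maximum age |
| μ, σ, τ_h | m, m, yr | 82.8, 0.58, 0 | water-table mean, s.d., correlation time |

The λ, a_f, A–D, μ, σ and the three plot levels η = 83.03/83.97/84.67 m
are a published calibration for white birch on a sandy riparian transect.
T_f = 1 yr is inferred from the continuity condition (a_d(1) = 0.4897
matches a_f = 0.49 to rounding); ε, n_e, t_ip and t_maxage are inferred
life-history defaults, labelled as such, and configurable everywhere.

With these coefficients a_d(t) is *negative* between roughly 24 and 80
years: the mean of log n locally rises in that window. This is allowed and
documented; it makes the lifespan drift integral non-monotonic, which is
why the lifespan solver scans for the **first** crossing rather than
trusting a single bracket.

## Analytic machinery

- Formative variance under O-U forcing is V1 + V2 + V3 with
  V2 = (8a_f²Σ²/α²)(αt − 1 + e^{−αt}) and
  V3 = (a_f²σ⁴/α²)(2αt − 1 + e^{−2αt}), α = 1/τ_h. The α⁻² scaling is
  forced by the requirement that V2, V3 → 0 as τ_h → 0 with V1 the
  white-noise variance.
- **Open question, quantified not resolved:** an independent derivation
  for literal O-U forcing gives Var[logit n] = V2 + V3 exactly, with V1
  its fast-noise counterpart rather than an additive term. The package
  implements the V1+V2+V3 formula in `analytic` and provides a
  formula-free oracle (`simulate` mode `ou_pathwise`: sample an O-U path,
  integrate the random ODE by cumulative trapezoid) so the discrepancy can
  be measured. At τ_h = 2 yr, t = 1 yr with the birch plot-1 parameters
  the pathwise ensemble variance matches V2 + V3 (≈ 0.0545) while the
  formula gives 0.0716; both exceed the white-noise value 0.0171, which is
  the qualitative statement all downstream results rely on.
- The continuity constant c2 = E[log n(T_f)] is computed by adaptive
  quadrature of −log(1 + e^{−x}) against the Gaussian law of logit n(T_f)
  on the standard-normal scale (no endpoint singularities; logaddexp for
  stability; absolute tolerance 1e-10). Mean abundance uses the same
  change of variables. ∫a_d has a closed form; ∫a_d² is adaptive
  quadrature at 1e-10 since the cross terms have no elementary
  antiderivative.
- The decline law is left untruncated at n = 1 (it assigns vanishing mass
  above the stage-boundary abundance); the samplers, by contrast, clamp
  paths to n ≤ 1, which is the physical carrying capacity.
- A caveat on correlation-time effects on n itself: the inverse logit is
  convex below 0 and concave above, so extra variance raises E[n] only
  while the mean of logit n is negative (early formative stage, or plots
  with substantial divergence). The variance of n rises with τ_h
  throughout.

## Simulation

`wgn_exact` advances logit n (formative) and log n (decline) by exact
Gaussian increments; the only discretization is freezing a_d within a step
(explicit, step ≤ 0.01 yr; a step-halving check is in the suite). The
diffusion amplitude uses |Σ|: the law depends on Σ² only. Stage switching
is pathwise (log n = log invlogit at T_f), with straddling steps split at
the boundary. Paths are floored at n = 1e-300 in transformed space.
First-passage times are read at the recorded grid resolution — no
Brownian-bridge correction; the bias is controlled by the step and, where
thinning is used for memory, by the recording stride.

`ou_pathwise` exists as the independent oracle for the colored-noise
question: it never touches the V-formulas.

## Lifespan

`mean_lifespan` implements the mean-crossing definition: the time at which
the *mean* of log n reaches log n_e, i.e. the root of
M∫_{T_f}^{T} a_d = c2 − log n_e. This is not the mean first-passage time
of the stochastic paths; `lifespan_mc` estimates that empirically and the
two are reported side by side, never conflated. The root is located by a
dense geometric scan (4096 points up to 10·t_maxage) for the first sign
change, refined by Brent's method; residuals are guaranteed below 1e-9,
and a bounded drift integral returns the `NON_EXTINGUISHING` sentinel
(inf). Because a_d changes sign, the crossing time can jump between the
early-age branch and the senescence branch as M varies — a genuine feature
of the calibrated coefficients, visible as a lifespan cliff between plot 2
(η′ = −1.17, ⟨T_d⟩ ≈ 125 yr) and plot 3 (η′ = −1.87, ⟨T_d⟩ ≈ 4.8 yr).

## Transect patterns

The published account fixes only the qualitative setting: σ decreases
linearly with distance x from the channel, and three "logarithmic
divergence gradients" produce three patterns (monotonic increase; peak
then flat; peak then rapid decline). The functional family and stock
parameters are this package's choice, made by forward reasoning about
which (η′, σ) ranges separate the three regimes under the birch
parameters: η′(x) = η′₀ + k ln(1 + x/x₀) with η′₀ = 2 m, x₀ = 50 m,
k ∈ {−0.55 (slow), −1.1 (moderate), −1.6 (rapid)}, and
σ(x) = max(0.6 − 0.001x, 0.15) m over x ∈ [0, 500] m. The classifier's
thresholds (a drawdown tolerance of 2% of range to call a curve monotonic;
a post-peak drop below 30% of the rise to call it flat) are configurable
defaults, since the source gives only verbal categories.

## Calibration

Two-stage, as in the field procedure: flow parameters first (sample
moments; correlation time by a through-origin log-linear fit of the
empirical autocorrelation, weighted by ρ² so the noisy small-ρ tail does
not bias τ upward; clamped to 0 when the lag-1 autocorrelation is
non-positive), then species parameters from formative-stage OLS slopes of
logit n versus t. The slope system λ − a_f((η′₁ − d_i)² + σ²) = v_i is
solved by bounded nonlinear least squares with multi-start over η′₁ (the
quadratic system is non-convex); comparable-residual alternative optima
are reported. The a_d coefficient system (continuity, inflection, minimum,
maximum sensitivity) reduces, at fixed D, to a linear solve in (A, B, C),
leaving a bracketed 1-D root-find on the inflection residual over D — this
replaces a fragile 4-D Newton iteration and certifies residuals < 1e-8 or
raises an explicit infeasibility error.

## Synthetic-data conditions

The generators default to the study conditions above: the birch parameter
set, μ = 82.8 m, σ = 0.58 m, the three plot levels, 10⁴ Monte-Carlo paths
for moment checks, 10⁵-point hydrology records for estimation round trips,
5% (of the mean slope) Gaussian noise for the recovery study. The noisy
recovery study uses six plots spanning both sides of the mean level with
3.5 m of relief (η = 82.3 … 85.8 m): a one-sided, narrow design leaves the
quadratic coefficient a_f weakly identified, so the spread is part of the
study design, not a tuning knob. The community experiment drives the three
calibrated plots with a 60-segment sinusoidal μ-drift of amplitude 1.5 m
and period 60 yr (τ_h = 0), 50–100 paths per cohort; the abundance-lag
diagnostic linearly detrends totals and suitability before
cross-correlating, because annual recruitment with multi-decade lifespans
superimposes a near-linear accumulation ramp.

What the synthetic tests do **not** show: performance on real hydrology
(regime shifts, skewed or seasonal water tables violate the stationary
Gaussian segments), observation error in abundance surveys (the recovery
study perturbs slopes, not raw counts), seed dispersal or establishment
suitability (recruitment is unconditional, one cohort per plot per year),
and inter-cohort competition.

## Known limitations

- The V1+V2+V3 formula and the pathwise O-U variance disagree (above);
  both are exposed, conclusions rely only on their shared qualitative
  behaviour.
- Community simulation supports white-noise segments only; colored noise
  is available at the single-cohort level.
- The O-U pathwise mode continues its recursion across segment boundaries
  by rescaling the running deviation to the new stationary spread — a
  modelling convenience, not a derived property.
- First-passage detection is grid-resolution; extremely sharp crossings
  need a finer step or stride.
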