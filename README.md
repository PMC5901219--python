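# riparia

Stochastic cohort dynamics of riparian vegetation under river-flow
fluctuation.

`riparia` is for ecohydrologists and quantitative ecologists who want to
simulate, analyse and calibrate the fate of **same-aged plant populations**
(cohorts) on a riparian transect whose growth is driven by a randomly
fluctuating flood water table. It provides the analytic abundance
distributions, Monte-Carlo ensembles, population-lifespan calculations,
cross-transect spatial patterns, least-squares parameter calibration, and
multi-cohort age-structure simulation under nonstationary flow regimes.

## The model

A cohort's normalized abundance n(t) follows stage-switched stochastic
dynamics. During the **formative stage** (age t ≤ T_f: germination and
establishment) growth is logistic; afterwards (**decline stage**) the
population only decays:

    dn/dt = r(h, t) · n(1 − n)        t ≤ T_f
    dn/dt = r(h, t) · n               t > T_f

The growth rate responds to the flood water table h through a quadratic
divergence penalty around the plot's favorable level η:

    r(h, t) = λ − a_f (h − η)²        t ≤ T_f
    r(h, t) = −a_d(t) (h − η)²        t > T_f

with time-varying decline sensitivity a_d(t) = A + B/t + C e^{Dt}
(growth reduces sensitivity as 1/t, senescence raises it exponentially).
The water table is a stationary Gaussian process with mean μ, standard
deviation σ and correlation time τ_h — white Gaussian noise for τ_h = 0, an
Ornstein–Uhlenbeck process otherwise.

Under Stratonovich calculus the transformed abundance is Gaussian: with
η′ = μ − η, M = η′² + σ², Σ = η′σ,

    logit n(t) ~ N( logit(ε) + (λ − a_f M) t,  V1 + V2 + V3 )    t ≤ T_f
    log n(t)   ~ N( c2 − M ∫ a_d dt,  4Σ² ∫ a_d² dt )            t > T_f

where V1 = 4a_f²Σ²t is the white-noise variance and V2, V3 are the extra
terms brought by a finite correlation time. So abundance transitions from a
**logit-normal** to a **log-normal** law. The average lifespan ⟨T_d⟩ solves
the mean-crossing equation M ∫ a_d dt = c2 − log n_e at the extinction
threshold n_e.

## Worked example

The calibrated white-birch parameter set (λ = 3.24 yr⁻¹, a_f = 0.49,
A = −0.024, B = 0.513, C = 7·10⁻⁴, D = 0.04; flow μ = 82.8 m, σ = 0.58 m)
at the lowest plot (η = 83.03 m, so η′ = −0.23 m):

```python
from riparia import FlowRegime, SpeciesParams
from riparia.model import CohortModel
from scipy.special import logit

sp = SpeciesParams.birch()
m = CohortModel(sp, FlowRegime(mu=82.8, sigma=0.58), eta=83.03)

mom = m.moments(1.0)                      # stage boundary t = T_f = 1 yr
print(mom.mean, mom.variance)             # 0.104804  0.0170909
print(m.mean_abundance(1.0))              # 0.526066
print(m.mean_lifespan())                  # 162.085

ens = m.simulate(t_max=1.0, n_paths=10_000, seed=1)
y = logit(ens.n[-1])
print(y.mean(), y.var(ddof=1))            # 0.104531  0.0170283
```

The analytic mean and variance of logit n at the stage boundary
(0.1048, 0.01709) are reproduced by 10⁴ exact Monte-Carlo paths to within
Monte-Carlo error; the expected abundance is 0.526, and the average
lifespan from the mean-crossing equation is ≈ 162 yr (the favorable plot —
lifespan drops to ≈ 4.8 yr at the highest plot, η = 84.67 m).

Calibration runs the other way — from per-plot formative-stage samples to
species parameters:

```python
from riparia import PlotSite, SpeciesCalibration, generate_calibration_fixture

plots = [PlotSite(f"plot{i+1}", x=10*(i+1), altitude=e, eta=e)
         for i, e in enumerate((83.03, 83.97, 84.67))]
samples = generate_calibration_fixture(sp, plots, m.regime,
                                       noise_sd=0.0, n_times=8, seed=1)
res = SpeciesCalibration.from_samples(samples, plots, m.regime).fit()
print(res.lam, res.a_f)                   # 3.24  0.49
```

A command line mirrors these workflows
(`riparia analytic|simulate|lifespan|transect|calibrate|community|estimate-flow|fixtures`,
each driven by one YAML config; see `riparia --help`).

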