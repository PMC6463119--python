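# Methods

## Model

The population of one sex is stratified by single year of age `a` and
calendar year `t` into four compartments: never-smokers `M(t,a)`, current
smokers `S(t,a)`, ex-smokers `E(t,a)` and diagnosed lung-cancer patients
`L(t,a)`. Transitions are governed by five nonnegative rate surfaces (per
person-year):

```
(∂t + ∂a) M = −(μ + σ + λ) M
(∂t + ∂a) S = σ M − ((1+qS) μ + δ + kS λ) S
(∂t + ∂a) E = δ S − ((1+qE) μ + kE λ) E
(∂t + ∂a) L = λ (M + kS S + kE E) − (μ + ν) L
```

with boundary condition `M(t, a0) = B(t)`, `S = E = L = 0` at the youngest
age: everyone is born a never-smoker, ex-smokers never relapse, and patients
leave only through death. `σ` is smoking uptake, `δ` cessation, `λ` the
never-smoker lung-cancer hazard (multiplied by fixed hazard ratios `kS`, `kE`
for current and former smokers), `μ` other-cause mortality (multiplied by
`1+qS`, `1+qE` for smokers/ex-smokers; patients keep baseline `μ`) and `ν`
the excess mortality of diagnosed patients. The fixed hazard ratios default
to published Japanese estimates: `kS=4.94, kE=2.20, qS=0.49, qE=0.20` (men)
and `kS=4.25, kE=2.19, qS=0.51, qE=0.46` (women).

## Discretization along characteristics

With yearly steps aligned to single years of age, the transport operator
reduces to an ordinary derivative along each cohort's characteristic. Rates
are frozen on each (year, age) cell, making the within-cell dynamics a linear
ODE with constant coefficients; the step is its **exact** solution via the
matrix exponential of an augmented 7×7 generator whose extra rows accumulate
the expected incident cases, cancer deaths and other-cause deaths of the
cell. This is unconditionally positive and conserves persons to round-off
(≈1e-14 relative per step), which the tests verify at 1e-10. The matrix
exponential is a batched scaling-and-squaring Taylor evaluation (norm scaled
below 0.25, degree 13 — truncation below double-precision round-off),
validated against `scipy.linalg.expm`.

Everyone reaching the top age `a_max` is pooled in a closed bin that keeps
experiencing the oldest cell's rates; census-style data cap at age 100, and
the bin's slow turnover (~1/μ years) is the slowest mode of the system —
stationarity tests must run several multiples of that time.

## Rate parameterization

Each rate surface is piecewise constant on rectangular (time block) × (age
block) cells; the parameter vector θ holds one **log** rate per block, so
unconstrained optimization keeps rates positive. Ages below a symbol's first
age edge (e.g. uptake before age 20, cancer hazard before 40) are
structurally zero. Expand/collapse between θ and surfaces is a bijection on the block
structure (round trips recover θ to the last unit in place — the exp/log
pair is not bit-exact). Forecast-horizon rates are the most recent fitted
year's age profile carried forward unchanged — the forecast is driven by
demography and accumulated smoking history, not by extrapolated trends.

## Observation model and likelihood

Five tables per sex: incidence, lung-cancer deaths and other-cause deaths on
5-year age strata; population by single age; surveyed current-smoker
prevalence on 10-year strata (numerator/denominator with an effective sample
size, default 1000 per stratum, a config input since survey sizes are rarely
published). Counts are independent Poisson observations of the model
expectations; the survey is binomial with proportion `S/(M+S+E+L)` pooled
over the stratum (patients are a negligible share of survey respondents).
The composite log-likelihood is the sum of exact log-pmfs; a structurally
zero mean facing a positive count yields −inf, not an exception.

The initial state at `t0` is built from the observed population split by the
observed `t0` prevalence, with `E = L = 0` (i.e. `t0` is taken early enough
that accumulated quitting and prevalent disease are negligible); the
boundary inflow is the observed (then projected) population at the youngest
modelled age. These are plug-ins: their sampling noise is conditioned on,
not modelled — see Calibration below.

## Estimation and uncertainty

θ̂ maximizes the composite likelihood with L-BFGS-B (finite-difference
gradients; 3-point by default, 2-point for the larger national fits where
each evaluation costs tens of milliseconds). An identifiability pre-check
requires every estimated block to touch at least one informative stratum
(prevalence informs uptake/cessation anywhere at or below the surveyed ages,
event counts inform their own cells). The covariance is the inverse of a
central-finite-difference Hessian of −log L at θ̂ (relative step 1e-4),
symmetrized and eigenvalue-clipped to positive semidefinite if round-off
leaves it indefinite (flagged). The parametric bootstrap draws θ from
N(θ̂, Σ) **on the log scale**, re-solves the projection per draw (default
1000 draws at full scale; 200 in the desk-scale studies here) and reports
2.5/97.5 percentile bands; peak intervals use each replicate's own maximum.

### Calibration

In a 200-replicate study on the small coverage scenario, the 95% interval
for the never-smoker cancer hazard λ — the quantity of scientific interest,
whose information comes almost entirely from its own Poisson incidence
channel — is well calibrated. The interval for other-cause mortality μ
undercovers (≈88%): μ is informed largely by the population series, whose
sampling noise also enters through the plugged-in initial state and inflow,
so the inverse Hessian understates its variance by ~25% (verified:
empirical sd / reported se ≈ 1.28, no bias). This is a known property of
conditioning on plug-in denominators, affects the demographic nuisance rates
rather than the cancer parameters, and is documented rather than patched;
a full fix would model the initial population as latent.

## Synthetic data generator

The generator emulates the structure of the national inputs from parametric
families: Gaussian-bump-in-age uptake peaking in early adulthood with
exponential calendar decline; cessation rising linearly in age and time;
Gompertz other-cause mortality; a cancer hazard rising exponentially beyond
age 40; constant excess case fatality. The initial pyramid combines a
birth-size history (exponential growth up to a boom cohort, a ~28% lower
plateau after it), Gompertz survival and a boom bulge; the inflow declines
exponentially with a transient echo. Smooth families are snapped to the
scenario's block structure by block means, so the generating θ* is exactly
representable by the fitted model and "recovery" is well defined. Counts are
Poisson draws around the deterministic expectations and survey numerators
binomial, from a single seeded generator; a noise-off mode returns the exact
expectations for oracle tests.

The national-scale default scenario (ages 0–100, fit years 1970–2010,
horizon 2050, ~5e7 population per sex) reproduces the qualitative situation
the model was designed for: male survey-age smoking prevalence ≈0.79
declining to ≈0.30, female prevalence low throughout, absolute cases peaking
inside the 2020s–2030s while per-100,000 rates keep rising with population
ageing. What it does **not** emulate: cohort smoking dose, secondhand
exposure, registry under-ascertainment, survey design effects, migration.
Passing tests therefore demonstrate the pipeline's internal correctness and
statistical calibration under the stated observation models, not fidelity of
any specific national forecast.

## Problem sizes and numerical choices

Desk-scale sizes keep the full suite in the minutes range and are the
package's own defaults: the national scenario estimates 26 parameters (two
20-year time blocks; one age block for uptake over ages 20–40 — where the
process actually occurs; blocks with negligible generating rates would be
unidentifiable — three 20-year-ish blocks for cessation and the cancer
hazard, five for μ, one for ν); the coverage scenario estimates 5 parameters
on a 10-age, 11-year grid with 2e5 persons and 200 replicate datasets × 200
bootstrap draws; the microsimulation oracle uses 1e6 agents on a 5-age,
10-year grid. Optimizer: `ftol=1e-15`, `gtol=1e-9` by default (termination
in a failed line search with a tiny relative gradient is reported as
converged); `ftol=1e-11` with 2-point gradients for the national fits.
Ties in peak detection break to the earliest year; an all-equal series is
flagged `flat`, a maximum at either end of the horizon `boundary`.

## Known limitations

- The μ interval undercoverage above.
- Entry-age attribution: events of the cell entered at (t, a) are reported
  at age a, a half-year-of-age offset relative to age-at-event tabulations.
- Carry-forward rates make no attempt to extrapolate secular trends.
- The closed top bin applies the oldest cell's rates to everyone above
  `a_max`.
- No overdispersion: registry counts are taken as exactly Poisson.
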