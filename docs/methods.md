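# Methods

`aedesfuse` fuses a statistical reconstruction of *Aedes aegypti*
adult-female abundance with a mechanistic, temperature-driven population
model, and uses the fused model to simulate insecticide spraying campaigns
in a spatially explicit stochastic setting.  This note records the model,
its assumptions, the numerical choices, and what the synthetic test bed
does and does not establish.

## The stage-structured model

Four stages are tracked at each location: eggs `E`, larvae `L`, pupae `P`
and adult females `N`:

    dE/dt = n_E a(T) N / 2            - (d_E + mu_E) E
    dL/dt = d_E E                     - (d_L + mu_L + mu_c(t) + L^2/kappa) L
    dP/dt = d_L L                     - (d_P + mu_P + mu_c(t)) P
    dN/dt = d_P P                     - mu_N N

All vital rates are daily and temperature-driven (next section).  Egg
laying is `n_E a N / 2`: `a(T)` is the gonotrophic-cycle rate, `n_E = 63`
eggs per cycle, and the factor 1/2 keeps only female eggs in a female-only
model.  Density-dependent larval mortality is quadratic in density — the
per-capita rate is `L^2/kappa` — reflecting competition for finite larval
habitat; the exponent makes post-perturbation rebound fast, consistent
with field observations of rapid recovery after adulticiding.  The
residual mortality `mu_c(t)` acts on larvae and pupae only; it is the
fusion parameter, calibrated so the model reproduces the statistical
abundance series, and absorbs every process the temperature-driven rates
miss (container turnover, rainfall, survey-scale anomalies).

The carrying capacity is fixed by a dominance rule: at the time-average
larval density, density-dependent mortality is ten times the
density-independent larval mortality,

    10 * mean(mu_L) = mean(L)^2 / kappa .

Some sources print this rule with `mean(L)/kappa` on the right; that form
is dimensionally inconsistent with the `L^2/kappa` per-capita term and
with the quadratic scaling of `kappa` across locations, so the squared
reading is the default (`derive_kappa(..., squared=False)` selects the
linear variant for sensitivity work).  `kappa` is location-specific and
time-invariant: the whole calibration runs once on the normalized system
(`N(0) = 1`) and each location `x` uses `kappa(x) = kappa_norm * N(x,0)^2`,
which leaves the per-capita dynamics exactly invariant.

## Temperature-driven rates

Development and gonotrophic-cycle rates follow the Sharpe–DeMichele
enthalpy model,

    r(T) = rho25 (T/298) exp[(dHa/R)(1/298 - 1/T)]
           / (1 + exp[(dHh/R)(1/T_half - 1/T)]),

with `T` in kelvin and the constants of the established *Ae. aegypti*
model lineage (shipped in `data/thermal_default.yaml`, not hard-coded).
Stage mortalities are a baseline plus a linear hinge above a
high-temperature threshold (default 40 °C) — and symmetrically below a
cold threshold, shipped inert because tropical minima never reach it.
Immature rates are driven by water temperature, obtained from linear
regressions on the daily air triple and the container sun-exposure
fraction (default 10%); the mean water temperature is the midpoint of the
regression-predicted minimum and maximum.  Argument mapping: development
uses mean water temperature, immature mortalities the water maximum, adult
mortality the air maximum, and the gonotrophic rate the air mean.  At a
typical 26 °C day the defaults give roughly `a = 0.24`, `d_E = 0.26`,
`d_L = 0.21`, `d_P = 0.42`, `mu_N = 0.091` per day.

## Inverse calibration

Given a strictly positive city-wide abundance series `N(t)` and daily
temperatures, `AbundanceFusionModel.fit()` runs four steps on the
normalized series:

1. **Pupae** from the adult equation, `P = (dN/dt + mu_N N)/d_P`, with
   derivatives from centered differences (one-sided at the ends).
2. **Eggs** by integrating the egg equation forced by the target `N(t)`,
   from a quasi-equilibrium start.
3. **Larvae** by integrating the first-order ODE obtained by eliminating
   `mu_c` between the larval and pupal equations.
4. **`mu_c`** from the rearranged larval equation,
   `mu_c = (d_E E - dL/dt)/L - (d_L + mu_L + L^2/kappa)`, clamped at zero.
   (A printed form of this rearrangement circulates with a `+` before the
   bracket; the algebra, and round-trip recovery of a known forcing,
   require the minus.)

All reconstructed quantities are kept non-negative: `P` and `L` are
floored at `eps = 1e-6` (normalized units) to protect divisions and
`mu_c` is clamped at zero; every floored day carries a flag, and flagged
days plus a 30-day burn-in window are excluded from the self-consistency
score `rmsd_self` (relative RMSD between the forward-integrated and target
adult series).

Two couplings in the procedure have no closed form and are resolved
numerically:

* `kappa` appears in the larval ODE but is derived from the mean of the
  reconstructed `L`; a fixed-point iteration (fast fixed-step sweeps,
  relative tolerance 1e-10, final pass at the full solver tolerances)
  closes the loop, so the dominance ratio is exactly 10 on the reported
  series.
* `L(0)` is not identified by the data.  An arbitrary start puts a fast
  transient on the reconstructed larval path; the finite-difference
  derivative then misreads that transient, `mu_c(0)` inherits the error as
  a spurious mortality impulse, and — because the calibrated system is
  nearly scale-invariant (the weak density dependence is its only
  restoring force) — the forward validation keeps the resulting offset for
  months.  The start value is therefore chosen so the day-0 residual
  mortality read from the larval-equation rearrangement equals the one
  implied by the pupal balance (a bracketed scalar root-solve; each
  evaluation integrates the larval ODE over one day).

Integration uses the implicit Radau method (SciPy) at absolute and
relative tolerances of 1e-6.  Temperatures, derived rates and `mu_c` are
step functions constant over each day, and integration restarts at each
day boundary so discontinuities never straddle a solver step.  With daily
data this discretization leaves a seasonal bias of order 1–2% in the
recovered `mu_c` (the centered difference at a day boundary estimates the
average of the adjacent one-sided derivatives, while each rate step acts
over a day interval); the round-trip and self-consistency checks bound
the end-to-end effect below 2% relative RMSD.

Whether `mu_c` should also act on eggs is ambiguous in parts of the
literature; here it acts on larvae and pupae only, matching the equations
above.

## Agent-based simulation

Each building holds a deterministic immature subsystem and an integer
population of adult females; only the adult stage is stochastic.

* **Immatures** integrate the `E, L, P` equations per building
  (vectorized fixed-step RK4, 10 substeps/day — validated against the
  Radau path; the per-capita rates never exceed a few per day, well inside
  the stability region).  Egg input uses the building's own start-of-day
  integer adult count, coupling adult kills back into future emergence —
  without this coupling a spraying campaign would have no lasting effect.
  Buildings with `kappa = 0` host no immatures.
* **Emergence** is Poisson with rate `d_P * ∫P dt` over the day (the
  trapezoid integral accumulated during the RK4 advance), which matches
  the continuous model's adult inflow exactly in expectation.  The draw
  does not decrement the deterministic pupal stock: immatures remain
  purely deterministic by design, which breaks individual-level mass
  balance but keeps the two layers consistent in expectation.
* **Death**: each adult dies with probability `1 - exp(-(mu_N + spray))`.
  Same-day emergents arrive mid-day on average and face the half-day
  hazard `1 - exp(-(mu_N + spray)/2)`; giving them the full-day hazard
  instead imposes a ~4.5% per-generation fecundity deficit that the
  near-neutral calibrated dynamics never forgive, depressing the city
  total by tens of percent.
* **Movement**: survivors relocate with daily probability 0.3 to a
  building chosen uniformly among those strictly within 100 m (centroid
  Euclidean distance); an adult with no neighbors stays.  Movement
  conserves adults exactly.
* **Order within a day**: immatures, emergence, death, movement, ageing.
  The census is taken each evening, so emergents first appear at age 1.

Adults are stored as a (building × age) count matrix; all stochastic
draws are vectorized binomial/Poisson calls from a single seeded
generator with fixed draw order, so runs are bit-reproducible and an
entire 2,000-building, three-year run takes tens of seconds.

### Finite-city artifacts and the spin-up

The uniform-neighbor walk has a degree-proportional stationary law:
adults accumulate in well-connected buildings and drain from the edge of
the map, while `kappa` stays matched to the target field.  In a city much
larger than the movement radius the mismatch is negligible, but in a
desk-scale city it erodes the total by ~10% over the first months as the
quadratic mortality culls the pile-up.  `run_abm(..., spin_up_days=365)`
replays one year of forcing (returning to the same seasonal phase) before
the recorded window, so the recorded run starts from the process's own
stationary state.  The stationary level sits a few percent below the
deterministic trajectory — a finite-size effect, not a bug — and the
city-wide correlation between the agent-based and deterministic series is
then ≥ 0.997 at the default scale.

## Interventions

Campaigns visit buildings in ascending (zone, id) order, a fixed number of
visits per day, each visit treating the building with probability 0.7.
ULV adds 1.5 deaths/day on the treatment day only; TIRS adds 9 deaths/day
for 90 days, then decays as `2^(-t/halflife)`.  The decay half-life is not
established; the default is 10 days and config-exposed.  Repeat treatments
reset the residual clock without stacking.  Increments act on adult
mortality only, added to `mu_N` before the probability conversion.  A
full-scale three-round campaign over 92,891 buildings at 11,000 visits/day
spans 27 days; the one-round TIRS arithmetic gives 47 days at 2,000
buildings/day, while the historical campaign length is ~39 days, so the
shipped TIRS spec pins `duration_override_days = 39` (the discrepancy is
not resolvable from the available descriptions).  `apply_campaign` runs
the sprayed scenario and a no-spray counterfactual from the same base
seed and feeds the rebound metrics (trough depth and timing against the
same-day baseline; days to a 7-day-sustained return within 10% and 1% of
baseline; months reported as days/30.44).

The hypothetical-insecticide factorial (increment ∈ {1.5, 9} ×
residuality ∈ {none, 90 days}) and the equal-baseline scenario (every
building set to the maximum weight) are plain configurations of
`CampaignSpec` and `SynthSpec`.

## Synthetic study area

The generator emulates the three inputs of the real analysis.  Buildings
are placed uniformly over a 1,000 m square (2,000 buildings ≈ 2,000/km²,
chosen to approach real urban density so movement neighborhoods are
well-populated); zones come from a regular 7×5 grid with a retry-shift
guarantee that every zone is nonempty.  Temperatures are a 26 °C annual
mean with a 1.5 °C seasonal sinusoid, ±(4, 5) °C diurnal offsets and AR(1)
noise (sd 0.5 °C, lag-1 correlation 0.8).  The abundance target is exactly
separable, `N(x, t) = w(x) S(t)`: the log-weights are a Gaussian random
field (sd 0.5, squared-exponential correlation over 400 m — statistical
abundance surfaces are smooth, so neighbors get similar baselines) boosted
near two hotspot centres (width 400 m, factor 3), and `S(t)` is a strictly
positive seasonal signal (relative amplitude 0.4) scaled so the city
holds ~1e5 adults.  Everything is deterministic given the seed.

What the synthetic bed does **not** emulate: day-to-day noise in the
statistical series (the real reconstruction is jagged; a noise knob
exists but the default target is smooth, and the finite-difference
inversion degrades gracefully but measurably on kinked inputs), rainfall
covariates, non-separable space–time interaction, and the real city's
geometry.  Passing tests therefore establish the internal consistency of
the machinery at realistic scales — not that the shipped thermal constants
match any particular field site.

## Numerical summary

| Quantity | Value |
|---|---|
| Solver | Radau, rtol = atol = 1e-6, day-restarted |
| Non-negativity floor (P, L) | 1e-6 normalized units, flagged |
| Burn-in window | 30 days |
| kappa fixed-point tolerance | 1e-10 relative |
| ABM immature integrator | RK4, 10 substeps/day |
| ABM age cap | 200 days (absorbing) |
| Movement | p = 0.3/day, radius 100 m, uniform over neighbors |
| Rebound sustain window | 7 days |

Problem sizes used by the shipped checks: calibrations on 365–1,095-day
series; agent-based runs of 2,000 buildings × 3 years (plus a 1-year
spin-up) with ~1e5 adults; movement and coverage estimators at ≥1e5
adult-days and 1e4 visits.
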