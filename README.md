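# aedesfuse

Fusing statistical reconstructions of *Aedes aegypti* abundance with
mechanistic population dynamics — and using the fused model to simulate
city-wide insecticide spraying campaigns.

## The problem

Statistical models (e.g. a GAM fitted to household mosquito surveys)
reconstruct *where and when* adult mosquitoes were abundant with great
fidelity, but cannot say what would have happened under an intervention
they never observed.  Mechanistic stage-structured models can simulate
interventions, but rarely reproduce observed abundance patterns.
`aedesfuse` joins the two: a temperature-driven model of egg, larval,
pupal and adult-female dynamics,

    dE/dt = n_E a(T) N/2 − (d_E + mu_E) E
    dL/dt = d_E E − (d_L + mu_L + mu_c(t) + L²/κ) L
    dP/dt = d_L L − (d_P + mu_P + mu_c(t)) P
    dN/dt = d_P P − mu_N N

is calibrated to a target abundance series by solving *inversely* for a
single time-varying residual mortality `mu_c(t)` (acting on larvae and
pupae) such that the model reproduces the target.  The carrying capacity
`κ` is set so density-dependent larval mortality is ten times the
density-independent rate at average density, is location-specific
(`κ(x) ∝ N(x,0)²`) and time-invariant, and controls how the population
rebounds after perturbation.  The calibrated forcing then drives a
spatially explicit stochastic agent-based model (deterministic immatures
per building; Poisson emergence; individual adult death and movement
within 100 m) in which ULV and TIRS spraying campaigns are simulated
building by building.

It is aimed at vector-control modellers who have an abundance time
series — real or synthetic — and want intervention counterfactuals with
spatial and age structure.

## Worked example

```python
import numpy as np
from aedesfuse import SynthSpec, generate_all, AbundanceFusionModel

spec = SynthSpec(n_buildings=500, n_zones=10, n_days=730, seed=42)
city, temps, target = generate_all(spec)          # synthetic city + target

model = AbundanceFusionModel(target.series, temps)
results = model.fit()                             # inverse calibration
print(results.summary())

out = results.simulate_abm(city, n0=target.n0, seed=1, spin_up_days=365)
ode_n = results.N_model * target.series[0]
print(f"ABM vs ODE Pearson r: {np.corrcoef(out.n_total, ode_n)[0, 1]:.4f}")
```

prints

```
Abundance fusion calibration
============================================
days                        730
kappa (normalized)          62.7129
kappa fixed-point sweeps    8
mean mu_c (1/day)           2.555
max mu_c (1/day)            3.349
clamped days                0
burn-in days                30
self RMSD (relative)        0.01719
density-dep. death share    0.9224

ABM vs ODE Pearson r: 0.9957
```

Reading it: the residual mortality averages ~2.6 deaths/day and never
needed clamping (it stayed a genuine mortality rate everywhere);
re-integrating the model forward with the calibrated `mu_c` reproduces
the target to 1.7% relative RMSD; density dependence accounts for 92% of
temperature-plus-density larval deaths, as the carrying-capacity rule
intends; and a single stochastic replicate of the 500-building simulation
tracks the deterministic trajectory at r ≈ 0.996.

Spraying experiments hang off the same objects:

```python
from aedesfuse import CampaignSpec, apply_campaign, rebound_metrics

baseline, sprayed, campaign = apply_campaign(
    city, results, target.n0, CampaignSpec.ulv(start_day=365), seed=1)
print(rebound_metrics(sprayed.n_total, baseline.n_total, campaign_start=365))
```

A `ScheduledCampaign` visits buildings in ascending zone order (ULV:
3 rounds, 11,000 visits/day, 0.7 treatment probability, +1.5 deaths/day
on the day of spraying; TIRS: 1 round, 2,000/day, +9 deaths/day for
90 days then exponential decay).  Zone heatmaps (`zone_matrix`) and
age-distribution statistics (`age_stats`, including the bimodality
coefficient `(skew² + 1)/kurtosis`) summarize the spatial and demographic
consequences.

There is also a CLI: `aedesfuse synth | calibrate | simulate-ode |
simulate-abm | spray | summarize` (see `aedesfuse --help`).

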