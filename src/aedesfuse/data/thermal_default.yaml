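# Default thermal parameterization for Aedes aegypti vital rates.
#
# Development and gonotrophic-cycle rates follow the Sharpe-DeMichele enthalpy
# model with the classical constants used in established Ae. aegypti
# simulation models (rho25 in 1/day at the 298 K reference; enthalpies in
# cal/mol; t_half in K).
# Setting enthalpy_inactivation to 0 disables the high-temperature inhibition
# denominator entirely.
#
# Mortality rates are a temperature-independent baseline plus a linear hinge
# above a high-temperature threshold (and, symmetrically, below a cold
# threshold; the cold branch ships inert with cold_coeff = 0 because tropical
# minima never reach it).
#
# Water temperatures are linear regressions on the daily air-temperature
# triple and on the container sun-exposure fraction.

eggs_per_cycle: 63.0
sun_exposure: 0.10

water_temperature:
  tw_mean: {intercept: 10.025, t_mean: 0.0, t_min: 0.54, t_max: 0.0, t_max_sq: 0.0055, sun: -0.68, sun_sq: 3.845}
  tw_min:  {intercept: 5.02,  t_mean: 0.0, t_min: 0.81, t_max: 0.0, t_max_sq: 0.001,  sun: -1.36, sun_sq: 0.0}
  tw_max:  {intercept: 15.03, t_mean: 0.0, t_min: 0.27, t_max: 0.0, t_max_sq: 0.01,   sun: 0.0,   sun_sq: 7.69}

development:
  d_E: {rho25: 0.24,   enthalpy_activation: 10798.0, enthalpy_inactivation: 100000.0,  t_half_inactivation: 14184.0}
  d_L: {rho25: 0.2088, enthalpy_activation: 26018.0, enthalpy_inactivation: 55990.0,   t_half_inactivation: 304.6}
  d_P: {rho25: 0.384,  enthalpy_activation: 14931.0, enthalpy_inactivation: -472379.0, t_half_inactivation: 148.0}
  a:   {rho25: 0.216,  enthalpy_activation: 15725.0, enthalpy_inactivation: 1756481.0, t_half_inactivation: 447.2}

mortality:
  mu_E: {baseline: 0.011, heat_threshold: 40.0, heat_coeff: 0.05, cold_threshold: 10.0, cold_coeff: 0.0}
  mu_L: {baseline: 0.01,  heat_threshold: 40.0, heat_coeff: 0.05, cold_threshold: 10.0, cold_coeff: 0.0}
  mu_P: {baseline: 0.01,  heat_threshold: 40.0, heat_coeff: 0.05, cold_threshold: 10.0, cold_coeff: 0.0}
  mu_N: {baseline: 0.091, heat_threshold: 40.0, heat_coeff: 0.04, cold_threshold: 10.0, cold_coeff: 0.0}
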