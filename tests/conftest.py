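import numpy as np
import pytest
from hypothesis import settings

from aedesfuse import AbundanceFusionModel, SynthSpec, generate_all
from aedesfuse.thermal import build_rate_series

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_setup():
    """A small synthetic study area: 150 buildings, 1 year."""
    spec = SynthSpec(n_buildings=150, n_zones=6, n_days=365, seed=7)
    city, temps, target = generate_all(spec)
    return spec, city, temps, target


@pytest.fixture(scope="session")
def small_fit(small_setup):
    """Calibration results on the small study area (shared; treat as
    read-only)."""
    _, _, temps, target = small_setup
    return AbundanceFusionModel(target.series, temps).fit()


@pytest.fixture(scope="session")
def constant_conditions():
    """Constant temperatures and a constant target: the system sits at a
    fixed point, handy for stationarity checks."""
    spec = SynthSpec(
        n_buildings=40,
        n_zones=4,
        n_days=400,
        seed=5,
        t_seasonal_amplitude=0.0,
        t_noise_sd=0.0,
        abundance_seasonal_amplitude=0.0,
    )
    city, temps, target = generate_all(spec)
    rates = build_rate_series(temps)
    fit = AbundanceFusionModel(target.series, temps).fit()
    return spec, city, temps, target, rates, fit
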