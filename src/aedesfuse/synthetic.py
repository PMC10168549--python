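"""Synthetic city generator.

Emulates the three inputs the fusion pipeline needs — a building map with
administrative zones, a seasonal daily temperature series, and a separable
space-by-time target abundance surface standing in for the output of a
statistical abundance model:

* buildings are placed uniformly over a square extent and assigned to zones
  by a regular spatial grid (so zones are contiguous);
* temperatures are a ~26 C annual mean with a seasonal sinusoid, fixed
  diurnal offsets and AR(1) noise;
* the abundance target is rank-1 separable, ``N(x, t) = w(x) S(t)``, with
  lognormal spatial weights boosted near two hotspot centres and a strictly
  positive seasonal city-wide signal.  The default scale (~2,000 buildings
  at ~50 adults each) keeps a city-wide population of ~1e5 adults.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import City
from .thermal import TemperatureSeries, ThermalConfig

__all__ = ["SynthSpec", "SyntheticTarget", "generate_city", "generate_temperature", "generate_target_abundance", "generate_all"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study area."""

    n_buildings: int = 2000
    extent: float = 1000.0  # metres, square side (urban-fabric density)
    n_zones: int = 35
    n_days: int = 1095
    seed: int = 0

    # temperature
    t_annual_mean: float = 26.0  # deg C
    t_seasonal_amplitude: float = 1.5
    t_diurnal_up: float = 5.0  # t_max - t_mean
    t_diurnal_down: float = 4.0  # t_mean - t_min
    t_noise_sd: float = 0.5
    t_noise_ar: float = 0.8

    # abundance
    mean_adults_per_building: float = 50.0
    abundance_seasonal_amplitude: float = 0.4
    abundance_seasonal_phase: float = 0.0  # days
    target_noise_sd: float = 0.0  # lognormal sd of day-to-day target noise
    hotspot_centers: tuple = ((0.25, 0.25), (0.75, 0.75))  # relative coords
    hotspot_width: float = 400.0  # metres
    hotspot_boost: float = 3.0
    weight_sd: float = 0.5  # lognormal sigma of spatial weights
    weight_corr_length: float = 400.0  # metres; 0 = independent weights
    equal_baseline: bool = False  # S7-style scenario

    def __post_init__(self):
        if self.n_buildings <= 0 or self.n_days <= 0 or self.n_zones <= 0:
            raise ValueError("counts must be positive")
        if self.n_zones > self.n_buildings:
            raise ValueError("n_zones must not exceed n_buildings")
        if not 0.0 <= self.abundance_seasonal_amplitude < 1.0:
            raise ValueError("abundance_seasonal_amplitude must lie in [0, 1)")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "SynthSpec":
        with open(path) as fh:
            raw = json.load(fh)
        if "hotspot_centers" in raw:
            raw["hotspot_centers"] = tuple(tuple(c) for c in raw["hotspot_centers"])
        return cls(**raw)


def _zone_grid_shape(n_zones: int) -> tuple[int, int]:
    """Near-square factorization of the zone count (7 x 5 for the default
    35)."""
    best = (1, n_zones)
    for nx in range(1, int(math.isqrt(n_zones)) + 1):
        if n_zones % nx == 0:
            best = (n_zones // nx, nx)
    return best


def generate_city(spec: SynthSpec) -> City:
    """Uniform-random building placement with contiguous grid zones.

    If a zone cell happens to catch no buildings the grid origin is shifted
    and zone assignment retried, so every zone is guaranteed nonempty.
    """
    rng = np.random.default_rng([spec.seed, 1])
    xy = rng.uniform(0.0, spec.extent, size=(spec.n_buildings, 2))
    nx, ny = _zone_grid_shape(spec.n_zones)
    for attempt in range(200):
        shift = attempt * spec.extent / (200.0 * max(nx, ny))
        ix = np.clip(((xy[:, 0] + shift) / spec.extent * nx).astype(int), 0, nx - 1)
        iy = np.clip(((xy[:, 1] + shift) / spec.extent * ny).astype(int), 0, ny - 1)
        zone = ix * ny + iy
        if len(np.unique(zone)) == spec.n_zones:
            break
    else:
        raise RuntimeError("could not assign buildings so that every zone is nonempty")
    frame = pd.DataFrame(
        {"id": np.arange(spec.n_buildings), "x": xy[:, 0], "y": xy[:, 1], "zone": zone}
    )
    return City(frame)


def generate_temperature(spec: SynthSpec, cfg: ThermalConfig | None = None) -> TemperatureSeries:
    """Seasonal sinusoid around the annual mean plus AR(1) noise; fixed
    positive diurnal offsets keep min <= mean <= max every day."""
    rng = np.random.default_rng([spec.seed, 2])
    t = np.arange(spec.n_days)
    seasonal = spec.t_annual_mean + spec.t_seasonal_amplitude * np.sin(
        2.0 * np.pi * t / 365.25
    )
    noise = np.zeros(spec.n_days)
    if spec.t_noise_sd > 0:
        innov_sd = spec.t_noise_sd * math.sqrt(1.0 - spec.t_noise_ar**2)
        eps = rng.normal(0.0, innov_sd, size=spec.n_days)
        for i in range(1, spec.n_days):
            noise[i] = spec.t_noise_ar * noise[i - 1] + eps[i]
    t_mean = seasonal + noise
    frame = pd.DataFrame(
        {
            "date": pd.date_range("2000-01-01", periods=spec.n_days, freq="D"),
            "t_mean": t_mean,
            "t_min": t_mean - spec.t_diurnal_down,
            "t_max": t_mean + spec.t_diurnal_up,
        }
    )
    return TemperatureSeries(frame, cfg=cfg)


@dataclass
class SyntheticTarget:
    """Separable target abundance: per-building weights ``w`` and a
    city-wide daily series; ``N(x, t) = w(x) series(t) / sum(w)`` so that
    summing over buildings recovers ``series``."""

    weights: np.ndarray  # per-building, mean ~ 1
    series: np.ndarray  # city-wide daily adult abundance

    @property
    def n0(self) -> np.ndarray:
        """Per-building initial adult abundance."""
        return self.weights / self.weights.sum() * self.series[0]

    def matrix(self) -> np.ndarray:
        """Full building x day abundance matrix (rank 1 by construction)."""
        share = self.weights / self.weights.sum()
        return np.outer(share, self.series)

    def save(self, abundance_csv: str | Path, weights_csv: str | Path | None = None) -> None:
        pd.DataFrame({"day": np.arange(len(self.series)), "N_city": self.series}).to_csv(
            abundance_csv, index=False
        )
        if weights_csv is not None:
            pd.DataFrame({"id": np.arange(len(self.weights)), "weight": self.weights}).to_csv(
                weights_csv, index=False
            )


def generate_target_abundance(city: City, spec: SynthSpec) -> SyntheticTarget:
    """Lognormal spatial weights with Gaussian hotspot boosts, times a
    strictly positive seasonal city-wide signal.

    The log-weight field is spatially correlated (squared-exponential
    covariance realized with random Fourier features) over
    ``weight_corr_length`` metres: statistical abundance surfaces are smooth
    in space, so neighbouring buildings get similar baselines rather than
    independent draws.
    """
    rng = np.random.default_rng([spec.seed, 3])
    sigma = spec.weight_sd
    if sigma > 0 and spec.weight_corr_length > 0:
        k_modes = 128
        freqs = rng.normal(0.0, 1.0 / spec.weight_corr_length, size=(k_modes, 2))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=k_modes)
        g = np.sqrt(2.0 / k_modes) * np.cos(city.xy @ freqs.T + phases).sum(axis=1)
        w = np.exp(sigma * g - 0.5 * sigma * sigma)
    else:
        w = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(city))
    xy = city.xy
    for cx, cy in spec.hotspot_centers:
        center = np.array([cx, cy]) * spec.extent
        d2 = np.sum((xy - center) ** 2, axis=1)
        w = w * (1.0 + spec.hotspot_boost * np.exp(-d2 / (2.0 * spec.hotspot_width**2)))
    if spec.equal_baseline:
        w = np.full(len(city), w.max())
    w = w / w.mean()

    t = np.arange(spec.n_days)
    s = 1.0 + spec.abundance_seasonal_amplitude * np.sin(
        2.0 * np.pi * (t + spec.abundance_seasonal_phase) / 365.25
    )
    if spec.target_noise_sd > 0:
        s = s * rng.lognormal(
            mean=-0.5 * spec.target_noise_sd**2, sigma=spec.target_noise_sd, size=spec.n_days
        )
    series = w.sum() * spec.mean_adults_per_building * s
    return SyntheticTarget(weights=w, series=series)


def generate_all(spec: SynthSpec, cfg: ThermalConfig | None = None):
    """Convenience: ``(city, temps, target)`` for one spec."""
    city = generate_city(spec)
    temps = generate_temperature(spec, cfg=cfg)
    target = generate_target_abundance(city, spec)
    return city, temps, target
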