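"""Temperature-dependent vital rates for *Aedes aegypti*.

All life-history rates in the population model are driven by daily air
temperature triples (mean, min, max).  Immature development and mortality are
governed by *water* temperature in breeding containers, obtained from linear
regressions on the air triple and on the fraction of direct sun exposure the
containers receive.  Development and gonotrophic-cycle rates use the
Sharpe-DeMichele enthalpy model; stage mortalities are a baseline plus a hinge
response above a high-temperature threshold (a symmetric cold branch exists
but is inert under the shipped defaults, since tropical daily minima never
reach it).

The numerical constants are data, not code: they live in
``data/thermal_default.yaml`` and can be replaced wholesale for other
parameterizations or climates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WaterRegression",
    "DevelopmentParams",
    "MortalityParams",
    "ThermalConfig",
    "TemperatureSeries",
    "RateSeries",
    "water_temperature",
    "development_rate",
    "mortality_rate",
    "build_rate_series",
]

#: Universal gas constant in cal / (mol K), the unit system of the enthalpy
#: constants.
GAS_CONSTANT_CAL = 1.987

#: Reference temperature (K) at which ``rho25`` is specified.
T_REF_K = 298.0

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class WaterRegression:
    """Linear map from an air-temperature triple (and sun exposure) to one
    water-temperature summary (deg C)."""

    intercept: float = 0.0
    t_mean: float = 0.0
    t_min: float = 0.0
    t_max: float = 0.0
    t_max_sq: float = 0.0
    sun: float = 0.0
    sun_sq: float = 0.0

    def __call__(self, t_mean, t_min, t_max, sun_exposure):
        return (
            self.intercept
            + self.t_mean * t_mean
            + self.t_min * t_min
            + self.t_max * t_max
            + self.t_max_sq * np.square(t_max)
            + self.sun * sun_exposure
            + self.sun_sq * sun_exposure**2
        )


@dataclass(frozen=True)
class DevelopmentParams:
    """Sharpe-DeMichele enthalpy-model constants for one maturation process.

    ``rho25``
        rate (1/day) at the 298 K reference temperature with no inhibition.
    ``enthalpy_activation``
        activation enthalpy (cal/mol) of the rate-controlling reaction.
    ``enthalpy_inactivation`` / ``t_half_inactivation``
        high-temperature inhibition enthalpy and its half-inhibition
        temperature (K).  ``enthalpy_inactivation = 0`` disables inhibition.
    """

    rho25: float
    enthalpy_activation: float
    enthalpy_inactivation: float = 0.0
    t_half_inactivation: float = 1.0

    def validate(self) -> None:
        if not np.isfinite(self.rho25) or self.rho25 < 0:
            raise ValueError(f"rho25 must be finite and >= 0, got {self.rho25}")
        if not np.isfinite(self.enthalpy_activation):
            raise ValueError("enthalpy_activation must be finite")
        if self.enthalpy_inactivation != 0.0 and self.t_half_inactivation <= 0:
            raise ValueError("t_half_inactivation must be positive (Kelvin)")


@dataclass(frozen=True)
class MortalityParams:
    """Baseline-plus-hinge mortality response for one life stage.

    The rate equals ``baseline`` whenever the driving maximum temperature is
    at or below ``heat_threshold``; above it the rate rises linearly with
    slope ``heat_coeff`` (per day per deg C).  The cold branch mirrors this
    below ``cold_threshold`` on the minimum temperature and ships inert
    (``cold_coeff = 0``).
    """

    baseline: float
    heat_threshold: float = 40.0
    heat_coeff: float = 0.0
    cold_threshold: float = 10.0
    cold_coeff: float = 0.0

    def validate(self) -> None:
        for name in ("baseline", "heat_coeff", "cold_coeff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ThermalConfig:
    """Full thermal parameterization: per-stage development and mortality
    constants, eggs per gonotrophic cycle, sun exposure, and the air-to-water
    temperature regressions."""

    development: Mapping[str, DevelopmentParams]
    mortality: Mapping[str, MortalityParams]
    water: Mapping[str, WaterRegression]
    eggs_per_cycle: float = 63.0
    sun_exposure: float = 0.10

    def __post_init__(self):
        if self.eggs_per_cycle <= 0:
            raise ValueError("eggs_per_cycle must be positive")
        if not 0.0 <= self.sun_exposure <= 1.0:
            raise ValueError("sun_exposure must lie in [0, 1]")
        for p in self.development.values():
            p.validate()
        for p in self.mortality.values():
            p.validate()

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ThermalConfig":
        dev = {k: DevelopmentParams(**v) for k, v in raw["development"].items()}
        mort = {k: MortalityParams(**v) for k, v in raw["mortality"].items()}
        water = {k: WaterRegression(**v) for k, v in raw["water_temperature"].items()}
        return cls(
            development=dev,
            mortality=mort,
            water=water,
            eggs_per_cycle=float(raw.get("eggs_per_cycle", 63.0)),
            sun_exposure=float(raw.get("sun_exposure", 0.10)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThermalConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ThermalConfig":
        text = (
            resources.files("aedesfuse.data")
            .joinpath("thermal_default.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def identity_water(cls) -> "ThermalConfig":
        """Default rates but water temperature equal to air temperature.
        Useful for controlled experiments."""
        base = cls.default()
        ident = {
            "tw_mean": WaterRegression(t_mean=1.0),
            "tw_min": WaterRegression(t_min=1.0),
            "tw_max": WaterRegression(t_max=1.0),
        }
        return cls(
            development=base.development,
            mortality=base.mortality,
            water=ident,
            eggs_per_cycle=base.eggs_per_cycle,
            sun_exposure=base.sun_exposure,
        )


# ---------------------------------------------------------------------------
# scalar/vector rate functions
# ---------------------------------------------------------------------------


def water_temperature(air_triple, cfg: ThermalConfig):
    """Convert an air-temperature triple ``(t_min, t_mean, t_max)`` in deg C
    to the corresponding water triple.

    Accepts scalars or equal-length arrays.  Raises ``ValueError`` on
    non-finite input or if the air triple is not ordered min <= mean <= max;
    the returned water triple is checked for the same ordering.
    """
    t_min, t_mean, t_max = (np.asarray(v, dtype=float) for v in air_triple)
    if not (np.all(np.isfinite(t_min)) and np.all(np.isfinite(t_mean)) and np.all(np.isfinite(t_max))):
        raise ValueError("air temperatures must be finite")
    if np.any(t_min > t_mean) or np.any(t_mean > t_max):
        raise ValueError("air triple must satisfy t_min <= t_mean <= t_max")
    s = cfg.sun_exposure
    tw_mean = cfg.water["tw_mean"](t_mean, t_min, t_max, s)
    tw_min = cfg.water["tw_min"](t_mean, t_min, t_max, s)
    tw_max = cfg.water["tw_max"](t_mean, t_min, t_max, s)
    if np.any(tw_min > tw_mean + 1e-9) or np.any(tw_mean > tw_max + 1e-9):
        raise ValueError(
            "water-temperature regression produced an unordered triple; "
            "check the regression coefficients for this climate"
        )
    return tw_min, tw_mean, tw_max


def development_rate(t_water, params: DevelopmentParams):
    """Sharpe-DeMichele enthalpy development rate (1/day) at water
    temperature ``t_water`` (deg C).

    rate(T) = rho25 * (T/298) * exp[(dHa/R) (1/298 - 1/T)]
              / (1 + exp[(dHh/R) (1/T_half - 1/T)])

    with T in Kelvin.  A zero inactivation enthalpy drops the denominator.
    """
    params.validate()
    t_k = np.asarray(t_water, dtype=float) + CELSIUS_OFFSET
    if np.any(t_k <= 0):
        raise ValueError("temperature below absolute zero")
    numer = (
        params.rho25
        * (t_k / T_REF_K)
        * np.exp((params.enthalpy_activation / GAS_CONSTANT_CAL) * (1.0 / T_REF_K - 1.0 / t_k))
    )
    if params.enthalpy_inactivation == 0.0:
        return numer
    expo = (params.enthalpy_inactivation / GAS_CONSTANT_CAL) * (
        1.0 / params.t_half_inactivation - 1.0 / t_k
    )
    # exp overflow above ~709 means total inhibition: rate -> 0, cleanly.
    denom = 1.0 + np.exp(np.clip(expo, None, 700.0))
    return numer / denom


def mortality_rate(t_max_relevant, params: MortalityParams, t_min_relevant=None):
    """Daily per-capita mortality as a function of the relevant daily maximum
    temperature (deg C), plus an optional cold response on the daily minimum.

    Equals ``params.baseline`` below the heat threshold, rising linearly
    above it; never less than baseline.
    """
    params.validate()
    t_hi = np.asarray(t_max_relevant, dtype=float)
    if np.any(~np.isfinite(t_hi)):
        raise ValueError("temperature must be finite")
    rate = params.baseline + params.heat_coeff * np.maximum(0.0, t_hi - params.heat_threshold)
    if t_min_relevant is not None and params.cold_coeff > 0:
        t_lo = np.asarray(t_min_relevant, dtype=float)
        rate = rate + params.cold_coeff * np.maximum(0.0, params.cold_threshold - t_lo)
    return rate


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class TemperatureSeries:
    """A contiguous daily series of air-temperature triples with derived
    water temperatures.

    Backed by a DataFrame with columns ``day, date, t_mean, t_min, t_max,
    tw_mean, tw_min, tw_max``.
    """

    AIR_COLUMNS = ("t_mean", "t_min", "t_max")

    def __init__(self, frame: pd.DataFrame, cfg: ThermalConfig | None = None):
        cfg = cfg or ThermalConfig.default()
        df = frame.copy().reset_index(drop=True)
        for col in self.AIR_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"temperature frame missing column {col!r}")
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in column {col!r}")
        if "day" in df.columns:
            days = df["day"].to_numpy()
            if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
                raise ValueError("day index must be contiguous (no missing days)")
            df["day"] = days - days[0]
        else:
            df.insert(0, "day", np.arange(len(df)))
        if "date" not in df.columns:
            df.insert(1, "date", pd.date_range("2000-01-01", periods=len(df), freq="D"))
        else:
            dates = pd.to_datetime(df["date"])
            if len(dates) > 1 and not (dates.diff().dropna() == pd.Timedelta(days=1)).all():
                raise ValueError("dates must be consecutive calendar days")
            df["date"] = dates
        if np.any(df["t_min"].to_numpy() > df["t_mean"].to_numpy()) or np.any(
            df["t_mean"].to_numpy() > df["t_max"].to_numpy()
        ):
            raise ValueError("each day must satisfy t_min <= t_mean <= t_max")
        tw_min, tw_mean, tw_max = water_temperature(
            (df["t_min"].to_numpy(), df["t_mean"].to_numpy(), df["t_max"].to_numpy()), cfg
        )
        df["tw_mean"], df["tw_min"], df["tw_max"] = tw_mean, tw_min, tw_max
        self.frame = df
        self.cfg = cfg

    def __len__(self) -> int:
        return len(self.frame)

    def __getattr__(self, name):
        if name in ("t_mean", "t_min", "t_max", "tw_mean", "tw_min", "tw_max", "day"):
            return self.frame[name].to_numpy(dtype=float)
        raise AttributeError(name)

    @classmethod
    def from_csv(cls, path: str | Path, cfg: ThermalConfig | None = None) -> "TemperatureSeries":
        return cls(pd.read_csv(path), cfg=cfg)

    def to_csv(self, path: str | Path, water: bool = True) -> None:
        cols = ["day", "date", "t_mean", "t_min", "t_max"]
        if water:
            cols += ["tw_mean", "tw_min", "tw_max"]
        self.frame[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class RateSeries:
    """Daily vital rates (all 1/day), one entry per day of the driving
    temperature series."""

    a: np.ndarray
    d_E: np.ndarray
    d_L: np.ndarray
    d_P: np.ndarray
    mu_E: np.ndarray
    mu_L: np.ndarray
    mu_P: np.ndarray
    mu_N: np.ndarray

    def __post_init__(self):
        n = len(self.a)
        for name in ("a", "d_E", "d_L", "d_P", "mu_E", "mu_L", "mu_P", "mu_N"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError("all rate series must have equal length")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"rate series {name} must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.a)

    def slice(self, start: int, stop: int) -> "RateSeries":
        return RateSeries(
            **{
                name: getattr(self, name)[start:stop]
                for name in ("a", "d_E", "d_L", "d_P", "mu_E", "mu_L", "mu_P", "mu_N")
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: getattr(self, name)
                for name in ("a", "d_E", "d_L", "d_P", "mu_E", "mu_L", "mu_P", "mu_N")
            }
        )


def build_rate_series(temps: TemperatureSeries, cfg: ThermalConfig | None = None) -> RateSeries:
    """Vectorize the scalar rate functions over a temperature series.

    Argument mapping: development rates use mean water temperature; immature
    mortalities use maximum water temperature; adult mortality uses maximum
    air temperature; the gonotrophic rate uses mean air temperature.
    """
    cfg = cfg or temps.cfg
    return RateSeries(
        a=development_rate(temps.t_mean, cfg.development["a"]),
        d_E=development_rate(temps.tw_mean, cfg.development["d_E"]),
        d_L=development_rate(temps.tw_mean, cfg.development["d_L"]),
        d_P=development_rate(temps.tw_mean, cfg.development["d_P"]),
        mu_E=mortality_rate(temps.tw_max, cfg.mortality["mu_E"], temps.tw_min),
        mu_L=mortality_rate(temps.tw_max, cfg.mortality["mu_L"], temps.tw_min),
        mu_P=mortality_rate(temps.tw_max, cfg.mortality["mu_P"], temps.tw_min),
        mu_N=mortality_rate(temps.t_max, cfg.mortality["mu_N"], temps.t_min),
    )
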