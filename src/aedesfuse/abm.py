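"""Spatially explicit stochastic simulation of adult mosquitoes.

Each building carries a deterministic immature subsystem (eggs, larvae,
pupae — continuous counts advanced by the immature equations of the stage
model) and an integer population of adult females.  Stochasticity enters
only through the adult stage:

* emergence — a Poisson draw with rate ``d_P(t) P(x, t)`` per building;
* death — each adult dies with probability ``1 - exp(-(mu_N + spray))``;
* movement — each survivor relocates with daily probability 0.3 to a
  building chosen uniformly among those strictly within 100 m.

Adults are stored as a (building x age) count matrix, so all stochastic
draws are vectorized binomials/Poissons on that matrix; a single seeded
generator with a fixed draw order makes runs bit-reproducible.

The calibrated residual mortality ``mu_c(t)`` forces the per-building
immature dynamics so that the city-wide simulation tracks the statistical
abundance target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Building",
    "City",
    "AbmConfig",
    "AbmState",
    "AbmResult",
    "rate_to_prob",
    "build_neighbor_index",
    "step_day",
    "run_abm",
]

DEFAULT_MOVEMENT_RADIUS = 100.0
DEFAULT_MOVEMENT_PROB = 0.3


def rate_to_prob(rate):
    """Convert a daily rate into a daily event probability:
    ``prob = 1 - exp(-rate)``.

    Survival composes multiplicatively, so consecutive days at rates ``a``
    and ``b`` are equivalent to one day at ``a + b``.
    """
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be >= 0")
    return 1.0 - np.exp(-r)


@dataclass(frozen=True)
class Building:
    id: int
    x: float
    y: float
    zone: int


class City:
    """Building table with a lazily built within-radius neighbor index."""

    def __init__(self, frame: pd.DataFrame, movement_radius: float = DEFAULT_MOVEMENT_RADIUS):
        df = frame.copy().reset_index(drop=True)
        for col in ("id", "x", "y", "zone"):
            if col not in df.columns:
                raise ValueError(f"building table missing column {col!r}")
        if df["id"].duplicated().any():
            raise ValueError("building ids must be unique")
        if not np.all(np.isfinite(df[["x", "y"]].to_numpy(dtype=float))):
            raise ValueError("building coordinates must be finite")
        self.frame = df
        self.movement_radius = float(movement_radius)
        self._neighbors: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def xy(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @property
    def zones(self) -> np.ndarray:
        return self.frame["zone"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "City":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        self.frame[["id", "x", "y", "zone"]].to_csv(path, index=False)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Neighbor row-indices (not ids) per building, symmetric and
        self-free."""
        flat, offsets = self.neighbor_csr()
        return [flat[offsets[i] : offsets[i + 1]] for i in range(len(self))]

    def neighbor_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR encoding of the neighbor relation: ``(flat, offsets)`` with
        the neighbors of building ``i`` at ``flat[offsets[i]:offsets[i+1]]``."""
        if self._neighbors is None:
            self._neighbors = build_neighbor_index(self, self.movement_radius)
        return self._neighbors


def build_neighbor_index(city: City, radius: float = DEFAULT_MOVEMENT_RADIUS):
    """All unordered building pairs strictly within ``radius`` metres
    (centroid Euclidean distance), as a CSR pair ``(flat, offsets)``.

    The relation is symmetric and excludes self-pairs by construction.
    """
    tree = cKDTree(city.xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    # query_pairs uses distance <= r; drop exact-radius ties to keep the
    # strict inequality
    if len(pairs):
        d = np.linalg.norm(city.xy[pairs[:, 0]] - city.xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]
    n = len(city)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, dtype=int)
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, dtype=int)
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=n)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return dst.astype(np.int64), offsets.astype(np.int64)


@dataclass
class AbmConfig:
    """Knobs of the agent-based layer (the vital rates come from the
    thermal module and the calibration)."""

    movement_prob: float = DEFAULT_MOVEMENT_PROB
    movement_radius: float = DEFAULT_MOVEMENT_RADIUS
    n_E: float = 63.0
    max_age: int = 200  # absorbing top age bin (days)
    immature_substeps: int = 10  # RK4 substeps per day

    def __post_init__(self):
        if not 0.0 <= self.movement_prob <= 1.0:
            raise ValueError("movement_prob must lie in [0, 1]")
        if self.immature_substeps < 1:
            raise ValueError("immature_substeps must be >= 1")


@dataclass
class AbmState:
    """Per-building immature stages plus the adult (building x age) count
    matrix."""

    E: np.ndarray
    L: np.ndarray
    P: np.ndarray
    kappa: np.ndarray
    adults: np.ndarray  # shape (n_buildings, max_age + 1), integer counts
    day: int = 0

    def __post_init__(self):
        for name in ("E", "L", "P"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be >= 0")
        if np.any(self.adults < 0):
            raise ValueError("adult counts must be >= 0")

    @property
    def adults_per_building(self) -> np.ndarray:
        return self.adults.sum(axis=1)

    @property
    def total_adults(self) -> int:
        return int(self.adults.sum())


def _advance_immatures(state: AbmState, r: dict[str, float], mu_c: float, cfg: AbmConfig) -> np.ndarray:
    """One day of the deterministic immature subsystem, fixed-step RK4
    vectorized over buildings.  Egg input uses each building's current
    integer adult count; buildings with zero carrying capacity host no
    immatures.

    Returns the per-building day-integral of the pupal stock (trapezoid
    over the substeps), which sets the expected emergence ``d_P * int P dt``
    exactly as in the continuous model."""
    A = state.adults_per_building.astype(float)
    habitable = state.kappa > 0
    inv_kappa = np.where(habitable, 1.0 / np.where(habitable, state.kappa, 1.0), 0.0)
    egg_input = np.where(habitable, cfg.n_E * r["a"] * A / 2.0, 0.0)

    loss_E = r["d_E"] + r["mu_E"]
    loss_P = r["d_P"] + r["mu_P"] + mu_c
    base_loss_L = r["d_L"] + r["mu_L"] + mu_c

    def deriv(E, L, P):
        dE = egg_input - loss_E * E
        dL = r["d_E"] * E - (base_loss_L + L * L * inv_kappa) * L
        dP = r["d_L"] * L - loss_P * P
        return dE, dL, dP

    h = 1.0 / cfg.immature_substeps
    E, L, P = state.E, state.L, state.P
    p_integral = np.zeros_like(P)
    for _ in range(cfg.immature_substeps):
        p_prev = P
        k1 = deriv(E, L, P)
        k2 = deriv(E + 0.5 * h * k1[0], L + 0.5 * h * k1[1], P + 0.5 * h * k1[2])
        k3 = deriv(E + 0.5 * h * k2[0], L + 0.5 * h * k2[1], P + 0.5 * h * k2[2])
        k4 = deriv(E + h * k3[0], L + h * k3[1], P + h * k3[2])
        E = E + (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        L = L + (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        P = P + (h / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        p_integral += 0.5 * h * (p_prev + P)
    np.maximum(E, 0.0, out=E)
    np.maximum(L, 0.0, out=L)
    np.maximum(P, 0.0, out=P)
    state.E, state.L, state.P = E, L, P
    return np.maximum(p_integral, 0.0)


def step_day(
    state: AbmState,
    rates_day: dict[str, float],
    mu_c_day: float,
    spray_increments,
    cfg: AbmConfig,
    rng: np.random.Generator,
    neighbor_csr: tuple[np.ndarray, np.ndarray] | None,
) -> dict[str, int]:
    """Advance the simulation by one day, in place.

    Event order: (1) immatures advance (egg input from the start-of-day
    adult counts), (2) Poisson emergence into age 0 (the deterministic pupal
    stock is not decremented by the draw), (3) death with probability
    ``1 - exp(-(mu_N + spray))`` — emergents, which arrive mid-day on
    average, face a half-day hazard ``1 - exp(-(mu_N + spray)/2)`` on their
    first day — (4) movement of survivors, (5) ageing.  New emergents
    appear in the evening census at age 1.

    Returns a diagnostics dict with the day's emergence, death, movement
    and adult-day tallies.
    """
    for key in ("a", "d_E", "d_L", "d_P", "mu_E", "mu_L", "mu_P", "mu_N"):
        if key not in rates_day:
            raise ValueError(f"rates_day missing {key!r}")
    if mu_c_day < 0:
        raise ValueError("mu_c must be >= 0")
    adults = state.adults
    n_buildings, n_ages = adults.shape
    adult_days = int(adults.sum())

    # (1) immatures
    p_integral = _advance_immatures(state, rates_day, mu_c_day, cfg)

    # (2) emergence: Poisson with the day's integrated pupal maturation
    emergents = rng.poisson(rates_day["d_P"] * p_integral)

    # (3) death; emergents arrive mid-day on average, so their first-day
    # exposure is half a day
    inc = np.broadcast_to(np.asarray(spray_increments, dtype=float), (n_buildings,))
    if np.any(inc < 0):
        raise ValueError("spray increments must be >= 0")
    hazard = rates_day["mu_N"] + inc
    deaths = rng.binomial(adults, rate_to_prob(hazard)[:, None])
    adults -= deaths
    new_deaths = rng.binomial(emergents, rate_to_prob(0.5 * hazard))
    adults[:, 0] += emergents - new_deaths
    deaths_total = int(deaths.sum()) + int(new_deaths.sum())

    # (4) movement
    n_moved = 0
    if cfg.movement_prob > 0 and neighbor_csr is not None:
        flat, offsets = neighbor_csr
        degree = np.diff(offsets)
        can_move = degree > 0
        movers = rng.binomial(adults, cfg.movement_prob)
        movers[~can_move, :] = 0
        adults -= movers
        rows, cols = np.nonzero(movers)
        if len(rows):
            reps = movers[rows, cols]
            src = np.repeat(rows, reps)
            ages = np.repeat(cols, reps)
            pick = (rng.random(len(src)) * degree[src]).astype(np.int64)
            dest = flat[offsets[src] + pick]
            np.add.at(adults, (dest, ages), 1)
            n_moved = len(src)

    # (5) ageing (top bin absorbs)
    adults[:, -1] += adults[:, -2]
    adults[:, 1:-1] = adults[:, :-2]
    adults[:, 0] = 0

    state.day += 1
    return {
        "emerged": int(emergents.sum()),
        "died": deaths_total,
        "moved": n_moved,
        "adult_days": adult_days,
    }


@dataclass
class AbmResult:
    """Daily outputs of one agent-based run."""

    days: np.ndarray
    n_total: np.ndarray
    per_building: np.ndarray | None  # (n_days, n_buildings) int32
    age_hist: np.ndarray  # (n_days, max_age + 1)
    emerged: np.ndarray
    died: np.ndarray
    moved: np.ndarray
    adult_days: np.ndarray
    city: City
    seed: int

    def city_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "N_total": self.n_total})

    def age_census_frame(self) -> pd.DataFrame:
        """Long-format census: day, age, count (zero counts omitted)."""
        d, a = np.nonzero(self.age_hist)
        return pd.DataFrame(
            {"day": self.days[d], "age": a, "count": self.age_hist[d, a]}
        )

    def save(self, out_dir: str | Path, per_building: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.city_frame().to_csv(out / "abm_city.csv", index=False)
        self.age_census_frame().to_csv(out / "abm_age_census.csv", index=False)
        if per_building and self.per_building is not None:
            df = pd.DataFrame(self.per_building, columns=[str(i) for i in self.city.ids])
            df.insert(0, "day", self.days)
            df.to_csv(out / "abm_buildings.csv", index=False)


def run_abm(
    city: City,
    calibration,
    n0,
    seed: int,
    t_span: tuple[int, int] | None = None,
    campaign=None,
    cfg: AbmConfig | None = None,
    record_buildings: bool = True,
    spin_up_days: int = 0,
) -> AbmResult:
    """Run the agent-based simulation forced by a calibration.

    Parameters
    ----------
    city
        Building map; its neighbor index defines the movement graph.
    calibration : CalibrationResults
        Supplies the daily vital rates, ``mu_c(t)``, the normalized
        immature profiles for initialization and ``kappa_norm``.
    n0 : array-like
        Initial adult-female abundance per building; per-building carrying
        capacities are ``kappa_norm * n0**2``.
    campaign : optional
        An object with ``increments(day) -> array`` giving the per-building
        added adult mortality for that day (see
        :mod:`aedesfuse.interventions`).
    spin_up_days : int
        Replay this many days of forcing (from the start of ``t_span``,
        no campaign, nothing recorded) before the recorded run, so the
        simulation starts from its own stationary state.  The matched
        initial placement is not stationary under movement in a
        finite city — adults redistribute toward well-connected buildings
        over the first weeks — and a one-year spin-up (which returns to the
        same seasonal phase) removes that initial transient from the
        recorded window.

    The census (``n_total``, ``per_building``, ``age_hist``) is taken at the
    end of each day, after deaths and movement.
    """
    cfg = cfg or AbmConfig(n_E=calibration.model.cfg.eggs_per_cycle)
    n0 = np.broadcast_to(np.asarray(n0, dtype=float), (len(city),)).copy()
    if np.any(n0 < 0):
        raise ValueError("n0 must be >= 0")
    if t_span is None:
        t_span = (0, calibration.nobs)
    start, stop = t_span
    if not 0 <= start < stop <= calibration.nobs:
        raise ValueError("t_span outside the calibration window")
    rates = calibration.model.rates
    rng = np.random.default_rng(seed)

    # stochastic rounding of the initial adult placement, all at age 0
    base = np.floor(n0)
    extra = rng.random(len(city)) < (n0 - base)
    adults0 = (base + extra).astype(np.int64)
    adults = np.zeros((len(city), cfg.max_age + 1), dtype=np.int64)
    adults[:, 0] = adults0

    state = AbmState(
        E=n0 * calibration.E[start],
        L=n0 * calibration.L[start],
        P=n0 * calibration.P[start],
        kappa=np.asarray(calibration.kappa_for(n0), dtype=float),
        adults=adults,
        day=start,
    )
    neighbor_csr = city.neighbor_csr()

    if spin_up_days > 0:
        if start + spin_up_days > calibration.nobs:
            raise ValueError("spin-up window extends beyond the calibration range")
        zero = np.zeros(len(city))
        for day in range(start, start + spin_up_days):
            step_day(
                state,
                {
                    "a": rates.a[day],
                    "d_E": rates.d_E[day],
                    "d_L": rates.d_L[day],
                    "d_P": rates.d_P[day],
                    "mu_E": rates.mu_E[day],
                    "mu_L": rates.mu_L[day],
                    "mu_P": rates.mu_P[day],
                    "mu_N": rates.mu_N[day],
                },
                calibration.mu_c[day],
                zero,
                cfg,
                rng,
                neighbor_csr,
            )
        state.day = start

    n_days = stop - start
    n_total = np.empty(n_days, dtype=np.int64)
    per_building = (
        np.empty((n_days, len(city)), dtype=np.int32) if record_buildings else None
    )
    age_hist = np.empty((n_days, cfg.max_age + 1), dtype=np.int64)
    emerged = np.empty(n_days, dtype=np.int64)
    died = np.empty(n_days, dtype=np.int64)
    moved = np.empty(n_days, dtype=np.int64)
    adult_days = np.empty(n_days, dtype=np.int64)

    zero_inc = np.zeros(len(city))
    for i, day in enumerate(range(start, stop)):
        inc = campaign.increments(day) if campaign is not None else zero_inc
        rates_day = {
            "a": rates.a[day],
            "d_E": rates.d_E[day],
            "d_L": rates.d_L[day],
            "d_P": rates.d_P[day],
            "mu_E": rates.mu_E[day],
            "mu_L": rates.mu_L[day],
            "mu_P": rates.mu_P[day],
            "mu_N": rates.mu_N[day],
        }
        diag = step_day(
            state, rates_day, calibration.mu_c[day], inc, cfg, rng, neighbor_csr
        )
        n_total[i] = state.total_adults
        if record_buildings:
            per_building[i] = state.adults_per_building
        age_hist[i] = state.adults.sum(axis=0)
        emerged[i], died[i], moved[i], adult_days[i] = (
            diag["emerged"],
            diag["died"],
            diag["moved"],
            diag["adult_days"],
        )

    return AbmResult(
        days=np.arange(start, stop),
        n_total=n_total,
        per_building=per_building,
        age_hist=age_hist,
        emerged=emerged,
        died=died,
        moved=moved,
        adult_days=adult_days,
        city=city,
        seed=seed,
    )
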