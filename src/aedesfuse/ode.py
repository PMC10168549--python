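"""Deterministic stage-structured population model.

Four coupled ODEs track eggs (E), larvae (L), pupae (P) and adult females
(N) at one location::

    dE/dt = n_E a(t) N / 2           - (d_E(t) + mu_E(t)) E
    dL/dt = d_E(t) E                 - (d_L(t) + mu_L(t) + mu_c(t) + L^2/kappa) L
    dP/dt = d_L(t) L                 - (d_P(t) + mu_P(t) + mu_c(t)) P
    dN/dt = d_P(t) P                 - mu_N(t) N

Egg laying contributes ``n_E a N / 2`` (the model tracks females only; half
of the ``n_E`` eggs per gonotrophic cycle are female).  Density-dependent
larval mortality is quadratic in density: the per-capita rate is
``L^2 / kappa``.  The residual mortality ``mu_c(t)`` acts on larvae and
pupae only.

All forcing (vital rates and ``mu_c``) is piecewise-constant per day;
integration restarts at each day boundary so forcing discontinuities never
straddle a solver step.  The solver is the implicit Radau method at absolute
and relative tolerances of 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .thermal import RateSeries

__all__ = ["OdeState", "derive_kappa", "scale_kappa", "integrate_forward", "equilibrium_state"]

#: target ratio of density-dependent to density-independent larval mortality
#: at average larval density.
DENSITY_DOMINANCE_FACTOR = 10.0

#: solver noise band: trajectory values in (-NEG_TOL, 0) are clamped to 0.
NEG_TOL = 1e-9

DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class OdeState:
    """Continuous stage abundances at one instant."""

    E: float
    L: float
    P: float
    N: float

    def __post_init__(self):
        for name in ("E", "L", "P", "N"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"state component {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.L, self.P, self.N], dtype=float)


def derive_kappa(
    mean_L: float,
    mean_mu_L: float,
    factor: float = DENSITY_DOMINANCE_FACTOR,
    squared: bool = True,
) -> float:
    """Carrying capacity of the normalized system from the dominance rule.

    The rule fixes the time-average per-capita density-dependent larval
    mortality, evaluated at the time-average larval density, at ``factor``
    times the time-average density-independent larval mortality:
    ``factor * mean(mu_L) = mean(L)^2 / kappa``, hence
    ``kappa = mean(L)^2 / (factor * mean(mu_L))``.

    ``squared=False`` selects the linear-in-density variant
    ``kappa = mean(L) / (factor * mean(mu_L))`` for sensitivity analyses.
    """
    if mean_L <= 0 or mean_mu_L <= 0:
        raise ValueError("mean_L and mean_mu_L must be positive")
    if factor <= 0:
        raise ValueError("factor must be positive")
    numer = mean_L**2 if squared else mean_L
    return numer / (factor * mean_mu_L)


def scale_kappa(kappa_norm: float, n0: float) -> float:
    """Location-specific carrying capacity: the normalized-system kappa
    scaled by the squared initial adult abundance at the location."""
    if n0 < 0:
        raise ValueError("initial abundance must be >= 0")
    return kappa_norm * n0 * n0


def _rhs(t, y, a, d_E, d_L, d_P, mu_E, mu_L, mu_P, mu_N, mu_c, kappa, n_E):
    E, L, P, N = y
    dd = L * L / kappa if np.isfinite(kappa) else 0.0
    return (
        n_E * a * N / 2.0 - (d_E + mu_E) * E,
        d_E * E - (d_L + mu_L + mu_c + dd) * L,
        d_L * L - (d_P + mu_P + mu_c) * P,
        d_P * P - mu_N * N,
    )


def integrate_forward(
    state0: OdeState,
    rates: RateSeries,
    mu_c,
    kappa: float,
    t_span: tuple[int, int] | None = None,
    n_E: float = 63.0,
    rtol: float = DEFAULT_TOL,
    atol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Integrate the model day by day under daily piecewise-constant forcing.

    Parameters
    ----------
    state0
        State at the start of ``t_span``.
    rates, mu_c
        Daily vital rates and residual larval/pupal mortality; ``mu_c`` may
        be a scalar or a per-day array covering ``t_span``.
    kappa
        Carrying capacity (``np.inf`` disables density dependence).
    t_span
        Half-open day range ``(start, stop)``; defaults to the full rate
        series.

    Returns
    -------
    DataFrame with columns ``day, E, L, P, N``: the state at the start of
    each day in ``t_span``.
    """
    if t_span is None:
        t_span = (0, len(rates))
    start, stop = t_span
    if not 0 <= start < stop <= len(rates):
        raise ValueError(f"t_span {t_span} outside the rate series (length {len(rates)})")
    mu_c_arr = np.broadcast_to(np.asarray(mu_c, dtype=float), (len(rates),))
    if np.any(mu_c_arr[start:stop] < 0):
        raise ValueError("mu_c must be >= 0 on every day")

    n_days = stop - start
    out = np.empty((n_days, 4))
    y = state0.as_array()
    out[0] = y
    for i, day in enumerate(range(start, stop - 1)):
        args = (
            rates.a[day],
            rates.d_E[day],
            rates.d_L[day],
            rates.d_P[day],
            rates.mu_E[day],
            rates.mu_L[day],
            rates.mu_P[day],
            rates.mu_N[day],
            mu_c_arr[day],
            kappa,
            n_E,
        )
        sol = solve_ivp(_rhs, (0.0, 1.0), y, method="Radau", rtol=rtol, atol=atol, args=args)
        if not sol.success:
            raise RuntimeError(f"Radau integration failed on day {day}: {sol.message}")
        y = sol.y[:, -1]
        y[(y > -NEG_TOL) & (y < 0.0)] = 0.0
        out[i + 1] = y

    out[(out > -NEG_TOL) & (out < 0.0)] = 0.0
    df = pd.DataFrame(out, columns=["E", "L", "P", "N"])
    df.insert(0, "day", np.arange(start, stop))
    return df


def equilibrium_state(
    rates_day: dict[str, float],
    mu_c: float,
    kappa: float,
    n_E: float = 63.0,
) -> OdeState:
    """Positive equilibrium of the model under constant rates, found by
    root-finding on the right-hand side.

    At equilibrium the adult equation gives ``P = mu_N N / d_P`` and the egg
    equation ``E = n_E a N / (2 (d_E + mu_E))``; substituting into the pupal
    and larval balances leaves a scalar equation in N, solved by bisection on
    the net larval balance.
    """
    a, d_E, d_L, d_P = (rates_day[k] for k in ("a", "d_E", "d_L", "d_P"))
    mu_E, mu_L, mu_P, mu_N = (rates_day[k] for k in ("mu_E", "mu_L", "mu_P", "mu_N"))

    def larval_balance(N):
        P = mu_N * N / d_P
        E = n_E * a * N / (2.0 * (d_E + mu_E))
        L = (d_P + mu_P + mu_c) * P / d_L
        dd = L * L / kappa if np.isfinite(kappa) else 0.0
        return d_E * E - (d_L + mu_L + mu_c + dd) * L

    # Bracket: balance is positive for small N (linear growth term dominates
    # when the unforced system is supercritical) and negative for large N.
    lo, hi = 1e-12, 1.0
    while larval_balance(hi) > 0:
        hi *= 10.0
        if hi > 1e18:
            raise RuntimeError("no positive equilibrium: system appears subcritical")
    if larval_balance(lo) < 0:
        raise RuntimeError("no positive equilibrium: system appears subcritical")
    from scipy.optimize import brentq

    N_eq = brentq(larval_balance, lo, hi, xtol=1e-12, rtol=1e-14)
    P_eq = mu_N * N_eq / d_P
    E_eq = n_E * a * N_eq / (2.0 * (d_E + mu_E))
    L_eq = (d_P + mu_P + mu_c) * P_eq / d_L
    return OdeState(E=E_eq, L=L_eq, P=P_eq, N=N_eq)
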