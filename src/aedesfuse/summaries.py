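"""Spatial, demographic and rebound summaries of simulation output.

* zone heatmaps: per-zone adult totals sampled every *n* days, optionally
  column-normalized so each sampled day sums to one;
* age-distribution statistics: moments of the integer-age census and the
  bimodality coefficient ``b = (skewness^2 + 1) / kurtosis`` (Pearson,
  non-excess kurtosis, so ``b`` lies in [0, 1]);
* rebound metrics of a sprayed run against its paired baseline: trough
  depth and timing, and the time for abundance to return to within 10% and
  1% of baseline (sustained crossings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import City

__all__ = [
    "zone_matrix",
    "age_stats",
    "fit_age_decay_rate",
    "ReboundMetrics",
    "rebound_metrics",
]

DAYS_PER_MONTH = 30.44


def zone_matrix(
    per_building_daily_N: np.ndarray,
    city: City,
    every_n_days: int = 100,
    normalize: bool = True,
) -> pd.DataFrame:
    """Zone-by-sampled-day abundance matrix.

    Rows are zone ids (ascending), columns the sampled day indices.  With
    ``normalize=True`` each column is divided by that day's city-wide total
    so it sums to one; a sampled day with zero total yields a NaN column and
    a warning.
    """
    N = np.asarray(per_building_daily_N, dtype=float)
    if N.ndim != 2 or N.shape[1] != len(city):
        raise ValueError("per_building_daily_N must be (n_days, n_buildings)")
    days = np.arange(0, N.shape[0], every_n_days)
    zones = city.zones
    zone_ids = np.unique(zones)
    # one-hot zone aggregation
    agg = np.zeros((len(zone_ids), len(days)))
    for j, z in enumerate(zone_ids):
        agg[j] = N[days][:, zones == z].sum(axis=1)
    if normalize:
        totals = agg.sum(axis=0)
        dead = totals == 0
        if dead.any():
            warnings.warn(
                f"zero city-wide abundance on sampled days {days[dead].tolist()}; "
                "normalized columns undefined"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            agg = np.where(dead, np.nan, agg / np.where(dead, 1.0, totals))
    return pd.DataFrame(agg, index=pd.Index(zone_ids, name="zone"), columns=days)


def _hist_moments(ages: np.ndarray, counts: np.ndarray):
    """Population moments of an integer-age histogram."""
    n = counts.sum()
    mean = float(np.sum(ages * counts) / n)
    d = ages - mean
    var = float(np.sum(counts * d**2) / n)
    if var == 0:
        return mean, var, np.nan, np.nan
    skew = float(np.sum(counts * d**3) / n / var**1.5)
    kurt = float(np.sum(counts * d**4) / n / var**2)  # Pearson, non-excess
    return mean, var, skew, kurt


def age_stats(age_census: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-day moments and bimodality coefficient of the adult age census.

    Accepts either a long-format census (columns ``day, age, count``) or an
    ``(n_days, n_ages)`` histogram matrix.  Returns one row per day with
    ``n, mean, var, skewness, kurtosis, bimodality``; days with fewer than
    two distinct ages get NaN skewness/kurtosis/bimodality.

    The bimodality coefficient ``b = (skewness^2 + 1) / kurtosis`` lies in
    (0, 1] by the Pearson inequality ``kurtosis >= skewness^2 + 1``; values
    near 1 indicate strong bimodality (the uniform distribution sits at
    5/9, the exponential at ~0.55, a symmetric two-point mass at 1).
    """
    if isinstance(age_census, pd.DataFrame):
        piv = age_census.pivot_table(
            index="day", columns="age", values="count", fill_value=0, aggfunc="sum"
        )
        hist = piv.to_numpy(dtype=float)
        ages = piv.columns.to_numpy(dtype=float)
        days = piv.index.to_numpy()
    else:
        hist = np.asarray(age_census, dtype=float)
        ages = np.arange(hist.shape[1], dtype=float)
        days = np.arange(hist.shape[0])
    if hist.size == 0 or hist.sum() == 0:
        raise ValueError("age census is empty")

    rows = []
    for i in range(hist.shape[0]):
        counts = hist[i]
        n = counts.sum()
        if n == 0:
            rows.append((days[i], 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        mean, var, skew, kurt = _hist_moments(ages, counts)
        b = (skew**2 + 1.0) / kurt if np.isfinite(kurt) and kurt > 0 else np.nan
        rows.append((days[i], int(n), mean, var, skew, kurt, b))
    return pd.DataFrame(
        rows, columns=["day", "n", "mean", "var", "skewness", "kurtosis", "bimodality"]
    )


def fit_age_decay_rate(ages: np.ndarray, counts: np.ndarray, min_age: int = 1) -> float:
    """Exponential decay rate of a stationary age distribution.

    Ages in the evening census start at 1 (emergents age once before being
    counted), so the stationary distribution under constant adult mortality
    ``mu_N`` is geometric on {min_age, min_age+1, ...} with survival
    ``exp(-mu_N)``.  The maximum-likelihood survival estimate is
    ``(m - min_age) / (m - min_age + 1)`` with ``m`` the census mean age;
    the returned rate is ``-log`` of it.
    """
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = ages >= min_age
    n = counts[keep].sum()
    if n <= 0:
        raise ValueError("empty census above min_age")
    m = float(np.sum(ages[keep] * counts[keep]) / n)
    s = (m - min_age) / (m - min_age + 1.0)
    if not 0 < s < 1:
        raise ValueError("degenerate age distribution: cannot fit a decay rate")
    return -float(np.log(s))


@dataclass(frozen=True)
class ReboundMetrics:
    """Trough and recovery summary of a sprayed run vs its baseline."""

    min_abundance: float
    min_day: int
    percent_reduction: float  # at the trough, vs same-day baseline
    days_to_within_10pct: float  # NaN if never recovered within the series
    days_to_within_1pct: float

    @property
    def months_to_within_10pct(self) -> float:
        return self.days_to_within_10pct / DAYS_PER_MONTH

    @property
    def months_to_within_1pct(self) -> float:
        return self.days_to_within_1pct / DAYS_PER_MONTH


def _sustained_crossing(ratio: np.ndarray, threshold: float, sustain: int) -> float:
    """First index at which ratio >= threshold holds for ``sustain``
    consecutive days (NaN if never)."""
    ok = ratio >= threshold
    if sustain <= 1:
        idx = np.flatnonzero(ok)
        return float(idx[0]) if len(idx) else float("nan")
    # rolling all-true window
    cum = np.convolve(ok.astype(int), np.ones(sustain, dtype=int), mode="valid")
    idx = np.flatnonzero(cum == sustain)
    return float(idx[0]) if len(idx) else float("nan")


def rebound_metrics(
    sprayed_series,
    baseline_series,
    campaign_start: int,
    sustain_days: int = 7,
    thresholds: tuple[float, float] = (0.90, 0.99),
) -> ReboundMetrics:
    """Trough depth/timing and sustained recovery times.

    The trough is the post-``campaign_start`` minimum of the sprayed series;
    its depth is measured against the baseline on the same day.  Recovery
    times are the first day (counted from ``campaign_start``) at which the
    ratio sprayed/baseline stays at or above each threshold for
    ``sustain_days`` consecutive days.  Both metrics are invariant to a
    common rescaling of the two series.
    """
    sprayed = np.asarray(sprayed_series, dtype=float)
    baseline = np.asarray(baseline_series, dtype=float)
    if sprayed.shape != baseline.shape:
        raise ValueError("series must have equal length")
    if not 0 <= campaign_start < len(sprayed):
        raise ValueError("campaign_start outside the series")
    post_s = sprayed[campaign_start:]
    post_b = baseline[campaign_start:]
    i_min = int(np.argmin(post_s))
    if post_b[i_min] == 0:
        raise ValueError(f"baseline is zero on the trough day {campaign_start + i_min}")
    reduction = 100.0 * (1.0 - post_s[i_min] / post_b[i_min])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(post_b > 0, post_s / post_b, np.nan)
    return ReboundMetrics(
        min_abundance=float(post_s[i_min]),
        min_day=campaign_start + i_min,
        percent_reduction=float(np.clip(reduction, 0.0, 100.0)),
        days_to_within_10pct=_sustained_crossing(ratio, thresholds[0], sustain_days),
        days_to_within_1pct=_sustained_crossing(ratio, thresholds[1], sustain_days),
    )
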