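"""Zone heatmaps, age-distribution statistics, rebound metrics and CSV
round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aedesfuse.abm import City
from aedesfuse.summaries import (
    ReboundMetrics,
    age_stats,
    fit_age_decay_rate,
    rebound_metrics,
    zone_matrix,
)
from aedesfuse.thermal import TemperatureSeries


def _two_zone_city():
    return City(
        pd.DataFrame({"id": [0, 1, 2], "x": [0, 10, 20], "y": [0, 0, 0], "zone": [1, 2, 2]})
    )


# --- zone matrix -----------------------------------------------------------


def test_constant_split_normalizes_to_shares():
    city = _two_zone_city()
    N = np.tile([30.0, 35.0, 35.0], (250, 1))  # zone 1: 30, zone 2: 70
    zm = zone_matrix(N, city, every_n_days=100)
    assert list(zm.columns) == [0, 100, 200]
    np.testing.assert_allclose(zm.loc[1], 0.3)
    np.testing.assert_allclose(zm.loc[2], 0.7)
    np.testing.assert_allclose(zm.sum(axis=0), 1.0, atol=1e-9)


def test_raw_zone_totals():
    city = _two_zone_city()
    N = np.tile([1.0, 2.0, 3.0], (10, 1))
    zm = zone_matrix(N, city, every_n_days=5, normalize=False)
    np.testing.assert_allclose(zm.loc[1], 1.0)
    np.testing.assert_allclose(zm.loc[2], 5.0)


def test_separable_input_gives_identical_columns():
    rng = np.random.default_rng(0)
    city = City(
        pd.DataFrame(
            {"id": range(20), "x": rng.uniform(0, 100, 20), "y": rng.uniform(0, 100, 20), "zone": rng.integers(0, 4, 20)}
        )
    )
    w = rng.lognormal(size=20)
    s = 1.0 + 0.5 * np.sin(np.arange(300) / 40.0)
    N = np.outer(s, w)
    zm = zone_matrix(N, city, every_n_days=60)
    arr = zm.to_numpy()
    np.testing.assert_allclose(arr, np.tile(arr[:, :1], (1, arr.shape[1])), rtol=1e-12)


def test_zero_total_day_reported():
    city = _two_zone_city()
    N = np.tile([1.0, 1.0, 1.0], (5, 1))
    N[3] = 0.0
    with pytest.warns(UserWarning, match="zero city-wide"):
        zm = zone_matrix(N, city, every_n_days=3)
    assert np.isnan(zm[3]).all()


# --- age statistics --------------------------------------------------------


def test_bimodality_of_reference_distributions():
    ages = np.arange(4000)
    # near-exponential: geometric weights on a fine grid
    w_exp = np.exp(-0.01 * ages)
    df = age_stats(w_exp[None, :] * 1e6)
    assert df.loc[0, "skewness"] == pytest.approx(2.0, abs=0.02)
    assert df.loc[0, "kurtosis"] == pytest.approx(9.0, abs=0.1)
    assert df.loc[0, "bimodality"] == pytest.approx(5.0 / 9.0, abs=0.01)
    # symmetric mesokurtic (discretized normal): b -> 1/3
    w_norm = stats.norm.pdf(ages, loc=2000, scale=150)
    df = age_stats(w_norm[None, :] * 1e9)
    assert df.loc[0, "bimodality"] == pytest.approx(1.0 / 3.0, abs=0.01)
    # symmetric two-point distribution: maximal bimodality b = 1
    two = np.zeros(11)
    two[[0, 10]] = 500.0
    df = age_stats(two[None, :])
    assert df.loc[0, "kurtosis"] == pytest.approx(1.0)
    assert df.loc[0, "bimodality"] == pytest.approx(1.0)


@given(
    counts=st.lists(st.integers(0, 50), min_size=3, max_size=40).filter(
        lambda c: sum(1 for x in c if x > 0) >= 2
    )
)
@settings(max_examples=60, deadline=None)
def test_bimodality_always_in_unit_interval(counts):
    hist = np.array([counts], dtype=float)
    df = age_stats(hist)
    b = df.loc[0, "bimodality"]
    if np.isfinite(b):
        assert 0.0 <= b <= 1.0 + 1e-12


def test_age_stats_long_format_and_histogram_agree():
    hist = np.array([[0, 5, 3, 2], [1, 0, 4, 0]], dtype=float)
    days, ages = np.nonzero(hist)
    long = pd.DataFrame({"day": days, "age": ages, "count": hist[days, ages]})
    a = age_stats(hist)
    b = age_stats(long)
    pd.testing.assert_frame_equal(a, b, check_dtype=False)


def test_degenerate_census_reported():
    with pytest.raises(ValueError):
        age_stats(np.zeros((2, 5)))
    one_age = np.zeros((1, 5))
    one_age[0, 2] = 7
    df = age_stats(one_age)
    assert np.isnan(df.loc[0, "bimodality"])  # fewer than 2 distinct ages


def test_fit_age_decay_rate_on_exact_geometric():
    mu = 0.09
    ages = np.arange(1, 400)
    counts = 1e6 * np.exp(-mu * (ages - 1))
    assert fit_age_decay_rate(ages, counts) == pytest.approx(mu, rel=1e-3)


# --- rebound metrics -------------------------------------------------------


def test_identical_series_yield_zero_metrics():
    s = np.linspace(100, 200, 120)
    rm = rebound_metrics(s, s, campaign_start=10)
    assert rm.percent_reduction == 0.0
    assert rm.days_to_within_10pct == 0.0
    assert rm.days_to_within_1pct == 0.0


def test_sixty_percent_reduction_at_trough():
    base = np.full(100, 1000.0)
    spray = base.copy()
    spray[40:] = 400.0  # trough at 40% of baseline
    rm = rebound_metrics(spray, base, campaign_start=30)
    assert rm.percent_reduction == pytest.approx(60.0)
    assert rm.min_abundance == 400.0


def test_threshold_crossing_days():
    n = 200
    base = np.full(n, 1000.0)
    spray = np.full(n, 500.0)
    start = 20
    spray[start + 40 :] = 950.0  # crosses 0.90 on day 40 after start
    spray[start + 70 :] = 995.0  # crosses 0.99 on day 70 after start
    rm = rebound_metrics(spray, base, campaign_start=start)
    assert rm.days_to_within_10pct == 40.0
    assert rm.days_to_within_1pct == 70.0
    assert rm.days_to_within_1pct >= rm.days_to_within_10pct
    assert rm.months_to_within_10pct == pytest.approx(40 / 30.44)


def test_rebound_invariant_to_common_rescaling():
    rng = np.random.default_rng(5)
    base = 1000 + 100 * np.sin(np.arange(300) / 30) + rng.normal(0, 5, 300)
    spray = base * np.clip(np.linspace(0.3, 1.05, 300), 0.3, 1.0)
    a = rebound_metrics(spray, base, 10)
    b = rebound_metrics(7.5 * spray, 7.5 * base, 10)
    assert a.percent_reduction == pytest.approx(b.percent_reduction)
    assert a.min_day == b.min_day
    assert a.days_to_within_10pct == b.days_to_within_10pct
    assert a.days_to_within_1pct == b.days_to_within_1pct


def test_sustained_crossing_ignores_single_day_blips():
    base = np.full(100, 1000.0)
    spray = np.full(100, 500.0)
    spray[30] = 999.0  # one-day flicker must not count with 7-day sustain
    spray[60:] = 999.0
    rm = rebound_metrics(spray, base, campaign_start=0, sustain_days=7)
    assert rm.days_to_within_10pct == 60.0


# --- CSV round trips -------------------------------------------------------


def test_buildings_round_trip(tmp_path):
    city = _two_zone_city()
    city.to_csv(tmp_path / "b.csv")
    back = City.from_csv(tmp_path / "b.csv")
    pd.testing.assert_frame_equal(city.frame, back.frame)


def test_temperature_round_trip(tmp_path, small_setup):
    _, _, temps, _ = small_setup
    temps.to_csv(tmp_path / "t.csv")
    back = TemperatureSeries.from_csv(tmp_path / "t.csv", cfg=temps.cfg)
    np.testing.assert_allclose(back.t_mean, temps.t_mean)
    np.testing.assert_allclose(back.tw_max, temps.tw_max)


def test_calibration_round_trip_preserves_flags(tmp_path, small_fit):
    small_fit.save(tmp_path / "cal.csv")
    back = pd.read_csv(tmp_path / "cal.csv")
    np.testing.assert_array_equal(back["clamp_mu_c"].to_numpy(), small_fit.clamp_mu_c)
    np.testing.assert_allclose(back["mu_c"].to_numpy(), small_fit.mu_c)
    import json

    side = json.loads((tmp_path / "cal.json").read_text())
    assert side["kappa_norm"] == pytest.approx(small_fit.kappa_norm)


def test_schedule_and_census_round_trip(tmp_path, small_setup, small_fit):
    from aedesfuse.abm import run_abm
    from aedesfuse.interventions import CampaignSpec, schedule_campaign

    _, city, _, target = small_setup
    sched = schedule_campaign(
        city, CampaignSpec(rounds=2, buildings_per_day=40), np.random.default_rng(6)
    )
    sched.to_csv(tmp_path / "s.csv", index=False)
    back = pd.read_csv(tmp_path / "s.csv")
    pd.testing.assert_frame_equal(back, sched)

    out = run_abm(city, small_fit, target.n0, seed=8, t_span=(0, 40))
    out.save(tmp_path)
    census = pd.read_csv(tmp_path / "abm_age_census.csv")
    rebuilt = np.zeros_like(out.age_hist)
    rebuilt[census["day"], census["age"]] = census["count"]
    np.testing.assert_array_equal(rebuilt, out.age_hist)


def test_abundance_matrix_round_trip_rank_one(tmp_path, small_setup):
    _, _, _, target = small_setup
    target.save(tmp_path / "a.csv", tmp_path / "w.csv")
    series = pd.read_csv(tmp_path / "a.csv")["N_city"].to_numpy()
    w = pd.read_csv(tmp_path / "w.csv")["weight"].to_numpy()
    m = np.outer(w / w.sum(), series)
    np.testing.assert_allclose(m, target.matrix(), rtol=1e-12)
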