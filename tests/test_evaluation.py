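"""Metric-suite tests: closed forms, oracles, decomposition additivity,
calibration, and horizon stratification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import richcast as rc
from conftest import toy_forecast


def _obs(site_ids, years, richness):
    frame = pd.DataFrame({
        "site_id": np.repeat(site_ids, len(years)),
        "year": np.tile(years, len(site_ids)),
    })
    frame["richness"] = np.asarray(richness, dtype=float)
    frame["observer_id"] = "o"
    return frame


def test_rmse_trivial_cases_and_loop_oracle():
    obs = _obs(["a"], [1, 2], [50.0, 52.0])
    perfect = toy_forecast(["a"], [1, 2], [50.0, 52.0], [1.0, 1.0])
    assert rc.rmse(perfect, obs) == 0.0
    pm1 = toy_forecast(["a"], [1, 2], [51.0, 51.0], [1.0, 1.0])
    assert rc.rmse(pm1, obs) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    y = rng.normal(50, 5, 40)
    m = rng.normal(50, 5, 40)
    fc = toy_forecast(["a"], list(range(40)), m, np.ones(40))
    ob = _obs(["a"], list(range(40)), y)
    brute = math.sqrt(sum((mi - yi) ** 2 for mi, yi in zip(m, y)) / 40)
    assert rc.rmse(fc, ob) == pytest.approx(brute)


def test_coverage_limits_and_zero_sd_convention():
    obs = _obs(["a"], [1, 2], [50.0, 52.0])
    huge = toy_forecast(["a"], [1, 2], [0.0, 0.0], [1e6, 1e6])
    assert rc.coverage(huge, obs) == 1.0
    zero = toy_forecast(["a"], [1, 2], [49.0, 51.0], [0.0, 0.0])
    assert rc.coverage(zero, obs) == 0.0
    exact = toy_forecast(["a"], [1, 2], [50.0, 52.0], [0.0, 0.0])
    assert rc.coverage(exact, obs) == 1.0


def test_coverage_calibration_of_well_specified_gaussian():
    rng = np.random.default_rng(1)
    n = 4000
    mean = rng.normal(50, 5, n)
    sd = rng.uniform(1, 4, n)
    y = rng.normal(mean, sd)
    fc = toy_forecast(["a"], list(range(n)), mean, sd)
    obs = _obs(["a"], list(range(n)), y)
    cov = rc.coverage(fc, obs, level=0.95)
    se = math.sqrt(0.95 * 0.05 / n)
    assert abs(cov - 0.95) < 3 * se


def test_mean_deviance_closed_form_and_monotonicity():
    obs = _obs(["a"], [1], [50.0])
    unit = toy_forecast(["a"], [1], [50.0], [1.0])
    assert rc.mean_deviance(unit, obs) == pytest.approx(math.log(2 * math.pi))
    wider = toy_forecast(["a"], [1], [50.0], [3.0])
    assert rc.mean_deviance(wider, obs) > rc.mean_deviance(unit, obs)


def test_mean_deviance_matches_gaussian_logpdf_oracle():
    rng = np.random.default_rng(2)
    n = 50
    mean = rng.normal(50, 5, n)
    sd = rng.uniform(0.5, 3, n)
    y = rng.normal(mean, sd)
    fc = toy_forecast(["a"], list(range(n)), mean, sd)
    obs = _obs(["a"], list(range(n)), y)
    oracle = float(np.mean(-2 * stats.norm.logpdf(y, mean, sd)))
    assert rc.mean_deviance(fc, obs) == pytest.approx(oracle)


def test_deviance_minimized_at_mse_variance():
    """For fixed predictions, mean deviance over a 1-D scan of sd^2 is
    minimized at sd^2 = mean squared error."""
    rng = np.random.default_rng(3)
    y = rng.normal(0, 2, 500)
    mse = np.mean(y**2)
    obs = _obs(["a"], list(range(500)), y)
    scan = np.linspace(0.5 * mse, 2.0 * mse, 81)
    devs = [
        rc.mean_deviance(
            toy_forecast(["a"], list(range(500)), np.zeros(500),
                         np.full(500, math.sqrt(v))), obs)
        for v in scan
    ]
    best = scan[int(np.argmin(devs))]
    assert best == pytest.approx(mse, rel=0.05)


def test_skill_baseline_vs_itself_is_zero():
    obs = _obs(["a", "b"], [1, 2], [50.0, 52.0, 48.0, 49.0])
    base = toy_forecast(["a", "b"], [1, 2], [51.0, 51.0, 47.0, 50.0], np.ones(4))
    skill = rc.skill_vs_baseline(base, base, obs)
    assert np.allclose(skill["d_abs_error"], 0.0)
    assert np.allclose(skill["d_deviance"], 0.0)


def test_skill_differences_and_mean_identity():
    obs = _obs(["a"], [1], [50.0])
    model = toy_forecast(["a"], [1], [53.0], [1.0])
    base = toy_forecast(["a"], [1], [48.0], [1.0])
    skill = rc.skill_vs_baseline(model, base, obs)
    assert skill["d_abs_error"].iloc[0] == pytest.approx(1.0)  # |3| - |2|
    rng = np.random.default_rng(4)
    n = 30
    obs = _obs(["a"], list(range(n)), rng.normal(50, 3, n))
    model = toy_forecast(["a"], list(range(n)), rng.normal(50, 3, n), np.ones(n))
    base = toy_forecast(["a"], list(range(n)), rng.normal(50, 3, n), np.ones(n))
    skill = rc.skill_vs_baseline(model, base, obs)
    me = np.abs(model["mean"] - obs["richness"]).mean()
    be = np.abs(base["mean"] - obs["richness"]).mean()
    assert skill["d_abs_error"].mean() == pytest.approx(me - be)


def test_skill_key_mismatch_raises():
    obs = _obs(["a"], [1, 2], [50.0, 51.0])
    model = toy_forecast(["a"], [1, 2], [50.0, 50.0], [1.0, 1.0])
    base = toy_forecast(["a"], [1, 3], [50.0, 50.0], [1.0, 1.0])
    with pytest.raises(ValueError, match="mismatch"):
        rc.skill_vs_baseline(model, base, obs)


def test_decompose_hand_example():
    """1 site, obs (50, 52), pred (53, 53): site term 4, annual term 1."""
    obs = _obs(["a"], [1, 2], [50.0, 52.0])
    fc = toy_forecast(["a"], [1, 2], [53.0, 53.0], [1.0, 1.0])
    d = rc.decompose_mse(fc, obs)
    assert d.site_component == pytest.approx(4.0)
    assert d.annual_component == pytest.approx(1.0)
    assert d.total == pytest.approx(5.0)


def test_decompose_constant_bias_and_perfect():
    obs = _obs(["a", "b"], [1, 2], [50.0, 52.0, 40.0, 42.0])
    biased = toy_forecast(["a", "b"], [1, 2], [53.0, 55.0, 43.0, 45.0], np.ones(4))
    d = rc.decompose_mse(biased, obs)
    assert d.site_component == pytest.approx(9.0)
    assert d.annual_component == pytest.approx(0.0, abs=1e-12)
    perfect = toy_forecast(["a", "b"], [1, 2], [50.0, 52.0, 40.0, 42.0], np.ones(4))
    d = rc.decompose_mse(perfect, obs)
    assert (d.site_component, d.annual_component, d.total) == (0.0, 0.0, 0.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 8))
def test_decomposition_additivity_property(seed, n_sites, n_years):
    """site + annual components equal the pooled MSE to 1e-9 relative on
    random instances (the within-site cross term cancels)."""
    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(n_sites)]
    years = list(range(n_years))
    y = rng.normal(50, 10, n_sites * n_years)
    m = rng.normal(50, 10, n_sites * n_years)
    obs = _obs(sites, years, y)
    fc = toy_forecast(sites, years, m, np.ones(n_sites * n_years))
    d = rc.decompose_mse(fc, obs)
    pooled_mse = float(np.mean((m - y) ** 2))
    assert d.total == pytest.approx(pooled_mse, rel=1e-9)
    assert d.site_component + d.annual_component == pytest.approx(d.total, rel=1e-9)


def test_metrics_by_horizon_partition_and_single_stratum():
    rng = np.random.default_rng(5)
    n = 60
    years = list(range(1, 7))
    sites = [f"s{i}" for i in range(10)]
    y = rng.normal(50, 3, n)
    obs = _obs(sites, years, y)
    fc = toy_forecast(sites, years, rng.normal(50, 3, n), np.full(n, 3.0),
                      horizon=years)
    table = rc.metrics_by_horizon(fc, obs)
    assert table["n"].sum() == n
    assert sorted(table["horizon"]) == years
    single = fc[fc["horizon"] == 1]
    t1 = rc.metrics_by_horizon(single, obs)
    assert t1["rmse"].iloc[0] == pytest.approx(rc.rmse(single, obs))
    assert t1["coverage95"].iloc[0] == pytest.approx(rc.coverage(single, obs))


def test_naive_coverage_grows_with_horizon_on_stationary_data():
    """A random-walk forecaster on stationary series over-covers at long
    horizons: its intervals expand as sqrt(h) while errors stay bounded."""
    rng = np.random.default_rng(6)
    rows_fc, rows_obs = [], []
    for i in range(150):
        series = 50 + rng.normal(0, 3, 22)
        fit = rc.fit_naive(series)
        mean, sd = rc.forecast_naive(fit, 10)
        future = 50 + rng.normal(0, 3, 10)
        for h in range(10):
            rows_fc.append((f"s{i}", h + 1, h + 1, mean[h], sd[h]))
            rows_obs.append((f"s{i}", h + 1, "o", future[h]))
    fc = pd.DataFrame(rows_fc, columns=["site_id", "year", "horizon", "mean", "sd"])
    obs = pd.DataFrame(rows_obs, columns=["site_id", "year", "observer_id", "richness"])
    table = rc.metrics_by_horizon(fc, obs).sort_values("horizon")
    cov = table["coverage95"].to_numpy()
    assert cov[-1] > cov[0]
    assert cov[-1] > 0.97


def test_empty_join_raises():
    obs = _obs(["a"], [1], [50.0])
    fc = toy_forecast(["b"], [1], [50.0], [1.0])
    with pytest.raises(ValueError):
        rc.rmse(fc, obs)
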