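"""Synthetic telemetry generator: OU moments, injected effects, ground truth."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from postcapture.config import ConfigurationError, SimConfig
from postcapture.metrics import centre_of_gravity, distance_series
from postcapture.synthetic import (
    AnimalSpec,
    EmptyDatasetError,
    expected_zero_crossing,
    monitoring_end_date,
    simulate_dataset,
    simulate_trajectory,
    write_dataset,
)

CAPTURE = dt.datetime(2022, 1, 10, 8, 0, tzinfo=dt.timezone.utc)


def _spec(ou_sd=150.0, capture=CAPTURE, method="box_trap"):
    return AnimalSpec(
        animal_id="a1",
        site_id="s1",
        capture_time=capture,
        method=method,
        sex="female",
        age_class="adult",
        centre_x=1000.0,
        centre_y=-2000.0,
        ou_sd_m=ou_sd,
    )


def test_degenerate_diffusion_sits_at_centre():
    cfg = SimConfig(
        ou_sd_m=0.0, obs_noise_m=0.0, cog_shift_m=0.0, step_suppression=0.0, fix_loss_prob=0.0
    )
    fx = simulate_trajectory(cfg, _spec(ou_sd=0.0), np.random.default_rng(0))
    assert len(fx) > 0
    assert np.allclose(fx["x_m"], 1000.0) and np.allclose(fx["y_m"], -2000.0)
    assert fx["timestamp_utc"].is_monotonic_increasing


def test_stationary_moments_without_effects():
    # ~9,200 hourly fixes across four independent animals at the same centre
    cfg = SimConfig(
        cog_shift_m=0.0,
        step_suppression=0.0,
        fix_loss_prob=0.0,
        obs_noise_m=0.0,
        fix_interval_h=1.0,
        seed=0,
    )
    capture = dt.datetime(2021, 12, 15, 0, 0, tzinfo=dt.timezone.utc)
    frames = [
        simulate_trajectory(cfg, _spec(capture=capture), np.random.default_rng(100 + i))
        for i in range(4)
    ]
    xy = pd.concat(frames)[["x_m", "y_m"]].to_numpy() - np.array([1000.0, -2000.0])
    n = len(xy)
    assert n > 9000
    # effective sample size for the OU mean under 1-h sampling, rho = e^(-1/12)
    rho = np.exp(-1.0 / 12.0)
    n_eff = n * (1 - rho) / (1 + rho)
    se_mean = 150.0 / np.sqrt(n_eff)
    assert np.abs(xy.mean(axis=0)).max() < 3 * se_mean
    assert np.std(xy, ddof=1) == pytest.approx(150.0, rel=0.10)


def test_capture_shift_elevates_early_distance_to_centre():
    cfg = SimConfig(cog_shift_m=300.0, cog_decay_days=5.0, step_suppression=0.0,
                    fix_loss_prob=0.0)
    early, late = [], []
    for i in range(1000):
        fx = simulate_trajectory(cfg, _spec(), np.random.default_rng(i))
        t = (fx["timestamp_utc"] - pd.Timestamp(CAPTURE)).dt.total_seconds() / 86400.0
        d = np.hypot(fx["x_m"] - 1000.0, fx["y_m"] + 2000.0)
        early.append(d[(t >= 0) & (t <= 1)].mean())
        late.append(d[(t >= 30) & (t <= 31)].mean())
    assert np.mean(early) > np.mean(late)
    # injected initial elevation is d0 = 300 m in expectation
    assert np.mean(early) - np.mean(late) > 150.0


def test_dataset_determinism_byte_identical(tmp_path):
    cfg = SimConfig(n_animals=6, seed=1)
    for sub in ("one", "two"):
        fixes, captures, truth = simulate_dataset(cfg)
        write_dataset(fixes, captures, truth, tmp_path / sub)
    for name in ("fixes.csv", "captures.csv", "truth.json"):
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


def test_empty_dataset_raises():
    with pytest.raises(EmptyDatasetError):
        simulate_dataset(SimConfig(n_animals=0))


def test_invalid_parameters_raise_configuration_error():
    with pytest.raises(ConfigurationError):
        SimConfig(ou_timescale_h=-1.0)
    with pytest.raises(ConfigurationError):
        SimConfig(step_suppression=1.0)
    with pytest.raises(ConfigurationError):
        SimConfig(season_start=dt.date(2022, 3, 1), season_end=dt.date(2021, 11, 1))
    with pytest.raises(ConfigurationError):
        SimConfig(method_mix={"box_trap": 0.5, "snare": 0.5})


def test_zero_crossing_closed_form_and_root_oracle():
    t_star = expected_zero_crossing(5.0, 76.0)
    assert t_star == pytest.approx(13.61, abs=0.01)
    # independent numeric root of the centred exponential
    c = 5.0 / 76.0 * (1.0 - np.exp(-76.0 / 5.0))
    root = brentq(lambda t: np.exp(-t / 5.0) - c, 1e-12, 76.0)
    assert t_star == pytest.approx(root, rel=1e-9)


def test_zero_crossing_limits_and_monotonicity():
    assert expected_zero_crossing(1e-9, 76.0) < 1e-6
    taus = np.linspace(0.5, 30, 40)
    ts = [expected_zero_crossing(t, 76.0) for t in taus]
    assert all(a < b for a, b in zip(ts, ts[1:]))
    horizons = np.linspace(20, 200, 40)
    th = [expected_zero_crossing(5.0, T) for T in horizons]
    assert all(a < b for a, b in zip(th, th[1:]))
    assert all(0 < expected_zero_crossing(tau, 76.0) < 76.0 for tau in taus)


def test_truth_entries_cover_methods_and_window():
    cfg = SimConfig(n_animals=40, seed=3)
    _, captures, truth = simulate_dataset(cfg)
    methods = set(captures["method"])
    assert {e.method for e in truth.entries} == methods
    for e in truth.entries:
        assert 0.0 < e.t_star_days < e.horizon_days
        assert e.tau_days == 5.0


def test_monitoring_end_spans_new_year():
    assert monitoring_end_date(dt.date(2021, 11, 2)) == dt.date(2022, 4, 15)
    assert monitoring_end_date(dt.date(2022, 2, 2)) == dt.date(2022, 4, 15)


def test_substreams_insertion_stable():
    # trajectories keyed by animal index: animal 3 identical whether or not
    # other animals exist
    cfg5 = SimConfig(n_animals=5, seed=9)
    cfg8 = SimConfig(n_animals=8, seed=9)
    fx5, cap5, _ = simulate_dataset(cfg5)
    fx8, cap8, _ = simulate_dataset(cfg8)
    a = fx5[fx5["animal_id"] == "a0003"].reset_index(drop=True)
    b = fx8[fx8["animal_id"] == "a0003"].reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_no_trend_in_distance_to_cog_without_effects():
    """Stationarity: under zero capture effects the distance to the COG has
    no time trend (HAC-robust slope test at alpha = 0.01, >= 48/50 seeds)."""
    import statsmodels.api as sm

    passes = 0
    capture = pd.Series(
        {"animal_id": "a1", "capture_time_utc": pd.Timestamp("2021-12-01T00:00:00Z")}
    )
    for seed in range(50):
        cfg = SimConfig(
            cog_shift_m=0.0, step_suppression=0.0, fix_loss_prob=0.0, seed=seed
        )
        fx = simulate_trajectory(
            cfg,
            _spec(capture=dt.datetime(2021, 12, 1, 0, 0, tzinfo=dt.timezone.utc)),
            np.random.default_rng(7000 + seed),
        )
        series = distance_series(fx, centre_of_gravity(fx), capture)
        # daily means over a 135-day window keep the HAC slope test calibrated
        daily = series.groupby(np.floor(series["t_days"]))["log_d_cog"].mean()
        X = sm.add_constant(daily.index.to_numpy())
        fit = sm.OLS(daily.to_numpy(), X).fit(cov_type="HAC", cov_kwds={"maxlags": 3})
        passes += fit.pvalues[1] > 0.01
    assert passes >= 48
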