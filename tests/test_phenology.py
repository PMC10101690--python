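"""Gompertz fitting, active-phase derivation, period classification and
root-pulse detection against generated truths."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treeflux.config import SimulationConfig
from treeflux import phenology as ph
from treeflux import synthetic as syn


# ---------------------------------------------------------------------------
# normalization


def _obs(tree, date, total, mature, width):
    rem = total - mature
    return {
        "tree_id": tree, "date": date, "n_a": rem * 0.5, "n_b": rem * 0.5,
        "n_c": mature, "n_total": total, "prev_ring_width_mm": width,
    }


def test_normalize_single_tree_unit_width_is_identity():
    obs = pd.DataFrame([_obs("T1", dt.date(2018, 6, 1), 10.0, 4.0, 1.0)])
    pooled, per_tree = ph.normalize_counts(obs)
    assert pooled["total_norm"].iloc[0] == pytest.approx(10.0)
    assert per_tree["mature_norm"].iloc[0] == pytest.approx(4.0)


def test_normalize_pools_identical_ratios():
    obs = pd.DataFrame([
        _obs("T1", dt.date(2018, 6, 1), 10.0, 2.0, 1.0),
        _obs("T2", dt.date(2018, 6, 1), 20.0, 4.0, 2.0),
    ])
    pooled, _ = ph.normalize_counts(obs)
    assert pooled["total_norm"].iloc[0] == pytest.approx(10.0)


def test_normalize_excludes_missing_width_with_warning():
    obs = pd.DataFrame([
        _obs("T1", dt.date(2018, 6, 1), 10.0, 2.0, 1.0),
        _obs("T2", dt.date(2018, 6, 1), 20.0, 4.0, np.nan),
    ])
    with pytest.warns(UserWarning):
        pooled, per_tree = ph.normalize_counts(obs)
    assert set(per_tree["tree_id"]) == {"T1"}
    assert pooled["total_norm"].iloc[0] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Gompertz fitting


def test_gompertz_fit_recovers_classical_parameterization():
    """Noise-free data from A=40, β=200, κ=0.08 recovered to 1e-4 relative."""
    a_true, beta_true, kappa_true = 40.0, 200.0, 0.08
    t = np.arange(0.0, 155.0, 7.0)
    y = a_true * np.exp(-beta_true * np.exp(-kappa_true * t))
    fit = ph.fit_gompertz(t, y)
    assert abs(fit.asymptote - a_true) / a_true < 1e-4
    assert abs(fit.rate - kappa_true) / kappa_true < 1e-4
    assert abs(fit.beta - beta_true) / beta_true < 1e-3
    assert fit.residual_sd < 1e-8


def test_gompertz_asymptote_reached_at_large_t():
    t = np.arange(110.0, 290.0, 7.0)
    y = syn.gompertz(t, 38.0, 155.0, 0.06)
    fit = ph.fit_gompertz(t, y)
    assert abs(fit.predict(1e4) - fit.asymptote) / fit.asymptote < 1e-3


def test_gompertz_requires_six_points():
    with pytest.raises(ValueError):
        ph.fit_gompertz(np.arange(5.0), np.arange(5.0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=st.floats(5.0, 80.0),
    t0=st.floats(140.0, 180.0),
    k=st.floats(0.03, 0.12),
)
def test_gompertz_fitted_curve_nondecreasing(a, t0, k):
    t = np.arange(110.0, 290.0, 7.0)
    rng = np.random.default_rng(1)
    y = np.maximum(syn.gompertz(t, a, t0, k) + rng.normal(0, 0.03 * a, len(t)), 0.0)
    fit = ph.fit_gompertz(t, y)
    curve = fit.predict(np.arange(100.0, 300.0))
    assert (np.diff(curve) >= -1e-9).all()


def test_parameter_recovery_over_simulated_stand():
    """Median relative parameter errors over noisy simulated trees."""
    rng = np.random.default_rng(2024)
    t = np.arange(115.0, 285.0, 7.0)
    err_a, err_k = [], []
    for _ in range(60):
        a, t0, k = rng.uniform(20, 60), rng.uniform(145, 165), rng.uniform(0.05, 0.09)
        y = syn.gompertz(t, a, t0, k) + rng.normal(0, 0.05 * a, len(t))
        fit = ph.fit_gompertz(t, np.maximum(y, 0.0))
        err_a.append(abs(fit.asymptote - a) / a)
        err_k.append(abs(fit.rate - k) / k)
    assert np.median(err_a) < 0.02
    assert np.median(err_k) < 0.10


# ---------------------------------------------------------------------------
# active phase and growth rate


def _fit_from_truth(a, t0, k):
    t = np.arange(110.0, 300.0, 5.0)
    return ph.fit_gompertz(t, syn.gompertz(t, a, t0, k))


def test_active_phase_zero_when_fits_identical():
    fit = _fit_from_truth(40.0, 153.0, 0.067)
    out = ph.derive_active_phase(fit, fit, np.arange(110.0, 300.0))
    np.testing.assert_allclose(out["n_ab"], 0.0, atol=1e-9)


def test_active_phase_peaks_between_inflections():
    total = _fit_from_truth(40.0, 150.0, 0.067)
    mature = _fit_from_truth(40.0, 180.0, 0.067)
    grid = np.arange(110.0, 300.0)
    out = ph.derive_active_phase(total, mature, grid)
    peak_doy = grid[out["n_ab"].to_numpy().argmax()]
    assert 150.0 <= peak_doy <= 180.0


def test_growth_rate_is_total_curve_increment_and_nonnegative():
    total = _fit_from_truth(40.0, 150.0, 0.067)
    mature = _fit_from_truth(40.0, 185.0, 0.05)
    grid = np.arange(110.0, 300.0)
    out = ph.derive_active_phase(total, mature, grid)
    assert (out["growth_rate"].to_numpy() >= -1e-12).all()
    np.testing.assert_allclose(
        out["growth_rate"].to_numpy()[1:], np.diff(total.predict(grid)), atol=1e-12
    )


def test_active_phase_recovery_from_noisy_stand():
    """Fitted n_ab tracks the simulation's phase-a+b truth within noise."""
    cfg = SimulationConfig(seed=21)
    obs, truth = syn.simulate_tracheid_counts(cfg)
    pooled, _ = ph.normalize_counts(obs)
    doy = pd.to_datetime(pooled["date"]).dt.dayofyear.to_numpy(float)
    total = ph.fit_gompertz(doy, pooled["total_norm"].to_numpy())
    mature = ph.fit_gompertz(doy, pooled["mature_norm"].to_numpy())
    grid = np.arange(doy.min(), doy.max())
    out = ph.derive_active_phase(total, mature, grid)
    g = cfg.gompertz
    truth_ab = np.zeros(len(grid))
    for _, t in truth.iterrows():
        truth_ab += (
            syn.gompertz(grid, t["asymptote"], t["midpoint_doy"], t["rate"])
            - syn.gompertz(grid, t["asymptote"], t["maturation_midpoint_doy"],
                           t["maturation_rate"])
        ) / len(truth)
    noise_envelope = 3.0 * g.count_noise_frac * g.asymptote / np.sqrt(cfg.n_trees)
    assert np.max(np.abs(out["n_ab"].to_numpy() - truth_ab)) < noise_envelope


def test_grid_must_be_increasing():
    fit = _fit_from_truth(40.0, 153.0, 0.067)
    with pytest.raises(ValueError):
        ph.derive_active_phase(fit, fit, np.array([3.0, 2.0, 1.0]))


# ---------------------------------------------------------------------------
# growth periods


def test_max_rate_interval_centered_on_peak():
    total = _fit_from_truth(40.0, 153.0, 0.067)
    mature = _fit_from_truth(40.0, 188.0, 0.05)
    periods = ph.classify_growth_periods(total, mature, 2018)
    start, end = periods["max_production"]
    mid = start + (end - start) / 2
    peak = dt.date(2018, 1, 1) + dt.timedelta(days=round(total.midpoint) - 1)
    assert abs((mid - peak).days) <= 2


def test_zero_threshold_spans_entire_grid():
    total = _fit_from_truth(40.0, 153.0, 0.067)
    mature = _fit_from_truth(40.0, 188.0, 0.05)
    grid = np.arange(100.0, 320.0)
    periods = ph.classify_growth_periods(
        total, mature, 2018, doy_grid=grid, rate_threshold_frac=0.0
    )
    start, end = periods["tracheid_production"]
    assert start == dt.date(2018, 4, 10) and end == dt.date(2018, 11, 15)


def test_configured_production_window_recovered_within_three_days():
    """Truth built to span May 7 - Jul 31 at the default 5% rate threshold."""
    # solve the 5% crossings of the normalized Gompertz rate for (t0, k)
    v_lo, v_hi = 5.7522, 0.019326  # v·e^{1-v} = 0.05 roots
    span = (np.log(v_lo) - np.log(v_hi)) / (212.0 - 127.0)
    k = span
    t0 = 127.0 + np.log(v_lo) / k
    total = _fit_from_truth(40.0, t0, k)
    mature = _fit_from_truth(40.0, t0 + 35.0, 0.05)
    periods = ph.classify_growth_periods(total, mature, 2018)
    start, end = periods["tracheid_production"]
    assert abs((start - dt.date(2018, 5, 7)).days) <= 3
    assert abs((end - dt.date(2018, 7, 31)).days) <= 3


def test_raising_threshold_never_widens_production():
    total = _fit_from_truth(40.0, 153.0, 0.067)
    mature = _fit_from_truth(40.0, 188.0, 0.05)
    prev = None
    for f1 in (0.02, 0.05, 0.10, 0.25):
        p = ph.classify_growth_periods(total, mature, 2018, rate_threshold_frac=f1)
        start, end = p["tracheid_production"]
        if prev is not None:
            assert start >= prev[0] and end <= prev[1]
        prev = (start, end)


def test_nested_max_periods_and_ordering():
    total = _fit_from_truth(40.0, 153.0, 0.067)
    mature = _fit_from_truth(40.0, 188.0, 0.05)
    p = ph.classify_growth_periods(total, mature, 2018)
    prod, prod_max = p["tracheid_production"], p["max_production"]
    assert prod[0] <= prod_max[0] <= prod_max[1] <= prod[1]
    ew, tr, lw = p["earlywood"], p["ew_lw_transition"], p["latewood"]
    assert ew[1] < tr[0] <= tr[1] < lw[0]


def test_empty_period_raises_naming_threshold():
    total = _fit_from_truth(40.0, 153.0, 0.067)
    mature = _fit_from_truth(40.0, 188.0, 0.05)
    with pytest.raises(ValueError, match="tracheid_production"):
        ph.classify_growth_periods(total, mature, 2018, rate_threshold_frac=1.0 + 1e-9)


# ---------------------------------------------------------------------------
# root periods


def _root_frame(series_by_scanner):
    rows = []
    dates = pd.date_range("2018-05-01", periods=len(next(iter(series_by_scanner.values()))))
    for scanner, vals in series_by_scanner.items():
        for d, v in zip(dates, vals):
            rows.append({"scanner_id": scanner, "date": d.date(), "elongation_mm": v})
    return pd.DataFrame(rows)


def test_single_pulse_gives_one_bracketing_period():
    vals = np.zeros(120)
    vals[40:60] = 1.0
    periods = ph.detect_root_periods(_root_frame({1: vals}), min_amp=0.3)
    assert len(periods.periods) == 1
    start, end = periods["root_period_I"]
    assert start <= dt.date(2018, 6, 15) <= end


def test_three_disjoint_pulses_in_order(env, sim_config):
    roots = syn.simulate_root_growth(env, sim_config)
    periods = ph.detect_root_periods(roots)
    names = list(periods.periods)
    assert names == ["root_period_I", "root_period_II", "root_period_III"]
    starts = [periods[n][0] for n in names]
    assert starts == sorted(starts)
    for name, pulse in zip(names, sim_config.root_pulses):
        start, end = periods[name]
        assert abs((start - pulse.start).days) <= 12
        assert abs((end - pulse.end).days) <= 12


def test_min_amp_above_max_gives_zero_periods():
    vals = np.zeros(120)
    vals[40:60] = 1.0
    periods = ph.detect_root_periods(_root_frame({1: vals}), min_amp=5.0)
    assert len(periods.periods) == 0


def test_all_zero_series_is_not_an_error():
    periods = ph.detect_root_periods(_root_frame({1: np.zeros(60), 2: np.zeros(60)}))
    assert len(periods.periods) == 0


def test_growth_periods_validate_ordering():
    with pytest.raises(ValueError):
        ph.GrowthPeriods({"bad": (dt.date(2018, 7, 1), dt.date(2018, 6, 1))})
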