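"""Wavelet coherence: transform localization, coherence identities,
lead/lag phase conventions, AR(1) significance and summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treeflux import wavelet as wv
from treeflux.phenology import GrowthPeriods


def make_series(values, start="2018-05-01"):
    n = len(values)
    return wv.DailySeries(pd.date_range(start, periods=n, freq="D"),
                          np.asarray(values, float), np.zeros(n, bool))


# ---------------------------------------------------------------------------
# gap interpolation


def test_linear_midpoint_fill():
    dates = pd.to_datetime(["2018-06-01", "2018-06-03"])
    out = wv.interpolate_gaps(dates, [-26.0, -28.0], max_gap_fraction=0.5)
    assert len(out.values) == 3
    assert out.values[1] == pytest.approx(-27.0)
    assert list(out.gap_mask) == [False, True, False]


def test_no_gaps_is_identity():
    dates = pd.date_range("2018-06-01", periods=5)
    vals = [1.0, 2.0, 3.0, 2.0, 1.0]
    out = wv.interpolate_gaps(dates, vals)
    np.testing.assert_array_equal(out.values, vals)
    assert not out.gap_mask.any()
    assert out.gap_fraction == 0.0


def test_leading_and_trailing_gaps_trimmed():
    dates = pd.date_range("2018-06-01", periods=6)
    vals = [np.nan, 1.0, np.nan, 3.0, 4.0, np.nan]
    out = wv.interpolate_gaps(dates, vals, max_gap_fraction=0.5)
    assert out.dates[0] == pd.Timestamp("2018-06-02")
    assert out.dates[-1] == pd.Timestamp("2018-06-05")
    assert out.values[1] == pytest.approx(2.0)


def test_gap_ceiling_enforced():
    dates = pd.to_datetime(["2018-06-01", "2018-06-30"])
    with pytest.raises(ValueError, match="gap fraction"):
        wv.interpolate_gaps(dates, [0.0, 1.0], max_gap_fraction=0.10)


def test_fill_error_small_on_smooth_series(rng):
    """~2% random gaps on a smooth series fill with RMSE << series SD."""
    n = 200
    t = np.arange(n)
    truth = np.sin(2 * np.pi * t / 40) + 0.3 * np.sin(2 * np.pi * t / 90)
    rmses = []
    for _ in range(20):
        vals = truth.copy()
        gaps = rng.choice(np.arange(1, n - 1), size=4, replace=False)
        vals[gaps] = np.nan
        out = wv.interpolate_gaps(pd.date_range("2018-05-01", periods=n), vals)
        rmses.append(np.sqrt(np.mean((out.values[gaps] - truth[gaps]) ** 2)))
    assert np.mean(rmses) < 0.05 * truth.std()


# ---------------------------------------------------------------------------
# transform


def test_cwt_peak_at_sinusoid_period():
    n = 256
    x = np.sin(2 * np.pi * np.arange(n) / 32.0)
    W, periods, coi = wv.cwt_morlet(x, max_period=64)
    power = (np.abs(W) ** 2).mean(axis=1)
    peak = periods[power.argmax()]
    voice = 2 ** (1 / 12)
    assert 32.0 / voice <= peak <= 32.0 * voice


def test_cwt_constant_series_near_zero():
    W, _, _ = wv.cwt_morlet(np.full(128, 7.3))
    assert np.abs(W).max() < 1e-10


def test_cwt_linearity():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(128)
    y = rng.standard_normal(128)
    Wx, _, _ = wv.cwt_morlet(x)
    Wy, _, _ = wv.cwt_morlet(y)
    Wxy, _, _ = wv.cwt_morlet(2.0 * x - 0.5 * y)
    np.testing.assert_allclose(Wxy, 2.0 * Wx - 0.5 * Wy, atol=1e-10)


def test_cwt_truncates_overlong_periods_with_warning():
    with pytest.warns(UserWarning, match="truncated"):
        _, periods, _ = wv.cwt_morlet(np.random.default_rng(1).standard_normal(64),
                                      max_period=1000.0)
    assert periods[-1] <= 32.0 + 1e-9


# ---------------------------------------------------------------------------
# coherence identities


def test_self_coherence_is_one_with_zero_phase(rng):
    x = make_series(rng.standard_normal(150).cumsum())
    res = wv.coherence(x, x, max_period=32)
    inside = res.inside_coi
    assert res.coherence[inside].min() > 1.0 - 1e-9
    assert np.abs(res.phase[inside]).max() < 1e-9


def test_antiphase_pair_has_phase_pi(rng):
    v = rng.standard_normal(150).cumsum()
    res = wv.coherence(make_series(v), make_series(-v), max_period=32)
    inside = res.inside_coi
    assert res.coherence[inside].min() > 1.0 - 1e-9
    assert np.abs(np.abs(res.phase[inside]) - np.pi).max() < 1e-9


def test_lag_recovered_as_quarter_period_phase(rng):
    """y = x delayed 8 d at period 32 d: phase π/2, lag 8 ± 1 d."""
    n = 192
    x = np.sin(2 * np.pi * np.arange(n) / 32.0) + 0.02 * rng.standard_normal(n)
    y = np.roll(x, 8)
    res = wv.coherence(make_series(x), make_series(y), max_period=48)
    i = int(np.argmin(np.abs(res.periods - 32.0)))
    sel = res.inside_coi[i]
    phase = np.median(res.phase[i, sel])
    assert phase == pytest.approx(np.pi / 2, abs=0.15)
    lag = phase * res.periods[i] / (2 * np.pi)
    assert abs(lag - 8.0) <= 1.0


@pytest.mark.parametrize("lag", [2, 5, 10])
def test_lag_scan_within_one_day(lag, rng):
    n = 192
    base = np.sin(2 * np.pi * np.arange(n) / 24.0) + 0.02 * rng.standard_normal(n)
    res = wv.coherence(make_series(base), make_series(np.roll(base, lag)), max_period=48)
    i = int(np.argmin(np.abs(res.periods - 24.0)))
    sel = res.inside_coi[i]
    est = np.median(res.phase[i, sel]) * res.periods[i] / (2 * np.pi)
    assert abs(est - lag) <= 1.0


def test_coherence_symmetry(rng):
    x = make_series(rng.standard_normal(140))
    y = make_series(rng.standard_normal(140))
    rxy = wv.coherence(x, y, max_period=32)
    ryx = wv.coherence(y, x, max_period=32)
    np.testing.assert_allclose(rxy.coherence, ryx.coherence, atol=1e-10)
    np.testing.assert_allclose(rxy.phase, -ryx.phase, atol=1e-10)


def test_time_shift_covariance(rng):
    """Shifting both series by k days shifts the map by k inside the cone."""
    n, k = 160, 12
    v1 = rng.standard_normal(n + k).cumsum()
    v2 = rng.standard_normal(n + k).cumsum()
    r0 = wv.coherence(make_series(v1[:n]), make_series(v2[:n]), max_period=16)
    r1 = wv.coherence(make_series(v1[k:]), make_series(v2[k:]), max_period=16)
    # compare a strip well inside both cones
    i = int(np.argmin(np.abs(r0.periods - 8.0)))
    a = r0.coherence[i, k + 40: n - 40]
    b = r1.coherence[i, 40: n - k - 40]
    np.testing.assert_allclose(a, b, atol=0.12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_coherence_bounded_for_random_inputs(seed):
    rng = np.random.default_rng(seed)
    x = make_series(rng.standard_normal(96))
    y = make_series(rng.standard_normal(96))
    res = wv.coherence(x, y, max_period=24)
    assert np.all(res.coherence >= 0.0) and np.all(res.coherence <= 1.0)
    assert np.all(res.phase > -np.pi - 1e-12) and np.all(res.phase <= np.pi + 1e-12)


# ---------------------------------------------------------------------------
# significance


def test_alpha_one_marks_every_cell_inside_cone(rng):
    x = make_series(rng.standard_normal(120))
    y = make_series(rng.standard_normal(120))
    res = wv.coherence(x, y, max_period=32)
    res = wv.significance(res, x, y, n_surrogates=100, alpha=1.0, seed=0)
    np.testing.assert_array_equal(res.sig_mask, res.inside_coi)


def test_injected_band_limited_coupling_detected(rng):
    n = 240
    t = np.arange(n)
    carrier = np.sin(2 * np.pi * t / 16.0)
    window = (t >= 80) & (t <= 160)
    x = rng.standard_normal(n) * 0.8 + carrier * window * 2.0
    y = rng.standard_normal(n) * 0.8 + carrier * window * 2.0
    xs, ys = make_series(x), make_series(y)
    res = wv.coherence(xs, ys, max_period=40)
    res = wv.significance(res, xs, ys, n_surrogates=150, alpha=0.05, seed=3)
    band = (res.periods >= 12) & (res.periods <= 22)
    inside = res.inside_coi
    in_win = np.zeros(n, bool)
    in_win[80:161] = True
    # "far" region: > ~2 smoothing lengths from the window edges
    far = np.zeros(n, bool)
    far[:40] = True
    far[200:] = True
    frac_in = res.sig_mask[band[:, None] & in_win[None, :] & inside].mean()
    frac_far = res.sig_mask[band[:, None] & far[None, :] & inside].mean()
    assert frac_in > 0.5
    assert frac_in > frac_far + 0.3


def test_degenerate_series_rejected():
    with pytest.raises(ValueError):
        wv.ar1_params(np.full(50, 3.0))


def test_significance_reproducible_under_seed(rng):
    x = make_series(rng.standard_normal(100))
    y = make_series(rng.standard_normal(100))
    r1 = wv.significance(wv.coherence(x, y, max_period=24), x, y,
                         n_surrogates=100, alpha=0.05, seed=7)
    r2 = wv.significance(wv.coherence(x, y, max_period=24), x, y,
                         n_surrogates=100, alpha=0.05, seed=7)
    np.testing.assert_array_equal(r1.sig_mask, r2.sig_mask)


# ---------------------------------------------------------------------------
# lead/lag summary


def test_lead_lag_summary_recovers_constructed_lag(rng):
    n = 180
    x = np.sin(2 * np.pi * np.arange(n) / 16.0) + 0.05 * rng.standard_normal(n)
    y = np.roll(x, 4)
    xs, ys = make_series(x), make_series(y)
    res = wv.coherence(xs, ys, max_period=40)
    res = wv.significance(res, xs, ys, n_surrogates=120, alpha=0.05, seed=5)
    periods = GrowthPeriods({"whole": (xs.dates[0].date(), xs.dates[-1].date())})
    out = wv.lead_lag_summary(res, periods, bands=[(8.0, 24.0)])
    row = out.iloc[0]
    assert row["frac_significant"] > 0.3
    assert row["lag_days"] == pytest.approx(4.0, abs=1.0)
    assert 0 < row["mean_phase_rad"] < np.pi


def test_lead_lag_summary_zero_significance_row(rng):
    x = make_series(rng.standard_normal(100))
    y = make_series(rng.standard_normal(100))
    res = wv.coherence(x, y, max_period=24)
    res.sig_mask = np.zeros_like(res.coherence, bool)
    periods = {"quiet": (x.dates[0].date(), x.dates[-1].date())}
    out = wv.lead_lag_summary(res, periods, bands=[(4.0, 8.0)])
    assert out["frac_significant"].iloc[0] == 0.0
    assert np.isnan(out["lag_days"].iloc[0])


def test_lead_lag_requires_significance_first(rng):
    x = make_series(rng.standard_normal(100))
    res = wv.coherence(x, x, max_period=24)
    with pytest.raises(ValueError):
        wv.lead_lag_summary(res, {"a": (x.dates[0].date(), x.dates[-1].date())})


def test_circular_mean_handles_phase_wrap():
    """Phases clustered at ±π average to magnitude ≈ π, not 0."""
    phases = np.array([np.pi - 0.05, -np.pi + 0.05, np.pi - 0.02, -np.pi + 0.03])
    mean = np.angle(np.exp(1j * phases).mean())
    assert abs(abs(mean) - np.pi) < 0.1
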