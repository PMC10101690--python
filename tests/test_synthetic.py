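"""Generator correctness: determinism, physical invariants, constructed
identities of the δ¹³C allocation truth, and the chamber forward model
checked against independent numerical integration."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from treeflux.config import R_VPDB, SimulationConfig
from treeflux import synthetic as syn
from treeflux.chamber import delta_from_fluxes


# ---------------------------------------------------------------------------
# environment


def test_environment_deterministic_under_fixed_seed(sim_config):
    a = syn.simulate_environment(sim_config)
    b = syn.simulate_environment(sim_config)
    assert (a.time == b.time).all()
    for attr in ("air_t", "soil_t", "par", "soil_moisture", "precipitation"):
        np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))


def test_environment_par_zero_at_night(env):
    night = syn.is_night(env.time)
    assert night.any() and (~night).any()
    assert (env.par[night] == 0).all()
    assert (env.par >= 0).all()


def test_environment_minimum_moisture_in_dry_window(env, sim_config):
    df = env.to_frame()
    df["date"] = df["timestamp"].dt.date
    daily_min = df.groupby("date")["soil_moisture"].min()
    trough = daily_min.idxmin()
    assert sim_config.dry_start <= trough <= sim_config.dry_end
    # decline is monotone inside the window
    window = daily_min[(daily_min.index >= sim_config.dry_start)
                       & (daily_min.index <= sim_config.dry_end)]
    assert (np.diff(window.to_numpy()) <= 1e-12).all()


def test_environment_timestamps_regular(env):
    step = np.diff(env.time.asi8)
    assert (step == step[0]).all() and step[0] > 0


def test_dry_window_outside_season_rejected():
    with pytest.raises(Exception):
        SimulationConfig(dry_start=dt.date(2018, 10, 5), dry_end=dt.date(2018, 10, 9))


# ---------------------------------------------------------------------------
# true fluxes


def test_true_flux_invariants(truth, env):
    assert (truth.stem_flux >= 0).all()
    assert (truth.soil_flux >= 0).all()
    assert (truth.shoot_flux[env.par == 0] == 0).all()
    assert (truth.shoot_flux[env.par > 0] > 0).all()
    for d in (truth.delta_shoot, truth.delta_stem, truth.delta_soil):
        assert (d >= -40).all() and (d <= 0).all()


def test_stem_flux_constant_when_temperature_and_growth_decoupled(env):
    cfg = SimulationConfig(seed=2, stem_resp_temp_coef=0.0, stem_growth_coupling=0.0)
    truth = syn.simulate_true_fluxes(env, cfg)
    np.testing.assert_allclose(truth.stem_flux, cfg.stem_resp_base, rtol=1e-12)


def test_allocation_lag_is_exact_shift(env):
    cfg = SimulationConfig(
        seed=5, allocation_lag_stem_days=3, fractionation_stem=0.0,
        coupling_base=1.0, coupling_high=1.0,
    )
    truth = syn.simulate_true_fluxes(env, cfg)
    d = truth.daily_delta
    lag = cfg.allocation_lag_stem_days
    np.testing.assert_allclose(
        d["delta_stem"].to_numpy()[lag:], d["delta_shoot"].to_numpy()[:-lag], atol=1e-12
    )


def test_fractionation_offsets_stem_delta(env):
    cfg = SimulationConfig(
        seed=5, allocation_lag_stem_days=0, fractionation_stem=4.5,
        coupling_base=1.0, coupling_high=1.0,
    )
    truth = syn.simulate_true_fluxes(env, cfg)
    diff = truth.daily_delta["delta_shoot"] - truth.daily_delta["delta_stem"]
    np.testing.assert_allclose(diff.to_numpy(), 4.5, atol=1e-12)


# ---------------------------------------------------------------------------
# chamber forward model


def test_closure_trace_zero_flux_stays_ambient():
    t = np.arange(100.0)
    c = syn.closure_trace(t, 0.0, 400.0, 400.0, 80.0, 0.4, 0.001, 24.055)
    np.testing.assert_allclose(c, 400.0, rtol=1e-14)


def test_closure_trace_linear_limit_small_leak():
    t = np.arange(100.0)
    c = syn.closure_trace(t, 1.0, 400.0, 400.0, 80.0, 0.4, 0.0, 24.055)
    slope = 1.0 * 0.4 * 24.055 / 80.0
    np.testing.assert_allclose(c, 400.0 + slope * t, rtol=1e-12)


def test_closure_trace_matches_numerical_ode_oracle():
    """Analytic trace equals independent stiff-ODE integration to 1e-9."""
    t = np.arange(201.0)
    F, V, S, q, mv, amb = 1.0, 80.0, 0.4, 0.001, 24.055, 400.0
    k = S * mv / V
    sol = solve_ivp(
        lambda _t, c: [F * k + q * (amb - c[0])], (0, 200), [amb],
        t_eval=t, rtol=1e-12, atol=1e-12, method="LSODA",
    )
    analytic = syn.closure_trace(t, F, amb, amb, V, S, q, mv)
    np.testing.assert_allclose(analytic, sol.y[0], rtol=1e-9, atol=1e-9)


def test_forward_model_conserves_imposed_flux():
    """Differencing a noise-free trace at t=0 recovers F·S·V_mol/V."""
    t = np.arange(100.0)
    F, V, S, q, mv = 0.7, 2.5, 0.1, 1e-6, 24.055
    c = syn.closure_trace(t, F, 400.0, 400.0, V, S, q, mv)
    slope0 = c[1] - c[0]
    assert abs(slope0 - F * S * mv / V) / (F * S * mv / V) < 1e-6


def test_delta_construction_identity():
    """Splitting a flux by the configured δ and converting back is exact."""
    for delta in (-35.0, -26.2, -5.0):
        r = R_VPDB * (1 + delta / 1000.0)
        f12 = 1.3 / (1 + r)
        f13 = 1.3 - f12
        assert abs(delta_from_fluxes(f12, f13) - delta) < 1e-9


def test_closures_deterministic_and_scheduled(truth, sim_config):
    a = syn.simulate_chamber_closures(truth, sim_config, kinds=("soil",))
    b = syn.simulate_chamber_closures(truth, sim_config, kinds=("soil",))
    assert len(a) == len(b) > 0
    np.testing.assert_array_equal(a[0].c12, b[0].c12)
    spec = sim_config.chambers["soil"]
    per_day = {}
    for rec in a:
        per_day.setdefault(rec.start.date(), 0)
        per_day[rec.start.date()] += 1
        assert len(rec.time_s) == spec.duration_s + 1
    assert max(per_day.values()) == spec.closures_per_day


def test_closure_record_validates_traces():
    with pytest.raises(ValueError):
        syn.ClosureRecord("x", "stem", pd.Timestamp("2018-06-01"),
                          np.arange(10.0), np.zeros(9), np.zeros(10), 2.5, 0.1, 0.0)


# ---------------------------------------------------------------------------
# tracheids


def test_tracheid_counts_noise_free_on_truth_curves():
    cfg = SimulationConfig(seed=4)
    cfg.gompertz.count_noise_frac = 0.0
    obs, truth = syn.simulate_tracheid_counts(cfg)
    for _, t in truth.iterrows():
        sub = obs[obs["tree_id"] == t["tree_id"]]
        doy = pd.to_datetime(sub["date"]).dt.dayofyear.to_numpy(float)
        expect = syn.gompertz(doy, t["asymptote"], t["midpoint_doy"], t["rate"]) * t["prev_ring_width_mm"]
        np.testing.assert_allclose(sub["n_total"].to_numpy(), expect, rtol=1e-10)
    # phase identity holds exactly
    np.testing.assert_allclose(
        obs["n_total"].to_numpy(),
        (obs["n_a"] + obs["n_b"] + obs["n_c"]).to_numpy(), rtol=1e-10,
    )


def test_tracheid_truth_shares_asymptote_between_total_and_mature():
    cfg = SimulationConfig(seed=4)
    cfg.gompertz.count_noise_frac = 0.0
    obs, truth = syn.simulate_tracheid_counts(cfg)
    # late-season mature counts approach the total asymptote
    last = obs[obs["date"] == obs["date"].max()]
    np.testing.assert_allclose(
        last["n_c"].to_numpy(), last["n_total"].to_numpy(), rtol=0.05
    )


def test_tracheid_counts_reproducible(sim_config):
    a, _ = syn.simulate_tracheid_counts(sim_config)
    b, _ = syn.simulate_tracheid_counts(sim_config)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# NSC


def test_nsc_wsc_is_sum_of_sugars(sim_config):
    nsc = syn.simulate_nsc_series(sim_config)
    phloem = nsc[nsc["organ"] == "phloem"]
    wide = phloem.pivot_table(index=["date", "replicate"], columns="compound",
                              values="conc_mg_g")
    np.testing.assert_allclose(
        wide["wsc"].to_numpy(),
        (wide["sucrose"] + wide["glucose"] + wide["fructose"]).to_numpy(),
        rtol=1e-12,
    )


def test_nsc_starch_depletion_across_transition(sim_config):
    nsc = syn.simulate_nsc_series(sim_config)
    starch = nsc[(nsc["organ"] == "phloem") & (nsc["compound"] == "starch")]
    mean = starch.groupby("date")["conc_mg_g"].mean()
    doy = pd.to_datetime(mean.index).dayofyear
    peak = mean[doy <= 200].max()
    trough = mean[(doy >= 205) & (doy <= 230)].min()
    assert abs(peak - 72) < 72 * 0.15
    assert abs(trough - 26) < 26 * 0.3
    assert peak > 2 * trough  # the configured remobilization drop


def test_nsc_sucrose_share_of_wsc(sim_config):
    nsc = syn.simulate_nsc_series(sim_config)
    phloem = nsc[nsc["organ"] == "phloem"]
    wide = phloem.pivot_table(index=["date", "replicate"], columns="compound",
                              values="conc_mg_g")
    share = (wide["sucrose"] / wide["wsc"]).mean()
    assert abs(share - 0.34) < 0.04


def test_nsc_starch_delta_more_stable_than_sucrose(sim_config):
    nsc = syn.simulate_nsc_series(sim_config)
    phloem = nsc[nsc["organ"] == "phloem"]
    by_date = phloem.pivot_table(index="date", columns="compound", values="d13C_permil")
    assert by_date["starch"].std() < by_date["sucrose"].std()


# ---------------------------------------------------------------------------
# roots


def test_root_growth_pulses_fall_in_configured_windows(env, sim_config):
    roots = syn.simulate_root_growth(env, sim_config)
    roots["date"] = pd.to_datetime(roots["date"])
    for s, pulse in zip((1, 2, 3), sim_config.root_pulses):
        # scanner s is the dominant recorder of pulse s (by construction)
        sub = roots[roots["scanner_id"] == s].set_index("date")["elongation_mm"]
        sm = sub.rolling(5, center=True, min_periods=1).mean()
        peak_day = sm.idxmax().date()
        assert pulse.start <= peak_day <= pulse.end
    assert (roots["elongation_mm"] >= 0).all()


def test_root_growth_zero_amplitude_all_zero(env):
    cfg = SimulationConfig(seed=9, root_noise_sd_mm=0.0)
    for p in cfg.root_pulses:
        p.amplitude_mm = 0.0
    roots = syn.simulate_root_growth(env, cfg)
    assert (roots["elongation_mm"] == 0).all()


def test_root_growth_reproducible(env, sim_config):
    a = syn.simulate_root_growth(env, sim_config)
    b = syn.simulate_root_growth(env, sim_config)
    pd.testing.assert_frame_equal(a, b)
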