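"""Synthetic field-season generators with known ground truth.

Every downstream stage of the package (chamber flux inversion, xylogenesis
phenology, environmental-response models, wavelet coherence) is exercised
against data produced here, so each generator carries its truth alongside the
noisy observations it emits.

The generators emulate one growing season of a boreal Scots pine stand:

* half-hourly environmental drivers with a configurable late-season dry-down,
* "true" shoot CO₂ influx, stem and soil CO₂ effluxes and the δ¹³C of each
  flux, with assimilate δ¹³C propagated to stem/soil with allocation lags,
  apparent respiratory fractionation and demand-dependent coupling strength,
* per-closure chamber ¹²CO₂/¹³CO₂ concentration traces at 1-s resolution
  (the forward model whose inversion lives in :mod:`treeflux.chamber`),
* weekly tracheid counts per phenophase for several trees drawn from
  tree-specific Gompertz truths,
* phloem and root non-structural carbohydrate concentration and δ¹³C series,
* daily fibrous-root elongation per scanner with pulse-period structure.

Determinism: every generator derives its RNG from ``config.seed`` plus a
fixed per-generator offset, so a fixed seed gives byte-identical outputs
regardless of call order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import R_VPDB, ChamberKind, SimulationConfig

__all__ = [
    "EnvironmentSeries",
    "TrueFluxSeries",
    "ClosureRecord",
    "simulate_environment",
    "simulate_true_fluxes",
    "simulate_chamber_closures",
    "simulate_tracheid_counts",
    "simulate_nsc_series",
    "simulate_root_growth",
    "gompertz",
    "gompertz_rate",
    "is_night",
    "closure_trace",
]

# fixed RNG stream offsets so generators are independent and order-free
_ENV_STREAM = 11
_DELTA_STREAM = 23
_CLOSURE_STREAM = 37
_TRACHEID_STREAM = 53
_NSC_STREAM = 71
_ROOT_STREAM = 89


# ---------------------------------------------------------------------------
# containers


@dataclass
class EnvironmentSeries:
    """Half-hourly environmental drivers for one season."""

    time: pd.DatetimeIndex
    air_t: np.ndarray            # °C
    soil_t: np.ndarray           # °C
    par: np.ndarray              # μmol m⁻² s⁻¹
    soil_moisture: np.ndarray    # m³ m⁻³
    precipitation: np.ndarray    # mm per 30-min step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.time,
                "air_T": self.air_t,
                "soil_T": self.soil_t,
                "PAR": self.par,
                "soil_moisture": self.soil_moisture,
                "precip": self.precipitation,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnvironmentSeries":
        t = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        return cls(
            time=t,
            air_t=df["air_T"].to_numpy(float),
            soil_t=df["soil_T"].to_numpy(float),
            par=df["PAR"].to_numpy(float),
            soil_moisture=df["soil_moisture"].to_numpy(float),
            precipitation=df["precip"].to_numpy(float),
        )


@dataclass
class TrueFluxSeries:
    """Ground-truth fluxes and flux δ¹³C on the environmental grid.

    ``daily_delta`` holds the day-resolved δ¹³C truth (the allocation model
    operates on daily assimilate signals); the grid arrays are its
    piecewise-daily expansion.
    """

    time: pd.DatetimeIndex
    shoot_flux: np.ndarray   # influx ≥ 0, μmol m⁻² s⁻¹ (leaf area basis)
    stem_flux: np.ndarray    # efflux ≥ 0
    soil_flux: np.ndarray    # efflux ≥ 0
    delta_shoot: np.ndarray  # ‰ V-PDB
    delta_stem: np.ndarray
    delta_soil: np.ndarray
    par: np.ndarray          # carried from the driver series for scheduling
    daily_delta: pd.DataFrame = field(repr=False)

    def flux(self, kind: ChamberKind) -> np.ndarray:
        return {"shoot": self.shoot_flux, "stem": self.stem_flux, "soil": self.soil_flux}[kind]

    def delta(self, kind: ChamberKind) -> np.ndarray:
        return {"shoot": self.delta_shoot, "stem": self.delta_stem, "soil": self.delta_soil}[kind]


@dataclass
class ClosureRecord:
    """One chamber closure: paired isotopologue traces plus geometry."""

    closure_id: str
    kind: ChamberKind
    start: pd.Timestamp
    time_s: np.ndarray
    c12: np.ndarray   # ppm
    c13: np.ndarray   # ppm
    volume_l: float
    area_m2: float
    par: float        # μmol m⁻² s⁻¹ at closure

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.c12) != n or len(self.c13) != n:
            raise ValueError("traces must have the same length as time_s")
        if n and (self.time_s[0] < 0 or np.any(np.diff(self.time_s) <= 0)):
            raise ValueError("time_s must start at >= 0 and be strictly increasing")


# ---------------------------------------------------------------------------
# solar geometry / environment


def _daylength_h(doy: np.ndarray | float) -> np.ndarray | float:
    """Approximate day length (h) at a high-boreal site (~62° N)."""
    return 12.0 + 7.5 * np.sin(2 * np.pi * (np.asarray(doy, float) - 80.0) / 365.0)


def is_night(time: pd.DatetimeIndex) -> np.ndarray:
    """Boolean night mask from the configured sunrise/sunset model."""
    doy = time.dayofyear.to_numpy(float)
    hour = time.hour.to_numpy(float) + time.minute.to_numpy(float) / 60.0
    half = _daylength_h(doy) / 2.0
    return ~((hour > 12.0 - half) & (hour < 12.0 + half))


def simulate_environment(config: SimulationConfig) -> EnvironmentSeries:
    """Half-hourly drivers: seasonal+diurnal T, diurnal PAR, soil dry-down.

    Soil moisture declines monotonically through the configured dry window
    (its seasonal minimum falls at the end of the window) and recovers after.
    """
    rng = np.random.default_rng(config.seed + _ENV_STREAM)
    t0 = pd.Timestamp(config.season_start)
    t1 = pd.Timestamp(config.season_end) + pd.Timedelta(hours=23, minutes=30)
    time = pd.date_range(t0, t1, freq="30min")
    doy = time.dayofyear.to_numpy(float)
    hour = time.hour.to_numpy(float) + time.minute.to_numpy(float) / 60.0
    n = len(time)
    dates = time.normalize()
    udates = dates.unique()
    day_idx = np.searchsorted(udates.asi8, dates.asi8)
    nd = len(udates)

    # air temperature: seasonal sinusoid + diurnal cycle + AR(1) daily anomaly
    seasonal = 7.0 + 11.0 * np.sin(2 * np.pi * (doy - 115.0) / 365.0)
    diurnal = 4.0 * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    anom = np.empty(nd)
    anom[0] = rng.normal(0, 2.0)
    eps = rng.normal(0, 2.0 * np.sqrt(1 - 0.7**2), nd)
    for i in range(1, nd):
        anom[i] = 0.7 * anom[i - 1] + eps[i]
    air_t = seasonal + diurnal + anom[day_idx]

    # soil temperature: multi-day smoothed, damped air T with small offset
    daily_air = np.bincount(day_idx, air_t) / np.bincount(day_idx)
    kernel = np.ones(7) / 7.0
    sm = np.convolve(np.pad(daily_air, 3, mode="edge"), kernel, mode="valid")
    soil_t = np.maximum(0.8 * sm[day_idx] + 1.0 + 0.3 * np.sin(2 * np.pi * (hour - 14) / 24), 0.2)

    # PAR: half-sine over the photoperiod, daily cloudiness factor
    night = is_night(time)
    half = _daylength_h(doy) / 2.0
    frac = np.clip((hour - (12.0 - half)) / (2.0 * half), 0.0, 1.0)
    clearsky = np.sin(np.pi * frac)
    pmax = 1500.0 * (0.75 + 0.25 * np.sin(2 * np.pi * (doy - 80.0) / 365.0))
    cloud = rng.uniform(0.45, 1.0, nd)
    par = pmax * cloud[day_idx] * clearsky
    par[night] = 0.0

    # precipitation: random events, suppressed during the dry window
    dry0 = pd.Timestamp(config.dry_start)
    dry1 = pd.Timestamp(config.dry_end)
    in_dry_day = (udates >= dry0) & (udates <= dry1)
    rain_day = rng.random(nd) < np.where(in_dry_day, 0.03, 0.35)
    amount = rng.exponential(3.0, nd) * rain_day
    precip = np.zeros(n)
    slot = rng.integers(0, 48, nd)
    for i in range(nd):
        if amount[i] > 0:
            j = np.searchsorted(dates.asi8, udates.asi8[i]) + slot[i]
            if j < n:
                precip[j] = amount[i]

    # soil moisture: relaxation toward field capacity with rain recharge,
    # forced monotone decline inside the dry window
    theta = np.empty(nd)
    theta[0] = 0.30
    drydown_days = max((dry1 - dry0).days, 1)
    for i in range(1, nd):
        d = udates[i]
        if dry0 <= d <= dry1:
            theta[i] = theta[i - 1] - (theta[0] - 0.10) / drydown_days
        else:
            recharge = 0.004 * min(amount[i], 8.0)
            theta[i] = theta[i - 1] + 0.08 * (0.30 - theta[i - 1]) + recharge
        theta[i] = min(max(theta[i], 0.05), 0.40)
    soil_moisture = theta[day_idx]

    return EnvironmentSeries(
        time=time, air_t=air_t, soil_t=soil_t, par=par,
        soil_moisture=soil_moisture, precipitation=precip,
    )


# ---------------------------------------------------------------------------
# growth truths used by the flux model


def gompertz(t: np.ndarray | float, asymptote: float, midpoint: float, rate: float) -> np.ndarray:
    """Gompertz curve ``A·exp(−exp(−κ(t−t0)))`` (β = e^{κ t0})."""
    return asymptote * np.exp(-np.exp(-rate * (np.asarray(t, float) - midpoint)))


def gompertz_rate(t: np.ndarray | float, asymptote: float, midpoint: float, rate: float) -> np.ndarray:
    """Analytic derivative of :func:`gompertz` (cells d⁻¹)."""
    u = -rate * (np.asarray(t, float) - midpoint)
    return asymptote * rate * np.exp(u) * np.exp(-np.exp(u))


def _tracheid_rate_norm(doy: np.ndarray, config: SimulationConfig) -> np.ndarray:
    g = config.gompertz
    r = gompertz_rate(doy, g.asymptote, g.midpoint_doy, g.rate)
    peak = g.asymptote * g.rate / np.e
    return r / peak


def _root_rate_norm(time: pd.DatetimeIndex, config: SimulationConfig) -> np.ndarray:
    total = np.zeros(len(time))
    t = time.normalize()
    for pulse in config.root_pulses:
        s, e = pd.Timestamp(pulse.start), pd.Timestamp(pulse.end)
        mid = s + (e - s) / 2
        sigma = max((e - s).days / 5.0, 1.0)
        x = (t - mid).days.to_numpy(float)
        total += pulse.amplitude_mm * np.exp(-0.5 * (x / sigma) ** 2)
    m = total.max()
    return total / m if m > 0 else total


# ---------------------------------------------------------------------------
# true fluxes and δ13C


def _daily_assimilate_delta(dates: pd.DatetimeIndex, config: SimulationConfig) -> np.ndarray:
    """Daily δ¹³C of fresh assimilates: seasonal drift, ~3-week synoptic
    oscillation, drought enrichment, AR(1) day-to-day weather jitter."""
    rng = np.random.default_rng(config.seed + _DELTA_STREAM)
    doy = dates.dayofyear.to_numpy(float)
    base = config.assim_d13c_base + config.assim_d13c_seasonal_amp * np.sin(
        2 * np.pi * (doy - 150.0) / 240.0
    )
    synoptic = 0.6 * np.sin(2 * np.pi * doy / 21.0 + 0.8)
    # dry-period enrichment ramps in over a week and decays afterwards
    d0 = (pd.Timestamp(config.dry_start) - dates[0]).days
    d1 = (pd.Timestamp(config.dry_end) - dates[0]).days
    idx = np.arange(len(dates), dtype=float)
    ramp = np.clip((idx - d0) / 7.0, 0.0, 1.0) * np.clip(1.0 - (idx - d1) / 10.0, 0.0, 1.0)
    dry = config.assim_d13c_dry_shift * ramp
    phi, sd = config.assim_d13c_ar1, config.assim_d13c_daily_sd
    jitter = np.empty(len(dates))
    jitter[0] = rng.normal(0, sd)
    eps = rng.normal(0, sd * np.sqrt(1 - phi**2), len(dates))
    for i in range(1, len(dates)):
        jitter[i] = phi * jitter[i - 1] + eps[i]
    return np.clip(base + synoptic + dry + jitter, -40.0, 0.0)


def _coupling_weight(dates: pd.DatetimeIndex, windows, config: SimulationConfig) -> np.ndarray:
    w = np.full(len(dates), config.coupling_base)
    for win in windows:
        mask = (dates >= pd.Timestamp(win.start)) & (dates <= pd.Timestamp(win.end))
        w[mask] = config.coupling_high
    return w


def simulate_true_fluxes(env: EnvironmentSeries, config: SimulationConfig) -> TrueFluxSeries:
    """Ground-truth flux magnitudes and δ¹³C on the environmental grid.

    Stem efflux follows a·e^{bT} scaled by the tracheid growth-rate truth;
    soil efflux a moisture-modulated exponential-T response plus a
    root-growth term; shoot influx a saturating light response. δ¹³C of the
    stem/soil effluxes mixes the lagged, fractionation-shifted assimilate
    signal with a slow storage pool, the mixing weight elevated inside the
    configured high-demand windows.
    """
    time = env.time
    doy = time.dayofyear.to_numpy(float)

    seasonal_cap = 0.55 + 0.45 * np.exp(-0.5 * ((doy - 195.0) / 55.0) ** 2)
    shoot = (
        config.shoot_amax * seasonal_cap * env.par / (env.par + config.shoot_par_half_sat)
    )
    shoot[env.par <= 0] = 0.0

    g_norm = _tracheid_rate_norm(doy, config)
    stem = config.stem_resp_base * np.exp(config.stem_resp_temp_coef * env.air_t) * (
        1.0 + config.stem_growth_coupling * g_norm
    )

    r_norm = _root_rate_norm(time, config)
    theta = env.soil_moisture
    soil = (
        config.soil_resp_base
        * np.exp(config.soil_resp_temp_coef * env.soil_t)
        * theta / (theta + config.soil_moisture_half_sat)
        * (1.0 + config.soil_root_coupling * r_norm)
    )

    # daily δ13C truth and its allocation to stem/soil
    dates = pd.date_range(time[0].normalize(), time[-1].normalize(), freq="D")
    d_shoot = _daily_assimilate_delta(dates, config)

    def allocate(lag: int, frac: float, pool: float, windows) -> np.ndarray:
        lagged = np.roll(d_shoot, lag)
        lagged[:lag] = d_shoot[0]
        w = _coupling_weight(dates, windows, config)
        return w * (lagged - frac) + (1.0 - w) * pool

    d_stem = allocate(
        config.allocation_lag_stem_days, config.fractionation_stem,
        config.stem_pool_d13c, config.stem_coupling_windows,
    )
    d_soil = allocate(
        config.allocation_lag_soil_days, config.fractionation_soil,
        config.soil_pool_d13c, config.soil_coupling_windows,
    )
    daily = pd.DataFrame(
        {"delta_shoot": d_shoot, "delta_stem": d_stem, "delta_soil": d_soil},
        index=dates.normalize(),
    )
    day_pos = np.searchsorted(dates.normalize().asi8, time.normalize().asi8)

    return TrueFluxSeries(
        time=time,
        shoot_flux=shoot,
        stem_flux=stem,
        soil_flux=soil,
        delta_shoot=d_shoot[day_pos],
        delta_stem=d_stem[day_pos],
        delta_soil=d_soil[day_pos],
        par=env.par.copy(),
        daily_delta=daily,
    )


# ---------------------------------------------------------------------------
# chamber forward model


def _phi(q: float, t: np.ndarray) -> np.ndarray:
    """(1 − e^{−qt})/q, stable as q → 0."""
    if q < 1e-12:
        return t.astype(float)
    return -np.expm1(-q * t) / q


def closure_trace(
    t: np.ndarray,
    flux: float,
    c_amb: float,
    c0: float,
    volume_l: float,
    area_m2: float,
    leak_rate: float,
    molar_volume_l: float,
) -> np.ndarray:
    """Exact solution of the chamber mass balance for one isotopologue.

    dC/dt = F·S·V_mol/V + q·(C_amb − C), C(0) = C0, concentrations in ppm.
    """
    k = area_m2 * molar_volume_l / volume_l  # ppm s⁻¹ per unit flux
    q = leak_rate
    return c_amb + flux * k * _phi(q, t) + (c0 - c_amb) * np.exp(-q * t)


def _split_isotopologues(total_ppm: float, delta: float) -> tuple[float, float]:
    r = R_VPDB * (1.0 + delta / 1000.0)
    c12 = total_ppm / (1.0 + r)
    return c12, total_ppm - c12


def simulate_chamber_closures(
    truth: TrueFluxSeries,
    config: SimulationConfig,
    kinds: tuple[ChamberKind, ...] = ("shoot", "stem", "soil"),
) -> list[ClosureRecord]:
    """Forward-simulate every scheduled chamber closure of the season.

    Each closure solves the chamber mass balance per isotopologue (shared
    leak rate, F13 = F12·R_flux with R_flux encoding the true δ¹³C), sampled
    at 1 s, plus independent Gaussian analyzer noise.
    """
    rng = np.random.default_rng(config.seed + _CLOSURE_STREAM)
    posix = truth.time.asi8 / 1e9
    records: list[ClosureRecord] = []

    for kind in kinds:
        spec = config.chambers[kind]
        day0 = truth.time[0].normalize()
        nday = (truth.time[-1].normalize() - day0).days + 1
        offsets = (np.arange(spec.closures_per_day) + 0.5) * (86400.0 / spec.closures_per_day)
        t_grid = np.arange(spec.duration_s + 1, dtype=float)
        counter = 0
        for d in range(nday):
            date = day0 + pd.Timedelta(days=d)
            if date not in truth.daily_delta.index:
                continue
            deltas = truth.daily_delta.loc[date]
            for off in offsets:
                start = date + pd.Timedelta(seconds=float(off))
                ts = start.timestamp()
                if ts < posix[0] or ts > posix[-1]:
                    continue
                f_total = float(np.interp(ts, posix, truth.flux(kind)))
                par = float(np.interp(ts, posix, truth.par))
                delta = float(deltas[f"delta_{kind}"])
                signed = -f_total if kind == "shoot" else f_total
                r_flux = R_VPDB * (1.0 + delta / 1000.0)
                f12 = signed / (1.0 + r_flux)
                f13 = signed - f12

                amb_total = config.ambient_co2_ppm + 5.0 * np.cos(
                    2 * np.pi * (start.hour - 3.0) / 24.0
                )
                c12a, c13a = _split_isotopologues(amb_total, config.ambient_d13c)
                mv = config.molar_volume_l
                c12 = closure_trace(t_grid, f12, c12a, c12a, spec.volume_l, spec.area_m2,
                                    spec.leak_rate, mv)
                c13 = closure_trace(t_grid, f13, c13a, c13a, spec.volume_l, spec.area_m2,
                                    spec.leak_rate, mv)
                if config.noise_sd_c12_ppm > 0:
                    c12 = c12 + rng.normal(0, config.noise_sd_c12_ppm, c12.shape)
                if config.noise_sd_c13_ppm > 0:
                    c13 = c13 + rng.normal(0, config.noise_sd_c13_ppm, c13.shape)
                records.append(
                    ClosureRecord(
                        closure_id=f"{kind}-{counter:05d}",
                        kind=kind,
                        start=start,
                        time_s=t_grid.copy(),
                        c12=c12,
                        c13=c13,
                        volume_l=spec.volume_l,
                        area_m2=spec.area_m2,
                        par=par,
                    )
                )
                counter += 1
    return records


# ---------------------------------------------------------------------------
# tracheids


def simulate_tracheid_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly tracheid counts per phenophase for ``n_trees`` trees.

    Returns ``(observations, truth)``: observations with columns
    (tree_id, date, n_a, n_b, n_c, n_total, prev_ring_width_mm) and the
    per-tree Gompertz truth parameters (normalized, cells per mm of previous
    ring). Counts are noisy raw cell numbers, i.e. normalized truth × the
    tree's previous-year ring width. Phases satisfy a + b = total − mature.
    """
    rng = np.random.default_rng(config.seed + _TRACHEID_STREAM)
    g = config.gompertz
    trees = [f"T{i+1}" for i in range(config.n_trees)]
    widths = rng.uniform(1.2, 3.0, config.n_trees)
    asym = g.asymptote * (1.0 + g.tree_asymptote_cv * rng.standard_normal(config.n_trees))
    asym = np.maximum(asym, 0.2 * g.asymptote)
    mid = g.midpoint_doy + g.tree_midpoint_sd_days * rng.standard_normal(config.n_trees)

    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end)
    dates = pd.date_range(start, end, freq=f"{config.tracheid_sampling_interval_days}D")
    doy = dates.dayofyear.to_numpy(float)

    rows = []
    truth_rows = []
    for i, tree in enumerate(trees):
        total_true = gompertz(doy, asym[i], mid[i], g.rate) * widths[i]
        mature_true = gompertz(doy, asym[i], mid[i] + g.maturation_delay_days,
                               g.maturation_rate) * widths[i]
        noise_sd = g.count_noise_frac * asym[i] * widths[i]
        total_obs = np.maximum(total_true + rng.normal(0, noise_sd, len(doy)), 0.0)
        mature_obs = np.clip(mature_true + rng.normal(0, noise_sd, len(doy)), 0.0, total_obs)
        rem = total_obs - mature_obs
        # enlargement share of the active pool declines over the season
        p_a = np.clip(0.9 - 0.8 * (doy - doy[0]) / max(doy[-1] - doy[0], 1), 0.08, 0.9)
        n_a = rem * p_a
        n_b = rem - n_a
        for j, date in enumerate(dates):
            rows.append(
                {
                    "tree_id": tree,
                    "date": date.date(),
                    "n_a": n_a[j],
                    "n_b": n_b[j],
                    "n_c": mature_obs[j],
                    "n_total": total_obs[j],
                    "prev_ring_width_mm": widths[i],
                }
            )
        truth_rows.append(
            {
                "tree_id": tree,
                "asymptote": asym[i],
                "midpoint_doy": mid[i],
                "rate": g.rate,
                "maturation_midpoint_doy": mid[i] + g.maturation_delay_days,
                "maturation_rate": g.maturation_rate,
                "prev_ring_width_mm": widths[i],
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# NSC pools


def _template_eval(tpl, doys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    conc = np.interp(doys, tpl.doy_knots, tpl.conc_knots)
    d13c = np.interp(doys, tpl.doy_knots, tpl.d13c_knots)
    return conc, d13c


def simulate_nsc_series(config: SimulationConfig) -> pd.DataFrame:
    """Phloem (sucrose/glucose/fructose/starch + derived WSC) and root
    (WSC/starch) concentration and δ¹³C observations.

    WSC is constructed per replicate and date as the sum of the sugar pools,
    with conc-weighted δ¹³C, so the pool identity holds exactly in the output.
    Columns: organ, compound, date, replicate, conc_mg_g, d13C_permil.
    """
    rng = np.random.default_rng(config.seed + _NSC_STREAM)
    year = config.season_start.year
    rows = []

    def emit(organ: str, templates: dict, doys: list[int], sugar_names: list[str]) -> None:
        for doy in doys:
            date = dt.date(year, 1, 1) + dt.timedelta(days=int(doy) - 1)
            for rep in range(1, config.nsc_replicates + 1):
                sugars_conc, sugars_d13c = {}, {}
                for name, tpl in templates.items():
                    conc, d13c = _template_eval(tpl, np.array([float(doy)]))
                    c = max(conc[0] * (1.0 + tpl.conc_noise_frac * rng.standard_normal()), 0.5)
                    d = d13c[0] + tpl.d13c_noise_sd * rng.standard_normal()
                    rows.append(
                        {
                            "organ": organ,
                            "compound": name,
                            "date": date,
                            "replicate": rep,
                            "conc_mg_g": c,
                            "d13C_permil": d,
                        }
                    )
                    if name in sugar_names:
                        sugars_conc[name] = c
                        sugars_d13c[name] = d
                if sugar_names:
                    tot = sum(sugars_conc.values())
                    dw = sum(sugars_conc[n] * sugars_d13c[n] for n in sugars_conc) / tot
                    rows.append(
                        {
                            "organ": organ,
                            "compound": "wsc",
                            "date": date,
                            "replicate": rep,
                            "conc_mg_g": tot,
                            "d13C_permil": dw,
                        }
                    )

    emit("phloem", config.phloem_nsc, config.phloem_sampling_doys,
         ["sucrose", "glucose", "fructose"])
    emit("root", config.root_nsc, config.root_sampling_doys, [])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# root growth


def simulate_root_growth(env: EnvironmentSeries, config: SimulationConfig) -> pd.DataFrame:
    """Daily fibrous-root elongation per scanner (mm d⁻¹, ≥ 0).

    Each configured pulse is a Gaussian bump over its window, expressed per
    scanner through the pulse's scanner weights.
    """
    rng = np.random.default_rng(config.seed + _ROOT_STREAM)
    dates = pd.date_range(env.time[0].normalize(), env.time[-1].normalize(), freq="D")
    rows = []
    for s in range(config.n_scanners):
        total = np.zeros(len(dates))
        for pulse in config.root_pulses:
            if s >= len(pulse.scanner_weights):
                raise ValueError("scanner_weights shorter than n_scanners")
            p0, p1 = pd.Timestamp(pulse.start), pd.Timestamp(pulse.end)
            mid = p0 + (p1 - p0) / 2
            sigma = max((p1 - p0).days / 5.0, 1.0)
            x = (dates - mid).days.to_numpy(float)
            total += (
                pulse.amplitude_mm * pulse.scanner_weights[s]
                * np.exp(-0.5 * (x / sigma) ** 2)
            )
        if config.root_noise_sd_mm > 0:
            total = total + rng.normal(0, config.root_noise_sd_mm, len(dates))
        total = np.maximum(total, 0.0)
        for j, date in enumerate(dates):
            rows.append({"scanner_id": s + 1, "date": date.date(), "elongation_mm": total[j]})
    return pd.DataFrame(rows)
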