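"""One-command orchestration: simulate → fluxes → phenology → associate →
coherence, with a reproducible run report.

Each stage reads only the plain-CSV artifacts of earlier stages (all written
under ``config.outdir``), so any stage can equally be fed user-supplied
tables in the documented dialects. Stage failures halt the run and are
recorded in the partial report. Re-running with an identical config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import traceback

import numpy as np
import pandas as pd

from . import chamber, envmodels, io, phenology, wavelet
from . import synthetic as syn
from .config import PipelineConfig, config_hash

__version__ = "0.1.0"

logger = logging.getLogger("treeflux")

__all__ = ["RunReport", "run_pipeline", "__version__"]


@dataclasses.dataclass
class RunReport:
    run_id: str
    config_hash: str
    version: str
    stages: dict[str, dict] = dataclasses.field(default_factory=dict)
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    key_results: dict = dataclasses.field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s.get("status") == "ok" for s in self.stages.values())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _out(cfg: PipelineConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, report: RunReport, state: dict) -> None:
    sim = cfg.simulation
    env = syn.simulate_environment(sim)
    truth = syn.simulate_true_fluxes(env, sim)
    closures = syn.simulate_chamber_closures(truth, sim)
    tracheids, tracheid_truth = syn.simulate_tracheid_counts(sim)
    nsc = syn.simulate_nsc_series(sim)
    roots = syn.simulate_root_growth(env, sim)

    io.write_environment_csv(env, _out(cfg, "environment.csv"))
    io.write_closures_csv(closures, _out(cfg, "closures.csv"))
    io.write_table_csv(tracheids, _out(cfg, "tracheids.csv"), io.TRACHEID_COLUMNS)
    io.write_table_csv(nsc, _out(cfg, "nsc.csv"), io.NSC_COLUMNS)
    io.write_table_csv(roots, _out(cfg, "roots.csv"), io.ROOT_COLUMNS)
    truth.daily_delta.rename_axis("date").reset_index().to_csv(
        _out(cfg, "truth_daily_delta.csv"), index=False
    )
    state.update(env=env, truth=truth, closures=closures, tracheids=tracheids,
                 nsc=nsc, roots=roots, tracheid_truth=tracheid_truth)
    report.outputs.update(
        environment=_out(cfg, "environment.csv"), closures=_out(cfg, "closures.csv"),
        tracheids=_out(cfg, "tracheids.csv"), nsc=_out(cfg, "nsc.csv"),
        roots=_out(cfg, "roots.csv"),
    )
    report.stages["simulate"] = {
        "status": "ok",
        "n_closures": len(closures),
        "n_env_steps": len(env.time),
    }


def _stage_fluxes(cfg: PipelineConfig, report: RunReport, state: dict) -> None:
    sim = cfg.simulation
    windows = cfg.flux.windows
    fluxes = chamber.fit_closures(
        state["closures"], windows=windows, molar_volume_l=sim.molar_volume_l,
        min_flux=cfg.flux.min_flux,
    )
    io.write_table_csv(fluxes, _out(cfg, "fluxes.csv"))
    parts = [chamber.aggregate_daily(fluxes, state["env"], kind)
             for kind in ("shoot", "stem", "soil")]
    daily = pd.concat([p for p in parts if not p.empty], ignore_index=True)
    io.write_table_csv(daily, _out(cfg, "daily_fluxes.csv"))
    state.update(fluxes=fluxes, daily=daily)
    report.outputs.update(fluxes=_out(cfg, "fluxes.csv"),
                          daily_fluxes=_out(cfg, "daily_fluxes.csv"))
    report.stages["fluxes"] = {
        "status": "ok",
        "n_fit": int(len(fluxes)),
        "n_flagged": int((fluxes["flag"] != "ok").sum()),
    }


def _stage_phenology(cfg: PipelineConfig, report: RunReport, state: dict) -> None:
    pc = cfg.phenology
    pooled, per_tree = phenology.normalize_counts(state["tracheids"])
    doy = pd.to_datetime(pooled["date"]).dt.dayofyear.to_numpy(float)
    year = pd.to_datetime(pooled["date"]).dt.year.iloc[0]
    total_fit = phenology.fit_gompertz(doy, pooled["total_norm"].to_numpy())
    mature_fit = phenology.fit_gompertz(doy, pooled["mature_norm"].to_numpy())

    grid = np.arange(doy.min(), doy.max() + 1)
    active = phenology.derive_active_phase(total_fit, mature_fit, grid)
    base = pd.Timestamp(f"{year}-01-01")
    active["date"] = [
        (base + pd.Timedelta(days=int(d) - 1)).date() for d in active["doy"]
    ]
    periods = phenology.classify_growth_periods(
        total_fit, mature_fit, int(year), doy_grid=grid,
        rate_threshold_frac=pc.rate_threshold_frac,
        max_rate_threshold_frac=pc.max_rate_threshold_frac,
        ew_quantile=pc.ew_quantile, lw_quantile=pc.lw_quantile,
    )
    root_periods = phenology.detect_root_periods(
        state["roots"], min_amp=pc.root_min_amp, min_gap_days=pc.root_min_gap_days,
        smooth_days=pc.root_smooth_days,
    )
    all_periods = phenology.GrowthPeriods({**periods.periods, **root_periods.periods})

    # per-tree fits feed the mixed models downstream
    tree_fits = {}
    for tree, grp in per_tree.groupby("tree_id"):
        tdoy = pd.to_datetime(grp["date"]).dt.dayofyear.to_numpy(float)
        try:
            tree_fits[tree] = phenology.fit_gompertz(tdoy, grp["total_norm"].to_numpy())
        except (phenology.GompertzFitError, ValueError) as exc:
            logger.warning("per-tree Gompertz fit failed for %s: %s", tree, exc)

    io.write_table_csv(active[["date", "n_ab", "growth_rate"]], _out(cfg, "phenology.csv"))
    io.write_table_csv(all_periods.to_frame(), _out(cfg, "periods.csv"))
    state.update(total_fit=total_fit, mature_fit=mature_fit, active=active,
                 periods=all_periods, tree_fits=tree_fits, per_tree=per_tree)
    report.outputs.update(phenology=_out(cfg, "phenology.csv"),
                          periods=_out(cfg, "periods.csv"))
    report.stages["phenology"] = {
        "status": "ok",
        "total_asymptote": total_fit.asymptote,
        "total_midpoint_doy": total_fit.midpoint,
        "n_periods": len(all_periods.periods),
    }
    report.key_results["periods"] = {
        k: [str(v[0]), str(v[1])] for k, v in all_periods.periods.items()
    }


def _stage_associate(cfg: PipelineConfig, report: RunReport, state: dict) -> None:
    ac = cfg.association
    daily = state["daily"]
    drivers = io.night_day_means(state["env"])
    results: list[envmodels.ModelResult] = []

    # --- stem: exponential T detrend of nighttime efflux, 1-day lag shift
    stem = daily[daily["chamber"] == "stem"].set_index("date")
    stem = stem.join(drivers, how="inner").dropna(subset=["mean_flux_umol_m2_s", "night_air_t"])
    exp_fit = envmodels.fit_exponential_temperature(
        stem["mean_flux_umol_m2_s"], stem["night_air_t"]
    )
    resid = pd.Series(exp_fit.residuals, index=pd.DatetimeIndex(pd.to_datetime(stem.index)))
    resid_shifted = envmodels.lag_shift(resid, ac.lag_days)

    active = state["active"].copy()
    growth = pd.Series(
        active["growth_rate"].to_numpy(),
        index=pd.DatetimeIndex(pd.to_datetime(active["date"])),
    )
    phloem_conc = io.nsc_wide(state["nsc"], "phloem", "conc_mg_g")
    phloem_conc["date"] = pd.to_datetime(phloem_conc["date"])
    tab = phloem_conc.set_index("date")
    tab["rstem_resid"] = resid_shifted.reindex(tab.index)
    tab["g_tracheid"] = growth.reindex(tab.index)
    tab = tab.reset_index()
    tab["doy"] = tab["date"].dt.dayofyear.astype(float)

    pools = [p for p in ("sucrose", "glucose", "starch", "wsc", "nsc") if p in tab.columns]
    lm_tab = tab.dropna(subset=["rstem_resid"])
    for pred in ["g_tracheid"] + pools:
        try:
            results.append(
                envmodels.fit_lm(lm_tab, "rstem_resid", pred, doy="doy", alpha=ac.alpha)
            )
        except ValueError as exc:
            logger.warning("stem LM for %s skipped: %s", pred, exc)

    # --- mixed models: per-tree tracheid growth vs per-tree phloem NSC
    per_rep = io.nsc_wide(state["nsc"], "phloem", "conc_mg_g", per_replicate=True)
    per_rep["date"] = pd.to_datetime(per_rep["date"])
    per_rep["doy"] = per_rep["date"].dt.dayofyear.astype(float)
    per_rep["tree_id"] = "T" + per_rep["replicate"].astype(str)
    tree_fits = state["tree_fits"]
    per_rep["g_tracheid"] = [
        tree_fits[t].rate_curve(d) if t in tree_fits else np.nan
        for t, d in zip(per_rep["tree_id"], per_rep["doy"])
    ]
    for pred in pools:
        try:
            results.append(
                envmodels.fit_lmm(per_rep.dropna(subset=["g_tracheid", pred]),
                                  "g_tracheid", pred, group="tree_id", doy="doy",
                                  alpha=ac.alpha)
            )
        except ValueError as exc:
            logger.warning("LMM for %s skipped: %s", pred, exc)

    # --- δ13C of stem efflux vs δ13C of phloem pools
    phloem_d = io.nsc_wide(state["nsc"], "phloem", "d13C_permil")
    phloem_d["date"] = pd.to_datetime(phloem_d["date"])
    dstem = stem["d13C_weighted_permil"]
    dstem.index = pd.to_datetime(dstem.index)
    dtab = phloem_d.set_index("date")
    dtab["d13c_rstem"] = dstem.reindex(dtab.index)
    dtab = dtab.reset_index().dropna(subset=["d13c_rstem"])
    dtab["doy"] = dtab["date"].dt.dayofyear.astype(float)
    for pred in [p for p in ("sucrose", "glucose", "starch", "wsc") if p in dtab.columns]:
        try:
            results.append(
                envmodels.fit_lm(dtab, "d13c_rstem", pred, doy="doy", alpha=ac.alpha,
                                 exclude_dates=ac.delta_exclude_dates)
            )
        except ValueError as exc:
            logger.warning("delta LM for %s skipped: %s", pred, exc)

    # --- roots: detrend growth and soil efflux on soil T + moisture
    roots = state["roots"].copy()
    roots["date"] = pd.to_datetime(roots["date"]).dt.date
    root_daily = roots.groupby("date")["elongation_mm"].mean()
    rtab = drivers.join(root_daily.rename("root_growth"), how="inner").dropna()
    root_resid, _ = envmodels.fit_env_regression(
        rtab["root_growth"], rtab["soil_t"], rtab["soil_moisture"]
    )
    rresid = pd.Series(root_resid, index=pd.DatetimeIndex(pd.to_datetime(rtab.index)))

    soil = daily[daily["chamber"] == "soil"].set_index("date")
    stab = drivers.join(soil["mean_flux_umol_m2_s"].rename("rsoil"), how="inner").dropna()
    soil_resid, _ = envmodels.fit_env_regression(
        stab["rsoil"], stab["soil_t"], stab["soil_moisture"]
    )
    sresid = pd.Series(soil_resid, index=pd.DatetimeIndex(pd.to_datetime(stab.index)))

    root_conc = io.nsc_wide(state["nsc"], "root", "conc_mg_g")
    root_conc["date"] = pd.to_datetime(root_conc["date"])
    rt = root_conc.set_index("date")
    rt["g_fibrous_resid"] = rresid.reindex(rt.index)
    rt["rsoil_resid"] = sresid.reindex(rt.index)
    rt = rt.reset_index()
    rt["doy"] = rt["date"].dt.dayofyear.astype(float)
    root_pools = [p for p in ("starch", "wsc", "nsc") if p in rt.columns]
    for pred in root_pools:
        try:
            results.append(
                envmodels.fit_lm(rt.dropna(subset=["g_fibrous_resid", pred]),
                                 "g_fibrous_resid", pred, doy="doy", alpha=ac.alpha)
            )
        except ValueError as exc:
            logger.warning("root LM for %s skipped: %s", pred, exc)
    for pred in ["g_fibrous_resid"] + root_pools:
        try:
            results.append(
                envmodels.fit_lm(rt.dropna(subset=["rsoil_resid", pred]),
                                 "rsoil_resid", pred, doy="doy", alpha=ac.alpha)
            )
        except ValueError as exc:
            logger.warning("soil LM for %s skipped: %s", pred, exc)

    rows = [row for res in results for row in res.to_rows()]
    models = pd.DataFrame(rows)
    io.write_table_csv(models, _out(cfg, "models.csv"))
    state.update(models=models, exp_fit=exp_fit)
    report.outputs["models"] = _out(cfg, "models.csv")
    report.stages["associate"] = {
        "status": "ok",
        "n_models": len(results),
        "stem_q10": exp_fit.q10,
        "stem_exp_r2": exp_fit.r2,
    }


def _stage_coherence(cfg: PipelineConfig, report: RunReport, state: dict) -> None:
    cc = cfg.coherence
    daily = state["daily"]

    def daily_delta(kind: str) -> pd.Series:
        sub = daily[daily["chamber"] == kind]
        return pd.Series(
            sub["d13C_weighted_permil"].to_numpy(),
            index=pd.DatetimeIndex(pd.to_datetime(sub["date"])),
        )

    x_raw = daily_delta("shoot")
    for kind, label in (("shoot", "ashoot"), ("stem", "rstem"), ("soil", "rsoil")):
        s = daily_delta(kind)
        pd.DataFrame({"date": s.index.date, "d13C_permil": s.to_numpy()}).to_csv(
            _out(cfg, f"delta_{label}.csv"), index=False
        )
    summaries = []
    for other in ("stem", "soil"):
        y_raw = daily_delta(other)
        common = x_raw.index.intersection(y_raw.index)
        xs = wavelet.interpolate_gaps(common, x_raw.reindex(common).to_numpy(),
                                      cc.max_gap_fraction)
        ys = wavelet.interpolate_gaps(common, y_raw.reindex(common).to_numpy(),
                                      cc.max_gap_fraction)
        # align after trimming
        start = max(xs.dates[0], ys.dates[0])
        end = min(xs.dates[-1], ys.dates[-1])
        xs = wavelet.DailySeries(
            xs.dates[(xs.dates >= start) & (xs.dates <= end)],
            xs.values[(xs.dates >= start) & (xs.dates <= end)],
            xs.gap_mask[(xs.dates >= start) & (xs.dates <= end)],
        )
        ys = wavelet.DailySeries(
            ys.dates[(ys.dates >= start) & (ys.dates <= end)],
            ys.values[(ys.dates >= start) & (ys.dates <= end)],
            ys.gap_mask[(ys.dates >= start) & (ys.dates <= end)],
        )
        res = wavelet.coherence(
            xs, ys, dj=1.0 / cc.voices_per_octave,
            min_period=cc.min_period_days, max_period=cc.max_period_days,
        )
        res = wavelet.significance(
            res, xs, ys, n_surrogates=cc.n_surrogates, alpha=cc.alpha, seed=cfg.seed,
        )
        io.write_table_csv(res.to_long_frame(), _out(cfg, f"coherence_shoot_{other}.csv"))
        summary = wavelet.lead_lag_summary(res, state["periods"], bands=cc.bands)
        summary.insert(0, "pair", f"shoot_vs_{other}")
        summaries.append(summary)
        report.outputs[f"coherence_shoot_{other}"] = _out(cfg, f"coherence_shoot_{other}.csv")

    summary = pd.concat(summaries, ignore_index=True)
    io.write_table_csv(summary, _out(cfg, "coherence_summary.csv"))
    state["coherence_summary"] = summary
    report.outputs["coherence_summary"] = _out(cfg, "coherence_summary.csv")
    report.stages["coherence"] = {
        "status": "ok",
        "n_summary_rows": len(summary),
    }
    report.key_results["coherence_summary"] = summary.to_dict(orient="records")


_STAGES = [
    ("simulate", _stage_simulate),
    ("fluxes", _stage_fluxes),
    ("phenology", _stage_phenology),
    ("associate", _stage_associate),
    ("coherence", _stage_coherence),
]


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order; halt on first failure.

    Writes every intermediate table plus ``run_report.json`` under
    ``cfg.outdir`` and returns the :class:`RunReport`.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    report = RunReport(run_id=cfg.run_id, config_hash=config_hash(cfg), version=__version__)
    state: dict = {}
    for name, fn in _STAGES:
        logger.info("stage %s ...", name)
        try:
            fn(cfg, report, state)
        except Exception as exc:  # halt with partial report
            report.stages[name] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
            logger.error("stage %s failed: %s", name, exc)
            break
    with open(_out(cfg, "run_report.json"), "w") as fh:
        fh.write(report.to_json())
    return report
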