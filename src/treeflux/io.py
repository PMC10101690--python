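"""Plain-CSV table dialects for every pipeline artifact.

Column names are fixed and documented here; every writer emits exactly these
headers and every reader validates them:

* closures:     closure_id, chamber, start_time, time_s, c12_ppm, c13_ppm,
                volume_l, area_m2, par (long format, one row per second)
* environment:  timestamp, air_T, soil_T, PAR, soil_moisture, precip
* tracheids:    tree_id, date, n_a, n_b, n_c, n_total, prev_ring_width_mm
* nsc:          organ, compound, date, replicate, conc_mg_g, d13C_permil
* roots:        scanner_id, date, elongation_mm
* fluxes:       per-closure inversion table (see chamber.fit_closures)
* daily fluxes: date, chamber, mean_flux_umol_m2_s, d13C_weighted_permil,
                n_closures
* phenology:    date, n_ab, growth_rate
* periods:      name, start, end
* models:       model, response, predictor, estimate, se, p, sign, r2,
                r2_conditional, doy_included, n, df
* coherence:    long format date, period_days, coherence, phase_rad,
                significant, in_coi
"""

from __future__ import annotations

import pandas as pd

from .synthetic import ClosureRecord, EnvironmentSeries

CLOSURE_COLUMNS = [
    "closure_id", "chamber", "start_time", "time_s", "c12_ppm", "c13_ppm",
    "volume_l", "area_m2", "par",
]
ENV_COLUMNS = ["timestamp", "air_T", "soil_T", "PAR", "soil_moisture", "precip"]
TRACHEID_COLUMNS = ["tree_id", "date", "n_a", "n_b", "n_c", "n_total", "prev_ring_width_mm"]
NSC_COLUMNS = ["organ", "compound", "date", "replicate", "conc_mg_g", "d13C_permil"]
ROOT_COLUMNS = ["scanner_id", "date", "elongation_mm"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def write_closures_csv(closures: list[ClosureRecord], path: str) -> None:
    frames = []
    for rec in closures:
        frames.append(
            pd.DataFrame(
                {
                    "closure_id": rec.closure_id,
                    "chamber": rec.kind,
                    "start_time": rec.start.isoformat(),
                    "time_s": rec.time_s,
                    "c12_ppm": rec.c12,
                    "c13_ppm": rec.c13,
                    "volume_l": rec.volume_l,
                    "area_m2": rec.area_m2,
                    "par": rec.par,
                }
            )
        )
    pd.concat(frames, ignore_index=True)[CLOSURE_COLUMNS].to_csv(path, index=False)


def read_closures_csv(path: str) -> list[ClosureRecord]:
    df = pd.read_csv(path)
    _check_columns(df, CLOSURE_COLUMNS, "closures")
    records = []
    for cid, grp in df.groupby("closure_id", sort=False):
        grp = grp.sort_values("time_s")
        records.append(
            ClosureRecord(
                closure_id=str(cid),
                kind=str(grp["chamber"].iloc[0]),
                start=pd.Timestamp(grp["start_time"].iloc[0]),
                time_s=grp["time_s"].to_numpy(float),
                c12=grp["c12_ppm"].to_numpy(float),
                c13=grp["c13_ppm"].to_numpy(float),
                volume_l=float(grp["volume_l"].iloc[0]),
                area_m2=float(grp["area_m2"].iloc[0]),
                par=float(grp["par"].iloc[0]),
            )
        )
    return records


def write_environment_csv(env: EnvironmentSeries, path: str) -> None:
    env.to_frame().to_csv(path, index=False)


def read_environment_csv(path: str) -> EnvironmentSeries:
    df = pd.read_csv(path)
    _check_columns(df, ENV_COLUMNS, "environment")
    return EnvironmentSeries.from_frame(df)


def write_table_csv(df: pd.DataFrame, path: str, required: list[str] | None = None) -> None:
    if required is not None:
        _check_columns(df, required, path)
        df = df[required + [c for c in df.columns if c not in required]]
    df.to_csv(path, index=False)


def read_tracheids_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRACHEID_COLUMNS, "tracheids")
    return df.assign(date=pd.to_datetime(df["date"]))


def read_nsc_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, NSC_COLUMNS, "nsc")
    return df.assign(date=pd.to_datetime(df["date"]))


def read_roots_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ROOT_COLUMNS, "roots")
    return df.assign(date=pd.to_datetime(df["date"]))


def read_daily_series_csv(path: str, value_col: str | None = None) -> pd.Series:
    """Read a (date, value) CSV into a date-indexed series."""
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise ValueError(f"{path}: expected a 'date' column")
    if value_col is None:
        others = [c for c in df.columns if c != "date"]
        if len(others) != 1:
            raise ValueError(f"{path}: expected exactly one value column, found {others}")
        value_col = others[0]
    s = pd.Series(
        df[value_col].to_numpy(float),
        index=pd.DatetimeIndex(pd.to_datetime(df["date"])),
        name=value_col,
    )
    return s.sort_index()


def nsc_wide(nsc: pd.DataFrame, organ: str, value: str = "conc_mg_g",
             per_replicate: bool = False) -> pd.DataFrame:
    """Pivot the long NSC table to date × compound (mean over replicates by
    default), adding a ``nsc`` column = wsc + starch when both exist."""
    sub = nsc[nsc["organ"] == organ]
    if per_replicate:
        wide = sub.pivot_table(index=["date", "replicate"], columns="compound",
                               values=value, aggfunc="mean").reset_index()
    else:
        wide = sub.pivot_table(index="date", columns="compound", values=value,
                               aggfunc="mean").reset_index()
    wide.columns.name = None
    if "wsc" in wide.columns and "starch" in wide.columns and value == "conc_mg_g":
        wide["nsc"] = wide["wsc"] + wide["starch"]
    return wide


def night_day_means(env: EnvironmentSeries, night_par_threshold: float = 30.0) -> pd.DataFrame:
    """Daily driver aggregates: nightly mean air T, daily mean soil T and
    moisture. Night is PAR < threshold; the night of a calendar day collects
    that day's sub-threshold timestamps."""
    df = env.to_frame()
    df["date"] = df["timestamp"].dt.normalize()
    night = df[df["PAR"] < night_par_threshold]
    out = pd.DataFrame(
        {
            "night_air_t": night.groupby("date")["air_T"].mean(),
            "soil_t": df.groupby("date")["soil_T"].mean(),
            "soil_moisture": df.groupby("date")["soil_moisture"].mean(),
        }
    )
    out.index = out.index.date
    out.index.name = "date"
    return out
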