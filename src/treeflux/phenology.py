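"""Xylogenesis phenology: tracheid normalization, Gompertz fits, growth
periods, and fibrous-root pulse detection.

Cumulative tracheid counts (total and mature, phase c) are normalized by each
tree's previous-year ring width, pooled per date, and fitted with the
three-parameter Gompertz curve

    y(t) = A·exp(−β·exp(−κ t)) = A·exp(−exp(−κ(t − t0))),   β = e^{κ t0}

with t in day-of-year. The fit is parameterized internally as (A, t0, κ) —
the displacement β of the classical form is numerically awkward (it reaches
1e5 for realistic mid-season inflections) while t0, the inflection day, is
well scaled. Daily counts of tracheids in the active phases (enlargement +
wall thickening, a+b) are the difference of the fitted total and mature
curves; the tracheid growth rate is the day-over-day increment of the fitted
total curve (new cells enter the active pool via enlargement), which is
non-negative by construction.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GompertzFit",
    "GrowthPeriods",
    "GompertzFitError",
    "normalize_counts",
    "fit_gompertz",
    "derive_active_phase",
    "classify_growth_periods",
    "detect_root_periods",
]


class GompertzFitError(RuntimeError):
    """Raised when the multi-start Gompertz fit fails to converge."""

    def __init__(self, message: str, best_params=None, best_cost=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_cost = best_cost


@dataclass
class GompertzFit:
    """Fitted Gompertz curve for a cumulative tracheid count series."""

    asymptote: float          # A, cells (per mm previous ring when normalized)
    midpoint: float           # t0, DOY of the inflection
    rate: float               # κ, d⁻¹
    residual_sd: float
    n_obs: int
    converged: bool
    t_obs: np.ndarray = field(repr=False)
    y_obs: np.ndarray = field(repr=False)

    @property
    def beta(self) -> float:
        """Displacement parameter of the classical A·exp(−β·exp(−κt)) form."""
        return float(np.exp(self.rate * self.midpoint))

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        return self.asymptote * np.exp(-np.exp(-self.rate * (np.asarray(t, float) - self.midpoint)))

    def rate_curve(self, t: np.ndarray | float) -> np.ndarray:
        """Analytic derivative dy/dt (cells d⁻¹)."""
        u = -self.rate * (np.asarray(t, float) - self.midpoint)
        return self.asymptote * self.rate * np.exp(u) * np.exp(-np.exp(u))


@dataclass
class GrowthPeriods:
    """Named date intervals delimiting growth phases."""

    periods: dict[str, tuple[dt.date, dt.date]]

    def __post_init__(self) -> None:
        for name, (start, end) in self.periods.items():
            if end < start:
                raise ValueError(f"period {name!r} ends before it starts")

    def __getitem__(self, name: str) -> tuple[dt.date, dt.date]:
        return self.periods[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"name": k, "start": v[0], "end": v[1]} for k, v in self.periods.items()]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GrowthPeriods":
        return cls(
            {
                str(r["name"]): (pd.Timestamp(r["start"]).date(), pd.Timestamp(r["end"]).date())
                for _, r in df.iterrows()
            }
        )


# ---------------------------------------------------------------------------


def normalize_counts(obs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ring-width-normalize tracheid counts and pool across trees per date.

    Each tree's counts are divided by its previous-year ring width; trees
    with missing or non-positive width are excluded with a warning. Returns
    ``(pooled, per_tree)``: pooled per-date means of the normalized total,
    mature and active counts, and the per-tree normalized table (kept for
    mixed models).
    """
    df = obs.copy()
    bad = df["prev_ring_width_mm"].isna() | (df["prev_ring_width_mm"] <= 0)
    if bad.any():
        dropped = sorted(df.loc[bad, "tree_id"].unique())
        warnings.warn(f"excluding trees with missing/non-positive ring width: {dropped}")
        df = df[~bad]
    w = df["prev_ring_width_mm"]
    per_tree = df.assign(
        total_norm=df["n_total"] / w,
        mature_norm=df["n_c"] / w,
        active_norm=(df["n_a"] + df["n_b"]) / w,
    )[["tree_id", "date", "total_norm", "mature_norm", "active_norm"]]
    pooled = (
        per_tree.groupby("date", as_index=False)[["total_norm", "mature_norm", "active_norm"]]
        .mean()
        .sort_values("date", ignore_index=True)
    )
    return pooled, per_tree


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a0 = 1.05 * max(y.max(), 1e-6)
    # inflection near y = A/e; log-linearize the mid-rise for the rate
    mid = (y > 0.05 * a0) & (y < 0.95 * a0)
    if mid.sum() >= 3:
        z = -np.log(-np.log(np.clip(y[mid] / a0, 1e-9, 1 - 1e-9)))
        k0, c0 = np.polyfit(t[mid], z, 1)
        k0 = abs(k0) if abs(k0) > 1e-4 else 0.05
        t00 = -c0 / k0
    else:
        k0, t00 = 0.05, float(np.median(t))
    t00 = float(np.clip(t00, t.min() - 100, t.max() + 100))
    return a0, t00, k0


def fit_gompertz(t, y, max_starts: int = 7) -> GompertzFit:
    """Least-squares Gompertz fit with multi-start initialization.

    ``t`` is day-of-year (or any monotone day axis), ``y`` the cumulative
    count. Requires at least 6 observations spanning rise and plateau.
    Raises :class:`GompertzFitError` carrying best-so-far diagnostics if no
    start converges.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if len(t) < 6:
        raise ValueError("at least 6 observations are required for a Gompertz fit")

    def resid(p):
        a, t0, k = p
        return a * np.exp(-np.exp(-k * (t - t0))) - y

    a0, t00, k0 = _initial_guess(t, y)
    span = max(t.max() - t.min(), 1.0)
    starts = [(a0, t00, k0)]
    jitter = [(1.0, 0.0, 0.5), (1.0, 0.0, 2.0), (1.2, 0.15, 1.0),
              (0.9, -0.15, 1.0), (1.0, 0.3, 0.7), (1.0, -0.3, 1.5)]
    for fa, ft, fk in jitter[: max_starts - 1]:
        starts.append((a0 * fa, t00 + ft * span, k0 * fk))

    best = None
    for start in starts:
        try:
            sol = least_squares(
                resid, x0=start,
                bounds=([1e-9, t.min() - 5 * span, 1e-5], [np.inf, t.max() + 5 * span, 5.0]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise GompertzFitError("Gompertz fit failed for all starts",
                               best_params=None if best is None else best.x,
                               best_cost=None if best is None else best.cost)
    a, t0, k = best.x
    res = resid(best.x)
    dof = max(len(t) - 3, 1)
    return GompertzFit(
        asymptote=float(a), midpoint=float(t0), rate=float(k),
        residual_sd=float(np.sqrt(res @ res / dof)), n_obs=len(t),
        converged=bool(best.success), t_obs=t, y_obs=y,
    )


def derive_active_phase(
    total_fit: GompertzFit,
    mature_fit: GompertzFit,
    doy_grid: np.ndarray,
) -> pd.DataFrame:
    """Daily active-phase counts and tracheid growth rate on ``doy_grid``.

    ``n_ab(t)`` is the fitted total minus fitted mature count, clipped at 0
    (with a warning when the curves cross); the growth rate is the
    day-over-day increase of the fitted total curve.
    """
    doy = np.asarray(doy_grid, float)
    if np.any(np.diff(doy) <= 0):
        raise ValueError("doy_grid must be strictly increasing")
    total = total_fit.predict(doy)
    mature = mature_fit.predict(doy)
    n_ab = total - mature
    if (n_ab < -1e-9).any():
        warnings.warn("fitted mature curve exceeds total curve; active counts clipped at 0")
    n_ab = np.maximum(n_ab, 0.0)
    growth = np.empty_like(total)
    growth[1:] = np.diff(total)
    growth[0] = growth[1] if len(growth) > 1 else 0.0
    return pd.DataFrame({"doy": doy, "n_ab": n_ab, "growth_rate": growth})


def _interval_from_mask(doy: np.ndarray, mask: np.ndarray, label: str) -> tuple[float, float]:
    if not mask.any():
        raise ValueError(f"no dates satisfy threshold for period {label!r}")
    idx = np.nonzero(mask)[0]
    return float(doy[idx[0]]), float(doy[idx[-1]])


def _doy_to_date(doy: float, year: int) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(round(doy)) - 1)


def classify_growth_periods(
    total_fit: GompertzFit,
    mature_fit: GompertzFit,
    year: int,
    doy_grid: np.ndarray | None = None,
    rate_threshold_frac: float = 0.05,
    max_rate_threshold_frac: float = 0.75,
    ew_quantile: float = 0.60,
    lw_quantile: float = 0.80,
) -> GrowthPeriods:
    """Delimit tracheid production/maturation and wood-type periods.

    Production (maturation) period: days where the fitted total (mature)
    rate exceeds ``rate_threshold_frac`` of its own maximum; "max" periods
    use ``max_rate_threshold_frac``. Earlywood ends where the fitted total
    curve reaches ``ew_quantile`` of its asymptote, latewood starts at
    ``lw_quantile``, with the transition in between. All thresholds are free
    parameters — the interval printed for a given stand depends on them.
    """
    if doy_grid is None:
        doy_grid = np.arange(60.0, 340.0)
    doy = np.asarray(doy_grid, float)
    rt = total_fit.rate_curve(doy)
    rm = mature_fit.rate_curve(doy)

    prod = _interval_from_mask(doy, rt >= rate_threshold_frac * rt.max(), "tracheid_production")
    matu = _interval_from_mask(doy, rm >= rate_threshold_frac * rm.max(), "tracheid_maturation")
    prod_max = _interval_from_mask(doy, rt >= max_rate_threshold_frac * rt.max(), "max_production")
    matu_max = _interval_from_mask(doy, rm >= max_rate_threshold_frac * rm.max(), "max_maturation")

    y_tot = total_fit.predict(doy)
    ew_mask = y_tot >= ew_quantile * total_fit.asymptote
    lw_mask = y_tot >= lw_quantile * total_fit.asymptote
    if not ew_mask.any() or not lw_mask.any():
        raise ValueError("earlywood/latewood quantile never reached on grid")
    ew_end = float(doy[np.nonzero(ew_mask)[0][0]])
    lw_start = float(doy[np.nonzero(lw_mask)[0][0]])

    d = lambda x: _doy_to_date(x, year)  # noqa: E731
    return GrowthPeriods(
        {
            "tracheid_production": (d(prod[0]), d(prod[1])),
            "tracheid_maturation": (d(matu[0]), d(matu[1])),
            "max_production": (d(prod_max[0]), d(prod_max[1])),
            "max_maturation": (d(matu_max[0]), d(matu_max[1])),
            "earlywood": (d(prod[0]), d(ew_end)),
            "ew_lw_transition": (d(ew_end + 1), d(max(lw_start - 1, ew_end + 1))),
            "latewood": (d(lw_start), d(matu[1])),
        }
    )


def detect_root_periods(
    roots: pd.DataFrame,
    min_amp: float = 0.15,
    min_gap_days: int = 5,
    smooth_days: int = 7,
) -> GrowthPeriods:
    """Segment per-scanner root elongation into pulse periods.

    Each scanner's daily elongation is smoothed with a centered moving mean
    of ``smooth_days``; runs of days at or above ``min_amp`` (mm d⁻¹) that
    are separated by fewer than ``min_gap_days`` are merged, and overlapping
    intervals from different scanners are merged into stand-level periods,
    named ``root_period_I``, ``root_period_II``, … in chronological order.
    An all-zero series yields zero periods (not an error).
    """
    df = roots.copy()
    df["date"] = pd.to_datetime(df["date"])
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for _, grp in df.groupby("scanner_id"):
        grp = grp.sort_values("date")
        sm = grp["elongation_mm"].rolling(smooth_days, center=True, min_periods=1).mean()
        dates = grp["date"].to_numpy()
        above = sm.to_numpy() >= min_amp
        runs = []
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                runs.append((dates[i], dates[j]))
                i = j + 1
            else:
                i += 1
        merged = []
        for run in runs:
            if merged and (run[0] - merged[-1][1]) / np.timedelta64(1, "D") < min_gap_days:
                merged[-1] = (merged[-1][0], run[1])
            else:
                merged.append(run)
        intervals.extend(merged)

    intervals.sort()
    pooled: list[list[pd.Timestamp]] = []
    for start, end in intervals:
        if pooled and start <= pooled[-1][1] + np.timedelta64(1, "D"):
            pooled[-1][1] = max(pooled[-1][1], end)
        else:
            pooled.append([start, end])

    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    names = {}
    for i, (start, end) in enumerate(pooled):
        label = roman[i] if i < len(roman) else str(i + 1)
        names[f"root_period_{label}"] = (pd.Timestamp(start).date(), pd.Timestamp(end).date())
    return GrowthPeriods(names)
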