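"""Morlet wavelet coherence with AR(1) surrogate significance.

The continuous wavelet transform follows the standard FFT implementation for
the analytic Morlet wavelet with ω₀ = 6 on a dyadic scale grid (default 12
voices per octave); period = scale·4π/(ω₀+√(2+ω₀²)) ≈ 1.033·scale. Squared
coherence between two daily series x and y is

    R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

with the usual smoothing operator S: a Gaussian window of standard deviation
s in time and a boxcar of 0.6 octaves across scales. The phase of the
smoothed cross-spectrum gives the local lead/lag: for y lagging x by L days
at period P the phase is +2πL/P, i.e. phases in (0, π) mean x leads.

Significance is assessed against coherence of independent AR(1) surrogate
pairs matched to each input's lag-1 autocorrelation, pooled per scale inside
the cone of influence (the region free of zero-padding edge effects, with
e-folding time √2·s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology import GrowthPeriods

__all__ = [
    "DailySeries",
    "WaveletCoherenceResult",
    "interpolate_gaps",
    "cwt_morlet",
    "coherence",
    "significance",
    "lead_lag_summary",
    "ar1_params",
    "plot_coherence",
]

OMEGA0 = 6.0
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))


@dataclass
class DailySeries:
    """Gap-free daily series with the record of which dates were filled."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    gap_mask: np.ndarray  # True where the value was interpolated

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.values) or len(self.values) != len(self.gap_mask):
            raise ValueError("dates, values and gap_mask must have equal length")
        step = np.diff(self.dates.asi8)
        if len(step) and not (step == 86_400_000_000_000).all():
            raise ValueError("dates must be contiguous daily")

    @property
    def gap_fraction(self) -> float:
        return float(self.gap_mask.mean()) if len(self.gap_mask) else 0.0


def interpolate_gaps(
    dates,
    values,
    max_gap_fraction: float = 0.10,
) -> DailySeries:
    """Linearly interpolate interior gaps of a daily series.

    ``dates`` need not be contiguous; missing dates and NaN values count as
    gaps. Leading/trailing gaps are trimmed rather than extrapolated. Raises
    if the interior gap fraction exceeds ``max_gap_fraction``.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    s = pd.Series(np.asarray(values, float), index=idx).sort_index()
    s = s[~s.index.duplicated(keep="first")]
    full = pd.date_range(s.index[0], s.index[-1], freq="D")
    s = s.reindex(full)
    valid = s.notna().to_numpy()
    if not valid.any():
        raise ValueError("series has no valid values")
    first, last = np.nonzero(valid)[0][[0, -1]]
    s = s.iloc[first:last + 1]
    gap = s.isna().to_numpy()
    frac = gap.mean()
    if frac > max_gap_fraction:
        raise ValueError(
            f"gap fraction {frac:.1%} exceeds ceiling {max_gap_fraction:.1%}"
        )
    filled = s.interpolate(method="linear")
    return DailySeries(dates=pd.DatetimeIndex(filled.index), values=filled.to_numpy(),
                       gap_mask=gap)


# ---------------------------------------------------------------------------
# transform


def _scale_grid(n: int, dt: float, dj: float, min_period: float,
                max_period: float) -> np.ndarray:
    limit = n * dt / 2.0
    if max_period > limit:
        warnings.warn(
            f"max period {max_period} exceeds half the series length; truncated to {limit:.1f}"
        )
        max_period = limit
    s0 = min_period / FOURIER_FACTOR
    n_oct = np.log2(max_period / min_period)
    j = int(np.floor(n_oct / dj))
    return s0 * 2.0 ** (dj * np.arange(j + 1))


def cwt_morlet(
    x: np.ndarray,
    dt: float = 1.0,
    dj: float = 1.0 / 12.0,
    min_period: float = 2.0,
    max_period: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet (ω₀=6) continuous wavelet transform of a 1-D series.

    Returns ``(W, periods, coi)``: complex coefficients of shape
    (n_scales, n), the Fourier periods of each scale row, and the cone of
    influence (maximum reliable period per time step). The series is
    mean-removed and zero-padded to the next power of two.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        raise ValueError("series too short for a wavelet transform")
    if max_period is None:
        max_period = n * dt / 2.0
    if n * dt < 2.0 * min_period:
        raise ValueError("series shorter than twice the minimum period")
    scales = _scale_grid(n, dt, dj, min_period, max_period)

    npad = int(2 ** np.ceil(np.log2(n)))
    xa = np.zeros(npad)
    xa[:n] = x - x.mean()
    xhat = np.fft.fft(xa)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)

    W = np.empty((len(scales), n), complex)
    norm_const = np.pi ** -0.25
    pos = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        psi_hat[pos] = (
            norm_const * np.sqrt(2.0 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega[pos] - OMEGA0) ** 2)
        )
        W[i] = np.fft.ifft(xhat * psi_hat)[:n]

    periods = scales * FOURIER_FACTOR
    t_edge = dt * np.minimum(np.arange(n), np.arange(n)[::-1])
    coi = FOURIER_FACTOR * np.sqrt(2.0) * np.maximum(t_edge, dt * 1e-9)
    return W, periods, coi


def _smooth(mat: np.ndarray, scales: np.ndarray, dt: float, dj: float) -> np.ndarray:
    """Coherence smoothing: Gaussian (SD = scale) in time, 0.6-octave boxcar
    across scales."""
    n = mat.shape[1]
    out = np.empty_like(mat)
    for i, s in enumerate(scales):
        sigma = s / dt
        # kernel truncated at 4σ but never longer than the series
        half = min(max(int(np.ceil(4 * sigma)), 1), (n - 1) // 2)
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        if np.iscomplexobj(mat):
            re = np.convolve(mat[i].real, k, mode="same")
            im = np.convolve(mat[i].imag, k, mode="same")
            out[i] = re + 1j * im
        else:
            out[i] = np.convolve(mat[i], k, mode="same")
    m = max(int(round(0.6 / dj)), 1)
    if m > 1:
        box = np.ones(m) / m
        pad = m // 2
        padded = np.pad(out, ((pad, m - 1 - pad), (0, 0)), mode="edge")
        out = np.apply_along_axis(lambda c: np.convolve(c, box, mode="valid"), 0, padded)
    return out


@dataclass
class WaveletCoherenceResult:
    """Coherence, phase and significance over the (time × period) plane."""

    dates: pd.DatetimeIndex
    periods: np.ndarray            # days
    coherence: np.ndarray          # [n_periods, n_times], in [0, 1]
    phase: np.ndarray              # radians, (−π, π]
    coi: np.ndarray                # max valid period per time, days
    dj: float
    sig_mask: np.ndarray | None = None
    sig_thresholds: np.ndarray | None = None   # per period row
    surrogate_spec: dict = field(default_factory=dict)

    @property
    def inside_coi(self) -> np.ndarray:
        return self.periods[:, None] <= self.coi[None, :]

    def to_long_frame(self) -> pd.DataFrame:
        nper, nt = self.coherence.shape
        sig = self.sig_mask if self.sig_mask is not None else np.zeros_like(self.coherence, bool)
        return pd.DataFrame(
            {
                "date": np.repeat(self.dates.date, nper),
                "period_days": np.tile(self.periods, nt),
                "coherence": self.coherence.T.ravel(),
                "phase_rad": self.phase.T.ravel(),
                "significant": sig.T.ravel(),
                "in_coi": self.inside_coi.T.ravel(),
            }
        )


def coherence(
    x: DailySeries,
    y: DailySeries,
    dj: float = 1.0 / 12.0,
    min_period: float = 2.0,
    max_period: float | None = None,
) -> WaveletCoherenceResult:
    """Squared wavelet coherence and phase between two daily series."""
    if len(x.dates) != len(y.dates) or not (x.dates == y.dates).all():
        raise ValueError("series must share a common date grid")
    n = len(x.values)
    Wx, periods, coi = cwt_morlet(x.values, 1.0, dj, min_period, max_period)
    Wy, _, _ = cwt_morlet(y.values, 1.0, dj, min_period, max_period)
    scales = periods / FOURIER_FACTOR
    if scales[0] * 4 > n:
        raise ValueError("smoothing window exceeds series length")
    inv_s = 1.0 / scales[:, None]
    s_xy = _smooth(Wx * np.conj(Wy) * inv_s, scales, 1.0, dj)
    s_xx = _smooth((np.abs(Wx) ** 2) * inv_s, scales, 1.0, dj)
    s_yy = _smooth((np.abs(Wy) ** 2) * inv_s, scales, 1.0, dj)
    denom = s_xx.real * s_yy.real
    with np.errstate(invalid="ignore", divide="ignore"):
        coh2 = np.abs(s_xy) ** 2 / denom
    coh2 = np.clip(np.nan_to_num(coh2, nan=0.0), 0.0, 1.0)
    phase = np.angle(s_xy)
    return WaveletCoherenceResult(
        dates=x.dates, periods=periods, coherence=coh2, phase=phase, coi=coi, dj=dj,
    )


# ---------------------------------------------------------------------------
# significance


def ar1_params(v: np.ndarray) -> tuple[float, float]:
    """Lag-1 autocorrelation and standard deviation of a series."""
    v = np.asarray(v, float)
    v = v - v.mean()
    sd = float(v.std())
    if sd < 1e-12:
        raise ValueError("degenerate (constant) series")
    r1 = float(np.dot(v[:-1], v[1:]) / np.dot(v, v))
    return float(np.clip(r1, -0.99, 0.99)), sd


def _ar1_surrogate(rng: np.random.Generator, r1: float, sd: float, n: int) -> np.ndarray:
    out = np.empty(n)
    out[0] = rng.normal(0, sd)
    eps = rng.normal(0, sd * np.sqrt(1 - r1**2), n)
    for i in range(1, n):
        out[i] = r1 * out[i - 1] + eps[i]
    return out


def null_thresholds(
    r1x: float,
    r1y: float,
    n: int,
    dj: float = 1.0 / 12.0,
    min_period: float = 2.0,
    max_period: float | None = None,
    n_surrogates: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-period (1−α) coherence quantiles under independent AR(1) pairs.

    Null values are pooled across times inside the cone of influence.
    Returns ``(periods, thresholds)``.
    """
    if n_surrogates < 100:
        raise ValueError("at least 100 surrogates are required")
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2000-01-01", periods=n, freq="D")
    pooled: list[list[float]] = []
    periods = None
    for _ in range(n_surrogates):
        xs = DailySeries(dates, _ar1_surrogate(rng, r1x, 1.0, n), np.zeros(n, bool))
        ys = DailySeries(dates, _ar1_surrogate(rng, r1y, 1.0, n), np.zeros(n, bool))
        res = coherence(xs, ys, dj, min_period, max_period)
        if periods is None:
            periods = res.periods
            pooled = [[] for _ in periods]
        inside = res.inside_coi
        for i in range(len(periods)):
            pooled[i].extend(res.coherence[i, inside[i]])
    thresholds = np.array([
        np.quantile(vals, 1.0 - alpha) if vals else np.nan for vals in pooled
    ])
    return periods, thresholds


def significance(
    result: WaveletCoherenceResult,
    x: DailySeries,
    y: DailySeries,
    n_surrogates: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> WaveletCoherenceResult:
    """Attach an AR(1)-surrogate significance mask to a coherence result.

    The null matches each series' lag-1 autocorrelation; the mask marks
    cells inside the cone of influence whose coherence exceeds the per-period
    (1−α) null quantile. ``alpha=1`` marks every in-cone cell.
    """
    r1x, _ = ar1_params(x.values)
    r1y, _ = ar1_params(y.values)
    if alpha >= 1.0:
        thresholds = np.zeros(len(result.periods)) - 1.0
    else:
        _, thresholds = null_thresholds(
            r1x, r1y, len(x.values), result.dj,
            float(result.periods[0]), float(result.periods[-1]),
            n_surrogates, alpha, seed,
        )
    mask = (result.coherence > thresholds[:, None]) & result.inside_coi
    result.sig_mask = mask
    result.sig_thresholds = thresholds
    result.surrogate_spec = {
        "n_surrogates": n_surrogates, "alpha": alpha, "seed": seed,
        "model": "ar1", "r1x": r1x, "r1y": r1y,
    }
    return result


# ---------------------------------------------------------------------------
# lead/lag summaries


def lead_lag_summary(
    result: WaveletCoherenceResult,
    named_periods: GrowthPeriods | dict,
    bands: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Lead/lag structure per (named date interval × period band).

    Within each stratum (inside the cone of influence), reports the fraction
    of significant cells, and — over significant cells where x leads y
    (phase in (0, π), the physiologically meaningful direction when x is the
    upstream signal) — the circular-mean phase and the mean implied lag in
    days (phase·P/2π per cell). Strata without significant leading cells get
    fraction/lag of 0/NaN.
    """
    if result.sig_mask is None:
        raise ValueError("run significance() before summarizing lead/lag")
    if bands is None:
        bands = [(4.0, 8.0), (8.0, 16.0), (16.0, 32.0)]
    if isinstance(named_periods, GrowthPeriods):
        named = named_periods.periods
    else:
        named = named_periods

    dates = result.dates
    rows = []
    for name, (start, end) in named.items():
        t_mask = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
        for pmin, pmax in bands:
            p_mask = (result.periods >= pmin) & (result.periods < pmax)
            stratum = result.inside_coi & p_mask[:, None] & t_mask[None, :]
            n_cells = int(stratum.sum())
            sig = result.sig_mask & stratum
            n_sig = int(sig.sum())
            lead = sig & (result.phase > 0) & (result.phase < np.pi)
            if lead.any():
                ph = result.phase[lead]
                per = np.broadcast_to(result.periods[:, None], result.phase.shape)[lead]
                mean_phase = float(np.angle(np.exp(1j * ph).mean()))
                lag = float(np.mean(ph * per / (2.0 * np.pi)))
            else:
                mean_phase = float("nan")
                lag = float("nan")
            rows.append(
                {
                    "period_name": name,
                    "band_days": f"{pmin:g}-{pmax:g}",
                    "n_cells": n_cells,
                    "frac_significant": n_sig / n_cells if n_cells else 0.0,
                    "n_leading": int(lead.sum()),
                    "mean_phase_rad": mean_phase,
                    "lag_days": lag,
                }
            )
    return pd.DataFrame(rows)


def plot_coherence(result: WaveletCoherenceResult, path: str) -> None:
    """Render the coherence plane with significance contours and the cone."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    t = np.arange(len(result.dates))
    mesh = ax.pcolormesh(t, result.periods, result.coherence, cmap="jet",
                         vmin=0, vmax=1, shading="auto")
    if result.sig_mask is not None and result.sig_mask.any():
        ax.contour(t, result.periods, result.sig_mask.astype(float), levels=[0.5],
                   colors="white", linewidths=1.2)
    ax.plot(t, result.coi, color="white", linestyle="--", linewidth=1)
    ax.fill_between(t, result.coi, result.periods.max(), color="white", alpha=0.35)
    ax.set_yscale("log", base=2)
    ax.set_ylim(result.periods.min(), result.periods.max())
    ax.invert_yaxis()
    ax.set_xlabel("day of record")
    ax.set_ylabel("period (days)")
    step = max(len(t) // 8, 1)
    ax.set_xticks(t[::step])
    ax.set_xticklabels([d.strftime("%b %d") for d in result.dates[::step]], rotation=30)
    fig.colorbar(mesh, ax=ax, label="squared coherence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
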