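"""Environmental detrending and growth–NSC–respiration association models.

The analysis chain mirrors standard practice in tree ecophysiology:

* nighttime stem CO₂ efflux is detrended against temperature with
  R = a·e^{bT} (the fitted b maps to Q10 = e^{10b});
* the residual response is shifted by one day because measured stem efflux
  lags actual stem respiration (within-stem diffusion resistance);
* root growth and soil efflux are detrended by an additive linear regression
  on soil temperature and soil moisture;
* associations are tested with ordinary linear models (stand-level averages)
  or linear mixed-effects models with a per-tree random intercept (repeated
  measures on the same trees). Day-of-year starts as a covariate and is
  dropped iff non-significant; an optional interaction term is likewise
  dropped when non-significant.

Mixed models are fitted by REML (statsmodels ``MixedLM``); p-values use a t
reference with containment-style degrees of freedom n − p − (g − 1), and R²
is reported in the marginal/conditional variance-partition sense.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "ExpFit",
    "ModelResult",
    "TermResult",
    "fit_exponential_temperature",
    "q10_from_coef",
    "lag_shift",
    "fit_env_regression",
    "fit_lm",
    "fit_lmm",
]


@dataclass
class ExpFit:
    """Exponential temperature response R = a·e^{bT} and its residuals."""

    a: float
    b: float
    r2: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)

    def predict(self, temp: np.ndarray | float) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(temp, float))

    @property
    def q10(self) -> float:
        return q10_from_coef(self.b)


def q10_from_coef(b: float) -> float:
    """Q10 implied by the exponential temperature coefficient: e^{10b}."""
    return float(np.exp(10.0 * b))


def fit_exponential_temperature(flux, temp) -> ExpFit:
    """Fit R = a·e^{bT} by non-linear least squares.

    Initialized in log space when all fluxes are positive, otherwise from
    inter-quartile ratios. Requires ≥ 10 paired observations.
    """
    y = np.asarray(flux, float)
    t = np.asarray(temp, float)
    if len(y) != len(t):
        raise ValueError("flux and temperature series must be paired")
    if len(y) < 10:
        raise ValueError("at least 10 paired days are required")

    if (y > 0).all():
        b0, loga = np.polyfit(t, np.log(y), 1)
        a0 = float(np.exp(loga))
    else:
        lo_t, hi_t = np.quantile(t, [0.25, 0.75])
        lo = y[t <= lo_t].mean()
        hi = y[t >= hi_t].mean()
        if lo > 0 and hi > 0 and hi_t > lo_t:
            b0 = float(np.log(hi / lo) / (hi_t - lo_t))
        else:
            b0 = 0.07
        a0 = max(float(np.mean(y) / np.exp(b0 * t.mean())), 1e-6)

    sol = least_squares(
        lambda p: p[0] * np.exp(p[1] * t) - y, x0=[a0, b0],
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a, b = sol.x
    fitted = a * np.exp(b * t)
    res = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(res @ res) / ss_tot if ss_tot > 0 else float("nan")
    return ExpFit(a=float(a), b=float(b), r2=r2, residuals=res, fitted=fitted)


def lag_shift(series: pd.Series, lag_days: int = 1) -> pd.Series:
    """Align a daily response so predictor day t pairs with response day t+lag.

    Returns the series re-indexed to the predictor's days (value at index t
    is the original value at t+lag); the trailing ``lag_days`` boundary days
    are dropped. ``lag_days=0`` is the identity.
    """
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    if lag_days >= len(series):
        raise ValueError(f"lag of {lag_days} days exceeds series length {len(series)}")
    if lag_days == 0:
        return series.copy()
    return series.shift(-lag_days).iloc[:-lag_days]


def fit_env_regression(response, soil_t, soil_moisture) -> tuple[np.ndarray, "ModelResult"]:
    """Residuals of an additive linear regression on soil T and moisture."""
    y = np.asarray(response, float)
    x1 = np.asarray(soil_t, float)
    x2 = np.asarray(soil_moisture, float)
    if not (len(y) == len(x1) == len(x2)):
        raise ValueError("response and drivers must be aligned")
    r = np.corrcoef(x1, x2)[0, 1]
    if abs(r) > 0.999:
        warnings.warn(f"soil T and moisture nearly collinear (r={r:.4f}); "
                      "pseudo-inverse solution used")
    exog = sm.add_constant(np.column_stack([x1, x2]))
    fit = sm.OLS(y, exog).fit()
    result = _ols_to_result(fit, "response", ["soil_T", "soil_moisture"], doy_included=False)
    return np.asarray(fit.resid), result


# ---------------------------------------------------------------------------
# association models


@dataclass
class TermResult:
    estimate: float
    se: float
    p: float

    @property
    def sign(self) -> str:
        return "+" if self.estimate >= 0 else "-"


@dataclass
class ModelResult:
    """Tidy summary of one fitted association model."""

    kind: str                      # "lm" | "lmm" | "lmm_fallback_lm"
    response: str
    terms: dict[str, TermResult]
    n: int
    df_resid: float
    r2: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    doy_included: bool = False
    trace: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = []
        for name, term in self.terms.items():
            rows.append(
                {
                    "model": self.kind,
                    "response": self.response,
                    "predictor": name,
                    "estimate": term.estimate,
                    "se": term.se,
                    "p": term.p,
                    "sign": term.sign,
                    "r2": self.r2 if self.r2 is not None else self.r2_marginal,
                    "r2_conditional": self.r2_conditional,
                    "doy_included": self.doy_included,
                    "n": self.n,
                    "df": self.df_resid,
                }
            )
        return rows


def _ols_to_result(fit, response: str, names: list[str], doy_included: bool) -> ModelResult:
    terms = {}
    for i, name in enumerate(["const"] + names):
        if name == "const":
            continue
        terms[name] = TermResult(
            estimate=float(fit.params[i]), se=float(fit.bse[i]), p=float(fit.pvalues[i])
        )
    return ModelResult(
        kind="lm", response=response, terms=terms, n=int(fit.nobs),
        df_resid=float(fit.df_resid), r2=float(fit.rsquared), doy_included=doy_included,
    )


def fit_lm(
    data: pd.DataFrame,
    response: str,
    predictors: list[str] | str,
    doy: str | None = None,
    alpha: float = 0.05,
    interaction: bool = False,
    exclude_dates: list[dt.date] | None = None,
    date_col: str = "date",
) -> ModelResult:
    """Ordinary least squares with the covariate-removal rules.

    Day-of-year (column ``doy``) is included first and removed iff its
    p ≥ ``alpha``; with ``interaction=True`` the product of the first two
    predictors is included and likewise removed when non-significant.
    ``exclude_dates`` drops named observation days from the design (used
    when, e.g., starch remobilization makes a sampling day uninterpretable).
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    df = data.copy()
    if exclude_dates:
        drop = {pd.Timestamp(d).date() for d in exclude_dates}
        keep = ~pd.to_datetime(df[date_col]).dt.date.isin(drop)
        df = df[keep]
    cols = [response] + predictors + ([doy] if doy else [])
    df = df.dropna(subset=cols)
    n = len(df)
    trace: list[str] = []

    names = list(predictors)
    if interaction:
        if len(predictors) < 2:
            raise ValueError("interaction requires two predictors")
        inter = f"{predictors[0]}:{predictors[1]}"
        df = df.assign(**{inter: df[predictors[0]] * df[predictors[1]]})
        names = names + [inter]
    if doy:
        names = names + [doy]
    if n <= len(names) + 1:
        raise ValueError(f"n={n} too small for {len(names)} predictors")

    def run(active: list[str]):
        exog = sm.add_constant(df[active].to_numpy(float))
        return sm.OLS(df[response].to_numpy(float), exog).fit()

    fit = run(names)
    if interaction:
        inter = f"{predictors[0]}:{predictors[1]}"
        p_int = float(fit.pvalues[names.index(inter) + 1])
        if p_int >= alpha:
            trace.append(f"interaction {inter} removed (p={p_int:.3f})")
            names.remove(inter)
            fit = run(names)
    doy_included = bool(doy)
    if doy:
        p_doy = float(fit.pvalues[names.index(doy) + 1])
        if p_doy >= alpha:
            trace.append(f"DOY removed (p={p_doy:.3f})")
            names.remove(doy)
            doy_included = False
            fit = run(names)

    result = _ols_to_result(fit, response, names, doy_included)
    result.trace = trace
    return result


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    group: str = "tree_id",
    doy: str | None = None,
    alpha: float = 0.05,
) -> ModelResult:
    """Random-intercept mixed model for repeated measures on the same trees.

    Fitted by REML; p-values use a t reference with containment degrees of
    freedom n − p − (g − 1). DOY is included as a covariate and removed iff
    p ≥ ``alpha``. A singular (zero) random-effect variance triggers a plain
    linear-model fallback, recorded in the result's warnings.
    """
    cols = [response, predictor, group] + ([doy] if doy else [])
    df = data.dropna(subset=cols).copy()
    groups = df[group].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("mixed model requires at least 2 groups")

    def run(names: list[str]) -> tuple[ModelResult | None, float | None]:
        exog = sm.add_constant(df[names].to_numpy(float))
        n, p = exog.shape
        dfree = n - p - (n_groups - 1)
        model = sm.MixedLM(df[response].to_numpy(float), exog, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                mfit = model.fit(reml=True)
            except Exception:
                return None, None
        var_re = float(np.asarray(mfit.cov_re)[0, 0])
        if not np.isfinite(var_re) or var_re < 1e-10 * mfit.scale:
            return None, None
        tvals = np.asarray(mfit.fe_params) / np.asarray(mfit.bse_fe)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), max(dfree, 1))
        terms = {
            name: TermResult(
                estimate=float(mfit.fe_params[i + 1]),
                se=float(mfit.bse_fe[i + 1]),
                p=float(pvals[i + 1]),
            )
            for i, name in enumerate(names)
        }
        linpred = exog @ np.asarray(mfit.fe_params)
        var_f = float(np.var(linpred))
        var_res = float(mfit.scale)
        tot = var_f + var_re + var_res
        result = ModelResult(
            kind="lmm", response=response, terms=terms, n=n, df_resid=float(dfree),
            r2_marginal=var_f / tot, r2_conditional=(var_f + var_re) / tot,
            doy_included=doy in names if doy else False,
        )
        return result, (terms[doy].p if doy in names else None)

    names = [predictor] + ([doy] if doy else [])
    result, p_doy = run(names)
    if result is not None and doy and p_doy is not None and p_doy >= alpha:
        result2, _ = run([predictor])
        if result2 is not None:
            result2.trace.append(f"DOY removed (p={p_doy:.3f})")
            result = result2

    if result is None:
        # singular random effect: plain linear model fallback
        lm = fit_lm(data=df, response=response, predictors=[predictor], doy=doy, alpha=alpha)
        lm.kind = "lmm_fallback_lm"
        lm.warnings.append("singular random-effect variance; plain linear model used")
        return lm
    return result
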