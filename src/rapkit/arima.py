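"""ARIMA structure analysis: stationarity, order search, diagnostics.

The temporal structure of ICP, AMP and RAP is summarized by the optimal
ARIMA(p, d, q) model per patient and signal.  These series are trend-heavy:
the joint ADF/KPSS verdict typically calls the raw series non-stationary,
so a first-order difference is taken after temporal resampling and models
are fitted with d = 0 on the differenced series (equivalent to d = 1 on the
original, and reported that way).  The optimal (p, q) is the AIC argmin
over an exhaustive grid, population structure is summarized by the
componentwise median model, and adequacy is checked through residual
magnitude and significant ACF/PACF spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tools.sm_exceptions import ConvergenceWarning, InterpolationWarning
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import acf as _acf
from statsmodels.tsa.stattools import adfuller, kpss, pacf as _pacf

from .core import IndexSeries, InvalidParameterError

#: significance threshold shared by the ADF and KPSS tests
STATIONARITY_ALPHA = 0.05

#: fewest non-missing samples for which the stationarity tests are attempted
MIN_STATIONARITY_SAMPLES = 20


@dataclass(frozen=True)
class ArimaSpec:
    """ARIMA orders (p, d, q) with p, q in [0, 10] and d in {0, 1}."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 10 and 0 <= self.q <= 10):
            raise InvalidParameterError("p and q must lie in [0, 10]")
        if self.d not in (0, 1):
            raise InvalidParameterError("d must be 0 or 1")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class StationarityResult:
    """Joint ADF/KPSS verdict.

    ``stationary`` is True iff ADF rejects a unit root (p < alpha) AND KPSS
    fails to reject stationarity (p > alpha).  ``None`` marks degenerate or
    insufficient input.  KPSS p-values come from truncated tables; when the
    statistic falls outside them the bounded value is used and flagged.
    """

    adf_p: float | None
    kpss_p: float | None
    stationary: bool | None
    kpss_bounded: bool = False
    adf_bounded: bool = False
    reason: str | None = None


def test_stationarity(series: IndexSeries | np.ndarray) -> StationarityResult:
    """Run ADF and KPSS on the non-missing samples of a series."""
    values = series.dropna() if isinstance(series, IndexSeries) else np.asarray(series, float)
    values = values[~np.isnan(values)]
    if values.size < MIN_STATIONARITY_SAMPLES:
        return StationarityResult(None, None, None, reason="insufficient_data")
    if np.ptp(values) == 0:
        return StationarityResult(None, None, None, reason="degenerate_constant")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        adf_p = float(adfuller(values, autolag="AIC")[1])
        kpss_p = float(kpss(values, regression="c", nlags="auto")[1])
    bounded = any(isinstance(w.message, InterpolationWarning) for w in caught)
    stationary = (adf_p < STATIONARITY_ALPHA) and (kpss_p > STATIONARITY_ALPHA)
    return StationarityResult(
        adf_p=adf_p, kpss_p=kpss_p, stationary=stationary, kpss_bounded=bounded
    )


def difference(series: IndexSeries, order: int = 1) -> IndexSeries:
    """First-order (or repeated) difference, y_t = x_t - x_{t-1}.

    Applied after temporal resampling, never before; length shrinks by
    ``order`` from the front.
    """
    if order < 1:
        raise InvalidParameterError("order must be >= 1")
    if len(series) < order + 1:
        raise InvalidParameterError("series too short to difference")
    values = np.diff(series.values, n=order)
    return IndexSeries(
        name=series.name,
        time=series.time[order:],
        values=values,
        resolution=series.resolution,
    )


@dataclass
class ArimaFit:
    """A fitted ARIMA model: orders, coefficients, criteria, residuals."""

    spec: ArimaSpec
    const: float = np.nan
    ar_coeffs: np.ndarray = field(default_factory=lambda: np.empty(0))
    ma_coeffs: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    loglik: float = np.nan
    k_params: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    reason: str | None = None


#: series length above which the innovations-algorithm MLE outruns the
#: state-space optimizer (both are exact Gaussian MLE; timing differs only)
_INNOVATIONS_MIN_N = 1500

#: minimum distance between AR and MA inverse roots below which a mixed
#: model is treated as redundant (common factor)
_COMMON_FACTOR_TOL = 0.02


def fit_arima(
    series: IndexSeries | np.ndarray,
    spec: ArimaSpec,
    trend: str = "c",
    method: str = "auto",
) -> ArimaFit:
    """Maximum-likelihood ARIMA fit at fixed orders.

    Fitting is on the series as given: callers difference first when
    spec.d == 1 would apply (the grid search handles this).  ``method``
    "auto" picks the state-space optimizer for short series and the
    innovations-algorithm MLE for long ones (identical likelihoods, large
    runtime difference); estimation failures are returned as a
    non-converged fit, never raised.
    """
    values = series.values if isinstance(series, IndexSeries) else np.asarray(series, float)
    values = values[~np.isnan(values)]
    if values.size < spec.p + spec.q + 2:
        return ArimaFit(spec=spec, converged=False, reason="insufficient_data")
    if spec.p == 0 and spec.q == 0:
        # the MLE has a closed form: constant = mean, sigma2 = mean squared
        # residual; residuals are exactly the demeaned series
        n = values.size
        mu = float(values.mean()) if trend == "c" else 0.0
        resid = values - mu
        sigma2 = float(np.mean(resid**2))
        if sigma2 <= 0:
            return ArimaFit(spec=spec, converged=False, reason="degenerate_constant")
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = 2 if trend == "c" else 1
        return ArimaFit(
            spec=spec, const=mu, sigma2=sigma2,
            aic=2 * k - 2 * llf, bic=k * np.log(n) - 2 * llf, loglik=llf,
            k_params=k, residuals=resid, converged=True,
        )
    if method == "auto":
        method = "innovations_mle" if values.size >= _INNOVATIONS_MIN_N else "statespace"
    order = (spec.p, 0, spec.q)
    res = None
    opt_converged = True
    for m in ([method, "statespace"] if method != "statespace" else ["statespace"]):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                res = ARIMA(values, order=order, trend=trend).fit(method=m)
            # an optimizer that stopped without converging can report an
            # inflated likelihood at boundary parameters; such fits must
            # not win the criterion argmin
            opt_converged = getattr(res, "mle_retvals", {}).get("converged", True)
            opt_converged = opt_converged and not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            break
        except Exception:
            res = None
    if res is None:
        return ArimaFit(spec=spec, converged=False, reason="estimation_failed")
    names = list(res.model.param_names)
    params = dict(zip(names, np.asarray(res.params, float)))
    ar = np.array([params[f"ar.L{i}"] for i in range(1, spec.p + 1)])
    ma = np.array([params[f"ma.L{j}"] for j in range(1, spec.q + 1)])
    if not np.all(np.isfinite(res.params)) or not np.isfinite(res.llf):
        return ArimaFit(spec=spec, converged=False, reason="nonfinite_estimate")
    if not opt_converged:
        fit = ArimaFit(spec=spec, converged=False, reason="optimizer_not_converged")
        fit.aic, fit.bic, fit.loglik = float(res.aic), float(res.bic), float(res.llf)
        fit.residuals = np.asarray(res.resid, float)
        return fit
    if spec.p > 0 and spec.q > 0:
        # common-factor check: an AR and an MA inverse root that (nearly)
        # coincide cancel, leaving a redundant parameter pair on a
        # likelihood ridge; such fits report spuriously high likelihoods
        # and must not win the criterion argmin
        inv_ar = np.roots(np.r_[1.0, -ar])
        inv_ma = np.roots(np.r_[1.0, ma])
        dist = np.abs(inv_ar[:, None] - inv_ma[None, :]).min()
        if dist < _COMMON_FACTOR_TOL:
            fit = ArimaFit(spec=spec, converged=False, reason="common_factor_redundancy")
            fit.aic, fit.bic, fit.loglik = float(res.aic), float(res.bic), float(res.llf)
            fit.residuals = np.asarray(res.resid, float)
            return fit
    return ArimaFit(
        spec=spec,
        const=float(params.get("const", 0.0)),
        ar_coeffs=ar,
        ma_coeffs=ma,
        sigma2=float(params.get("sigma2", np.nan)),
        aic=float(res.aic),
        bic=float(res.bic),
        loglik=float(res.llf),
        k_params=len(names),
        residuals=np.asarray(res.resid, float),
        converged=True,
    )


@dataclass
class GridSearchResult:
    best: ArimaSpec
    best_fit: ArimaFit
    table: pd.DataFrame  # one row per (p, q) cell: criteria or failure marker


def grid_search(
    series: IndexSeries | np.ndarray,
    p_max: int = 10,
    q_max: int = 10,
    d: int = 1,
    criterion: str = "aic",
    trend: str = "c",
    method: str = "auto",
) -> GridSearchResult:
    """Exhaustive ARIMA order search under an information criterion.

    Every (p, q) combination in [0, p_max] x [0, q_max] is fitted with
    d = 0 on the (already differenced) input and reported with the given
    ``d`` against the original series.  The optimum is the criterion argmin
    among converged fits; ties break to smaller p + q, then smaller p.
    Non-convergent cells are recorded in the table, never silently dropped.
    """
    if criterion not in ("aic", "bic", "loglik"):
        raise InvalidParameterError("criterion must be one of aic/bic/loglik")
    rows = []
    fits: dict[tuple[int, int], ArimaFit] = {}
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            fit = fit_arima(series, ArimaSpec(p, 0, q), trend=trend, method=method)
            fits[(p, q)] = fit
            rows.append(
                {
                    "p": p,
                    "q": q,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                    "reason": fit.reason,
                }
            )
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    if ok.empty:
        raise InvalidParameterError("no (p, q) combination produced a converged fit")
    sign = -1.0 if criterion == "loglik" else 1.0
    ranked = ok.assign(
        _score=sign * ok[criterion], _sum=ok.p + ok.q
    ).sort_values(["_score", "_sum", "p"], kind="mergesort")
    best_row = ranked.iloc[0]
    best = ArimaSpec(int(best_row.p), d, int(best_row.q))
    best_fit = fits[(best.p, best.q)]
    best_fit.spec = best
    return GridSearchResult(best=best, best_fit=best_fit, table=table)


def median_model(specs: list[ArimaSpec]) -> ArimaSpec:
    """Componentwise median of p- and q-orders across a population.

    Half-integer medians round to the nearest even integer (Python's
    banker's rounding); d is passed through from the first spec.
    """
    if not specs:
        raise InvalidParameterError("at least one spec required")
    p = round(float(np.median([s.p for s in specs])))
    q = round(float(np.median([s.q for s in specs])))
    return ArimaSpec(int(p), specs[0].d, int(q))


@dataclass
class DiagnosticsReport:
    median_abs_residual: float
    residual_variance: float
    data_variance: float
    acf_spike_count: int
    pacf_spike_count: int
    n_lags: int
    ci_level: float = 0.95
    fit: ArimaFit | None = None


def diagnostics(
    series: IndexSeries | np.ndarray,
    spec: ArimaSpec,
    n_lags: int = 30,
    trend: str = "c",
) -> DiagnosticsReport:
    """Residual diagnostics for a given model refitted on a series.

    With spec.d == 1 the series is differenced before fitting (coefficients
    are re-estimated; only the orders are taken from ``spec``).  A spike is
    an ACF/PACF value at lags 1..n_lags exceeding the 95% white-noise band
    +/- 1.96/sqrt(N).  ``data_variance`` refers to the series as passed,
    before differencing; ARIMA(0, 0, 0) therefore reproduces the raw-data
    baseline (residuals = demeaned series).
    """
    values = series.values if isinstance(series, IndexSeries) else np.asarray(series, float)
    values = values[~np.isnan(values)]
    data_var = float(values.var())
    work = np.diff(values) if spec.d == 1 else values
    fit = fit_arima(work, ArimaSpec(spec.p, 0, spec.q), trend=trend)
    if not fit.converged:
        # diagnostics are descriptive, not model selection: residuals from an
        # optimizer that stopped early are still reportable, with a warning
        if fit.reason == "optimizer_not_converged" and fit.residuals.size:
            warnings.warn(
                f"model {spec.as_tuple()}: optimizer did not fully converge", stacklevel=2
            )
        else:
            raise InvalidParameterError(
                f"model {spec.as_tuple()} did not converge: {fit.reason}"
            )
    fit.spec = spec
    resid = fit.residuals
    n = resid.size
    n_lags = min(n_lags, n // 2 - 1)
    band = 1.96 / np.sqrt(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acf_vals = _acf(resid, nlags=n_lags, fft=True)[1:]
        pacf_vals = _pacf(resid, nlags=n_lags)[1:]
    return DiagnosticsReport(
        median_abs_residual=float(np.median(np.abs(resid))),
        residual_variance=float(resid.var()),
        data_variance=data_var,
        acf_spike_count=int((np.abs(acf_vals) > band).sum()),
        pacf_spike_count=int((np.abs(pacf_vals) > band).sum()),
        n_lags=int(n_lags),
        fit=fit,
    )


def plot_acf_pacf(residuals: np.ndarray, path, n_lags: int = 30, title: str = "") -> None:
    """Write an ACF/PACF panel of model residuals with the 95% band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resid = np.asarray(residuals, float)
    n_lags = min(n_lags, resid.size // 2 - 1)
    band = 1.96 / np.sqrt(resid.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acf_vals = _acf(resid, nlags=n_lags, fft=True)[1:]
        pacf_vals = _pacf(resid, nlags=n_lags)[1:]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, vals, label in zip(axes, (acf_vals, pacf_vals), ("ACF", "PACF")):
        lags = np.arange(1, len(vals) + 1)
        ax.stem(lags, vals, basefmt=" ")
        ax.axhspan(-band, band, color="0.85", zorder=0)
        ax.set_xlabel("lag")
        ax.set_title(f"{label} {title}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
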