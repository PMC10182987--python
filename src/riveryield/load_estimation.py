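"""Station-level carbon load estimation from paired flow/concentration data.

The workflow mirrors the LOADEST rating-curve approach for uncensored
records: pair same-day streamflow (m3 s-1) and concentration (mgC L-1)
observations into instantaneous loads (gC day-1), center the covariates,
fit the nine candidate log-linear models by maximum likelihood, select by
AIC, and predict daily loads over the full flow record with a lognormal
retransformation bias correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models

logger = logging.getLogger(__name__)

#: gC day-1 per (m3 s-1 * mgC L-1): 86400 s/day * 1000 L/m3 * 1e-3 gC/mgC
SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 365.25
CFS_TO_M3S = 0.0283168

DEFAULT_MIN_OBS = 12


@dataclass(frozen=True)
class Centers:
    """Decorrelating centers for ln-streamflow and decimal time."""

    lnq: float
    dtime: float


@dataclass
class ModelFit:
    """One fitted rating-curve model.

    ``coefficients`` are positional (a0 = intercept, then the model's own
    term order); ``coefficient_vector()`` pads to length 7 with zeros for
    absent terms.
    """

    model_id: int
    coefficients: np.ndarray
    residual_variance: float  # ML estimate, RSS / n
    log_likelihood: float
    aic: float
    r_square_pct: float
    n_obs: int
    centers: Centers
    failed: bool = False
    fail_reason: str = ""

    def coefficient_vector(self) -> np.ndarray:
        out = np.zeros(models.MAX_COEFFICIENTS)
        out[: len(self.coefficients)] = self.coefficients
        return out


@dataclass
class StationLoad:
    """Mean-load summary for one station/constituent."""

    station_id: str
    mean_daily_load: float  # gC day-1
    annual_load: float  # kgC yr-1
    n_obs: int
    period_start: int
    period_end: int
    model_id: int
    r_square_pct: float
    constituent: str = ""
    excluded: bool = False
    exclusion_reason: str = ""


def decimal_time(dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Decimal time in years: year + (day_of_year - 0.5) / days_in_year."""
    dates = pd.DatetimeIndex(dates)
    days_in_year = np.where(dates.is_leap_year, 366.0, 365.0)
    return dates.year.to_numpy() + (dates.dayofyear.to_numpy() - 0.5) / days_in_year


def pair_same_day(
    flow_series: pd.DataFrame, concentration_series: pd.DataFrame
) -> pd.DataFrame:
    """Pair same-day flow and concentration records into instantaneous loads.

    Parameters
    ----------
    flow_series
        Columns ``date`` (datetime-like) and ``flow`` (m3 s-1).
    concentration_series
        Columns ``date`` and ``concentration`` (mgC L-1). Multiple samples
        on one day are averaged before the load is computed.

    Returns
    -------
    DataFrame with columns date, Q, C, load (gC day-1), dtime_raw; one row
    per calendar day present in both series. Rows with nonpositive flow or
    concentration are dropped with a warning.
    """
    flow = flow_series.copy()
    flow["date"] = pd.to_datetime(flow["date"]).dt.normalize()
    conc = concentration_series.copy()
    conc["date"] = pd.to_datetime(conc["date"]).dt.normalize()
    conc = conc.groupby("date", as_index=False)["concentration"].mean()

    merged = flow.merge(conc, on="date", how="inner").sort_values("date")
    bad = (merged["flow"] <= 0) | (merged["concentration"] <= 0)
    if bad.any():
        logger.warning(
            "dropping %d paired day(s) with nonpositive flow or concentration",
            int(bad.sum()),
        )
        merged = merged[~bad]
    out = pd.DataFrame(
        {
            "date": merged["date"].to_numpy(),
            "Q": merged["flow"].to_numpy(dtype=float),
            "C": merged["concentration"].to_numpy(dtype=float),
        }
    )
    out["load"] = SECONDS_PER_DAY * out["Q"] * out["C"]
    out["dtime_raw"] = decimal_time(out["date"])
    return out.reset_index(drop=True)


def passes_min_obs(paired: pd.DataFrame, min_n: int = DEFAULT_MIN_OBS) -> bool:
    """Station retention filter: at least ``min_n`` paired observations."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return len(paired) >= min_n


def _decorrelating_center(x: np.ndarray) -> float:
    # center = mean + sum(d^3) / (2 sum(d^2)); makes cov(x-c, (x-c)^2) = 0
    x = np.asarray(x, dtype=float)
    m = x.mean()
    d = x - m
    s2 = np.sum(d**2)
    if s2 == 0.0:
        return float(m)
    return float(m + np.sum(d**3) / (2.0 * s2))


def compute_centers(paired: pd.DataFrame) -> Centers:
    """Decorrelating centers of ln Q and decimal time (LOADEST convention).

    The center is mean + sum((x-mean)^3) / (2 sum((x-mean)^2)), which zeroes
    the sample covariance between the centered covariate and its square.
    """
    if len(paired) < 2:
        raise ValueError("need at least 2 paired observations to center")
    return Centers(
        lnq=_decorrelating_center(np.log(paired["Q"].to_numpy())),
        dtime=_decorrelating_center(paired["dtime_raw"].to_numpy()),
    )


def _gaussian_loglik(rss: float, n: int) -> float:
    # profile log-likelihood of the linear model at the ML variance rss/n
    if rss <= 0.0:
        return np.inf
    s2 = rss / n
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def fit_model(paired: pd.DataFrame, centers: Centers, model_id: int) -> ModelFit:
    """Fit one rating-curve model to ln(load) by maximum likelihood.

    For uncensored data the ML fit is ordinary least squares with variance
    RSS/n. AIC counts the variance parameter: AIC = -2*loglik + 2*(p+1).
    A rank-deficient design marks the fit failed rather than raising.
    """
    n = len(paired)
    p = models.n_coefficients(model_id)
    lnq_c = np.log(paired["Q"].to_numpy()) - centers.lnq
    dt_c = paired["dtime_raw"].to_numpy() - centers.dtime
    y = np.log(paired["load"].to_numpy())

    def _failed(reason: str) -> ModelFit:
        return ModelFit(
            model_id=model_id,
            coefficients=np.zeros(p),
            residual_variance=np.nan,
            log_likelihood=np.nan,
            aic=np.inf,
            r_square_pct=np.nan,
            n_obs=n,
            centers=centers,
            failed=True,
            fail_reason=reason,
        )

    if n < p + 2:
        return _failed(f"n={n} too small for p={p}")
    X = models.design_matrix(model_id, lnq_c, dt_c)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        return _failed("rank-deficient design")
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / n
    ll = _gaussian_loglik(rss, n)
    aic = -2.0 * ll + 2.0 * (p + 1)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0.0:
        r2_pct = 100.0 * (1.0 - rss / tss)
    else:
        r2_pct = 100.0 if rss == 0.0 else np.nan
    return ModelFit(
        model_id=model_id,
        coefficients=beta,
        residual_variance=s2,
        log_likelihood=ll,
        aic=aic,
        r_square_pct=r2_pct,
        n_obs=n,
        centers=centers,
    )


def fit_all_models(paired: pd.DataFrame, centers: Centers) -> list[ModelFit]:
    """Fit all nine candidate models."""
    return [fit_model(paired, centers, mid) for mid in models.MODEL_IDS]


def select_best_model(fits: list[ModelFit]) -> ModelFit:
    """Pick the minimum-AIC fit; ties go to the smaller model id."""
    ok = [f for f in fits if not f.failed]
    if not ok:
        raise ValueError("all candidate fits failed")
    return min(ok, key=lambda f: (f.aic, f.model_id))


def bias_correction_factor(residual_variance: float) -> float:
    """Lognormal retransformation correction exp(s^2 / 2).

    Isolated so the exact small-sample AMLE correction can be swapped in.
    """
    return float(np.exp(0.5 * residual_variance))


def predict_daily_loads(fit: ModelFit, daily_flow_series: pd.DataFrame) -> pd.DataFrame:
    """Predict bias-corrected daily loads (gC day-1) over a flow record.

    Days with nonpositive flow are skipped with a warning.
    """
    if fit.failed:
        raise ValueError("cannot predict from a failed fit")
    flow = daily_flow_series.copy()
    flow["date"] = pd.to_datetime(flow["date"]).dt.normalize()
    bad = flow["flow"] <= 0
    if bad.any():
        logger.warning("skipping %d day(s) with nonpositive flow", int(bad.sum()))
        flow = flow[~bad]
    lnq_c = np.log(flow["flow"].to_numpy(dtype=float)) - fit.centers.lnq
    dt_c = decimal_time(flow["date"]) - fit.centers.dtime
    lp = models.linear_predictor(fit.model_id, fit.coefficients, lnq_c, dt_c)
    load = np.exp(lp) * bias_correction_factor(fit.residual_variance)
    return pd.DataFrame({"date": flow["date"].to_numpy(), "load": load})


def summarize_station_load(
    daily_loads: pd.DataFrame,
    n_obs: int,
    period: tuple[int, int],
    fit: ModelFit,
    station_id: str = "",
    constituent: str = "",
) -> StationLoad:
    """Whole-record mean daily load and its annual equivalent.

    annual_load (kgC yr-1) = mean_daily_load (gC day-1) * 365.25 / 1000.
    """
    if len(daily_loads) == 0:
        raise ValueError("daily load series is empty")
    mean_daily = float(daily_loads["load"].mean())
    return StationLoad(
        station_id=station_id,
        mean_daily_load=mean_daily,
        annual_load=mean_daily * DAYS_PER_YEAR / 1000.0,
        n_obs=n_obs,
        period_start=period[0],
        period_end=period[1],
        model_id=fit.model_id,
        r_square_pct=fit.r_square_pct,
        constituent=constituent,
    )


def estimate_station_load(
    flow_series: pd.DataFrame,
    concentration_series: pd.DataFrame,
    station_id: str = "",
    constituent: str = "",
    min_obs: int = DEFAULT_MIN_OBS,
) -> StationLoad:
    """End-to-end estimate for one station/constituent.

    Stations failing the minimum-observation filter, or for which every
    candidate fit fails, are returned as excluded records with a reason
    code rather than dropped.
    """

    def _excluded(n: int, reason: str) -> StationLoad:
        return StationLoad(
            station_id=station_id,
            mean_daily_load=np.nan,
            annual_load=np.nan,
            n_obs=n,
            period_start=0,
            period_end=0,
            model_id=0,
            r_square_pct=np.nan,
            constituent=constituent,
            excluded=True,
            exclusion_reason=reason,
        )

    paired = pair_same_day(flow_series, concentration_series)
    if not passes_min_obs(paired, min_obs):
        return _excluded(len(paired), f"fewer than {min_obs} paired observations")
    centers = compute_centers(paired)
    fits = fit_all_models(paired, centers)
    try:
        best = select_best_model(fits)
    except ValueError:
        return _excluded(len(paired), "all candidate fits failed")
    daily = predict_daily_loads(best, flow_series)
    years = pd.DatetimeIndex(paired["date"]).year
    return summarize_station_load(
        daily,
        n_obs=len(paired),
        period=(int(years.min()), int(years.max())),
        fit=best,
        station_id=station_id,
        constituent=constituent,
    )
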