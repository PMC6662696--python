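"""Per-pixel heat-stress exposure metrics and AR1-GLS trends.

Five metrics summarize each pixel's annual-maximum-DHW history: the overall
maximum, the number of years reaching the bleaching-risk (>= 4 degC-weeks)
and mortality-risk (>= 8 degC-weeks) thresholds, the calendar year of the
maximum, and the linear trend of the annual maxima. Trends come from a
generalized least squares fit with AR1 error covariance — annual values are
temporally autocorrelated, and ignoring that understates slope uncertainty.
Non-significant slopes (two-sided p > alpha) are set to zero in the trend
grid so maps show only trends distinguishable from noise.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ar1_gls_fit",
    "gls_ar1_trend",
    "exposure_summary",
    "trend_grid",
    "BLEACHING_THRESHOLD",
    "MORTALITY_THRESHOLD",
]

BLEACHING_THRESHOLD = 4.0  # degC-weeks; bleaching-risk level
MORTALITY_THRESHOLD = 8.0  # degC-weeks; mortality-risk level

_RHO_BOUND = 0.99


def _whiten(z: np.ndarray, rho: float) -> np.ndarray:
    """Prais-Winsten transform making AR1 errors white."""
    out = np.empty_like(z, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * z[0]
    out[1:] = z[1:] - rho * z[:-1]
    return out


def ar1_gls_fit(y: np.ndarray, X: np.ndarray):
    """Exact Gaussian ML fit of ``y = X beta + e`` with AR1(rho) errors.

    The AR1 parameter is estimated by maximizing the profile likelihood
    (sigma^2 and beta concentrated out) over rho in [0, 0.99): temporal
    persistence of heat stress is physically non-negative, and allowing
    spuriously negative estimates on short annual series deflates the slope
    standard error and makes the trend test liberal. The whitened design
    then yields the GLS coefficients and their covariance.

    Returns ``(beta, cov, rho, loglik, df_resid)`` where ``cov`` uses the
    residual-variance estimate RSS/(n-p) and ``loglik`` is the maximized
    Gaussian log-likelihood (ML, sigma^2 = RSS/n).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations, got {n}")

    def _rss(rho: float):
        Xs = _whiten(X, rho)
        ys = _whiten(y, rho)
        beta, rss, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        return float(resid @ resid), beta, Xs

    def neg_profile_ll(rho: float) -> float:
        rss, _, _ = _rss(rho)
        rss = max(rss, 1e-300)
        return 0.5 * n * np.log(rss / n) - 0.5 * np.log1p(-rho**2)

    opt = minimize_scalar(
        neg_profile_ll, bounds=(0.0, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(opt.x)
    if neg_profile_ll(0.0) <= opt.fun:  # boundary (no persistence) wins
        rho = 0.0
    rss, beta, Xs = _rss(rho)
    df_resid = n - p
    s2 = rss / df_resid if rss > 0 else 0.0
    XtX_inv = np.linalg.pinv(Xs.T @ Xs)
    cov = s2 * XtX_inv
    sigma2_ml = max(rss / n, 1e-300)
    loglik = (
        -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0)
        + 0.5 * np.log1p(-rho**2)
    )
    return beta, cov, rho, float(loglik), df_resid


def gls_ar1_trend(series: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Slope and two-sided p-value of a linear-in-time AR1-GLS trend.

    The model is ``y_t = a + b t + e_t`` with AR1 errors, the AR1 parameter
    estimated by maximum likelihood; no seasonal terms (annual input). A
    constant series returns ``(0.0, 1.0)``.

    Parameters
    ----------
    series : 1-D array of annual values (>= 10, finite).
    alpha : significance level; kept for interface symmetry with
        :func:`trend_grid`, which zeroes slopes with ``p > alpha``.
    """
    y = np.asarray(series, float)
    if y.ndim != 1 or len(y) < 10:
        raise ValueError("trend needs a 1-D series of at least 10 annual values")
    if not np.isfinite(y).all():
        raise ValueError("trend input contains non-finite values")
    if np.ptp(y) == 0.0:
        return 0.0, 1.0
    t = np.arange(len(y), dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, cov, _, _, df_resid = ar1_gls_fit(y, X)
    slope = float(beta[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se == 0.0:
        return slope, 1.0 if slope == 0.0 else 0.0
    tval = slope / se
    p = 2.0 * stats.t.sf(abs(tval), df_resid)
    return slope, float(p)


def exposure_summary(
    annual_max: xr.DataArray,
    bleach_thr: float = BLEACHING_THRESHOLD,
    mort_thr: float = MORTALITY_THRESHOLD,
    include_trend: bool = True,
) -> xr.Dataset:
    """The five per-pixel exposure metrics from an annual-maximum-DHW stack.

    Returns a dataset with ``max_dhw``, ``n_bleaching_events``,
    ``n_mortality_events``, ``year_of_max`` (ties broken to the earliest
    year), and — when the series is long enough (>= 10 years) and
    ``include_trend`` — ``trend_slope`` / ``trend_p`` from the AR1-GLS fit.
    Pixels with no data at all get NaN in every metric.
    """
    if annual_max.sizes["year"] < 2:
        raise ValueError("need at least 2 years of annual maxima")
    vals = annual_max.values  # (year, lat, lon)
    years = annual_max["year"].values
    finite = np.isfinite(vals)
    any_data = finite.any(axis=0)

    with np.errstate(all="ignore"):
        max_dhw = np.nanmax(np.where(finite, vals, -np.inf), axis=0)
    max_dhw[~any_data] = np.nan

    n_bleach = np.where(any_data, np.nansum(vals >= bleach_thr, axis=0), np.nan)
    n_mort = np.where(any_data, np.nansum(vals >= mort_thr, axis=0), np.nan)

    filled = np.where(finite, vals, -np.inf)
    year_of_max = years[np.argmax(filled, axis=0)].astype(float)  # argmax -> first/earliest tie
    year_of_max[~any_data] = np.nan

    ds = xr.Dataset(
        {
            "max_dhw": (("lat", "lon"), max_dhw),
            "n_bleaching_events": (("lat", "lon"), n_bleach),
            "n_mortality_events": (("lat", "lon"), n_mort),
            "year_of_max": (("lat", "lon"), year_of_max),
        },
        coords={"lat": annual_max["lat"], "lon": annual_max["lon"]},
        attrs={
            "bleaching_threshold": bleach_thr,
            "mortality_threshold": mort_thr,
        },
    )
    if include_trend and annual_max.sizes["year"] >= 10:
        tg = trend_grid(annual_max, zero_nonsignificant=False)
        ds["trend_slope"] = tg["slope"]
        ds["trend_p"] = tg["p"]
    return ds


def trend_grid(
    annual_max: xr.DataArray,
    alpha: float = 0.05,
    zero_nonsignificant: bool = True,
) -> xr.Dataset:
    """AR1-GLS trend per pixel; non-significant slopes set to zero.

    Returns a dataset with ``slope`` (degC-weeks/year) and ``p``. When
    ``zero_nonsignificant``, slope is exactly 0 wherever ``p > alpha`` —
    the convention used for mapping, where zero stands for "no detectable
    trend". Pixels whose series are incomplete propagate as NaN.
    """
    vals = annual_max.values
    ny, nlat, nlon = vals.shape
    if ny < 10:
        raise ValueError("per-pixel trend needs >= 10 years")
    slope = np.full((nlat, nlon), np.nan)
    pval = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            y = vals[:, i, j]
            if not np.isfinite(y).all():
                continue
            slope[i, j], pval[i, j] = gls_ar1_trend(y, alpha=alpha)
    if zero_nonsignificant:
        slope[np.isfinite(pval) & (pval > alpha)] = 0.0
    out = xr.Dataset(
        {"slope": (("lat", "lon"), slope), "p": (("lat", "lon"), pval)},
        coords={"lat": annual_max["lat"], "lon": annual_max["lon"]},
        attrs={
            "alpha": alpha,
            "ar1_estimation": "maximum likelihood",
            "zeroed_nonsignificant": int(zero_nonsignificant),
        },
    )
    return out
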