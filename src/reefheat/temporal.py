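"""Regional DHW time series and their temporal battery.

The spatial fields are reduced to one series per heat-stress region — the
cross-pixel *median* DHW on each day, robust to within-region outliers —
and averaged to monthly resolution to match the ENSO index. On these monthly
series the module provides:

* Pettitt's nonparametric single change-point test (rank-based, Mann-Whitney
  flavoured), locating an abrupt shift in level;
* the continuous Morlet wavelet transform with red-noise (AR1) chi-square
  significance and the cone of influence, following the standard
  Torrence & Compo (1998) construction;
* the bias-corrected cross-wavelet against the ONI, exposing common
  periodicities and relative phase;
* lagged Pearson cross-correlation (positive lag = ONI leads DHW), the
  direct estimate of the ENSO-to-heat-stress delay.

Monthly DHW means include zeros, so wavelet inputs use log(x + 1); the
offset is configurable and recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import fft as sp_fft
from scipy.stats import chi2

__all__ = [
    "regional_series",
    "monthly_mean",
    "pettitt",
    "wavelet",
    "cross_wavelet",
    "cross_correlation",
    "ChangePointResult",
    "WaveletResult",
    "CrossWaveletResult",
]

MORLET_OMEGA0 = 6.0
# Fourier wavelength per unit scale for Morlet(6): 4*pi/(w0 + sqrt(2 + w0^2))
FOURIER_FACTOR = 4.0 * np.pi / (MORLET_OMEGA0 + np.sqrt(2.0 + MORLET_OMEGA0**2))
DEFAULT_MAX_LAG = 38  # months; >= 10 annual cycles inside a 33-year record


# ---------------------------------------------------------------------------
# regional reduction


def regional_series(dhw_cube: xr.Dataset, labels: xr.DataArray) -> pd.DataFrame:
    """Daily median DHW across the member pixels of each region.

    ``labels`` is an integer (lat, lon) grid; label 0 means unassigned.
    Returns a DataFrame indexed by time with one column per region id.
    Regions with no member pixels are omitted.
    """
    if labels.shape != dhw_cube["dhw"].shape[1:]:
        raise ValueError("labels grid does not align with the DHW cube")
    lab = labels.values
    vals = dhw_cube["dhw"].values
    out = {}
    for region in np.unique(lab):
        if region == 0:
            continue
        members = lab == region
        sub = vals[:, members]
        med = np.full(sub.shape[0], np.nan)
        has_data = np.isfinite(sub).any(axis=1)  # DHW spin-up days are all-NaN
        med[has_data] = np.nanmedian(sub[has_data], axis=1)
        out[int(region)] = med
    return pd.DataFrame(out, index=pd.DatetimeIndex(dhw_cube["time"].values, name="time"))


def monthly_mean(daily: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Average a daily series to calendar months (PeriodIndex, freq='M')."""
    grouped = daily.groupby(daily.index.to_period("M")).mean()
    grouped.index.name = "month"
    return grouped


# ---------------------------------------------------------------------------
# change point


@dataclass
class ChangePointResult:
    """Pettitt test outcome.

    ``tau`` is the 1-based length of the first segment (the change falls
    between observations tau and tau+1); ``None`` for a degenerate (constant)
    series. ``p`` is the usual approximation 2*exp(-6K^2/(n^3 + n^2)).
    """

    K: float
    tau: int | None
    p: float
    tau_label: object | None = None

    @property
    def significant(self) -> bool:
        return self.tau is not None and self.p <= 0.05


def pettitt(series) -> ChangePointResult:
    """Pettitt's rank-based test for a single change point.

    U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i); the statistic is
    K = max_t |U_t| and the change point estimate tau = argmax. Computed via
    ranks (mid-ranks for ties), equivalent to the O(n^2) double sum.
    """
    if isinstance(series, (pd.Series, pd.DataFrame)):
        index = series.index
        x = np.asarray(series, float).ravel()
    else:
        index = None
        x = np.asarray(series, float).ravel()
    n = len(x)
    if n < 10:
        raise ValueError("Pettitt test needs at least 10 observations")
    if np.ptp(x) == 0.0:
        return ChangePointResult(K=0.0, tau=None, p=1.0)
    r = pd.Series(x).rank(method="average").to_numpy()
    # U_t = 2 * sum_{i<=t} r_i - t*(n+1), t = 1..n-1
    csum = np.cumsum(r)[:-1]
    t = np.arange(1, n)
    U = 2.0 * csum - t * (n + 1.0)
    k_idx = int(np.argmax(np.abs(U)))
    K = float(np.abs(U[k_idx]))
    tau = k_idx + 1
    p = float(min(1.0, 2.0 * np.exp(-6.0 * K**2 / (n**3 + n**2))))
    tau_label = index[k_idx] if index is not None else None
    return ChangePointResult(K=K, tau=tau, p=p, tau_label=tau_label)


# ---------------------------------------------------------------------------
# wavelets


@dataclass
class WaveletResult:
    periods: np.ndarray  # months
    times: np.ndarray  # month index 0..n-1
    power: np.ndarray  # (period, time), bias-corrected (|W|^2 / scale)
    sig_mask: np.ndarray  # True where power exceeds the 95% background
    coi: np.ndarray  # per time: largest credible period (months)
    phase: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def in_coi(self) -> np.ndarray:
        """Boolean (period, time) mask of cells inside the cone of influence."""
        return self.periods[:, None] <= self.coi[None, :]


def _cwt_morlet(x: np.ndarray, dt: float = 1.0, dj: float = 1.0 / 12.0, s0: float | None = None):
    """Continuous Morlet(6) wavelet transform via FFT.

    Returns ``(W, scales, periods, coi)`` with W complex of shape
    (n_scales, n). Zero-padding to the next power of two limits wrap-around;
    the cone of influence marks where it still leaks in.
    """
    n = len(x)
    if s0 is None:
        s0 = 2.0 * dt
    x = np.asarray(x, float) - np.mean(x)
    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = sp_fft.fft(x, npad)
    wk = 2.0 * np.pi * sp_fft.fftfreq(npad, d=dt)
    J = int(np.floor(np.log2(n * dt / s0) / dj))
    scales = s0 * 2.0 ** (dj * np.arange(J + 1))
    W = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi**-0.25
    for i, s in enumerate(scales):
        psi_hat = norm_const * np.sqrt(2.0 * np.pi * s / dt) * np.exp(
            -0.5 * (s * wk - MORLET_OMEGA0) ** 2
        ) * (wk > 0)
        W[i] = sp_fft.ifft(xhat * psi_hat)[:n]
    periods = FOURIER_FACTOR * scales
    # e-folding time sqrt(2)*s -> credible periods shorter than the coi curve
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = FOURIER_FACTOR / np.sqrt(2.0) * dt * np.maximum(t_edge, 1e-9)
    return W, scales, periods, coi


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    r1 = float(x[1:] @ x[:-1]) / denom
    return float(np.clip(r1, 0.0, 0.999))


def _red_noise_spectrum(alpha: float, periods: np.ndarray, dt: float) -> np.ndarray:
    freq = dt / periods
    return (1.0 - alpha**2) / (1.0 + alpha**2 - 2.0 * alpha * np.cos(2.0 * np.pi * freq))


def wavelet(series, log_offset: float = 1.0, dt: float = 1.0, dj: float = 1.0 / 12.0) -> WaveletResult:
    """Morlet wavelet power of log(series + log_offset) with 95% significance.

    The null background is a lag-1 autoregressive (red-noise) spectrum with
    the AR coefficient estimated from the transformed series; cells whose raw
    power exceeds the chi-square(2) 95% level of that background are flagged
    significant. Power is reported bias-corrected (divided by scale) so peaks
    at different periods are comparable.
    """
    x = np.asarray(series, float).ravel()
    if len(x) < 64:
        raise ValueError("wavelet analysis needs at least 64 monthly values")
    shifted = x + log_offset
    if np.any(shifted <= 0.0):
        raise ValueError("series + log_offset must be positive for the log transform")
    z = np.log(shifted)
    W, scales, periods, coi = _cwt_morlet(z, dt=dt, dj=dj)
    raw_power = np.abs(W) ** 2
    var = float(np.var(z))
    alpha = _lag1_autocorr(z)
    background = var * _red_noise_spectrum(alpha, periods, dt)
    signif = background * (chi2.ppf(0.95, 2) / 2.0)
    sig_mask = raw_power > signif[:, None]
    power = raw_power / scales[:, None]
    return WaveletResult(
        periods=periods,
        times=np.arange(len(x), dtype=float),
        power=power,
        sig_mask=sig_mask,
        coi=coi,
        meta={"log_offset": log_offset, "ar1": alpha, "variance": var, "dj": dj},
    )


@dataclass
class CrossWaveletResult(WaveletResult):
    pass


# 95% point of sqrt(chi2_2 * chi2_2)/2 for two complex-normal spectra
_XWT_Z95 = 3.999


def cross_wavelet(x, y, dt: float = 1.0, dj: float = 1.0 / 12.0) -> CrossWaveletResult:
    """Bias-corrected cross-wavelet power and phase between two series.

    ``W_xy = W_x * conj(W_y)``; the phase angle gives the local lead/lag
    relation and the 95% significance follows the standard cross-spectrum
    null in which the two series share no common variation, each behaving as
    red noise with its own estimated lag-1 coefficient. Interpretation should
    stay inside the cone of influence (see :meth:`WaveletResult.in_coi`).
    """
    xv = np.asarray(x, float).ravel()
    yv = np.asarray(y, float).ravel()
    if len(xv) != len(yv):
        raise ValueError(f"series lengths differ: {len(xv)} vs {len(yv)}")
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            raise ValueError("series are not aligned on the same monthly axis")
    Wx, scales, periods, coi = _cwt_morlet(xv, dt=dt, dj=dj)
    Wy, _, _, _ = _cwt_morlet(yv, dt=dt, dj=dj)
    Wxy = Wx * np.conj(Wy)
    raw_power = np.abs(Wxy)
    phase = np.angle(Wxy)

    sx, sy = float(np.std(xv)), float(np.std(yv))
    Px = _red_noise_spectrum(_lag1_autocorr(xv), periods, dt)
    Py = _red_noise_spectrum(_lag1_autocorr(yv), periods, dt)
    signif = sx * sy * (_XWT_Z95 / 2.0) * np.sqrt(Px * Py)
    sig_mask = raw_power > signif[:, None]
    power = raw_power / scales[:, None]
    return CrossWaveletResult(
        periods=periods,
        times=np.arange(len(xv), dtype=float),
        power=power,
        sig_mask=sig_mask,
        coi=coi,
        phase=phase,
        meta={"dj": dj},
    )


# ---------------------------------------------------------------------------
# cross-correlation


def cross_correlation(dhw_series, oni, max_lag: int = DEFAULT_MAX_LAG) -> pd.DataFrame:
    """Pearson correlation between DHW and ONI at lags -max_lag..+max_lag.

    Positive lag means the ONI leads the DHW series by that many months.
    Significance bounds are the usual +/- 1.96/sqrt(n_pairs) per lag, without
    autocorrelation adjustment (a known simplification of the common
    implementations; treat borderline bars with caution).

    Returns a DataFrame with columns ``lag``, ``r``, ``n``, ``sig``.
    """
    d = np.asarray(dhw_series, float).ravel()
    o = np.asarray(oni, float).ravel()
    if len(d) != len(o):
        raise ValueError("series must share one monthly axis")
    n = len(d)
    if n < 5 * max_lag:
        raise ValueError(
            f"overlap of {n} months is too short for max_lag={max_lag} (need >= {5 * max_lag})"
        )
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = o[: n - lag] if lag else o, d[lag:]
        else:
            a, b = o[-lag:], d[: n + lag]
        m = len(b)
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        bound = 1.96 / np.sqrt(m)
        rows.append({"lag": lag, "r": r, "n": m, "sig": bool(np.isfinite(r) and abs(r) > bound)})
    return pd.DataFrame(rows)
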