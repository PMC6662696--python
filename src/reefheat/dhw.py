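"""Coral bleaching HotSpots and Degree Heating Weeks from SST and MMM.

HotSpot (HS) is the daily positive SST anomaly above the Maximum Monthly
Mean climatology::

    HS = max(SST_daily - MMM, 0)

Degree Heating Weeks (DHW) accumulate HotSpots of at least 1 degC over a
trailing 84-day (12-week) window, divided by 7 to express the result in
degC-weeks::

    DHW(t) = (1/7) * sum_{i=t-83..t} HS_i * [HS_i >= 1]

computed daily. The window is 84 calendar days inclusive of the current day
(day counting, not month arithmetic), so the first 83 days of a series have
no DHW value rather than a downward-biased partial-window one. Windows with
more than 10% missing days also yield missing DHW; available days within a
tolerably gappy window are summed as-is, never gap-filled.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = ["hotspot", "dhw", "annual_max_dhw", "DEFAULT_WINDOW_DAYS", "HS_ACCUMULATION_CUTOFF"]

DEFAULT_WINDOW_DAYS = 84
HS_ACCUMULATION_CUTOFF = 1.0  # degC; HS below this do not accumulate into DHW
MAX_MISSING_FRACTION = 0.10


def _check_aligned(cube: xr.Dataset, mmm: xr.DataArray) -> None:
    if cube["sst"].shape[1:] != mmm.shape:
        raise ValueError(
            f"grid mismatch: sst {cube['sst'].shape[1:]} vs mmm {mmm.shape}"
        )
    if not (
        np.array_equal(cube["lat"].values, mmm["lat"].values)
        and np.array_equal(cube["lon"].values, mmm["lon"].values)
    ):
        raise ValueError("sst and mmm coordinates differ")


def hotspot(cube: xr.Dataset, mmm: xr.DataArray) -> xr.Dataset:
    """Daily HotSpot cube: positive anomalies of SST above the MMM.

    Returns a dataset with an ``hs`` variable on the cube's axes; ``hs`` is 0
    wherever SST <= MMM and NaN where SST is missing.
    """
    _check_aligned(cube, mmm)
    anom = cube["sst"] - mmm
    hs = anom.where(anom > 0, 0.0).where(np.isfinite(cube["sst"]))
    out = cube.drop_vars([v for v in cube.data_vars if v != "mask"])
    out["hs"] = hs
    out["hs"].attrs["units"] = "degC"
    return out


def dhw(hs_cube: xr.Dataset, window_days: int = DEFAULT_WINDOW_DAYS) -> xr.Dataset:
    """Degree Heating Weeks from a HotSpot cube.

    For each day from ``window_days`` on, sums HotSpots >= 1 degC over the
    trailing window and divides by 7. The first ``window_days - 1`` days are
    NaN, as are windows with more than 10% missing days.
    """
    hs = hs_cube["hs"].values
    n = hs.shape[0]
    if n < window_days:
        raise ValueError(
            f"series too short for DHW: {n} days < required {window_days}"
        )
    contrib = np.where(
        np.isfinite(hs) & (hs >= HS_ACCUMULATION_CUTOFF), hs, 0.0
    )
    missing = (~np.isfinite(hs)).astype(np.int64)

    # trailing-window sums via cumulative sums; exact for integer-day windows
    csum = np.concatenate(
        [np.zeros((1,) + hs.shape[1:]), np.cumsum(contrib, axis=0)], axis=0
    )
    cmiss = np.concatenate(
        [np.zeros((1,) + hs.shape[1:], np.int64), np.cumsum(missing, axis=0)], axis=0
    )
    win_sum = csum[window_days:] - csum[:-window_days]
    win_miss = cmiss[window_days:] - cmiss[:-window_days]

    vals = np.full(hs.shape, np.nan)
    vals[window_days - 1 :] = win_sum / 7.0
    bad = win_miss > MAX_MISSING_FRACTION * window_days
    vals[window_days - 1 :][bad] = np.nan

    out = hs_cube.drop_vars([v for v in hs_cube.data_vars if v != "mask"])
    out["dhw"] = (("time", "lat", "lon"), vals)
    out["dhw"].attrs["units"] = "degC-weeks"
    out["dhw"].attrs["window_days"] = window_days
    return out


def annual_max_dhw(dhw_cube: xr.Dataset) -> xr.DataArray:
    """Per-pixel annual maximum DHW, the pipeline's main exposure indicator.

    Returns a ``(year, lat, lon)`` array; a pixel-year is NaN when every day
    is missing, and a ``flagged_years`` attribute lists calendar years in
    which more than 10% of days had no DHW value anywhere on the grid (the
    spin-up year is flagged by construction).
    """
    da = dhw_cube["dhw"]
    years = da["time"].dt.year
    if len(np.unique(years)) < 1:
        raise ValueError("DHW cube spans no full calendar year")
    with np.errstate(all="ignore"):
        am = da.groupby("time.year").max("time", skipna=True)
    missing_frac = (~np.isfinite(da)).groupby("time.year").mean("time")
    flagged = [
        int(y)
        for y in am["year"].values
        if float(missing_frac.sel(year=y).max()) > MAX_MISSING_FRACTION
    ]
    am.name = "annual_max_dhw"
    am.attrs["units"] = "degC-weeks"
    am.attrs["flagged_years"] = flagged
    return am
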