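"""Readers, writers and the grid/coordinate contract shared by the pipeline.

Conventions
-----------
* SST cubes are :class:`xarray.Dataset` objects with dims ``(time, lat, lon)``,
  an ``sst`` variable in degrees Celsius and a boolean ``mask`` variable on
  ``(lat, lon)`` marking the pixels under analysis.
* Coordinates are pixel centers in decimal degrees, EPSG:4326.
* Great-circle distances use the haversine formula on a sphere of radius
  6371.0 km; at the 20-km reef buffer this is indistinguishable from an
  ellipsoidal geodesic.
* Time is a daily, strictly increasing datetime64 axis on the proleptic
  Gregorian calendar; "year" always means calendar year.

All on-disk cube formats are CF-style NetCDF (classic model, via the scipy
backend), ONI series are plain ``year,month,oni`` CSV, and reef points are
``lon,lat[,region]`` CSV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0

SST_VALID_RANGE = (-5.0, 45.0)

__all__ = [
    "EARTH_RADIUS_KM",
    "FormatError",
    "ValidationError",
    "haversine_km",
    "validate_sst_cube",
    "read_sst_cube",
    "write_sst_cube",
    "mask_from_reefs",
    "write_indicator_grid",
    "read_indicator_grid",
    "read_oni",
    "write_oni",
    "read_reef_points",
    "write_reef_points",
]


class FormatError(ValueError):
    """A file does not contain the variables/columns the format requires."""


class ValidationError(ValueError):
    """Data violate an invariant of the pipeline's domain types."""


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Broadcasts over array inputs.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _as_days(delta: np.ndarray) -> np.ndarray:
    return delta / np.timedelta64(1, "D")


def validate_sst_cube(ds: xr.Dataset, max_gap_days: float = 1.0) -> xr.Dataset:
    """Check the SST-cube invariants; return the dataset unchanged.

    Raises :class:`ValidationError` on duplicated or non-increasing time
    steps, gaps larger than ``max_gap_days``, or out-of-range temperatures on
    masked pixels. Missing days on masked pixels are allowed for up to 1% of
    the series and produce a warning.
    """
    for name in ("time", "lat", "lon"):
        if name not in ds.coords:
            raise FormatError(f"cube is missing coordinate {name!r}")
    if "sst" not in ds:
        raise FormatError("cube is missing the 'sst' variable")
    t = ds["time"].values
    if len(t) > 1:
        dt = _as_days(np.diff(t))
        if np.any(dt <= 0):
            raise ValidationError("time axis is not strictly increasing")
        if np.any(dt > max_gap_days):
            raise ValidationError(
                f"time axis has gaps > {max_gap_days} days (largest: {dt.max():.1f} d)"
            )
    mask = ds["mask"].values if "mask" in ds else np.ones(ds["sst"].shape[1:], bool)
    sst = ds["sst"].values[:, mask]
    finite = np.isfinite(sst)
    if sst.size:
        frac_missing = 1.0 - finite.mean()
        if frac_missing > 0.01:
            warnings.warn(
                f"{frac_missing:.1%} of masked-pixel days are missing SST", stacklevel=2
            )
        vals = sst[finite]
        if vals.size and (vals.min() < SST_VALID_RANGE[0] or vals.max() > SST_VALID_RANGE[1]):
            raise ValidationError(
                f"SST outside plausible range {SST_VALID_RANGE} on masked pixels"
            )
    return ds


def read_sst_cube(path, bbox: tuple[float, float, float, float] | None = None) -> xr.Dataset:
    """Read a NetCDF SST cube, converting Kelvin to Celsius if needed.

    Parameters
    ----------
    path : str or Path
        NetCDF file with a CF-style ``(time, lat, lon)`` temperature variable
        named ``sst`` (or any variable with units K/Kelvin/degC/...).
    bbox : (lat_min, lat_max, lon_min, lon_max), optional
        Subset to this box (inclusive) before validation.
    """
    ds = xr.open_dataset(path, engine="scipy").load()
    if "sst" not in ds:
        cands = [v for v in ds.data_vars if ds[v].ndim == 3]
        if not cands:
            raise FormatError("no 3-D temperature variable found")
        ds = ds.rename({cands[0]: "sst"})
    units = str(ds["sst"].attrs.get("units", "degC")).lower()
    if units in ("k", "kelvin"):
        ds["sst"] = ds["sst"] - 273.15
        ds["sst"].attrs["units"] = "degC"
    if bbox is not None:
        lat_min, lat_max, lon_min, lon_max = bbox
        ds = ds.sel(lat=slice(lat_min, lat_max), lon=slice(lon_min, lon_max))
    if "mask" in ds:
        ds["mask"] = ds["mask"].astype(bool)
    else:
        ds["mask"] = (("lat", "lon"), np.ones((ds.sizes["lat"], ds.sizes["lon"]), bool))
    return validate_sst_cube(ds)


def write_sst_cube(ds: xr.Dataset, path) -> None:
    """Write an SST cube (or any aligned cube dataset) to classic NetCDF."""
    out = ds.copy()
    if "mask" in out:
        out["mask"] = out["mask"].astype(np.int8)  # NetCDF3 has no bool
    out.attrs.setdefault("Conventions", "CF-1.6")
    out.attrs.setdefault("crs", "EPSG:4326")
    out.to_netcdf(path, engine="scipy")


def _grid_resolution(coord: np.ndarray) -> float:
    if len(coord) < 2:
        return 0.05
    return float(np.median(np.abs(np.diff(coord))))


def mask_from_reefs(cube: xr.Dataset, reefs: pd.DataFrame, buffer_km: float = 20.0) -> xr.Dataset:
    """Return a copy of ``cube`` masked to pixels near reef locations.

    A pixel is kept when its center lies within ``buffer_km`` great-circle km
    of at least one reef point, or when a reef point falls inside the pixel's
    cell (so a zero buffer still selects the containing cell). The default
    20-km buffer is the conventional reef-adjacency rule at 5-km resolution.

    ``reefs`` is a DataFrame with ``lon`` and ``lat`` columns.
    """
    if len(reefs) == 0:
        raise ValidationError("empty reef point set")
    if reefs[["lon", "lat"]].isna().any().any():
        raise ValidationError("reef points contain NaN coordinates")
    lat = cube["lat"].values
    lon = cube["lon"].values
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    half_lat = _grid_resolution(lat) / 2.0
    half_lon = _grid_resolution(lon) / 2.0
    mask = np.zeros(glat.shape, dtype=bool)
    for plon, plat in reefs[["lon", "lat"]].itertuples(index=False):
        mask |= haversine_km(glat, glon, plat, plon) <= buffer_km
        mask |= (np.abs(glat - plat) <= half_lat) & (np.abs(glon - plon) <= half_lon)
    if not mask.any():
        warnings.warn("no pixel within buffer of any reef point; mask is all false", stacklevel=2)
    out = cube.copy()
    out["mask"] = (("lat", "lon"), mask)
    return out


def write_indicator_grid(grid: xr.DataArray, path, name: str | None = None) -> None:
    """Write a per-pixel indicator grid to NetCDF (EPSG:4326, NaN = unmasked).

    ``grid`` must be 2-D on ``(lat, lon)``.
    """
    if grid.dims != ("lat", "lon"):
        raise ValidationError(f"indicator grid must have dims (lat, lon), got {grid.dims}")
    vals = np.asarray(grid.values, dtype=float)
    if not np.isfinite(vals).any():
        warnings.warn("indicator grid is all-NaN", stacklevel=2)
    da = grid.astype(float)
    da.name = name or grid.name or "indicator"
    ds = da.to_dataset()
    ds.attrs["crs"] = "EPSG:4326"
    ds.to_netcdf(path, engine="scipy")


def read_indicator_grid(path) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy").load()
    names = list(ds.data_vars)
    if not names:
        raise FormatError("no indicator variable in file")
    return ds[names[0]]


def read_oni(path) -> pd.Series:
    """Read a monthly ONI CSV with ``year, month, oni`` columns.

    Returns a Series of anomalies (degC) indexed by a monthly
    :class:`pandas.PeriodIndex`. Duplicated or missing months raise.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "oni" not in df.columns and "anomaly" in df.columns:
        df = df.rename(columns={"anomaly": "oni"})
    for col in ("year", "month", "oni"):
        if col not in df.columns:
            raise FormatError(f"ONI CSV is missing column {col!r}")
    idx = pd.PeriodIndex(
        [pd.Period(freq="M", year=int(y), month=int(m)) for y, m in zip(df["year"], df["month"])]
    )
    if idx.duplicated().any():
        raise ValidationError(f"duplicated months in ONI series: {idx[idx.duplicated()].tolist()}")
    series = pd.Series(df["oni"].to_numpy(float), index=idx, name="oni").sort_index()
    full = pd.period_range(series.index[0], series.index[-1], freq="M")
    missing = full.difference(series.index)
    if len(missing):
        raise ValidationError(f"ONI series has missing months: {missing.tolist()}")
    if not np.isfinite(series.to_numpy()).all():
        raise ValidationError("ONI series contains non-finite values")
    return series


def write_oni(series: pd.Series, path) -> None:
    df = pd.DataFrame(
        {"year": series.index.year, "month": series.index.month, "oni": series.to_numpy()}
    )
    df.to_csv(path, index=False)


def read_reef_points(path) -> pd.DataFrame:
    """Read reef point locations from a ``lon,lat[,region]`` CSV."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("lon", "lat"):
        if col not in df.columns:
            raise FormatError(f"reef point CSV is missing column {col!r}")
    if df[["lon", "lat"]].isna().any().any():
        raise ValidationError("reef points contain NaN coordinates")
    return df


def write_reef_points(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
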