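"""Synthetic SST scenarios with the statistical structure the analysis assumes.

The generator emulates the features of tropical-Atlantic reef SST that drive
the heat-stress pipeline: a seasonal sinusoid peaking in late boreal summer, a
slow linear warming trend, red (AR1) daily noise, a lagged ENSO forcing, and
spatially contiguous blocks of pixels with distinct exposure regimes. The
ENSO index itself is built from piecewise-trapezoidal events so that event
timing — and hence the planted DHW/ONI coupling lag — is exactly known for
recovery experiments.

Default scenario: 33 years starting in 1985 (matching the satellite SST era
analysed), a small grid split into three longitudinal blocks whose mean
anomaly and warming trend increase from west to east, AR1(0.7) daily noise
with 0.3 degC innovations, and an ENSO coupling of 0.4 degC per unit ONI at
an 8-month lag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

__all__ = [
    "BlockSpec",
    "EnsoEvent",
    "ScenarioConfig",
    "simulate_sst",
    "plant_changepoint",
    "make_oni",
    "compute_mmm",
    "separable_scenario",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class BlockSpec:
    """A contiguous pixel block with its own exposure regime.

    ``rows``/``cols`` are half-open index ranges into the grid; ``offset`` is
    a constant mean-SST anomaly (degC) and ``trend`` a linear warming rate
    (degC/year) applied on top of the scenario baseline.
    """

    rows: tuple[int, int]
    cols: tuple[int, int]
    offset: float = 0.0
    trend: float = 0.0
    noise_sd: float | None = None  # override the scenario-wide innovation SD


@dataclass(frozen=True)
class EnsoEvent:
    """Trapezoidal ENSO event: ramp up, plateau, ramp down.

    ``start`` is the month index (0-based from the series start) at which the
    onset ramp begins; ``peak`` is the plateau ONI anomaly in degC (negative
    for La Nina-like events).
    """

    start: int
    peak: float
    rise: int = 6
    plateau: int = 4
    decay: int = 6


def _default_blocks() -> tuple[BlockSpec, ...]:
    return (
        BlockSpec(rows=(0, 8), cols=(0, 4), offset=0.0, trend=0.0),
        BlockSpec(rows=(0, 8), cols=(4, 8), offset=0.5, trend=0.025),
        BlockSpec(rows=(0, 8), cols=(8, 12), offset=1.0, trend=0.05),
    )


def _default_events() -> tuple[EnsoEvent, ...]:
    # A stylized 33-year ENSO calendar: warm/cold events of realistic
    # amplitude roughly every 3-5 years, two of them strong (~+2 degC).
    return (
        EnsoEvent(start=24, peak=1.2),
        EnsoEvent(start=42, peak=-1.5),
        EnsoEvent(start=74, peak=1.5),
        EnsoEvent(start=148, peak=2.3),
        EnsoEvent(start=166, peak=-1.5),
        EnsoEvent(start=210, peak=1.1),
        EnsoEvent(start=262, peak=-1.4),
        EnsoEvent(start=290, peak=1.4),
        EnsoEvent(start=306, peak=-1.6),
        EnsoEvent(start=362, peak=2.5),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic SST scenario.

    Identical configs (including ``seed``) produce bit-identical outputs.
    """

    n_years: int = 33
    start_year: int = 1985
    nlat: int = 8
    nlon: int = 12
    lat0: float = 15.0
    lon0: float = -80.0
    resolution_deg: float = 0.05
    mean_sst: float = 28.0
    seasonal_amplitude: float = 1.5
    peak_doy: int = 245  # seasonal maximum in early September (boreal)
    ar1: float = 0.7
    noise_sd: float = 0.3
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    enso_events: tuple[EnsoEvent, ...] = field(default_factory=_default_events)
    enso_coupling: float = 0.4  # degC of SST per degC of ONI
    enso_lag_months: int = 8  # ONI leads SST by this many months
    mmm_base_years: int = 28  # climatology base period (first N years)
    changepoint_year: int | None = None
    changepoint_step: float = 0.0
    reef_point_stride: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("AR1 coefficient must be in [0, 1)")
        occupied = np.zeros((self.nlat, self.nlon), dtype=int)
        for b in self.blocks:
            occupied[b.rows[0] : b.rows[1], b.cols[0] : b.cols[1]] += 1
        if (occupied > 1).any():
            raise ValueError("blocks overlap")


def plant_changepoint(config: ScenarioConfig, year: int, step: float) -> ScenarioConfig:
    """Return a config whose mean anomaly shifts upward by ``step`` degC from ``year`` on."""
    if not (config.start_year <= year < config.start_year + config.n_years):
        raise ValueError(
            f"changepoint year {year} outside simulated span "
            f"{config.start_year}-{config.start_year + config.n_years - 1}"
        )
    return dataclasses.replace(config, changepoint_year=year, changepoint_step=float(step))


def make_oni(config: ScenarioConfig) -> pd.Series:
    """Build the monthly ONI series from the scenario's event calendar."""
    n_months = config.n_years * 12
    oni = np.zeros(n_months)
    for ev in config.enso_events:
        ramp_up = np.linspace(0.0, ev.peak, ev.rise, endpoint=False)
        plateau = np.full(ev.plateau, ev.peak)
        ramp_down = np.linspace(ev.peak, 0.0, ev.decay, endpoint=False)
        profile = np.concatenate([ramp_up, plateau, ramp_down])
        lo = ev.start
        hi = min(lo + len(profile), n_months)
        if lo < n_months:
            oni[lo:hi] += profile[: hi - lo]
    idx = pd.period_range(start=f"{config.start_year}-01", periods=n_months, freq="M")
    return pd.Series(oni, index=idx, name="oni")


def _block_fields(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    offset = np.zeros((config.nlat, config.nlon))
    trend = np.zeros((config.nlat, config.nlon))
    label = np.zeros((config.nlat, config.nlon), dtype=int)
    for i, b in enumerate(config.blocks, start=1):
        sl = (slice(*b.rows), slice(*b.cols))
        offset[sl] = b.offset
        trend[sl] = b.trend
        label[sl] = i
    return offset, trend, label


def simulate_sst(config: ScenarioConfig) -> tuple[xr.Dataset, xr.DataArray, pd.Series, pd.DataFrame]:
    """Simulate a daily SST cube and its companion inputs.

    Returns ``(cube, mmm, oni, reefs)`` where ``cube`` is an SST dataset with
    ``sst``, ``mask`` (all true) and the generating ``block`` labels, ``mmm``
    is the warmest-month climatological mean computed from the simulated SST
    over the base period, ``oni`` is the synthetic monthly ENSO index and
    ``reefs`` a point set spread across the grid.

    The daily signal at pixel p is::

        mean + offset_p + A*cos(2*pi*(doy - peak_doy)/365.25)
             + trend_p * years  + coupling * ONI(month - lag)
             + step * [year >= changepoint_year] + AR1 noise
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(f"{config.start_year}-01-01")
    end = pd.Timestamp(f"{config.start_year + config.n_years - 1}-12-31")
    time = pd.date_range(start, end, freq="D")
    n_days = len(time)
    lat = config.lat0 + config.resolution_deg * np.arange(config.nlat)
    lon = config.lon0 + config.resolution_deg * np.arange(config.nlon)

    doy = time.dayofyear.to_numpy(float)
    years_since = (time - start).days.to_numpy(float) / DAYS_PER_YEAR
    seasonal = config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - config.peak_doy) / DAYS_PER_YEAR
    )

    oni = make_oni(config)
    month_idx = (time.year - config.start_year) * 12 + (time.month - 1)
    lagged = np.asarray(month_idx) - config.enso_lag_months
    oni_vals = oni.to_numpy()
    forcing = np.where(lagged >= 0, oni_vals[np.clip(lagged, 0, None)], 0.0)

    step = np.zeros(n_days)
    if config.changepoint_year is not None and config.changepoint_step != 0.0:
        step = np.where(time.year >= config.changepoint_year, config.changepoint_step, 0.0)

    offset, trend, label = _block_fields(config)

    base = (
        config.mean_sst
        + seasonal
        + config.enso_coupling * forcing
        + step
    )
    sst = base[:, None, None] + offset[None, :, :] + trend[None, :, :] * years_since[:, None, None]

    sd_field = np.full((config.nlat, config.nlon), float(config.noise_sd))
    for b in config.blocks:
        if b.noise_sd is not None:
            sd_field[b.rows[0] : b.rows[1], b.cols[0] : b.cols[1]] = b.noise_sd

    if np.any(sd_field > 0):
        eps = rng.standard_normal((n_days, config.nlat, config.nlon)) * sd_field
        if config.ar1 > 0:
            eps[0] /= np.sqrt(1.0 - config.ar1**2)  # stationary start
            noise = lfilter([1.0], [1.0, -config.ar1], eps, axis=0)
        else:
            noise = eps
        sst = sst + noise

    cube = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst.astype(np.float64)),
            "mask": (("lat", "lon"), np.ones((config.nlat, config.nlon), bool)),
            "block": (("lat", "lon"), label),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"crs": "EPSG:4326"},
    )
    cube["sst"].attrs["units"] = "degC"

    mmm = compute_mmm(cube, base_years=config.mmm_base_years)

    stride = max(1, config.reef_point_stride)
    pts = []
    for i in range(0, config.nlat, stride):
        for j in range(0, config.nlon, stride):
            pts.append((lon[j], lat[i], int(label[i, j])))
    reefs = pd.DataFrame(pts, columns=["lon", "lat", "region"])
    return cube, mmm, oni, reefs


def separable_scenario(seed: int = 0, n_years: int = 33) -> ScenarioConfig:
    """Benchmark scenario with three clearly distinct exposure regimes.

    Used by the clustering recovery experiments: a stable low-exposure block,
    a strongly warming block, and a high-variability block whose exposure is
    elevated throughout. The three annual-max-DHW histories differ in shape,
    not just level, so the true partition is identifiable by K-means and the
    inertia curve has its elbow at k = 3.
    """
    blocks = (
        BlockSpec(rows=(0, 8), cols=(0, 4), offset=0.0, trend=0.0),
        BlockSpec(rows=(0, 8), cols=(4, 8), offset=0.5, trend=0.12),
        BlockSpec(rows=(0, 8), cols=(8, 12), offset=1.0, trend=0.0, noise_sd=0.9),
    )
    return ScenarioConfig(seed=seed, n_years=n_years, blocks=blocks)


def compute_mmm(cube: xr.Dataset, base_years: int = 28) -> xr.DataArray:
    """Warmest monthly climatological mean SST per pixel over the base period.

    The climatology uses the first ``base_years`` calendar years of the cube,
    mirroring a 1985-2012 base on a 1985-start series.
    """
    first_year = int(cube["time"].dt.year.min())
    base = cube["sst"].sel(time=cube["time"].dt.year < first_year + base_years)
    monthly = base.groupby("time.month").mean("time")
    mmm = monthly.max("month")
    mmm.name = "mmm"
    mmm.attrs["units"] = "degC"
    mmm.attrs["base_years"] = base_years
    return mmm
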