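# reefheat

Analysis pipeline for **coral-reef heat-stress exposure** from gridded daily
sea-surface temperature (SST). It is written for reef ecologists and climate
analysts who want to go from an SST archive (e.g. a 5-km satellite product)
plus a bleaching climatology to the standard exposure indicators, a
data-driven regionalization, and the temporal analyses that relate heat
stress to ENSO — without any GIS tooling.

## What it computes

The thermal-stress core is the Coral Reef Watch metric pair. Daily
**HotSpots** are positive anomalies above the Maximum Monthly Mean (MMM)
climatology,

    HS = max(SST_daily − MMM, 0),

and **Degree Heating Weeks** accumulate HotSpots of at least 1 °C over a
trailing 84-day (12-week) window,

    DHW(t) = (1/7) · Σ_{i=t−83..t} HS_i · [HS_i ≥ 1 °C]   (°C-weeks),

computed daily. Annual maximum DHW is the main exposure indicator; 4 and
8 °C-weeks are the conventional bleaching-risk and mortality-risk levels.

On top of the engine, the package provides:

- **Exposure indicators** per pixel: overall maximum DHW, counts of
  bleaching-risk and mortality-risk years, year of maximum, and the trend of
  annual maxima from a generalized least squares fit with AR1 errors
  (non-significant slopes mapped as zero).
- **Heat-stress regions**: K-means on each pixel's annual-max-DHW history,
  elbow-curve selection of the number of regions, PCA diagnostics, and
  per-region annual exposure profiles.
- **Temporal battery** on regional daily-median DHW series averaged to
  months: Pettitt's nonparametric change-point test, Morlet wavelet and
  bias-corrected cross-wavelet spectra against the Oceanic Niño Index (ONI)
  with red-noise 95% significance and cone of influence, and lagged
  cross-correlation (±38 months).
- **ENSO-phase trend models**: yearly El Niño / La Niña / Neutral labels from
  monthly ONI, and a comparison of a Gamma GLM (log link) against an AR1-GLS
  model of annual heat stress with additive year and phase terms, including a
  sequential analysis of deviance and AICc selection.
- **Robust comparisons**: heteroscedastic one-way ANOVA on 10%-trimmed means
  with familywise-controlled pairwise post hoc tests, for ranking regions by
  exposure.
- **Synthetic scenarios** (`reefheat.synthetic`): SST cubes with seasonal
  cycle, warming trend, AR1 noise, lagged ENSO forcing and contiguous
  exposure-regime blocks, plus matching MMM grids, ONI series and reef
  points — so the whole pipeline runs and is testable with no downloads.

## Worked example

```python
from reefheat.synthetic import ScenarioConfig, simulate_sst
from reefheat.dhw import hotspot, dhw, annual_max_dhw
from reefheat.indicators import exposure_summary
from reefheat.regions import cluster_regions, elbow_curve
from reefheat.temporal import regional_series, monthly_mean, pettitt, cross_correlation
from reefheat.enso import classify_enso, annual_stress, fit_glm, fit_gls, compare_models

cube, mmm, oni, reefs = simulate_sst(ScenarioConfig(seed=42))   # 33 years
d = dhw(hotspot(cube, mmm))
am = annual_max_dhw(d).isel(year=slice(1, None))                # drop spin-up year
summary = exposure_summary(am)

curve, k, low_conf = elbow_curve(am, k_max=8, seed=0)
labeling = cluster_regions(am, k=3, seed=0)

monthly = monthly_mean(regional_series(d, labeling.labels))
series = monthly[1].dropna()                                    # most exposed region
cp = pettitt(series)
cc = cross_correlation(series, oni[series.index])

phases = classify_enso(oni)
y = annual_stress(series)
report = compare_models(fit_glm(y, phases), fit_gls(y, phases))
```

Output for this seed:

```
peak DHW: 23.8 degC-weeks
bleaching-risk pixels: 100%
elbow suggests k=3; region sizes: [32, 32, 32]
change point: 2003-07 (p=3.12e-10)
peak ONI->DHW correlation at lag 10 months
year effect: 0.280 (log scale); AICc GLM -53.8 vs GLS 181.1 -> GLM-Gamma-log
```

Reading it: the hottest pixel accumulated 23.8 °C-weeks in its worst year and
every pixel crossed the 4 °C-weeks bleaching-risk level at least once; the
elbow criterion recovers the three planted exposure regimes; the most exposed
region's monthly series shifts level in mid-2003; its heat stress trails the
ENSO index by ~10 months (the 8-month forcing lag plus the delay the 84-day
accumulation window itself introduces); and the Gamma GLM, with a positive
year effect, is preferred over the AR1-GLS by AICc.

The same pipeline is scriptable from a shell via the `reefheat` command
(`simulate`, `dhw`, `indicators`, `regionalize`, `temporal`, `enso-model`,
`compare`; see `reefheat --help`).

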