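# Methods

This note records the models implemented in `reefheat`, the parameter
choices that matter, what the synthetic scenarios do and do not emulate, and
the numerical conventions a user auditing results should know.

## Thermal-stress engine

HotSpots are daily positive anomalies of SST above the Maximum Monthly Mean
(MMM) climatology; Degree Heating Weeks (DHW) sum HotSpots ≥ 1 °C over a
trailing 84-calendar-day window and divide by 7 (°C-weeks). Conventions:

- The window is the current day plus the preceding 83 days, by day counting
  (leap years need no special casing). The first 83 days of a series are
  reported missing rather than as downward-biased partial accumulations.
- The 1 °C cutoff applies only to accumulation; HotSpots themselves are
  reported unthresholded.
- Missing days are never gap-filled. A window with more than 10% of its days
  missing yields missing DHW; with fewer, the available contributions are
  summed as-is (a conservative lower bound, flagged by the annual-max
  `flagged_years` attribute at the year level).
- The rolling implementation uses cumulative sums and is exact (absolute
  agreement with per-window re-summation at ~1e-14, verified on random
  cubes). DHW is invariant to adding a constant to both SST and MMM, and
  monotone in any single day's SST; both properties are tested.

Annual maximum DHW (per pixel, calendar year) is the main exposure
indicator; 4 and 8 °C-weeks mark bleaching risk and mortality risk.

## Grids, distances, time

Pixel-center coordinates in EPSG:4326; great-circle distances on a sphere of
radius 6371 km (at the 20-km reef-selection buffer, ellipsoidal corrections
are two orders of magnitude below the cell size). Reef masking keeps a pixel
when its center lies within the buffer of a reef point **or** when a point
falls inside the cell, so a zero buffer still selects the containing cell.
"Year" always means calendar year on the proleptic Gregorian calendar.

## Per-pixel trend: GLS with AR1 errors

Annual maxima are autocorrelated, so trends use a linear-in-time Gaussian
GLS with AR1 error covariance. The AR1 parameter is estimated per pixel by
maximum likelihood (profile likelihood with Prais–Winsten whitening), with
ρ constrained to [0, 0.99): persistence of annual heat stress is physically
non-negative, and admitting spuriously negative estimates on ~33-point
series deflates the slope standard error enough to make the nominal 5% test
reject ~7–8% of white noise. With the constraint the empirical size is
0.04–0.05 and a planted slope under AR1(0.6) noise is recovered without bias
(both measured in the acceptance checks). Slope significance is a two-sided
t-test with n−2 degrees of freedom; on maps, slopes with p > 0.05 are set to
zero so that zero reads as "no detectable trend". No seasonal terms enter
(the inputs are annual).

## Regionalization

Pixels are clustered by K-means (Lloyd, 25 random restarts, best inertia
kept) on their raw annual-max-DHW vectors. No standardization: the features
share units and scale carries real information (a uniformly hotter history
should separate from a cooler one). Pixels with any missing year are
excluded and counted. Labels are renumbered by descending mean of the
cluster center so region 1 is always the most exposed — stable across seeds.

The number of regions is suggested by an automated elbow: the k maximizing
the second difference of **log** inertia, i.e. the sharpest change in the
ratio of successive drops. The raw (linear) second difference was rejected
because it provably peaks at k = 2 whenever one separation dominates —
which is the generic case for exposure gradients — regardless of how many
groups are planted. The log variant is scale-invariant, recovers planted
three-regime structure, and degrades gracefully: when the winning contrast
is below 0.2 (no pronounced elbow, e.g. unstructured data) the suggestion is
flagged low-confidence. The full inertia curve is always returned, and the
CLI accepts `--k` to override; the choice is ultimately the analyst's.

## Temporal battery

Regional series are the cross-pixel **median** DHW per day (robust to
within-region outliers), averaged to calendar months.

**Pettitt test.** Rank-based single change-point test; U_t computed from
mid-ranks (exactly the double sign sum, verified against an O(n²) oracle
including ties), K = max|U_t|, p ≈ 2·exp(−6K²/(n³+n²)). τ is the length of
the first segment; a constant series reports no change point.

**Wavelets.** Continuous Morlet (ω₀ = 6) transform via FFT with zero
padding, 12 voices per octave, following the standard Torrence–Compo
construction. Monthly DHW means include zeros, so the input is
log(x + 1); the offset is configurable and recorded in the result metadata.
Significance is chi-square(2) at 95% against a red-noise background whose
lag-1 coefficient is estimated from the (transformed) series; the cone of
influence uses the e-folding time √2·s. Reported power is bias-corrected
(divided by scale) so peaks at different periods are comparable; the
significance decision is scale-consistent either way. The cross-wavelet is
W_x·conj(W_y) with the standard two-spectrum chi-square null (Z₉₅ = 3.999)
and each series' own red-noise spectrum; interpretation should stay inside
the cone of influence. On independent white noise the in-cone significant
fraction measures ~0.04–0.05.

**Cross-correlation.** Pearson r at lags −38..+38 months (≥10 annual cycles
inside a 33-year record); positive lag means ONI leads DHW. Significance
bounds are ±1.96/√n_pairs without autocorrelation adjustment — the
convention of common implementations, noted as a limitation: bars near the
bound on strongly autocorrelated series should not be over-read.

**Accumulation delay.** A coupling injected into SST at lag L reappears in
DHW at roughly L + 2 months: the trailing 84-day accumulation shifts the
response by about its window centroid (~6 weeks). The recovery experiments
therefore check the injected lag on the monthly SST series (exact recovery)
and the constructed monthly-pair case, while the DHW route is expected at
L + 1..3 — worth remembering when reading observed DHW–ENSO lags.

## ENSO phases and annual trend models

Years are classified from monthly ONI: El Niño (La Niña) needs at least 5
months above +0.05 °C (below −0.05 °C). The 0.05 °C default follows the
analysis this package reproduces; the conventional ONI cutoff is ±0.5 °C and
the threshold is exposed everywhere (`--oni-threshold`). If both phases
qualify, the larger month count wins, then the larger mean absolute anomaly;
a complete tie stays Neutral.

The annual response is the hottest monthly mean of the regional daily-median
DHW. Two models with additive year and phase terms (Neutral baseline):

- **Gamma GLM, log link** — annual maxima are positive and right-skewed.
  Zero responses are shifted by a configurable ε = 1e-3 (logged) rather than
  dropped. The analysis of deviance is sequential (year, then phase), F
  statistics scaled by the full model's deviance-based dispersion. Residual
  degrees of freedom are reported as n − p − 1, charging one degree of
  freedom for the estimated dispersion: for 33 years this gives (1, 30) for
  the year term and (2, 28) for the phase term.
- **Gaussian GLS with AR1 errors** — same mean structure, persistence in the
  errors, fitted by the exact ML machinery above.

Model choice is by AICc (= AIC + 2k(k+1)/(n−k−1)), counting the dispersion
(GLM) or ρ and σ² (GLS) as parameters. The two likelihoods live on
different families, so the comparison is a heuristic and the report says so;
lag-1 residual autocorrelation of each model is reported alongside.

## Robust group comparisons

Wilcox's heteroscedastic one-way ANOVA on trimmed means (`t1way`
construction): 10% trimming, Winsorized variances, Welch-type F with
non-integer degrees of freedom. Post hoc contrasts are pairwise Yuen tests
with familywise control via Studentized-maximum-modulus critical values
computed from the independence relation (2·T_ν(c) − 1)^C = 1 − α — the
standard `lincon` approximation when SMM tables are unavailable. A
per-group 10th–90th percentile pre-filter (type-7 quantiles, inclusive
bounds) is available and applied before testing when requested; it is
near-redundant with trimming by construction and both steps are logged.
With zero trimming and equal variances the omnibus reduces exactly to
classical Welch ANOVA (tested). Pixels are treated as independent sampling
units, as is conventional for these comparisons; spatial autocorrelation is
not adjusted for and p-values for spatial metrics are accordingly
optimistic.

## Synthetic scenarios

`ScenarioConfig` builds daily SST as
mean + seasonal sinusoid + block trend·t + coupling·ONI(t − lag) + step +
AR1 noise, with the seasonal peak in early September (day 245). Defaults
are the study conditions the pipeline targets: 33 years from 1985, AR1(0.7)
daily noise with 0.3 °C innovations, 0.4 °C of SST response per °C of ONI at
an 8-month lag, an event calendar of ~10 warm/cold ENSO events of realistic
amplitude (two strong, ~+2.3/+2.5 °C), and three longitudinal blocks with
graded mean anomaly and warming trend. The MMM is computed from the
simulated SST itself over the first 28 years, mirroring a 1985–2012 base on
a 1985-start archive. The ONI is piecewise-trapezoidal (onset, plateau,
decay) rather than autoregressive so that event timing — and the planted
coupling lag — is exactly known for recovery experiments.
`separable_scenario()` is the clustering benchmark: stable, strongly
warming, and high-variability blocks whose annual-max histories differ in
shape, making the true partition identifiable.

What the generator does **not** emulate: spatial correlation of the noise
beyond block structure, cloud-driven gaps, mesoscale dynamics (eddies,
upwelling), hemisphere mixtures, or ENSO's autoregressive dynamics.
Passing recovery tests therefore demonstrate correctness of the estimators
under the assumed signal structure, not skill on real archives; in
particular, real-data significance will be more optimistic than the
synthetic results wherever spatial or temporal correlation is stronger than
simulated.

## Degenerate inputs and tie-breaks

Constant series: trend (0, p = 1), Pettitt (K = 0, no τ), GLM/GLS (zero
effects, perfect fit). Year-of-maximum ties break to the earliest year.
K-means label numbering is deterministic (descending mean exposure);
clustering and PCA are seeded. Equal AICc reports a tie rather than a
selection. The ENSO phase tie chain ends at Neutral.

## Problem sizes

The shipped verification runs use grids of 8×12–10×10 pixels, 33-year daily
series (~12k days), 50–1000 replicates per statistical check — sizes chosen
so the full battery completes in minutes on one core while keeping Monte
Carlo error well inside the asserted bands.
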