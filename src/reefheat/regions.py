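"""Heat-stress regionalization by K-means on annual-maximum-DHW histories.

Each masked pixel contributes a feature vector of its annual maximum DHW over
the analysis years (raw degC-weeks; features share units, so no
standardization). K-means with multiple random restarts partitions pixels
into heat-stress regions; the elbow of the inertia curve suggests the number
of regions, and labels are renumbered by descending mean exposure so region 1
is always the most exposed. PCA scores of the feature matrix provide a 2-D
diagnostic embedding of the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["RegionLabeling", "cluster_regions", "elbow_curve", "region_profiles"]

# Minimum winning second difference of log-inertia below which the elbow
# suggestion is flagged low-confidence (no pronounced elbow).
ELBOW_CONTRAST_THRESHOLD = 0.2


@dataclass
class RegionLabeling:
    """K-means result: per-pixel labels plus clustering diagnostics.

    ``labels`` is an int grid on (lat, lon); 1..k on clustered pixels, 0 on
    pixels excluded for missing years or falling outside the mask.
    """

    labels: xr.DataArray
    k: int
    cluster_centers: np.ndarray  # (k, n_years), ordered by descending mean
    inertia: float
    pca_coords: pd.DataFrame  # columns pc1, pc2, label; one row per pixel
    n_excluded: int

    def member_index(self, region: int) -> np.ndarray:
        return self.labels.values == region


def _feature_matrix(annual_max: xr.DataArray, mask: np.ndarray | None):
    vals = annual_max.values  # (year, lat, lon)
    ny = vals.shape[0]
    flat = vals.reshape(ny, -1).T  # (pixels, years)
    ok = np.isfinite(flat).all(axis=1)
    if mask is not None:
        ok &= mask.ravel()
    return flat[ok], ok


def cluster_regions(
    annual_max: xr.DataArray,
    k: int,
    seed: int = 0,
    n_init: int = 25,
    mask: np.ndarray | None = None,
) -> RegionLabeling:
    """Partition pixels into ``k`` heat-stress regions.

    Runs Lloyd's K-means with ``n_init`` random restarts (best inertia kept)
    on the raw annual-max-DHW vectors. Pixels with any missing year are
    excluded and reported via ``n_excluded``. Deterministic for a fixed seed.
    """
    X, ok = _feature_matrix(annual_max, mask)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} complete pixels")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)

    # renumber so region 1 has the hottest mean center, stable across seeds
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    new_labels = relabel[raw]
    centers = km.cluster_centers_[order]

    grid = np.zeros(annual_max.shape[1:], dtype=int).ravel()
    grid[ok] = new_labels
    labels = xr.DataArray(
        grid.reshape(annual_max.shape[1:]),
        coords={"lat": annual_max["lat"], "lon": annual_max["lon"]},
        dims=("lat", "lon"),
        name="region",
        attrs={"k": k, "standardized_features": 0},
    )

    if len(X) >= 2 and X.shape[1] >= 2 and X.std(axis=0).sum() > 0:
        pcs = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        pcs = np.zeros((len(X), 2))
    pca_coords = pd.DataFrame({"pc1": pcs[:, 0], "pc2": pcs[:, 1], "label": new_labels})

    return RegionLabeling(
        labels=labels,
        k=k,
        cluster_centers=centers,
        inertia=float(km.inertia_),
        pca_coords=pca_coords,
        n_excluded=int((~ok).sum()),
    )


def elbow_curve(
    annual_max: xr.DataArray,
    k_max: int,
    seed: int = 0,
    n_init: int = 25,
    mask: np.ndarray | None = None,
):
    """Inertia for k = 1..k_max with an automated elbow suggestion.

    The suggestion is the k maximizing the second difference of the
    *log*-inertia curve — i.e. the point where the ratio of successive
    inertia drops changes most sharply. This is a scale-invariant stand-in
    for reading the elbow off the graph (the raw second difference always
    peaks at k = 2 when one separation dominates, even with more planted
    groups), and the full curve is always returned for the user to override.
    ``low_confidence`` is set when the winning contrast is small (no
    pronounced elbow, e.g. unstructured data).

    Returns ``(inertia_curve, suggested_k, low_confidence)`` where
    ``inertia_curve`` is a Series indexed by k.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3 to locate an elbow")
    X, _ = _feature_matrix(annual_max, mask)
    ks = np.arange(1, k_max + 1)
    inertia = np.empty(len(ks))
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed, algorithm="lloyd")
        km.fit(X)
        inertia[i] = km.inertia_
    # best-of-restarts inertia can still tick up by numeric noise; clamp
    inertia = np.minimum.accumulate(inertia)
    floor = max(inertia[0], 1.0) * 1e-12
    log_i = np.log(np.maximum(inertia, floor))
    d2 = log_i[:-2] - 2.0 * log_i[1:-1] + log_i[2:]  # at k = 2..k_max-1
    best = int(np.argmax(d2))
    suggested_k = int(ks[best + 1])
    contrast = float(d2[best])
    low_confidence = contrast < ELBOW_CONTRAST_THRESHOLD
    curve = pd.Series(inertia, index=pd.Index(ks, name="k"), name="inertia")
    return curve, suggested_k, low_confidence


def region_profiles(labeling: RegionLabeling, annual_max: xr.DataArray) -> pd.DataFrame:
    """Annual distribution of exposure within each region.

    Per region and calendar year: median, 25th and 75th percentiles of the
    annual maximum DHW across member pixels. Empty regions yield no rows.
    """
    vals = annual_max.values
    years = annual_max["year"].values
    rows = []
    for region in range(1, labeling.k + 1):
        members = labeling.member_index(region)
        if not members.any():
            continue
        sub = vals[:, members]  # (year, n_members)
        for yi, year in enumerate(years):
            v = sub[yi]
            v = v[np.isfinite(v)]
            if len(v) == 0:
                continue
            q25, med, q75 = np.percentile(v, [25, 50, 75])
            rows.append(
                {"region": region, "year": int(year), "median": med, "q25": q25, "q75": q75}
            )
    return pd.DataFrame(rows, columns=["region", "year", "median", "q25", "q75"])
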