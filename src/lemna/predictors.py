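"""Derived predictors computed from site geometry and occurrence data.

These are the variables a lake survey feeds into occurrence models beyond the
water-chemistry measurements themselves: shoreline complexity, unit-interval
rescaling of model covariates, great-circle distances, neighbour counts
within a radius, distance to the nearest water body occupied by a focal
taxon, and a collinearity screen over candidate predictors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import OccurrenceMatrix, SiteTable

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

M2_PER_HA = 10_000.0


def shoreline_development_index(shore_length_m: float, area_ha: float) -> float:
    """Shoreline development index: L / (2 * sqrt(pi * A)).

    The ratio of shoreline length to the circumference of a circle with the
    same area — 1 for a perfect circle, larger for convoluted shorelines.
    ``shore_length_m`` in metres, ``area_ha`` in hectares (converted to m2
    internally).  Scale-invariant: (cL, c^2 A) gives the same index.
    """
    L = float(shore_length_m)
    A = float(area_ha) * M2_PER_HA
    if L <= 0 or A <= 0:
        raise ValueError("shore length and area must be positive")
    return L / (2.0 * np.sqrt(np.pi * A))


def rescale_unit_interval(values) -> np.ndarray:
    """Affinely map values so min -> 0 and max -> 1.

    Used on every model covariate so coefficient magnitudes are comparable
    across predictors measured on different scales.  A constant vector has no
    spread and cannot be rescaled: the caller must drop that predictor.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least two finite values to rescale")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError("constant vector cannot be rescaled to [0, 1]")
    return (x - lo) / (hi - lo)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def pairwise_distances_km(sites: SiteTable, metric: str = "haversine") -> np.ndarray:
    """Symmetric n x n distance matrix between all site pairs.

    ``metric`` is ``"haversine"`` (default) or ``"euclidean"`` — the latter
    treats coordinates as planar km offsets, useful for synthetic grids.
    """
    coords = sites.coordinates()
    if metric == "euclidean":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))
    if metric != "haversine":
        raise ValueError(f"unknown metric {metric!r}")
    lat, lon = coords[:, 0], coords[:, 1]
    return np.asarray(haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :]))


def _site_index(sites: SiteTable, focal: str) -> int:
    ids = list(sites.site_ids)
    try:
        return ids.index(focal)
    except ValueError:
        raise KeyError(f"unknown site_id {focal!r}") from None


def count_neighbors_within(sites: SiteTable, focal: str, radius_km: float,
                           distances: np.ndarray | None = None) -> int:
    """Number of other water bodies within ``radius_km`` of the focal site.

    Closed-ball convention: distance <= radius counts.  The focal site itself
    never counts, even at radius 0.
    """
    if radius_km < 0:
        raise ValueError("radius must be non-negative")
    i = _site_index(sites, focal)
    d = pairwise_distances_km(sites) if distances is None else distances
    mask = d[i] <= radius_km
    mask[i] = False
    return int(mask.sum())


def neighbor_counts(sites: SiteTable, radius_km: float,
                    distances: np.ndarray | None = None) -> pd.Series:
    """Vector of neighbour counts for every site (self excluded)."""
    d = pairwise_distances_km(sites) if distances is None else distances
    within = d <= radius_km
    np.fill_diagonal(within, False)
    return pd.Series(within.sum(axis=1), index=list(sites.site_ids))


def distance_to_nearest_occupied(sites: SiteTable, occ: OccurrenceMatrix,
                                 taxon: str, focal: str,
                                 distances: np.ndarray | None = None) -> float:
    """Distance (km) from the focal site to the nearest *other* occupied site.

    The focal site is excluded even when itself occupied — the quantity is
    the distance to another water body holding the taxon.  Returns NaN when
    no other site is occupied (a missing value, never zero).
    """
    i = _site_index(sites, focal)
    presence = occ.taxon_presence(taxon).to_numpy()
    d = pairwise_distances_km(sites) if distances is None else distances
    occupied = presence.astype(bool).copy()
    occupied[i] = False
    if not occupied.any():
        return float("nan")
    return float(d[i, occupied].min())


def nearest_occupied_distances(sites: SiteTable, occ: OccurrenceMatrix, taxon: str,
                               distances: np.ndarray | None = None) -> pd.Series:
    """distance_to_nearest_occupied for every site at once."""
    d = pairwise_distances_km(sites) if distances is None else distances
    presence = occ.taxon_presence(taxon).to_numpy().astype(bool)
    out = np.full(len(d), np.nan)
    for i in range(len(d)):
        occupied = presence.copy()
        occupied[i] = False
        if occupied.any():
            out[i] = d[i, occupied].min()
    return pd.Series(out, index=list(sites.site_ids))


def collinearity_screen(sites: SiteTable, threshold: float = 0.7,
                        variables: list[str] | None = None) -> pd.DataFrame:
    """Flag predictor pairs whose |Pearson r| meets the threshold.

    Binary 0/1 predictors enter as-is: the point-biserial correlation is
    numerically the Pearson correlation on the 0/1 coding.  Constant columns
    are excluded with a warning.  Returns a DataFrame with columns
    ``var1, var2, r`` sorted by |r| descending; the screen only reports —
    which member of a flagged pair to drop is the analyst's call.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    names = variables if variables is not None else sites.covariate_names
    if len(sites.data) < 3:
        raise ValueError("need at least 3 sites for a correlation screen")
    cols = {}
    for name in names:
        v = sites.covariate(name)
        if np.nanstd(v) == 0:
            warnings.warn(f"constant column {name!r} excluded from collinearity screen")
            continue
        cols[name] = v
    corr = pd.DataFrame(cols).corr(method="pearson")
    rows = []
    keys = list(corr.columns)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                rows.append((a, b, float(r)))
    rows.sort(key=lambda t: -abs(t[2]))
    return pd.DataFrame(rows, columns=["var1", "var2", "r"])
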