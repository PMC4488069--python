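"""Core containers for lake and pond survey data.

A survey consists of a table of per-site environmental covariates
(:class:`SiteTable`), a binary site-by-taxon presence/absence matrix with
functional-group labels (:class:`OccurrenceMatrix`), and one or more response
definitions (:class:`ResponseSpec`) naming what is to be modelled — a single
taxon, or the presence of any member of a functional group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariate codes understood by the validators, with units:
#: size (ha), shoreline (dimensionless index), depth (m), totalP (mg/L),
#: pH (unitless), cond (uS/cm), alk (mg/L), secchi (m), nonFP (taxon count),
#: lakes1km / lakes10km (neighbour counts), distLM / distSP / distW (km),
#: boatlaunch (0/1).
COVARIATE_CODES = (
    "size", "shoreline", "depth", "totalP", "pH", "cond", "alk", "secchi",
    "nonFP", "lakes1km", "lakes10km", "distLM", "distSP", "distW",
    "boatlaunch",
)

COUNT_COVARIATES = frozenset({"nonFP", "lakes1km", "lakes10km"})
BINARY_COVARIATES = frozenset({"boatlaunch"})
#: Physically non-negative quantities (pH additionally bounded above by 14).
NONNEGATIVE_COVARIATES = frozenset({
    "size", "shoreline", "depth", "totalP", "cond", "alk", "secchi",
    "distLM", "distSP", "distW",
})

ID_COLUMNS = ("site_id", "latitude", "longitude")


class SurveyValidationError(ValueError):
    """Raised when a survey table violates its structural invariants."""


@dataclass
class SiteTable:
    """Per-site covariates and coordinates, one row per water body.

    ``data`` must contain ``site_id``, ``latitude`` and ``longitude`` columns;
    every other column is treated as a covariate.  Validation is structural
    only — unknown covariate codes are allowed and pass through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("site_id",):
            if col not in df.columns:
                raise SurveyValidationError(f"site table lacks required column {col!r}")
        dup = df["site_id"][df["site_id"].duplicated()]
        if len(dup):
            raise SurveyValidationError(f"duplicate site_id: {dup.iloc[0]!r}")
        if "latitude" in df.columns:
            lat = df["latitude"].to_numpy(float)
            if np.any((lat < -90) | (lat > 90)):
                raise SurveyValidationError("latitude outside [-90, 90]")
        if "longitude" in df.columns:
            lon = df["longitude"].to_numpy(float)
            if np.any((lon < -180) | (lon > 180)):
                raise SurveyValidationError("longitude outside [-180, 180]")
        for col in df.columns:
            if col in ID_COLUMNS:
                continue
            vals = df[col].to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if col in COUNT_COVARIATES:
                if np.any(finite < 0) or np.any(finite != np.round(finite)):
                    raise SurveyValidationError(f"{col} must hold non-negative integers")
            if col in BINARY_COVARIATES and not np.all(np.isin(finite, (0.0, 1.0))):
                raise SurveyValidationError(f"{col} must be 0/1")
            if col in NONNEGATIVE_COVARIATES and np.any(finite < 0):
                raise SurveyValidationError(f"{col} must be non-negative")
            if col == "pH" and np.any((finite < 0) | (finite > 14)):
                raise SurveyValidationError("pH outside [0, 14]")

    @property
    def site_ids(self) -> pd.Series:
        return self.data["site_id"]

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    def covariate(self, name: str) -> np.ndarray:
        if name in ("latitude", "longitude"):
            return self.data[name].to_numpy(float)
        if name not in self.covariate_names:
            raise KeyError(f"unknown covariate {name!r}")
        return self.data[name].to_numpy(float)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of latitude, longitude in decimal degrees."""
        return self.data[["latitude", "longitude"]].to_numpy(float)


@dataclass
class OccurrenceMatrix:
    """Binary site-by-taxon matrix with a functional-group label per taxon.

    ``presence`` is indexed by site_id with one column per taxon; cells are
    0/1.  ``group_of`` maps every taxon to exactly one group label (for
    example ``"floating"`` vs ``"other"``).
    """

    presence: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if vals.size and not np.all(np.isin(vals, (0, 1))):
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise SurveyValidationError(
                f"occurrence value outside {{0,1}} at site "
                f"{self.presence.index[bad[0]]!r}, taxon "
                f"{self.presence.columns[bad[1]]!r}"
            )
        self.presence = self.presence.astype(np.int8)
        missing = [t for t in self.presence.columns if t not in self.group_of]
        for t in missing:
            self.group_of[t] = "other"

    @property
    def sites(self) -> pd.Index:
        return self.presence.index

    @property
    def taxa(self) -> pd.Index:
        return self.presence.columns

    @property
    def n_sites(self) -> int:
        return len(self.presence)

    def occupancy(self) -> pd.Series:
        """Occupancy frequency k_i: number of occupied sites per taxon."""
        return self.presence.sum(axis=0)

    def group_members(self, group: str) -> list[str]:
        """Taxa carrying this group label (and present as matrix columns).

        A known label with no matrix columns yields an empty list — a group
        that exists in principle but has no observed members.
        """
        if group not in self.group_of.values():
            raise KeyError(f"unknown functional group {group!r}")
        return [t for t, g in self.group_of.items()
                if g == group and t in self.presence.columns]

    def group_presence(self, group: str) -> pd.Series:
        """Per-site indicator: any member of ``group`` present."""
        members = self.group_members(group)
        if not members:
            return pd.Series(0, index=self.sites, dtype=np.int8)
        return (self.presence[members].sum(axis=1) > 0).astype(np.int8)

    def taxon_presence(self, taxon: str) -> pd.Series:
        if taxon not in self.presence.columns:
            raise KeyError(f"unknown taxon {taxon!r}")
        return self.presence[taxon]


@dataclass
class ResponseSpec:
    """What to model: one taxon's presence, or any-member presence of a group.

    Exactly one of ``taxon`` / ``group`` must be given.  ``distance_predictor``
    optionally names the distance-to-nearest-occupied covariate that only
    applies to this response (per-taxon models include the distance to the
    nearest water body holding that taxon; the group model does not).
    """

    name: str
    taxon: str | None = None
    group: str | None = None
    distance_predictor: str | None = None

    def __post_init__(self) -> None:
        if (self.taxon is None) == (self.group is None):
            raise ValueError("ResponseSpec needs exactly one of taxon/group")

    def resolve(self, occ: OccurrenceMatrix) -> pd.Series:
        """Binary response vector aligned to the occurrence matrix's sites."""
        if self.taxon is not None:
            return occ.taxon_presence(self.taxon)
        return occ.group_presence(self.group)
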