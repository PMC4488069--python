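"""Delimited-text readers and writers for survey data.

Three plain CSV files describe a survey:

* sites file — one row per water body: ``site_id``, ``latitude``,
  ``longitude`` and covariate columns;
* occurrence file — rows are sites (``site_id`` first column), one column
  per taxon, cells 0/1;
* taxa file — two columns ``taxon,group`` assigning each taxon to a
  functional group.

Writers emit RFC-4180-style CSV with a fixed column order and ``.`` decimal
separator, so read -> write is the identity on files the writers produced.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .types import OccurrenceMatrix, SiteTable, SurveyValidationError


def read_sites(path: str | os.PathLike) -> SiteTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if "site_id" not in df.columns:
        raise SurveyValidationError(f"{path}: missing site_id column")
    df["site_id"] = df["site_id"].astype(str)
    return SiteTable(df)


def read_occurrence(path: str | os.PathLike,
                    taxa_path: str | os.PathLike | None = None) -> OccurrenceMatrix:
    df = pd.read_csv(path)  # integer cells; no float round-trip concern
    if "site_id" not in df.columns:
        raise SurveyValidationError(f"{path}: missing site_id column")
    df["site_id"] = df["site_id"].astype(str)
    dup = df["site_id"][df["site_id"].duplicated()]
    if len(dup):
        raise SurveyValidationError(f"{path}: duplicate site_id: {dup.iloc[0]!r}")
    presence = df.set_index("site_id")
    vals = presence.to_numpy()
    bad = np.argwhere(~np.isin(vals, (0, 1)))
    if len(bad):
        r, c = bad[0]
        raise SurveyValidationError(
            f"{path}: occurrence value {vals[r, c]!r} outside {{0,1}} at "
            f"row site_id={presence.index[r]!r}, column {presence.columns[c]!r}"
        )
    group_of: dict[str, str] = {}
    if taxa_path is not None:
        taxa = pd.read_csv(taxa_path)
        group_of = dict(zip(taxa["taxon"].astype(str), taxa["group"].astype(str)))
    return OccurrenceMatrix(presence, group_of)


def read_survey(site_path: str | os.PathLike,
                occurrence_path: str | os.PathLike,
                taxa_path: str | os.PathLike | None = None,
                ) -> tuple[SiteTable, OccurrenceMatrix]:
    """Read and align the sites and occurrence files.

    Raises if a site appears in one file only; the occurrence matrix is
    reordered to match the site-table row order.
    """
    sites = read_sites(site_path)
    occ = read_occurrence(occurrence_path, taxa_path)
    site_ids = list(sites.site_ids)
    only_sites = set(site_ids) - set(occ.sites)
    only_occ = set(occ.sites) - set(site_ids)
    if only_sites or only_occ:
        raise SurveyValidationError(
            "site/occurrence mismatch: "
            f"only in sites file {sorted(only_sites)!r}, "
            f"only in occurrence file {sorted(only_occ)!r}"
        )
    occ = OccurrenceMatrix(occ.presence.loc[site_ids], occ.group_of)
    return sites, occ


def write_sites(sites: SiteTable, path: str | os.PathLike) -> None:
    # canonical order: ids/coords first, then covariates in stored order
    cols = [c for c in ("site_id", "latitude", "longitude") if c in sites.data.columns]
    cols += [c for c in sites.data.columns if c not in cols]
    sites.data[cols].to_csv(path, index=False)


def write_occurrence(occ: OccurrenceMatrix, path: str | os.PathLike,
                     taxa_path: str | os.PathLike | None = None) -> None:
    out = occ.presence.reset_index()
    out.columns = ["site_id", *occ.presence.columns]
    out.to_csv(path, index=False)
    if taxa_path is not None:
        pd.DataFrame({
            "taxon": list(occ.taxa),
            "group": [occ.group_of[t] for t in occ.taxa],
        }).to_csv(taxa_path, index=False)


def write_survey(sites: SiteTable, occ: OccurrenceMatrix, outdir: str | os.PathLike,
                 prefix: str = "survey") -> dict[str, str]:
    """Write the three canonical files into ``outdir``; returns their paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sites": os.path.join(outdir, f"{prefix}_sites.csv"),
        "occurrence": os.path.join(outdir, f"{prefix}_occurrence.csv"),
        "taxa": os.path.join(outdir, f"{prefix}_taxa.csv"),
    }
    write_sites(sites, paths["sites"])
    write_occurrence(occ, paths["occurrence"], paths["taxa"])
    return paths
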