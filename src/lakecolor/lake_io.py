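"""Reading, validation and pairing of lake-survey and plankton tables.

Survey tables are CSV files with one row per site-visit. Column names vary
between survey exports, so reading goes through a *dialect*: a mapping from
canonical field names to the column names found in the file. Two built-in
dialects approximate the 2007- and 2012-style national survey exports; a
``generic`` dialect expects canonical names directly.

Canonical survey columns: ``site_id``, ``year``, ``ecoregion``, ``weight``
(design weight, lakes represented), ``lat``, ``lon``, ``tp`` (total
phosphorus, µg/L), ``color`` (true color, PCU), ``tp_below_detection``,
``area_ha``. Any unmapped numeric columns are carried through as covariates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY = ("site_id", "year", "weight", "tp", "color")
OPTIONAL = ("ecoregion", "lat", "lon", "tp_below_detection", "area_ha")

#: Built-in column dialects (canonical name -> file column name).
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in MANDATORY + OPTIONAL},
    "nla2007": {
        "site_id": "SITE_ID",
        "year": "YEAR",
        "ecoregion": "WSA_ECO9",
        "weight": "WGT_NLA",
        "lat": "LAT_DD",
        "lon": "LON_DD",
        "tp": "PTL",
        "color": "COLOR",
        "tp_below_detection": "PTL_BELOW_DETECT",
        "area_ha": "LAKEAREA_HA",
    },
    "nla2012": {
        "site_id": "SITE_ID",
        "year": "YEAR",
        "ecoregion": "AGGR_ECO9_2015",
        "weight": "WGT_ALL",
        "lat": "LAT_DD83",
        "lon": "LON_DD83",
        "tp": "PTL_RESULT",
        "color": "COLOR_RESULT",
        "tp_below_detection": "PTL_BELOW_DETECT",
        "area_ha": "AREA_HA",
    },
}

_TRUTHY = {"1", "true", "t", "yes", "y"}


class DialectError(ValueError):
    """A mandatory column is missing from the dialect or the file."""


def _resolve_dialect(dialect) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return dict(DIALECTS[dialect])
        except KeyError:
            raise DialectError(f"unknown dialect {dialect!r}; "
                               f"built-ins: {sorted(DIALECTS)}") from None
    return dict(dialect)


def read_survey_table(path, dialect="generic"):
    """Read a survey CSV into the canonical schema.

    Parameters
    ----------
    path : path-like
        CSV file with a header row (UTF-8).
    dialect : str or mapping
        Built-in dialect name or a canonical→source column mapping. Units
        are taken at face value from the dialect (TP µg/L, color PCU).

    Returns
    -------
    (DataFrame, DataFrame)
        The validated samples and a table of rejected rows with a
        ``reject_reason`` column. Rows with non-numeric or missing TP,
        color, weight or year, or non-positive weight, are rejected, not
        zero-filled.

    Raises
    ------
    DialectError
        If a mandatory column is absent from the dialect or the file.
    """
    mapping = _resolve_dialect(dialect)
    missing = [c for c in MANDATORY if c not in mapping]
    if missing:
        raise DialectError(f"dialect lacks mandatory columns: {missing}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    absent = [mapping[c] for c in MANDATORY if mapping[c] not in raw.columns]
    if absent:
        raise DialectError(f"file {path} lacks mandatory columns: {absent}")

    df = pd.DataFrame(index=raw.index)
    df["site_id"] = raw[mapping["site_id"]].astype(str)
    for field, kind in (("year", int), ("weight", float),
                        ("tp", float), ("color", float)):
        df[field] = pd.to_numeric(raw[mapping[field]], errors="coerce")
    for field in ("ecoregion",):
        src = mapping.get(field)
        df[field] = raw[src].astype(str) if src in raw.columns else ""
    for field in ("lat", "lon", "area_ha"):
        src = mapping.get(field)
        df[field] = (pd.to_numeric(raw[src], errors="coerce")
                     if src in raw.columns else np.nan)
    src = mapping.get("tp_below_detection")
    if src in raw.columns:
        df["tp_below_detection"] = (raw[src].str.strip().str.lower()
                                    .isin(_TRUTHY))
    else:
        df["tp_below_detection"] = False

    # unmapped numeric columns ride along as covariates
    mapped_src = set(mapping.values())
    for col in raw.columns:
        if col in mapped_src:
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.notna().any():
            df[col] = vals

    reasons = pd.Series("", index=df.index)
    for field in ("year", "weight", "tp", "color"):
        bad = df[field].isna()
        reasons[bad & (reasons == "")] = f"non-numeric or missing {field}"
    bad_w = df["weight"].notna() & (df["weight"] <= 0)
    reasons[bad_w & (reasons == "")] = "non-positive weight"
    bad_neg = (df["tp"].notna() & (df["tp"] < 0) & ~df["tp_below_detection"]) | (
        df["color"].notna() & (df["color"] < 0))
    reasons[bad_neg & (reasons == "")] = "negative tp or color"

    rejected = raw.loc[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    samples = df.loc[reasons == ""].copy()
    samples["year"] = samples["year"].astype(int)

    dup = samples.duplicated(subset=["site_id", "year"], keep=False)
    if dup.any():
        sites = sorted(samples.loc[dup, "site_id"].unique())
        raise ValueError(f"duplicate (site_id, year) rows for sites: {sites}")
    if len(rejected):
        logger.warning("rejected %d of %d rows from %s",
                       len(rejected), len(raw), path)
    return samples.reset_index(drop=True), rejected.reset_index(drop=True)


def apply_detection_filter(samples: pd.DataFrame):
    """Drop samples whose TP was flagged below the detection limit.

    Returns
    -------
    (DataFrame, int)
        Retained samples and the number removed.
    """
    flagged = samples["tp_below_detection"].astype(bool)
    n_removed = int(flagged.sum())
    if n_removed:
        logger.info("removed %d samples with TP below detection", n_removed)
    return samples.loc[~flagged].reset_index(drop=True), n_removed


def pair_resampled(survey1: pd.DataFrame, survey2: pd.DataFrame):
    """Pair lakes sampled in both surveys.

    A pair requires the same ``site_id`` in both tables and usable (finite)
    TP and color in both years. Output columns carry ``_t1`` / ``_t2``
    suffixes for the year-specific fields.

    Returns
    -------
    (DataFrame, dict)
        The paired table (one row per resampled lake) and a report dict
        with ``unmatched_t1`` / ``unmatched_t2`` site-id lists and
        ``excluded`` (shared sites dropped for missing values).

    Raises
    ------
    ValueError
        If either survey contains a duplicated site_id.
    """
    for name, df in (("survey1", survey1), ("survey2", survey2)):
        dup = df["site_id"].duplicated(keep=False)
        if dup.any():
            sites = sorted(df.loc[dup, "site_id"].unique())
            raise ValueError(f"{name} has duplicate site_id: {sites}")
    y1 = survey1["year"].iloc[0] if len(survey1) else None
    y2 = survey2["year"].iloc[0] if len(survey2) else None
    if y1 is not None and y2 is not None and not (y1 < y2):
        raise ValueError(f"survey1 year ({y1}) must precede survey2 year ({y2})")

    merged = survey1.merge(survey2, on="site_id", how="inner",
                           suffixes=("_t1", "_t2"))
    usable = (merged["tp_t1"].notna() & merged["color_t1"].notna()
              & merged["tp_t2"].notna() & merged["color_t2"].notna())
    excluded = merged.loc[~usable, "site_id"].tolist()
    pairs = merged.loc[usable].reset_index(drop=True)
    shared = set(merged["site_id"])
    report = {
        "unmatched_t1": sorted(set(survey1["site_id"]) - shared),
        "unmatched_t2": sorted(set(survey2["site_id"]) - shared),
        "excluded": excluded,
    }
    if excluded:
        logger.info("excluded %d shared sites with missing TP/color", len(excluded))
    return pairs, report


# ---------------------------------------------------------------------------
# plankton count tables

TAXON_MANDATORY = ("site_id", "group", "order_name", "taxon_id", "density")
TAXON_OPTIONAL = ("genus_name", "mesh", "biovolume", "biomass")
_GROUPS = {"phytoplankton", "zooplankton"}
_MESHES = {"none", "fine", "coarse"}


def read_taxon_table(path) -> pd.DataFrame:
    """Read a plankton count CSV with canonical columns.

    Mandatory: site_id, group (phytoplankton|zooplankton), order_name,
    taxon_id, density (per mL). Optional: genus_name, mesh
    (none|fine|coarse), biovolume (µm³/mL), biomass (µg dry weight/L).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in TAXON_MANDATORY if c not in raw.columns]
    if missing:
        raise DialectError(f"taxon table lacks columns: {missing}")
    df = pd.DataFrame()
    for col in ("site_id", "group", "order_name", "taxon_id"):
        df[col] = raw[col].astype(str)
    df["genus_name"] = raw["genus_name"] if "genus_name" in raw.columns else ""
    df["mesh"] = raw["mesh"].str.lower() if "mesh" in raw.columns else "none"
    df.loc[df["mesh"] == "", "mesh"] = "none"
    for col in ("density", "biovolume", "biomass"):
        df[col] = (pd.to_numeric(raw[col], errors="coerce")
                   if col in raw.columns else np.nan)

    bad_group = ~df["group"].isin(_GROUPS)
    if bad_group.any():
        raise ValueError(f"unknown group values: {sorted(df.loc[bad_group, 'group'].unique())}")
    bad_mesh = ~df["mesh"].isin(_MESHES)
    if bad_mesh.any():
        raise ValueError(f"unknown mesh values: {sorted(df.loc[bad_mesh, 'mesh'].unique())}")
    for col in ("density", "biovolume", "biomass"):
        if (df[col] < 0).any():
            raise ValueError(f"negative {col} values present")
    # group must be fixed per taxon_id
    ngroups = df.groupby("taxon_id")["group"].nunique()
    mixed = ngroups[ngroups > 1]
    if len(mixed):
        raise ValueError(f"taxa assigned to multiple groups: {list(mixed.index)}")
    return df
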