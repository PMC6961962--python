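"""Plankton community processing.

Builds sites × taxa biomass (or density) matrices from count tables:
converting phytoplankton biovolume to dry biomass, averaging zooplankton
taxa counted in both net meshes, removing rare taxa (the 5% rule, first at
order level, then at genus level within retained orders), aggregating
genera to orders, and computing zooplankton:phytoplankton biomass ratios.

Units: density is individuals (or cells) per mL; biovolume is µm³/mL;
biomass is µg dry weight per L.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Dry fraction of wet mass.
DRY_FRACTION = 0.20
#: Wet-mass density assumed for biovolume: 1 g/mL, i.e. 1 µm³ = 1e-6 µg.
UG_PER_UM3 = 1e-6
ML_PER_L = 1000.0

#: Default order membership for ratio partitioning.
ROTIFER_ORDERS = frozenset({"Ploima", "Flosculariaceae"})
CRUSTACEAN_ORDERS = frozenset({"Diplostraca", "Calanoida", "Cyclopoida"})


def biovolume_to_dry_biomass(biovolume):
    """Convert phytoplankton biovolume (µm³/mL) to dry biomass (µg dw/L).

    Wet mass assumes unit density (1 µm³ = 10⁻⁶ µg); per-mL values are
    scaled to per-L; dry weight is 20% of wet weight. Hence
    10⁶ µm³/mL → 1000 µg wet/L → 200 µg dry/L. Linear in the input.
    """
    bv = np.asarray(biovolume, dtype=float)
    if np.any(bv < 0):
        raise ValueError("biovolume must be non-negative")
    out = bv * UG_PER_UM3 * ML_PER_L * DRY_FRACTION
    return out.item() if out.ndim == 0 else out


def merge_mesh_duplicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Average zooplankton taxa counted in both net meshes.

    For each (site_id, taxon_id) of the zooplankton group present in both
    the fine (50 µm) and coarse (150 µm) mesh samples, density and biomass
    are replaced by their arithmetic means in a single merged record
    (mesh = ``merged``). Single-mesh records and phytoplankton pass
    through unchanged. Idempotent.
    """
    zoo = counts["group"] == "zooplankton"
    both = counts.loc[zoo & counts["mesh"].isin(["fine", "coarse"])]
    keys = both.groupby(["site_id", "taxon_id"])["mesh"].nunique()
    dup_keys = set(keys[keys == 2].index)
    if not dup_keys:
        return counts.copy()

    idx = pd.MultiIndex.from_frame(counts[["site_id", "taxon_id"]])
    is_dup = zoo.to_numpy() & idx.isin(dup_keys) & counts["mesh"].isin(
        ["fine", "coarse"]).to_numpy()
    dups = counts.loc[is_dup]
    agg = {"density": "mean", "biovolume": "mean", "biomass": "mean"}
    first = {c: "first" for c in counts.columns
             if c not in ("site_id", "taxon_id", "mesh", *agg)}
    merged = (dups.groupby(["site_id", "taxon_id"], as_index=False)
              .agg({**agg, **first}))
    merged["mesh"] = "merged"
    out = pd.concat([counts.loc[~is_dup], merged], ignore_index=True)
    return out[counts.columns.tolist()]


def community_matrix(counts: pd.DataFrame, group: str, rank: str = "genus",
                     value: str = "biomass") -> pd.DataFrame:
    """Pivot a count table into a sites × taxa matrix.

    Parameters
    ----------
    counts : DataFrame
        Canonical taxon-count table (one record per site × taxon × mesh).
    group : "phytoplankton" or "zooplankton"
    rank : "genus" or "order"
        Column identity of the matrix; genus-level columns are labelled
        ``order_name|genus_name`` so they can later be aggregated.
    value : "biomass" or "density"

    Records within the same cell (e.g. multiple species of a genus) are
    summed. Missing values count as zero.
    """
    sub = counts.loc[counts["group"] == group].copy()
    if rank == "genus":
        sub["taxon"] = sub["order_name"] + "|" + sub["genus_name"].fillna("")
    elif rank == "order":
        sub["taxon"] = sub["order_name"]
    else:
        raise ValueError("rank must be 'genus' or 'order'")
    mat = sub.pivot_table(index="site_id", columns="taxon", values=value,
                          aggfunc="sum", fill_value=0.0)
    mat.attrs.update({"rank": rank, "group": group, "value": value,
                      "transform": "none"})
    return mat


def filter_rare_taxa(matrix: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Drop taxa that never contribute ≥ ``threshold`` of any sample.

    A taxon (column) is retained iff its relative contribution to at least
    one site's total is ≥ threshold (so a 5.0% share in a single sample
    retains it; 4.9% everywhere removes it). Sites with zero total are
    ignored when computing shares. Idempotent; never increases the column
    count.

    Raises
    ------
    ValueError
        If no taxa survive — lower the threshold.
    """
    totals = matrix.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("matrix has no non-empty samples")
    shares = matrix.loc[nonzero].div(totals[nonzero], axis=0)
    keep = (shares >= threshold).any(axis=0)
    if not keep.any():
        raise ValueError(
            f"no taxa reach a {threshold:.0%} share in any sample; "
            "lower the threshold")
    out = matrix.loc[:, keep.index[keep]].copy()
    out.attrs.update(matrix.attrs)
    return out


def filter_rare_two_stage(counts: pd.DataFrame, group: str,
                          value: str = "biomass",
                          threshold: float = 0.05) -> pd.DataFrame:
    """Apply the 5% rule first at order level, then at genus level.

    Orders that never reach the threshold share of any sample are removed;
    within the retained orders, genera that never reach the threshold are
    removed. Returns the filtered genus-level matrix.
    """
    order_mat = community_matrix(counts, group, rank="order", value=value)
    kept_orders = set(filter_rare_taxa(order_mat, threshold).columns)
    sub = counts.loc[(counts["group"] == group)
                     & counts["order_name"].isin(kept_orders)]
    genus_mat = community_matrix(sub, group, rank="genus", value=value)
    return filter_rare_taxa(genus_mat, threshold)


def aggregate_rank(matrix: pd.DataFrame,
                   genus_to_order: dict[str, str] | None = None) -> pd.DataFrame:
    """Aggregate a genus-level matrix to order level by summing columns.

    By default the order is parsed from the ``order|genus`` column labels
    produced by :func:`community_matrix`; alternatively a genus→order
    mapping may be supplied. Per-site totals are conserved exactly.

    Raises
    ------
    KeyError
        If any genus column cannot be mapped to an order.
    """
    if matrix.attrs.get("rank") == "order":
        return matrix.copy()
    orders = []
    unknown = []
    for col in matrix.columns:
        if genus_to_order is not None:
            genus = str(col).split("|", 1)[-1]
            if genus in genus_to_order:
                orders.append(genus_to_order[genus])
                continue
        if "|" in str(col):
            orders.append(str(col).split("|", 1)[0])
        else:
            unknown.append(str(col))
    if unknown:
        raise KeyError(f"genera with unknown order: {unknown}")
    out = matrix.T.groupby(np.asarray(orders)).sum().T
    out.columns.name = "taxon"
    out.attrs.update(matrix.attrs)
    out.attrs["rank"] = "order"
    return out


def zp_ratios(zoo_matrix: pd.DataFrame, phyto_matrix: pd.DataFrame,
              rotifer_orders=ROTIFER_ORDERS,
              crustacean_orders=CRUSTACEAN_ORDERS) -> pd.DataFrame:
    """Zooplankton:phytoplankton biomass ratios per site.

    Both inputs are sites × taxa biomass matrices (µg dw/L); the
    zooplankton matrix may be at genus (``order|genus``) or order level.
    Ratios are reported for total zooplankton, crustaceans only
    (copepod + cladoceran orders) and rotifers only. Sites with zero
    phytoplankton biomass keep their biomass columns but get NaN ratios
    and ``ratio_defined = False``.
    """
    zoo_orders = aggregate_rank(zoo_matrix)
    sites = zoo_orders.index.intersection(phyto_matrix.index)
    zoo_orders = zoo_orders.loc[sites]
    phyto_total = phyto_matrix.loc[sites].sum(axis=1)

    zoo_total = zoo_orders.sum(axis=1)
    rot_cols = [c for c in zoo_orders.columns if c in rotifer_orders]
    cru_cols = [c for c in zoo_orders.columns if c in crustacean_orders]
    rot = zoo_orders[rot_cols].sum(axis=1) if rot_cols else pd.Series(0.0, index=sites)
    cru = zoo_orders[cru_cols].sum(axis=1) if cru_cols else pd.Series(0.0, index=sites)

    defined = phyto_total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, zoo_total / phyto_total, np.nan)
        cru_ratio = np.where(defined, cru / phyto_total, np.nan)
        rot_ratio = np.where(defined, rot / phyto_total, np.nan)
    return pd.DataFrame({
        "site_id": sites,
        "zoo_biomass": zoo_total.to_numpy(),
        "phyto_biomass": phyto_total.to_numpy(),
        "zp_ratio": ratio,
        "crustacean_zp_ratio": cru_ratio,
        "rotifer_zp_ratio": rot_ratio,
        "ratio_defined": defined.to_numpy(),
    }).reset_index(drop=True)
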