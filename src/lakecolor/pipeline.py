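"""End-to-end orchestration of the survey analysis.

:func:`run_full_analysis` chains every stage — reading and filtering the
two survey tables, classification, design-based estimation and change
analysis, pairing and change vectors with circular statistics, plankton
community processing, and the class-comparison statistics — writing all
outputs (CSV + JSON) to a directory along with a manifest recording input
hashes, parameters, seeds and output-file hashes. Given the same inputs
and master seed, a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import lakecolor.circular as circular
import lakecolor.classification as classify
import lakecolor.community as community
import lakecolor.groupstats as groupstats
import lakecolor.lake_io as lake_io
import lakecolor.survey as survey

logger = logging.getLogger(__name__)

_SEED_NAMES = ("bootstrap", "rao", "permanova_biomass", "nmds", "dunn")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    survey1_path: str
    survey2_path: str
    output_dir: str
    taxa_path: str | None = None
    dialect1: str = "generic"
    dialect2: str = "generic"
    tp_threshold: float = 30.0
    color_threshold: float = 20.0
    neighborhood_size: int = 4
    n_boot: int = 999
    rao_mc: int = 10000
    n_perm: int = 999
    nmds_k: int = 2
    nmds_restarts: int = 20
    alpha: float = 0.05
    n_tests: int = 14
    rose_bins: int = 16
    #: Ordination/PERMANOVA run on at most this many sites (seeded
    #: subsample) to keep the O(n²) distance stages tractable.
    max_ordination_sites: int = 200
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from a YAML or JSON file."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def derive_seeds(master_seed: int, names=_SEED_NAMES) -> dict[str, int]:
    """Independent named integer seeds derived from one master seed."""
    rng = np.random.default_rng(master_seed)
    return {name: int(rng.integers(0, 2 ** 31 - 1)) for name in names}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, index=index, lineterminator="\n")


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every pipeline stage; return the manifest dict.

    Any stage failure propagates with the stage name prepended to the
    error message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    inputs = {}
    outputs: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        s1, rej1 = lake_io.read_survey_table(config.survey1_path, config.dialect1)
        s2, rej2 = lake_io.read_survey_table(config.survey2_path, config.dialect2)
        for p in (config.survey1_path, config.survey2_path):
            inputs[str(p)] = _sha256(Path(p))
        s1, removed1 = lake_io.apply_detection_filter(s1)
        s2, removed2 = lake_io.apply_detection_filter(s2)
        _write_csv(rej1, out / "rejected_t1.csv")
        _write_csv(rej2, out / "rejected_t2.csv")
        outputs += [out / "rejected_t1.csv", out / "rejected_t2.csv"]

        stage = "classify"
        for df in (s1, s2):
            df["lake_class"] = classify.classify(
                df["tp"], df["color"], config.tp_threshold, config.color_threshold)
        for df, name in ((s1, "classified_t1.csv"), (s2, "classified_t2.csv")):
            thr = classify.extreme_thresholds(df)
            df["extreme"] = classify.flag_extreme(df, thr)
            _write_csv(df, out / name)
            outputs.append(out / name)

        stage = "estimate"
        scope_col = "ecoregion" if s1["ecoregion"].nunique() > 1 else None
        est1 = survey.category_estimates(s1, scope_col,
                                         neighborhood_size=config.neighborhood_size)
        est2 = survey.category_estimates(s2, scope_col,
                                         neighborhood_size=config.neighborhood_size)
        change = survey.change_analysis(est1, est2)
        for df, name in ((est1, "estimates_t1.csv"), (est2, "estimates_t2.csv"),
                         (change, "change.csv")):
            _write_csv(df, out / name)
            outputs.append(out / name)

        stage = "vectors"
        pairs, pair_report = lake_io.pair_resampled(s1, s2)
        vectors_summary = {}
        if len(pairs):
            mat = classify.transition_matrix(pairs, config.tp_threshold,
                                             config.color_threshold)
            _write_csv(mat, out / "transition_matrix.csv", index=True)
            _write_json(classify.transition_summary(mat),
                        out / "transition_summary.json")
            outputs += [out / "transition_matrix.csv",
                        out / "transition_summary.json"]
            vec = circular.change_vectors(pairs)
            _write_csv(vec, out / "vectors.csv")
            outputs.append(out / "vectors.csv")
            angles = vec["angle_deg"].dropna()
            if len(angles) >= 10:
                mean = circular.bootstrap_mean_angle_ci(
                    angles, n_boot=config.n_boot, seed=seeds["bootstrap"])
                rao = circular.rao_spacing(angles, n_mc=config.rao_mc,
                                           seed=seeds["rao"])
                anova_mag = circular.vector_group_anova(vec, "magnitude")
                vectors_summary = {
                    "mean_angle_deg": mean.mean_angle_deg,
                    "resultant_length": mean.resultant_length,
                    "ci95_arc": list(mean.ci95_arc),
                    "n_boot": mean.n_boot,
                    "rao_T": rao.T,
                    "rao_p": rao.p_value,
                    "anova_magnitude_F": anova_mag.F,
                    "anova_magnitude_df": anova_mag.df_between,
                    "anova_magnitude_p": anova_mag.p_value,
                    "n_pairs": int(len(pairs)),
                    "seeds": {k: seeds[k] for k in ("bootstrap", "rao")},
                }
                try:
                    anova_ang = circular.vector_group_anova(vec, "angle_deg")
                    vectors_summary.update({
                        "anova_angle_F": anova_ang.F,
                        "anova_angle_p": anova_ang.p_value,
                    })
                except ValueError:
                    pass
                _write_json(vectors_summary, out / "vectors_summary.json")
                _write_csv(circular.rose_bins(angles, config.rose_bins),
                           out / "rose_bins.csv")
                outputs += [out / "vectors_summary.json", out / "rose_bins.csv"]

        stage = "community"
        stats_rows = []
        if config.taxa_path:
            inputs[str(config.taxa_path)] = _sha256(Path(config.taxa_path))
            taxa = lake_io.read_taxon_table(config.taxa_path)
            taxa = community.merge_mesh_duplicates(taxa)
            phyto = taxa.loc[taxa["group"] == "phytoplankton"].copy()
            needs_conv = phyto["biomass"].isna() & phyto["biovolume"].notna()
            phyto.loc[needs_conv, "biomass"] = community.biovolume_to_dry_biomass(
                phyto.loc[needs_conv, "biovolume"])
            taxa = pd.concat([phyto, taxa.loc[taxa["group"] == "zooplankton"]],
                             ignore_index=True)
            zoo_genus = community.filter_rare_two_stage(taxa, "zooplankton")
            phyto_genus = community.filter_rare_two_stage(taxa, "phytoplankton")
            zoo_order = community.aggregate_rank(zoo_genus)
            ratios = community.zp_ratios(zoo_genus, phyto_genus)
            for df, name in ((zoo_genus, "zoo_genus_matrix.csv"),
                             (zoo_order, "zoo_order_matrix.csv"),
                             (phyto_genus, "phyto_genus_matrix.csv"),
                             (ratios, "zp_ratios.csv")):
                _write_csv(df, out / name, index=name != "zp_ratios.csv")
                outputs.append(out / name)

            stage = "stats"
            # class comparisons on the survey carrying the plankton data
            classes = s2.set_index("site_id")["lake_class"]
            common = zoo_genus.index.intersection(classes.index)
            if len(common) >= 8 and classes.loc[common].nunique() >= 2:
                labels = classes.loc[common]
                zoo_tot = zoo_genus.loc[common].sum(axis=1)
                groups = {c: zoo_tot[labels == c].to_numpy()
                          for c in labels.unique()}
                kw = groupstats.kruskal_wallis(groups)
                stats_rows.append({"test": kw.test, "response": "zoo_biomass",
                                   "statistic": kw.statistic, "df": kw.df,
                                   "p_value": kw.p_value})
                for r in groupstats.dunn_posthoc(groups):
                    stats_rows.append({"test": r.test, "response": "zoo_biomass",
                                       "statistic": r.statistic, "df": None,
                                       "p_value": r.p_value,
                                       "adjusted_p": r.adjusted_p,
                                       "comparison": "-".join(r.groups)})
                counts = labels.value_counts()
                usable = counts[counts >= 2].index
                mask = labels.isin(usable)
                if mask.sum() > config.max_ordination_sites:
                    rng = np.random.default_rng(seeds["nmds"])
                    keep = rng.choice(np.flatnonzero(mask.to_numpy()),
                                      size=config.max_ordination_sites,
                                      replace=False)
                    sub_mask = np.zeros(len(mask), dtype=bool)
                    sub_mask[keep] = True
                    mask = pd.Series(sub_mask, index=mask.index)
                    usable = labels[mask].value_counts()
                    usable = usable[usable >= 2].index
                    mask &= labels.isin(usable)
                if usable.size >= 2:
                    dist = groupstats.bray_curtis(zoo_genus.loc[common][mask])
                    perm = groupstats.permanova(dist, labels[mask],
                                                n_perm=config.n_perm,
                                                seed=seeds["permanova_biomass"])
                    _write_json(dataclasses.asdict(perm), out / "permanova.json")
                    ord_res = groupstats.nmds(dist, k=config.nmds_k,
                                              n_restarts=config.nmds_restarts,
                                              seed=seeds["nmds"])
                    coords = ord_res.coordinates.copy()
                    coords["lake_class"] = labels[mask]
                    _write_csv(coords, out / "nmds_coords.csv", index=True)
                    _write_json({"stress": ord_res.stress,
                                 "converged": ord_res.converged,
                                 "n_restarts": ord_res.n_restarts,
                                 "seed": ord_res.seed},
                                out / "nmds_summary.json")
                    outputs += [out / "permanova.json", out / "nmds_coords.csv",
                                out / "nmds_summary.json"]
        if stats_rows:
            _write_csv(pd.DataFrame(stats_rows), out / "group_tests.csv")
            outputs.append(out / "group_tests.csv")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "adjusted_alpha": groupstats.bonferroni_alpha(config.alpha, config.n_tests),
        "detection_removed": {"t1": removed1, "t2": removed2},
        "pairing": {k: len(v) for k, v in pair_report.items()},
        "inputs": inputs,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
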