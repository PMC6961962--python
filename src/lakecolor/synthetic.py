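"""Synthetic lake-survey and plankton-community generator.

Emulates the statistical structure the analysis pipeline assumes so every
stage can be tested against known truth:

* a stratified population (nine ecoregions) with per-stratum inclusion
  probabilities and design weights (population / sample size),
* per-class TP and color drawn from lognormals calibrated to the published
  per-class quartiles, truncated to the class region so the classifier
  recovers the intended class,
* paired-year drift: additive displacement in (ΔTP, Δcolor) space with a
  von Mises direction (default mean 32.68°, the published national mean
  direction of change) and lognormal magnitude, floored at zero,
* per-class plankton communities: Dirichlet order compositions around
  class means (murky lakes with roughly double the rotifer share of blue
  lakes), total biomass scaled by class, genera split within orders, and
  a subset of zooplankton taxa duplicated across the two net meshes.

All draws are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lakecolor import nla
from lakecolor.classification import CLASSES, classify
from lakecolor.community import DRY_FRACTION, ML_PER_L, UG_PER_UM3

#: Q3/Q1 spans 2 × 0.6745 standard normal quantiles on the log scale.
_IQR_Z = 1.3489795003921634


def _lognormal_params(q1: float, median: float, q3: float):
    """(mu, sigma) of a lognormal matched to the median and quartile ratio."""
    return np.log(median), np.log(q3 / q1) / _IQR_Z


_DEFAULT_TP_COLOR = {
    cls: {axis: _lognormal_params(*nla.CLASS_QUARTILES[cls][axis])
          for axis in ("tp", "color")}
    for cls in CLASSES
}

_ZOO_COMPOSITION = {
    "blue": {"Ploima": 0.08, "Flosculariaceae": 0.02, "Diplostraca": 0.50,
             "Calanoida": 0.21, "Cyclopoida": 0.19},
    "green": {"Ploima": 0.12, "Flosculariaceae": 0.03, "Diplostraca": 0.60,
              "Calanoida": 0.13, "Cyclopoida": 0.12},
    "brown": {"Ploima": 0.10, "Flosculariaceae": 0.02, "Diplostraca": 0.52,
              "Calanoida": 0.19, "Cyclopoida": 0.17},
    "murky": {"Ploima": 0.16, "Flosculariaceae": 0.04, "Diplostraca": 0.55,
              "Calanoida": 0.13, "Cyclopoida": 0.12},
}

_PHYTO_COMPOSITION = {
    "blue": {"Chroococcales": 0.15, "Nostocales": 0.05, "Chlorellales": 0.25,
             "Fragilariales": 0.40, "Peridiniales": 0.15},
    "green": {"Chroococcales": 0.30, "Nostocales": 0.20, "Chlorellales": 0.25,
              "Fragilariales": 0.15, "Peridiniales": 0.10},
    "brown": {"Chroococcales": 0.10, "Nostocales": 0.05, "Chlorellales": 0.20,
              "Fragilariales": 0.45, "Peridiniales": 0.20},
    "murky": {"Chroococcales": 0.35, "Nostocales": 0.20, "Chlorellales": 0.20,
              "Fragilariales": 0.15, "Peridiniales": 0.10},
}

_GENERA = {
    "Ploima": {"Keratella": 0.6, "Brachionus": 0.4},
    "Flosculariaceae": {"Conochilus": 0.7, "Ptygura": 0.3},
    "Diplostraca": {"Daphnia": 0.65, "Bosmina": 0.35},
    "Calanoida": {"Skistodiaptomus": 0.7, "Leptodiaptomus": 0.3},
    "Cyclopoida": {"Mesocyclops": 0.6, "Diacyclops": 0.4},
    "Chroococcales": {"Microcystis": 0.7, "Chroococcus": 0.3},
    "Nostocales": {"Dolichospermum": 0.8, "Aphanizomenon": 0.2},
    "Chlorellales": {"Chlorella": 0.6, "Closteriopsis": 0.4},
    "Fragilariales": {"Fragilaria": 0.5, "Synedra": 0.5},
    "Peridiniales": {"Peridinium": 0.8, "Parvodinium": 0.2},
}

#: Zooplankton genera recorded in both net meshes (small-bodied taxa caught
#: by the fine net but also retained by the coarse one).
_MESH_DUPLICATED = frozenset({"Keratella", "Brachionus", "Bosmina"})


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey generator.

    Defaults reproduce the study conditions: nine ecoregion strata with
    ~115 sampled lakes each (≈1030 per survey), the 2007 national class
    mixture, TP/color lognormals matched to the published per-class
    quartiles, drift direction 32.68° with concentration κ = 2, and a
    revisit fraction of 0.39 (≈ 401 of 1028 lakes).
    """

    seed: int | None = None
    #: (ecoregion, population size, sample size) per stratum.
    strata: tuple = tuple((eco, 2000, 115) for eco in nla.ECOREGIONS)
    #: Probabilities over (blue, green, brown, murky); a single tuple for
    #: all strata or an ecoregion→tuple mapping.
    class_mixture: tuple | dict = (0.457, 0.208, 0.100, 0.235)
    #: per-class {"tp": (mu, sigma), "color": (mu, sigma)} on the log scale.
    tp_color_model: dict = field(default_factory=lambda: _DEFAULT_TP_COLOR)
    #: drift: mean direction (deg CCW from +ΔTP), von Mises concentration,
    #: lognormal magnitude (mu, sigma) in mixed native units.
    drift_theta0_deg: float = nla.RESAMPLED_MEAN_ANGLE_DEG
    drift_kappa: float = 2.0
    drift_magnitude: tuple = (np.log(15.0), 1.0)
    revisit_fraction: float = 0.39
    #: Dirichlet concentration scaling the order compositions; 0 disables
    #: overdispersion (sites equal class means).
    community_overdispersion: float = 25.0
    zoo_biomass_medians: dict = field(
        default_factory=lambda: dict(nla.CLASS_BIOMASS_MEDIANS["zooplankton"]))
    phyto_biomass_medians: dict = field(
        default_factory=lambda: dict(nla.CLASS_BIOMASS_MEDIANS["phytoplankton"]))
    biomass_sigma: float = 0.9  # lognormal spread of per-site total biomass
    detection_limit: float = 3.9  # µg/L TP

    def mixture_for(self, ecoregion: str) -> np.ndarray:
        mix = (self.class_mixture.get(ecoregion)
               if isinstance(self.class_mixture, dict) else self.class_mixture)
        p = np.asarray(mix, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"class mixture for {ecoregion!r} must be 4 "
                             "probabilities summing to 1")
        return p


def _truncated_class_draw(rng, cls: str, n: int, model: dict,
                          tp_threshold: float = 30.0,
                          color_threshold: float = 20.0):
    """Draw (tp, color) from the class lognormals, rejected into the class box."""
    mu_tp, sg_tp = model[cls]["tp"]
    mu_co, sg_co = model[cls]["color"]
    tp = np.empty(n)
    color = np.empty(n)
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            break
        t = rng.lognormal(mu_tp, sg_tp, size=2 * need + 16)
        c = rng.lognormal(mu_co, sg_co, size=2 * need + 16)
        ok_tp = t > tp_threshold if cls in ("green", "murky") else t <= tp_threshold
        ok_co = c > color_threshold if cls in ("brown", "murky") else c <= color_threshold
        ok = np.flatnonzero(ok_tp & ok_co)[:need]
        take = len(ok)
        tp[filled:filled + take] = t[ok]
        color[filled:filled + take] = c[ok]
        filled += take
    if filled < n:
        raise ValueError(f"class {cls!r} lognormals are incompatible with the "
                         "class thresholds (rejection sampling starved)")
    return tp, color


def generate_population(config: SyntheticConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Generate the full stratified lake population with true classes.

    Each stratum occupies its own longitude band (a crude spatial layout;
    coordinates are uniform within the stratum box). Inclusion probability
    is sample size / population size per stratum.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for s_idx, (eco, n_pop, n_sample) in enumerate(config.strata):
        mix = config.mixture_for(eco)
        counts = rng.multinomial(n_pop, mix)
        tp = np.empty(n_pop)
        color = np.empty(n_pop)
        cls_labels = np.empty(n_pop, dtype=object)
        pos = 0
        for cls, cnt in zip(CLASSES, counts):
            if cnt == 0:
                continue
            t, c = _truncated_class_draw(rng, cls, cnt, config.tp_color_model)
            tp[pos:pos + cnt] = t
            color[pos:pos + cnt] = c
            cls_labels[pos:pos + cnt] = cls
            pos += cnt
        lon0 = -125.0 + s_idx * 6.0
        frames.append(pd.DataFrame({
            "site_id": [f"{eco[:3].upper()}{s_idx}_{i:05d}" for i in range(n_pop)],
            "ecoregion": eco,
            "lat": rng.uniform(30.0, 48.0, n_pop),
            "lon": rng.uniform(lon0, lon0 + 6.0, n_pop),
            "tp": tp,
            "color": color,
            "true_class": cls_labels,
            "area_ha": rng.lognormal(np.log(40.0), 1.2, n_pop) + 4.0,
            "incl_prob": n_sample / n_pop,
            "weight": n_pop / n_sample,
        }))
    pop = pd.concat(frames, ignore_index=True)
    pop["tp_below_detection"] = pop["tp"] < config.detection_limit
    return pop


def true_proportions(population: pd.DataFrame) -> dict[str, float]:
    """True population class proportions, percent."""
    counts = population["true_class"].value_counts()
    total = len(population)
    return {cls: 100.0 * counts.get(cls, 0) / total for cls in CLASSES}


def sample_survey(population: pd.DataFrame, config: SyntheticConfig,
                  seed: int | None = None, year: int = 2007) -> pd.DataFrame:
    """Draw the stratified random sample, attaching design weights."""
    rng = np.random.default_rng(seed)
    picks = []
    for eco, n_pop, n_sample in config.strata:
        idx = population.index[population["ecoregion"] == eco]
        picks.append(rng.choice(idx, size=n_sample, replace=False))
    sample = population.loc[np.concatenate(picks)].copy()
    sample["year"] = year
    return sample.reset_index(drop=True)


def apply_drift(population: pd.DataFrame, config: SyntheticConfig,
                seed: int | None = None, year2: int = 2012) -> pd.DataFrame:
    """Drift every lake to its year-2 state.

    Each lake moves by magnitude·(cos θ, sin θ) in (TP, color) space with
    θ ~ von Mises(θ₀, κ) and lognormal magnitude, floored at zero so TP
    and color stay non-negative. Site ids are kept (it is the same lake);
    class labels are re-derived from the year-2 values, never carried
    over. κ = ∞ puts every vector exactly at θ₀; κ = 0 is uniform.
    """
    rng = np.random.default_rng(seed)
    n = len(population)
    theta0 = np.radians(config.drift_theta0_deg)
    if np.isinf(config.drift_kappa):
        theta = np.full(n, theta0)
    elif config.drift_kappa == 0:
        theta = rng.uniform(0.0, 2 * np.pi, n)
    else:
        theta = rng.vonmises(theta0, config.drift_kappa, n)
    mu_mag, sg_mag = config.drift_magnitude
    # mu = -inf encodes zero displacement (degenerate lognormal)
    mag = (np.zeros(n) if not np.isfinite(mu_mag)
           else rng.lognormal(mu_mag, sg_mag, size=n))
    out = population.copy()
    out["tp"] = np.maximum(population["tp"].to_numpy() + mag * np.cos(theta), 0.0)
    out["color"] = np.maximum(population["color"].to_numpy() + mag * np.sin(theta), 0.0)
    out["year"] = year2
    out["tp_below_detection"] = out["tp"] < config.detection_limit
    out["true_class"] = classify(out["tp"], out["color"])
    return out


def sample_revisit_survey(population2: pd.DataFrame, survey1: pd.DataFrame,
                          config: SyntheticConfig, seed: int | None = None,
                          year: int = 2012) -> pd.DataFrame:
    """Draw the year-2 sample with deliberate revisits.

    Per stratum, ``revisit_fraction`` of the year-2 sample is taken from
    the year-1 sampled sites (same site_id, drifted values); the rest are
    fresh draws from the remaining year-2 population, so the paired
    subset has size ≈ revisit_fraction × n_sample. A ``resampled``
    column marks the revisits.
    """
    rng = np.random.default_rng(seed)
    pop_by_id = population2.set_index("site_id")
    picks = []
    for eco, n_pop, n_sample in config.strata:
        s1_ids = survey1.loc[survey1["ecoregion"] == eco, "site_id"].to_numpy()
        n_revisit = min(int(round(config.revisit_fraction * n_sample)), len(s1_ids))
        revisit_ids = rng.choice(s1_ids, size=n_revisit, replace=False)
        fresh_pool = pop_by_id.index[
            (pop_by_id["ecoregion"] == eco) & ~pop_by_id.index.isin(s1_ids)]
        fresh_ids = rng.choice(fresh_pool, size=n_sample - n_revisit,
                               replace=False)
        sub = pop_by_id.loc[np.concatenate([revisit_ids, fresh_ids])].reset_index()
        sub["resampled"] = np.concatenate(
            [np.ones(n_revisit, bool), np.zeros(n_sample - n_revisit, bool)])
        picks.append(sub)
    sample = pd.concat(picks, ignore_index=True)
    sample["year"] = year
    return sample


def generate_communities(survey: pd.DataFrame, config: SyntheticConfig,
                         seed: int | None = None,
                         class_col: str = "true_class") -> pd.DataFrame:
    """Generate a plankton count table for classified survey sites.

    Per site: total zooplankton and phytoplankton biomass are lognormal
    around the class medians; order compositions are Dirichlet around the
    class means (exactly the means when overdispersion is 0); genera split
    each order by fixed fractions. Phytoplankton records carry the
    biovolume consistent with their biomass under the standard conversion;
    a fixed set of small-bodied zooplankton genera is recorded in both net
    meshes with identical values.
    """
    rng = np.random.default_rng(seed)
    records = []
    biomass_to_biovolume = 1.0 / (UG_PER_UM3 * ML_PER_L * DRY_FRACTION)

    def site_composition(class_comp: dict[str, float]) -> np.ndarray:
        means = np.array(list(class_comp.values()))
        if not np.isclose(means.sum(), 1.0):
            raise ValueError("order composition must sum to 1")
        if config.community_overdispersion <= 0:
            return means
        return rng.dirichlet(means * config.community_overdispersion)

    for _, row in survey.iterrows():
        cls = row[class_col]
        site = row["site_id"]
        for group, comp_table, medians in (
            ("zooplankton", _ZOO_COMPOSITION, config.zoo_biomass_medians),
            ("phytoplankton", _PHYTO_COMPOSITION, config.phyto_biomass_medians),
        ):
            total = rng.lognormal(np.log(medians[cls]), config.biomass_sigma)
            comp = site_composition(comp_table[cls])
            for order, share in zip(comp_table[cls], comp):
                for genus, gfrac in _GENERA[order].items():
                    biomass = total * share * gfrac
                    if biomass <= 0:
                        continue
                    density = biomass * 0.5  # per mL, nominal body size
                    biovolume = (biomass * biomass_to_biovolume
                                 if group == "phytoplankton" else np.nan)
                    meshes = (("fine", "coarse")
                              if group == "zooplankton" and genus in _MESH_DUPLICATED
                              else (("fine",) if group == "zooplankton"
                                    else ("none",)))
                    for mesh in meshes:
                        records.append((site, group, order, genus,
                                        f"{order}:{genus}", mesh, density,
                                        biovolume, biomass))
    return pd.DataFrame(records, columns=[
        "site_id", "group", "order_name", "genus_name", "taxon_id", "mesh",
        "density", "biovolume", "biomass"])
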