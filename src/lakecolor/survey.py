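"""Design-based estimation of lake-class proportions and their change.

The survey is a stratified random sample with known design weights
(lakes represented per sampled lake, the inverse inclusion probability).
Class proportions are estimated with the weighted Horvitz–Thompson ratio

    P̂_c = Σ w_i 1[class_i = c] / Σ w_i,

and their variance with a local-neighborhood estimator that exploits the
spatial balance of the design: each site's weighted residual is compared
with a weighted mean over its nearest neighbors, so spatially structured
populations yield smaller variances than the simple-random-sampling (SRS)
formula. Change between two surveys is the difference of the per-survey
estimates, treated as independent, with normal-approximation 95% CIs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from lakecolor.classification import CLASSES

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal-approximation multiplier for 95% CIs


def ht_proportion(samples: pd.DataFrame, category: str,
                  class_col: str = "lake_class") -> float:
    """Horvitz–Thompson estimate of a class proportion, in percent.

    Invariant to uniform rescaling of all weights.
    """
    w = samples["weight"].to_numpy(float)
    if len(w) == 0:
        raise ValueError("empty sample")
    if np.any(w <= 0):
        raise ValueError("all design weights must be > 0")
    total = w.sum()
    ind = (samples[class_col] == category).to_numpy()
    return 100.0 * float(w[ind].sum() / total)


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between sites."""
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2) ** 2
    return 2.0 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _srs_variance(w: np.ndarray, z: np.ndarray) -> float:
    """Weighted SRS-style variance of the ratio estimator (proportion scale)."""
    n = len(w)
    total = w.sum()
    p = float((w * z).sum() / total)
    if n < 2:
        return 0.0
    resid = w * (z - p) / total
    return float(n / (n - 1) * np.sum(resid ** 2))


def local_mean_variance(indicator, weights, lat=None, lon=None,
                        neighborhood_size: int = 4) -> float:
    """Local-neighborhood variance of the HT proportion estimator.

    Parameters
    ----------
    indicator : array-like of {0, 1}
        Class membership per site.
    weights : array-like
        Design weights, > 0.
    lat, lon : array-like, optional
        Site coordinates (decimal degrees). When absent (or when fewer than
        ``neighborhood_size + 1`` sites are available) the estimator falls
        back to the weighted SRS ratio variance, with a warning.
    neighborhood_size : int
        Number of sites per neighborhood, the site itself included.

    Returns
    -------
    float
        Non-negative variance of P̂_c on the proportion (0–1) scale.

    Notes
    -----
    Each site's neighborhood is itself plus its nearest sites by
    great-circle distance. Neighborhood weights are proportional to the
    inverse distance rank (1, 1/2, 1/3, …), normalized to sum to one, in a
    single pass (no iterative row/column balancing). The squared deviations
    of weighted residuals from the neighborhood mean are divided by
    (1 − Σ a_j²) per neighborhood so that, for spatially unstructured
    residuals, the estimator is approximately unbiased for the SRS
    variance; spatially clustered residuals deflate it.
    """
    z = np.asarray(indicator, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(z)
    if n == 0:
        raise ValueError("empty sample")
    if np.any(w <= 0):
        raise ValueError("all design weights must be > 0")
    have_coords = (
        lat is not None and lon is not None
        and np.all(np.isfinite(np.asarray(lat, float)))
        and np.all(np.isfinite(np.asarray(lon, float)))
    )
    if not have_coords or n < neighborhood_size + 1:
        if n >= neighborhood_size + 1:
            warnings.warn("coordinates absent; falling back to SRS variance",
                          stacklevel=2)
        return _srs_variance(w, z)

    total = w.sum()
    p = float((w * z).sum() / total)
    e = w * (z - p) / total  # weighted residuals; Σe = 0

    dist = _haversine_matrix(np.asarray(lat, float), np.asarray(lon, float))
    np.fill_diagonal(dist, -1.0)  # self first in the ordering
    order = np.argsort(dist, axis=1, kind="stable")[:, :neighborhood_size]
    a = 1.0 / np.arange(1, neighborhood_size + 1)
    a = a / a.sum()
    correction = 1.0 - np.sum(a ** 2)

    e_nb = e[order]  # (n, k) residuals of each neighborhood
    local_mean = e_nb @ a
    dev2 = (e_nb - local_mean[:, None]) ** 2
    var = float(np.sum(dev2 @ a) / correction)
    return max(var, 0.0)


def category_estimates(samples: pd.DataFrame, scope_col: str | None = None,
                       class_col: str = "lake_class",
                       neighborhood_size: int = 4) -> pd.DataFrame:
    """Design-based class-proportion estimates per scope.

    One row per scope × category with the HT proportion (percent), its
    standard error from the local-mean variance estimator, and a 95%
    normal-approximation CI truncated to [0, 100]. A ``national`` row over
    all samples is always included; per-stratum rows are added when
    ``scope_col`` is given. Empty scopes are omitted with a warning.
    """
    scopes: list[tuple[str, pd.DataFrame]] = [("national", samples)]
    if scope_col is not None:
        for name, grp in samples.groupby(scope_col, sort=True):
            if len(grp) == 0:
                warnings.warn(f"scope {name!r} has no samples; omitted",
                              stacklevel=2)
                continue
            scopes.append((str(name), grp))

    rows = []
    for scope, grp in scopes:
        w = grp["weight"].to_numpy(float)
        lat = grp["lat"].to_numpy(float) if "lat" in grp.columns else None
        lon = grp["lon"].to_numpy(float) if "lon" in grp.columns else None
        for category in CLASSES:
            prop = ht_proportion(grp, category, class_col)
            z = (grp[class_col] == category).to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                var = local_mean_variance(z, w, lat, lon, neighborhood_size)
            se = 100.0 * float(np.sqrt(var))
            lo = max(prop - Z95 * se, 0.0)
            hi = min(prop + Z95 * se, 100.0)
            rows.append({"scope": scope, "category": category,
                         "proportion": prop, "se": se,
                         "ci95_low": lo, "ci95_high": hi, "n": len(grp)})
    return pd.DataFrame(rows)


def change_analysis(estimates_t1: pd.DataFrame,
                    estimates_t2: pd.DataFrame) -> pd.DataFrame:
    """Between-survey change in class proportions, scope × category.

    delta = P̂₂ − P̂₁ (percentage points); se_delta = √(se₁² + se₂²)
    treating the two surveys as independent; the change is flagged
    significant when the 95% CI excludes zero.

    Raises
    ------
    KeyError
        If the two estimate tables do not share identical
        (scope, category) keys; the message lists the offenders.
    """
    k1 = set(map(tuple, estimates_t1[["scope", "category"]].itertuples(index=False)))
    k2 = set(map(tuple, estimates_t2[["scope", "category"]].itertuples(index=False)))
    if k1 != k2:
        raise KeyError(f"scope/category keys differ: only_t1={sorted(k1 - k2)}, "
                       f"only_t2={sorted(k2 - k1)}")
    merged = estimates_t1.merge(estimates_t2, on=["scope", "category"],
                                suffixes=("_t1", "_t2"))
    delta = merged["proportion_t2"] - merged["proportion_t1"]
    se = np.sqrt(merged["se_t1"] ** 2 + merged["se_t2"] ** 2)
    lo = delta - Z95 * se
    hi = delta + Z95 * se
    out = merged[["scope", "category"]].copy()
    out["delta"] = delta
    out["se_delta"] = se
    out["ci95_low"] = lo
    out["ci95_high"] = hi
    out["significant"] = (lo > 0) | (hi < 0)
    return out
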