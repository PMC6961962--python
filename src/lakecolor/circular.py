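"""Per-lake change vectors in (TP, color) space and circular statistics.

Each lake sampled in both surveys defines a displacement vector
(ΔTP, Δcolor) = (tp₂ − tp₁, color₂ − color₁). Its direction angle is
measured counterclockwise from the +ΔTP axis (TP on the x-axis, color on
the y-axis), so 45° means equal increases in TP and color, 0° a pure TP
increase, and 90° a pure color increase. Magnitudes mix µg/L and PCU in
native units; no standardization is applied by default.

The direction distribution is summarized by the circular mean with a
bootstrap percentile confidence arc, and tested for non-uniformity with
the Rao spacing test (Monte-Carlo p-value). Angle and magnitude are also
compared across origin classes with one-way ANOVAs (angles treated
linearly, a deliberate simplification documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lakecolor.classification import classify


def _wrap360(angle):
    """Map angles to [0, 360), guarding the float edge case 360.0."""
    a = np.mod(angle, 360.0)
    return np.where(a >= 360.0, 0.0, a)


def change_vectors(pairs: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Compute per-lake change vectors from a paired table.

    Parameters
    ----------
    pairs : DataFrame
        Output of :func:`lakecolor.pair_resampled`: columns ``site_id``,
        ``tp_t1``, ``color_t1``, ``tp_t2``, ``color_t2``.
    standardize : bool
        If True, z-scale ΔTP and Δcolor before computing magnitude and
        angle (off by default; the native-unit mix is intentional).

    Returns
    -------
    DataFrame
        site_id, delta_tp, delta_color, magnitude, angle_deg (NaN for
        zero-length vectors, which are excluded from circular statistics
        but keep magnitude 0), origin_class, dest_class.
    """
    dtp = (pairs["tp_t2"] - pairs["tp_t1"]).to_numpy(float)
    dcol = (pairs["color_t2"] - pairs["color_t1"]).to_numpy(float)
    x, y = dtp, dcol
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    mag = np.hypot(x, y)
    angle = np.asarray(_wrap360(np.degrees(np.arctan2(y, x))), dtype=float)
    angle[mag == 0] = np.nan
    return pd.DataFrame({
        "site_id": pairs["site_id"].to_numpy(),
        "delta_tp": dtp,
        "delta_color": dcol,
        "magnitude": mag,
        "angle_deg": angle,
        "origin_class": classify(pairs["tp_t1"], pairs["color_t1"]),
        "dest_class": classify(pairs["tp_t2"], pairs["color_t2"]),
    })


@dataclass(frozen=True)
class CircularMeanResult:
    """Circular mean direction with optional bootstrap confidence arc."""

    mean_angle_deg: float
    resultant_length: float  # mean resultant length R̄ in [0, 1]
    n: int
    ci95_arc: tuple[float, float] | None = None
    n_boot: int | None = None
    seed: int | None = None
    stable: bool = True  # False when R̄ ≈ 0 (mean direction ill-defined)


def _mean_angle(angles_rad: np.ndarray, axis=None):
    c = np.cos(angles_rad).mean(axis=axis)
    s = np.sin(angles_rad).mean(axis=axis)
    return _wrap360(np.degrees(np.arctan2(s, c))), np.hypot(c, s)


def circular_mean(angles_deg, unstable_tol: float = 1e-9) -> CircularMeanResult:
    """Mean direction of a sample of angles (degrees).

    The mean is the direction of the vector sum of unit vectors. When the
    mean resultant length is ~0 the direction is ill-defined and the
    result is flagged ``stable=False``.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if len(a) == 0:
        raise ValueError("no defined angles")
    mean_deg, rbar = _mean_angle(a)
    return CircularMeanResult(float(mean_deg), float(rbar), len(a),
                              stable=rbar > unstable_tol)


def _signed_diff(angles_deg, reference_deg):
    """Angular difference mapped to (−180, 180]."""
    return (np.asarray(angles_deg) - reference_deg + 180.0) % 360.0 - 180.0


def bootstrap_mean_angle_ci(angles_deg, n_boot: int = 999,
                            seed: int | None = None) -> CircularMeanResult:
    """Percentile bootstrap confidence arc for the circular mean.

    Resamples the angles with replacement ``n_boot`` times, computes each
    resample's circular mean, and takes the 2.5/97.5 percentile arc of the
    bootstrap means *around the point estimate* — so the reported arc
    always contains it.

    Requires at least 10 defined angles and a stable mean direction.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < 10:
        raise ValueError("need >= 10 defined angles for a bootstrap arc")
    point = circular_mean(a)
    if not point.stable:
        raise ValueError("mean direction unstable (resultant length ~ 0)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(a), size=(n_boot, len(a)))
    boot_means, _ = _mean_angle(np.radians(a[idx]), axis=1)
    dev = _signed_diff(boot_means, point.mean_angle_deg)
    lo, hi = np.percentile(dev, [2.5, 97.5])
    arc = ((point.mean_angle_deg + lo) % 360.0, (point.mean_angle_deg + hi) % 360.0)
    return CircularMeanResult(point.mean_angle_deg, point.resultant_length,
                              point.n, ci95_arc=arc, n_boot=n_boot, seed=seed,
                              stable=True)


@dataclass(frozen=True)
class RaoResult:
    """Rao spacing test of circular uniformity."""

    T: float  # spacing statistic, degrees; 0 ≤ T ≤ 360 − 360/n
    n: int
    lam: float  # expected spacing 360/n
    p_value: float
    n_mc: int
    seed: int | None


def rao_statistic(angles_deg) -> float:
    """Rao spacing statistic T = ½ Σ |spacing_i − 360/n| (degrees).

    Spacings are the gaps between successive sorted angles including the
    wrap-around gap. T = 0 iff the angles are exactly equally spaced; the
    maximum, attained when all angles coincide, is 360 − 360/n.
    """
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 angles")
    gaps = np.diff(a, append=a[0] + 360.0)
    lam = 360.0 / n
    return float(0.5 * np.sum(np.abs(gaps - lam)))


def rao_null_statistics(n: int, n_mc: int = 10000,
                        seed: int | None = None) -> np.ndarray:
    """Monte-Carlo null distribution of the Rao statistic at sample size n."""
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.uniform(0.0, 360.0, size=(n_mc, n)), axis=1)
    gaps = np.diff(sims, axis=1)
    wrap = (sims[:, 0] + 360.0 - sims[:, -1])[:, None]
    gaps = np.concatenate([gaps, wrap], axis=1)
    lam = 360.0 / n
    return 0.5 * np.sum(np.abs(gaps - lam), axis=1)


def rao_spacing(angles_deg, n_mc: int = 10000,
                seed: int | None = None) -> RaoResult:
    """Rao spacing test for non-uniformity of directions.

    The p-value is the Monte-Carlo tail probability
    (1 + #{null T ≥ observed T}) / (n_mc + 1) under uniform resampling of
    n angles, seeded for reproducibility. Requires n ≥ 4.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    n = len(a)
    if n < 4:
        raise ValueError("need >= 4 defined angles")
    T = rao_statistic(a)
    null = rao_null_statistics(n, n_mc=n_mc, seed=seed)
    p = (1.0 + np.sum(null >= T)) / (n_mc + 1.0)
    return RaoResult(T=T, n=n, lam=360.0 / n, p_value=float(p),
                     n_mc=n_mc, seed=seed)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA of a vector attribute across origin classes."""

    response: str
    F: float
    df_between: int
    df_within: int
    p_value: float
    groups: tuple[str, ...]


def vector_group_anova(vectors: pd.DataFrame, response: str = "magnitude",
                       group_col: str = "origin_class") -> AnovaResult:
    """One-way ANOVA of angle or magnitude across origin classes.

    Angles are treated as linear values on [0, 360); zero-change lakes
    (undefined angle) are dropped from angle comparisons but keep
    magnitude 0 in magnitude comparisons. Groups with fewer than 2 values
    are excluded with a warning.
    """
    if response not in ("magnitude", "angle_deg"):
        raise ValueError("response must be 'magnitude' or 'angle_deg'")
    frames = []
    labels = []
    for name, grp in vectors.groupby(group_col, sort=True):
        vals = grp[response].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            import warnings

            warnings.warn(f"group {name!r} has < 2 values; excluded", stacklevel=2)
            continue
        frames.append(vals)
        labels.append(str(name))
    if len(frames) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    F, p = stats.f_oneway(*frames)
    n = sum(len(v) for v in frames)
    return AnovaResult(response=response, F=float(F),
                       df_between=len(frames) - 1, df_within=n - len(frames),
                       p_value=float(p), groups=tuple(labels))


def rose_bins(angles_deg, n_bins: int = 16) -> pd.DataFrame:
    """Bin angles for a rose diagram.

    Bins partition [0°, 360°) evenly starting at 0°; returns bin edges,
    centers and counts (finite angles only).
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    a = a[np.isfinite(a)]
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame({
        "bin_low_deg": edges[:-1],
        "bin_high_deg": edges[1:],
        "bin_center_deg": (edges[:-1] + edges[1:]) / 2.0,
        "count": counts,
    })
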