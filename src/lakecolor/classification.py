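"""Four-way nutrient-color classification of lakes.

Lakes are classified on two axes: trophic state, measured as total
phosphorus (TP, µg/L), and water color, measured as true color (PCU, a
proxy for chromophoric dissolved organic matter). Crossing the two axes at
fixed thresholds (30 µg/L TP, 20 PCU color) yields four classes:

* ``blue``  — oligotrophic: TP ≤ 30 and color ≤ 20
* ``green`` — eutrophic:    TP > 30 and color ≤ 20
* ``brown`` — dystrophic:   TP ≤ 30 and color > 20
* ``murky`` — mixotrophic:  TP > 30 and color > 20

The four rules partition the non-negative (TP, color) plane: every valid
pair maps to exactly one class. Thresholds are inclusive on the blue/brown
side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Class labels in canonical order.
CLASSES = ("blue", "green", "brown", "murky")

#: Default class thresholds.
TP_THRESHOLD = 30.0  # µg/L
COLOR_THRESHOLD = 20.0  # PCU


def classify(tp, color, tp_threshold: float = TP_THRESHOLD,
             color_threshold: float = COLOR_THRESHOLD):
    """Assign nutrient-color class labels from TP and true color.

    Parameters
    ----------
    tp : float or array-like
        Total phosphorus, µg/L. Must be ≥ 0.
    color : float or array-like
        True color, PCU. Must be ≥ 0.
    tp_threshold, color_threshold : float
        Class boundaries; values at or below the threshold fall on the
        blue/brown (low-TP) and blue/green (low-color) side respectively.

    Returns
    -------
    str or ndarray of str
        Class label(s): one of ``blue``, ``green``, ``brown``, ``murky``.
    """
    tp_arr = np.asarray(tp, dtype=float)
    color_arr = np.asarray(color, dtype=float)
    if np.any(np.isnan(tp_arr)) or np.any(np.isnan(color_arr)):
        raise ValueError("tp and color must be non-missing")
    if np.any(tp_arr < 0) or np.any(color_arr < 0):
        raise ValueError("tp and color must be non-negative")
    high_tp = tp_arr > tp_threshold
    high_color = color_arr > color_threshold
    labels = np.where(
        high_tp,
        np.where(high_color, "murky", "green"),
        np.where(high_color, "brown", "blue"),
    )
    if labels.ndim == 0:
        return labels.item()
    return labels


@dataclass(frozen=True)
class ExtremeThresholds:
    """Per-class quartile bounds defining 'extreme' class membership.

    Extreme lakes sit deep inside their class, away from the threshold
    intersection: blue lakes below the class first quartile in both TP and
    color; murky lakes above the third quartile in both; green lakes below
    the color Q1 but above the TP Q3; brown lakes above the color Q3 but
    below the TP Q1. Membership is strict (< or >).
    """

    tp_bound: dict[str, float]
    color_bound: dict[str, float]
    #: "below" (Q1) or "above" (Q3), per class and axis.
    tp_direction: dict[str, str]
    color_direction: dict[str, str]


#: Quartile direction per class: blue deep = low TP/low color, etc.
_EXTREME_RULES = {
    "blue": {"tp": "below", "color": "below"},
    "green": {"tp": "above", "color": "below"},
    "brown": {"tp": "below", "color": "above"},
    "murky": {"tp": "above", "color": "above"},
}


def _quartile(values: np.ndarray, which: str) -> float:
    # linear interpolation between order statistics (numpy default, "type 7")
    q = 0.25 if which == "below" else 0.75
    return float(np.quantile(values, q))


def extreme_thresholds(samples: pd.DataFrame,
                       class_col: str = "lake_class") -> ExtremeThresholds:
    """Compute per-class extreme bounds from classified samples.

    Parameters
    ----------
    samples : DataFrame
        Must carry ``tp``, ``color`` and a class-label column.

    Raises
    ------
    ValueError
        If any class present has fewer than 4 samples.
    """
    tp_bound, color_bound = {}, {}
    tp_dir, color_dir = {}, {}
    for cls, rule in _EXTREME_RULES.items():
        grp = samples.loc[samples[class_col] == cls]
        if len(grp) == 0:
            continue
        if len(grp) < 4:
            raise ValueError(
                f"class {cls!r} has {len(grp)} samples; >= 4 required for quartiles"
            )
        tp_bound[cls] = _quartile(grp["tp"].to_numpy(float), rule["tp"])
        color_bound[cls] = _quartile(grp["color"].to_numpy(float), rule["color"])
        tp_dir[cls] = rule["tp"]
        color_dir[cls] = rule["color"]
    return ExtremeThresholds(tp_bound, color_bound, tp_dir, color_dir)


def flag_extreme(samples: pd.DataFrame, thresholds: ExtremeThresholds,
                 class_col: str = "lake_class") -> pd.Series:
    """Boolean flag: lake is 'extreme' within its class (strict inequality)."""
    flags = pd.Series(False, index=samples.index)
    for cls in thresholds.tp_bound:
        mask = samples[class_col] == cls
        if not mask.any():
            continue
        tp = samples.loc[mask, "tp"]
        color = samples.loc[mask, "color"]
        tp_ok = (tp < thresholds.tp_bound[cls]
                 if thresholds.tp_direction[cls] == "below"
                 else tp > thresholds.tp_bound[cls])
        color_ok = (color < thresholds.color_bound[cls]
                    if thresholds.color_direction[cls] == "below"
                    else color > thresholds.color_bound[cls])
        flags.loc[mask] = (tp_ok & color_ok).to_numpy()
    return flags


def transition_matrix(pairs: pd.DataFrame,
                      tp_threshold: float = TP_THRESHOLD,
                      color_threshold: float = COLOR_THRESHOLD) -> pd.DataFrame:
    """4×4 class-transition counts for lakes sampled in both surveys.

    Parameters
    ----------
    pairs : DataFrame
        Paired table as produced by :func:`lakecolor.pair_resampled`, with
        columns ``tp_t1``, ``color_t1``, ``tp_t2``, ``color_t2``.

    Returns
    -------
    DataFrame
        Counts indexed by origin (year-1) class, columns destination
        (year-2) class, in canonical class order. Row sums equal year-1
        class counts; the grand total equals the number of pairs.
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    origin = classify(pairs["tp_t1"], pairs["color_t1"], tp_threshold, color_threshold)
    dest = classify(pairs["tp_t2"], pairs["color_t2"], tp_threshold, color_threshold)
    mat = pd.crosstab(
        pd.Categorical(origin, categories=CLASSES),
        pd.Categorical(dest, categories=CLASSES),
        dropna=False,
    )
    mat.index = pd.Index(CLASSES, name="origin")
    mat.columns = pd.Index(CLASSES, name="destination")
    return mat


def transition_summary(matrix: pd.DataFrame) -> dict:
    """Summarize a transition matrix.

    Returns
    -------
    dict with keys
        ``fraction_unchanged`` / ``fraction_changed`` (in [0, 1]),
        ``pct_unchanged`` / ``pct_changed`` (percent),
        ``origin_totals`` (per-class year-1 counts),
        ``origin_shifts`` (per-class off-diagonal counts), and
        ``total``.
    """
    mat = matrix.loc[list(CLASSES), list(CLASSES)].to_numpy(float)
    total = mat.sum()
    if total <= 0:
        raise ValueError("transition matrix total must be > 0")
    trace = np.trace(mat)
    unchanged = trace / total
    origin_totals = {c: int(mat[i].sum()) for i, c in enumerate(CLASSES)}
    origin_shifts = {c: int(mat[i].sum() - mat[i, i]) for i, c in enumerate(CLASSES)}
    return {
        "fraction_unchanged": unchanged,
        "fraction_changed": 1.0 - unchanged,
        "pct_unchanged": 100.0 * unchanged,
        "pct_changed": 100.0 * (1.0 - unchanged),
        "origin_totals": origin_totals,
        "origin_shifts": origin_shifts,
        "total": int(total),
    }
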