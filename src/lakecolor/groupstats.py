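"""Nonparametric and multivariate comparisons across lake classes.

Univariate responses (Chl a, cyanobacterial density, biomass, land cover)
are compared across the four nutrient-color classes with the
Kruskal–Wallis rank test (tie-corrected) followed by Dunn's pairwise
post-hoc z tests with Bonferroni adjustment. Community composition is
compared on Bray–Curtis dissimilarities of square-root-transformed
sites × taxa matrices using PERMANOVA (permutation pseudo-F) and
visualized with non-metric multidimensional scaling (NMDS, Kruskal
stress-1 minimized by alternating isotonic regression and Guttman
configuration updates).

These routines are implemented here directly; the test suite cross-checks
them against independent library implementations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression


@dataclass(frozen=True)
class TestResult:
    """A univariate test outcome."""

    test: str
    statistic: float
    df: int | None
    p_value: float
    groups: tuple[str, ...]
    adjusted_p: float | None = None


def _rank_with_ties(pooled: np.ndarray):
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    return ranks, tie_term


def _group_splits(indices: tuple, sizes: tuple):
    """All distinct partitions of ``indices`` into ordered groups of ``sizes``."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in first)
        for tail in _group_splits(rest, sizes[1:]):
            yield (first, *tail)


def _kw_h(arrays: list[np.ndarray]) -> float:
    n = np.array([len(a) for a in arrays])
    N = int(n.sum())
    pooled = np.concatenate(arrays)
    ranks, tie_term = _rank_with_ties(pooled)
    splits = np.split(ranks, np.cumsum(n)[:-1])
    rank_sums = np.array([s.sum() for s in splits])
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums ** 2 / n) - 3.0 * (N + 1)
    correction = 1.0 - tie_term / (N ** 3 - N)
    if correction <= 0:
        return np.nan  # all pooled values identical
    return max(h / correction, 0.0)


def kruskal_wallis(groups: dict[str, np.ndarray] | list,
                   p_method: str = "chi2") -> TestResult:
    """Tie-corrected Kruskal–Wallis H test.

    H = [12/(N(N+1)) · Σ R_j²/n_j − 3(N+1)] / C with the tie correction
    C = 1 − Σ(t³ − t)/(N³ − N); the p-value is the χ² upper tail with
    df = k − 1. When every pooled value is identical, H = 0 and p = 1.

    ``p_method="exact"`` replaces the χ² approximation with full
    enumeration of all assignments of the pooled values to groups
    (feasible only for small samples, total n ≤ 10):
    p = #{assignments with H ≥ H_obs} / #assignments.

    ``groups`` is a label→values mapping or a list of arrays.
    """
    if isinstance(groups, dict):
        labels = tuple(str(k) for k in groups)
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    n = np.array([len(a) for a in arrays])
    N = int(n.sum())
    if N < 5:
        raise ValueError("need total n >= 5")
    h = _kw_h(arrays)
    if np.isnan(h):  # all pooled values identical
        return TestResult("kruskal-wallis", 0.0, len(arrays) - 1, 1.0, labels)
    if p_method == "chi2":
        p = float(stats.chi2.sf(h, df=len(arrays) - 1))
    elif p_method == "exact":
        if N > 10:
            raise ValueError("exact enumeration requires total n <= 10")
        pooled = np.concatenate(arrays)
        count = total = 0
        for split in _group_splits(tuple(range(N)), tuple(int(x) for x in n)):
            h_perm = _kw_h([pooled[list(idx)] for idx in split])
            total += 1
            if np.isnan(h_perm) or h_perm >= h - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError("p_method must be 'chi2' or 'exact'")
    return TestResult("kruskal-wallis", float(h), len(arrays) - 1, p, labels)


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjustment: str = "bonferroni") -> list[TestResult]:
    """Dunn's pairwise mean-rank z tests after Kruskal–Wallis.

    For each pair (i, j): z = (R̄_i − R̄_j) / σ_ij with
    σ_ij² = [N(N+1)/12 − Σ(t³ − t)/(12(N − 1))]·(1/n_i + 1/n_j).
    p-values are two-sided normal tails; Bonferroni adjustment multiplies
    by the number of pairs (capped at 1). Empty groups are excluded.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    items = [(str(k), np.asarray(v, dtype=float)) for k, v in groups.items()]
    items = [(k, v[np.isfinite(v)]) for k, v in items]
    items = [(k, v) for k, v in items if len(v) > 0]
    if len(items) < 2:
        raise ValueError("need >= 2 non-empty groups")
    n = np.array([len(v) for _, v in items])
    N = int(n.sum())
    pooled = np.concatenate([v for _, v in items])
    ranks, tie_term = _rank_with_ties(pooled)
    splits = np.split(ranks, np.cumsum(n)[:-1])
    mean_ranks = np.array([s.mean() for s in splits])
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    pairs = list(itertools.combinations(range(len(items)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        adj = min(p * m, 1.0) if adjustment == "bonferroni" else p
        results.append(TestResult("dunn", float(z), None, p,
                                  (items[i][0], items[j][0]), adjusted_p=adj))
    return results


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 14) -> float:
    """Bonferroni-adjusted per-test alpha: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Bray–Curtis dissimilarities between sites.

    d(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ) computed on square-root-transformed
    rows by default (pass ``transform="none"`` to skip). Values lie in
    [0, 1], the matrix is symmetric with zero diagonal, and Bray–Curtis is
    a semi-metric (the triangle inequality may fail). Pairs of all-zero
    sites are undefined and returned as NaN.
    """
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("community values must be non-negative")
    if not np.any(x > 0):
        raise ValueError("all-zero community matrix")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError("transform must be 'sqrt' or 'none'")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class PermanovaResult:
    """Permutation multivariate ANOVA on a distance matrix."""

    pseudo_F: float
    df_between: int
    df_within: int
    r_squared: float
    p_value: float
    n_perm: int
    seed: int | None


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    # Σ_g (1/n_g) Σ_{i<j∈g} d²_ij via indicator-matrix quadratic forms
    m = np.zeros((d2.shape[0], n_groups))
    m[np.arange(d2.shape[0]), codes] = 1.0
    group_sums = np.einsum("ig,ij,jg->g", m, d2, m)
    sizes = m.sum(axis=0)
    return float(np.sum(group_sums / (2.0 * sizes)))


def permanova(dist: pd.DataFrame | np.ndarray, labels, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA with free permutation of labels.

    pseudo-F = [SS_between/(a − 1)] / [SS_within/(n − a)] from the
    distance-based sum-of-squares decomposition; R² = SS_between/SS_total;
    p = (1 + #{permuted F ≥ observed F}) / (n_perm + 1).
    """
    d = dist.to_numpy(float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains undefined (NaN) entries")
    labels = np.asarray([str(x) for x in labels])
    if d.shape[0] != len(labels):
        raise ValueError("labels length must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    n = len(labels)
    if a < 2 or np.min(np.bincount(codes)) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = d ** 2
    ss_total = float(d2[np.triu_indices(n, k=1)].sum() / n)

    def pseudo_f(c):
        ss_w = _ss_within(d2, c, a)
        ss_between = ss_total - ss_w
        return (ss_between / (a - 1)) / (ss_w / (n - a)), ss_between / ss_total

    f_obs, r2 = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(rng.permutation(codes))
        if f_perm >= f_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return PermanovaResult(pseudo_F=float(f_obs), df_between=a - 1,
                           df_within=n - a, r_squared=float(r2),
                           p_value=float(p), n_perm=n_perm, seed=seed)


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS ordination of a distance matrix."""

    coordinates: pd.DataFrame  # sites × k
    stress: float  # Kruskal stress-1 of the best restart
    converged: bool
    n_restarts: int
    seed: int | None
    stress_trace: tuple[float, ...] = field(default=())


def _pairwise(config: np.ndarray) -> np.ndarray:
    diff = config[:, None, :] - config[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _nmds_single(d_cond: np.ndarray, n: int, k: int, init: np.ndarray,
                 max_iter: int, tol: float, window: int = 10):
    iu = np.triu_indices(n, k=1)
    order = np.argsort(d_cond, kind="stable")
    iso = IsotonicRegression(increasing=True)
    xs = np.arange(len(d_cond), dtype=float)

    config = init.copy()
    trace = []
    prev_config = config

    def stress1(dist_cond, dhat_cond):
        denom = np.sum(dist_cond ** 2)
        if denom == 0:
            return 0.0
        return float(np.sqrt(np.sum((dist_cond - dhat_cond) ** 2) / denom))

    current = None
    converged = False
    for _ in range(max_iter):
        dist = _pairwise(config)
        dist_cond = dist[iu]
        # isotonic disparities: monotone non-decreasing in the input ranks
        dhat_sorted = iso.fit_transform(xs, dist_cond[order])
        dhat_cond = np.empty_like(dist_cond)
        dhat_cond[order] = dhat_sorted
        s = stress1(dist_cond, dhat_cond)
        if current is not None and s > current + 1e-12:
            config = prev_config  # reject a worsening step: majorization stalled
            converged = True
            break
        trace.append(s)
        if current is not None and current - s < tol:
            current = s
            converged = True
            break
        current = s
        if s == 0.0:
            converged = True
            break
        # Guttman transform toward the disparities
        dhat = np.zeros((n, n))
        dhat[iu] = dhat_cond
        dhat += dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        prev_config = config
        config = (b @ config) / n
    return config, (trace[-1] if trace else np.inf), converged, trace


def nmds(dist: pd.DataFrame | np.ndarray, k: int = 2, n_restarts: int = 20,
         seed: int | None = None, max_iter: int = 300,
         tol: float = 1e-6) -> OrdinationResult:
    """Non-metric multidimensional scaling by stress majorization.

    Alternates isotonic regression of configuration distances on the rank
    order of the input dissimilarities with Guttman configuration updates,
    minimizing Kruskal stress-1. The first start is the classical
    (metric) scaling solution; the remaining ``n_restarts − 1`` are
    random. Stress is non-increasing across the recorded iterations of
    each restart (a worsening step ends the restart). The best restart is
    returned; ``converged`` is False if no restart met the tolerance.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(float)
    else:
        d = np.asarray(dist, float)
        ids = list(range(d.shape[0]))
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains undefined (NaN) entries")
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"need >= k + 2 = {k + 2} sites")
    iu = np.triu_indices(n, k=1)
    d_cond = d[iu]
    rng = np.random.default_rng(seed)

    scale = d_cond.mean() if d_cond.mean() > 0 else 1.0
    inits = [_classical_mds(d, k)]
    inits += [rng.normal(scale=scale, size=(n, k)) for _ in range(n_restarts - 1)]

    best = None
    for init in inits:
        config, s, conv, trace = _nmds_single(d_cond, n, k, init, max_iter, tol)
        if best is None or s < best[1]:
            best = (config, s, conv, trace)
    config, s, conv, trace = best
    coords = pd.DataFrame(config, index=ids,
                          columns=[f"nmds{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=coords, stress=float(s),
                            converged=bool(conv), n_restarts=n_restarts,
                            seed=seed, stress_trace=tuple(trace))
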