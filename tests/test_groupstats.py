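import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from lakecolor.groupstats import (bonferroni_alpha, bray_curtis, dunn_posthoc,
                                  kruskal_wallis, nmds, permanova)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.statistic == pytest.approx(12 / 42 * 13.5)
        assert res.df == 1

    def test_identical_values_h_zero_p_one(self):
        res = kruskal_wallis({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(21)
        groups = [rng.integers(0, 8, 15).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_p_matches_full_enumeration_oracle(self):
        groups = {"a": [1.2, 3.4, 0.5, 2.2], "b": [4.0, 5.5, 6.1, 2.9]}
        res = kruskal_wallis(groups, p_method="exact")
        pooled = np.array(groups["a"] + groups["b"])
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            g1 = pooled[list(combo)]
            g2 = pooled[[i for i in range(8) if i not in combo]]
            h = sps.kruskal(g1, g2).statistic  # independent H implementation
            total += 1
            if h >= res.statistic - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    @given(shift=st.floats(min_value=-5, max_value=5),
           scale=st.floats(min_value=0.1, max_value=10))
    def test_invariant_to_monotone_transform(self, shift, scale):
        groups = [[1.0, 4.0, 2.5], [3.0, 6.0, 8.0], [0.5, 7.0, 9.0]]
        base = kruskal_wallis(groups).statistic
        transformed = [[scale * np.exp(x) + shift for x in g] for g in groups]
        assert kruskal_wallis(transformed).statistic == pytest.approx(base)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": [2.0]})


class TestDunn:
    def test_two_group_z_squared_equals_h(self):
        groups = {"a": [1.0, 2.0, 3.0, 7.0, 7.0], "b": [4.0, 5.0, 6.0, 7.0]}
        z = dunn_posthoc(groups)[0].statistic
        h = kruskal_wallis(groups).statistic
        assert z ** 2 == pytest.approx(h)

    def test_shifted_group_dominates_significance(self):
        rng = np.random.default_rng(22)
        groups = {"a": rng.normal(0, 1, 25), "b": rng.normal(0, 1, 25),
                  "c": rng.normal(6, 1, 25)}
        results = dunn_posthoc(groups)
        for r in results:
            involves_c = "c" in r.groups
            assert (r.adjusted_p < 0.01) == involves_c

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(23)
        groups = {k: rng.normal(0, 1, 10) for k in "abcd"}
        assert all(r.adjusted_p <= 1.0 for r in dunn_posthoc(groups))
        assert all(r.adjusted_p >= r.p_value for r in dunn_posthoc(groups))

    def test_empty_group_excluded(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": []}
        results = dunn_posthoc(groups)
        assert all("c" not in r.groups for r in results)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 14, 0.05 / 14),
        (0.05, 1, 0.05),
        (0.05, 2, 0.025),
    ])
    def test_adjustment(self, alpha, n, expected):
        assert bonferroni_alpha(alpha, n) == pytest.approx(expected)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        m = pd.DataFrame([[3.0, 0.0], [0.0, 7.0]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(1.0)

    def test_untransformed_formula(self):
        m = pd.DataFrame([[2.0, 2.0], [2.0, 0.0]], index=["a", "b"])
        assert bray_curtis(m, transform="none").loc["a", "b"] == pytest.approx(1 / 3)

    def test_matches_scipy_on_sqrt_data(self):
        rng = np.random.default_rng(24)
        m = pd.DataFrame(rng.gamma(1.0, size=(6, 4)))
        ours = bray_curtis(m).to_numpy()
        ref = squareform(pdist(np.sqrt(m.to_numpy()), metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_symmetric_bounded_zero_diagonal(self):
        rng = np.random.default_rng(25)
        m = pd.DataFrame(rng.gamma(0.7, size=(10, 6)))
        d = bray_curtis(m).to_numpy()
        np.testing.assert_allclose(d, d.T)
        assert np.all((d >= 0) & (d <= 1))
        np.testing.assert_allclose(np.diag(d), 0)

    def test_double_zero_pair_undefined(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]],
                         index=["a", "b", "c"])
        d = bray_curtis(m)
        assert np.isnan(d.loc["a", "b"])
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[0.0], [0.0]]))


def _pseudo_f_oracle(d, labels):
    """Independent distance-based sum-of-squares decomposition."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ssb = sst - ssw
    a = len(groups)
    return (ssb / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    @pytest.fixture
    def small_data(self):
        rng = np.random.default_rng(26)
        x = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.5, 1, (3, 2))])
        d = squareform(pdist(x))
        labels = ["a"] * 3 + ["b"] * 3
        return d, labels

    def test_p_matches_full_enumeration(self, small_data):
        d, labels = small_data
        res = permanova(d, labels, n_perm=49999, seed=1)
        # exhaustive oracle over all distinct label assignments
        f_obs = _pseudo_f_oracle(d, labels)
        assert res.pseudo_F == pytest.approx(f_obs)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            perm = np.array(["b"] * 6, dtype=object)
            perm[list(combo)] = "a"
            total += 1
            if _pseudo_f_oracle(d, perm) >= f_obs - 1e-12:
                count += 1
        exact_p = count / total
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_matches_skbio_pseudo_f(self, small_data):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, labels = small_data
        dm = skbio_stats.DistanceMatrix(d, ids=[str(i) for i in range(6)])
        ref = skbio_stats.permanova(dm, grouping=list(labels), permutations=99)
        res = permanova(d, labels, n_perm=99, seed=0)
        assert res.pseudo_F == pytest.approx(ref["test statistic"])

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(27)
        pvals = []
        for _ in range(40):
            x = rng.normal(size=(12, 3))
            d = squareform(pdist(x))
            labels = ["a"] * 6 + ["b"] * 6
            rng.shuffle(labels)
            pvals.append(permanova(d, labels, n_perm=199,
                                   seed=int(rng.integers(2 ** 31))).p_value)
        assert 0.2 < np.mean(pvals) < 0.8

    def test_separated_clusters_detected(self):
        rng = np.random.default_rng(28)
        x = np.vstack([rng.normal(0, 0.5, (8, 3)), rng.normal(6, 0.5, (8, 3))])
        d = squareform(pdist(x))
        res = permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=2)
        assert res.r_squared > 0.5
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seed_reproducible(self, small_data):
        d, labels = small_data
        a = permanova(d, labels, n_perm=99, seed=5)
        b = permanova(d, labels, n_perm=99, seed=5)
        assert a.p_value == b.p_value

    def test_single_group_raises(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4)


class TestNMDS:
    def test_recovers_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 11.0])[:, None]
        d = squareform(pdist(pts))
        res = nmds(d, k=1, n_restarts=5, seed=3)
        assert res.stress < 0.01
        assert res.converged

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=(12, 4))
        d = squareform(pdist(x))
        res = nmds(d, k=2, n_restarts=3, seed=4)
        trace = np.array(res.stress_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=(10, 3))
        d = squareform(pdist(x))
        a = nmds(d, k=2, n_restarts=4, seed=6)
        b = nmds(d, k=2, n_restarts=4, seed=6)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_too_few_sites_raise(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            nmds(d, k=2)

    def test_nan_distance_raises(self):
        d = np.zeros((5, 5))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nmds(d, k=2)
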