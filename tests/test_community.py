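import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lakecolor.community import (aggregate_rank, biovolume_to_dry_biomass,
                                 community_matrix, filter_rare_taxa,
                                 filter_rare_two_stage, merge_mesh_duplicates,
                                 zp_ratios)


def taxon_row(site, group, order, genus, mesh="fine", density=1.0,
              biomass=np.nan, biovolume=np.nan):
    return {"site_id": site, "group": group, "order_name": order,
            "genus_name": genus, "taxon_id": f"{order}:{genus}", "mesh": mesh,
            "density": density, "biovolume": biovolume, "biomass": biomass}


class TestBiovolumeConversion:
    @pytest.mark.parametrize("biovolume,expected", [
        (0.0, 0.0),
        (1e6, 200.0),   # 10⁶ µm³/mL → 1000 µg wet/L → 200 µg dry/L
        (5e6, 1000.0),
    ])
    def test_dimensional_oracle(self, biovolume, expected):
        assert biovolume_to_dry_biomass(biovolume) == pytest.approx(expected)

    @given(a=st.floats(min_value=0, max_value=1e6),
           v=st.floats(min_value=0, max_value=1e9))
    def test_linearity(self, a, v):
        assert biovolume_to_dry_biomass(a * v) == pytest.approx(
            a * biovolume_to_dry_biomass(v), rel=1e-9)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            biovolume_to_dry_biomass(-1.0)


class TestMeshMerge:
    def test_single_mesh_passes_through(self):
        df = pd.DataFrame([taxon_row("A", "zooplankton", "Ploima", "Keratella",
                                     mesh="fine", density=4.0, biomass=2.0)])
        out = merge_mesh_duplicates(df)
        pd.testing.assert_frame_equal(out, df)

    def test_dual_mesh_averaged(self):
        df = pd.DataFrame([
            taxon_row("A", "zooplankton", "Ploima", "Keratella", "fine", 4.0, 2.0),
            taxon_row("A", "zooplankton", "Ploima", "Keratella", "coarse", 6.0, 4.0),
            taxon_row("B", "zooplankton", "Ploima", "Keratella", "fine", 10.0, 5.0),
        ])
        out = merge_mesh_duplicates(df)
        assert len(out) == 2
        merged = out[out["site_id"] == "A"].iloc[0]
        assert merged["density"] == pytest.approx(5.0)
        assert merged["biomass"] == pytest.approx(3.0)
        assert merged["mesh"] == "merged"
        assert out[out["site_id"] == "B"].iloc[0]["density"] == 10.0

    def test_idempotent(self):
        df = pd.DataFrame([
            taxon_row("A", "zooplankton", "Ploima", "Keratella", "fine", 4.0, 2.0),
            taxon_row("A", "zooplankton", "Ploima", "Keratella", "coarse", 6.0, 4.0),
        ])
        once = merge_mesh_duplicates(df)
        twice = merge_mesh_duplicates(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_phytoplankton_untouched(self):
        df = pd.DataFrame([
            taxon_row("A", "phytoplankton", "Nostocales", "Dolichospermum",
                      "none", 4.0, 2.0),
        ])
        pd.testing.assert_frame_equal(merge_mesh_duplicates(df), df)


def matrix(values, sites=None, taxa=None):
    values = np.asarray(values, dtype=float)
    sites = sites or [f"S{i}" for i in range(values.shape[0])]
    taxa = taxa or [f"T{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=sites, columns=taxa)


class TestRareTaxonFilter:
    def test_share_boundary(self):
        # taxon B at exactly 5% in one sample retained; C below everywhere removed
        m = matrix([[95.0, 5.0, 4.0],
                    [96.0, 2.0, 2.0]])
        m.iloc[0, 0] = 91.0  # totals: 100, 100
        out = filter_rare_taxa(m, threshold=0.05)
        assert list(out.columns) == ["T0", "T1"]

    def test_taxon_below_threshold_everywhere_removed(self):
        m = matrix([[95.1, 4.9], [96.0, 4.0]])
        out = filter_rare_taxa(m, threshold=0.05)
        assert list(out.columns) == ["T0"]

    def test_single_taxon_samples_all_retained(self):
        m = matrix(np.diag([3.0, 5.0, 9.0]))
        out = filter_rare_taxa(m, threshold=0.05)
        assert out.shape == (3, 3)

    def test_matches_brute_force_shares(self):
        rng = np.random.default_rng(11)
        m = matrix(rng.gamma(0.5, size=(3, 5)))
        out = filter_rare_taxa(m, threshold=0.05)
        expected = []
        for taxon in m.columns:
            keep = False
            for site in m.index:
                total = m.loc[site].sum()
                if total > 0 and m.loc[site, taxon] / total >= 0.05:
                    keep = True
            if keep:
                expected.append(taxon)
        assert list(out.columns) == expected

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(12)
        m = matrix(rng.gamma(0.3, size=(6, 8)))
        once = filter_rare_taxa(m)
        twice = filter_rare_taxa(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once.shape[1] <= m.shape[1]

    def test_empty_result_advises(self):
        # impossible threshold > 1 removes everything
        m = matrix([[1.0, 1.0]])
        with pytest.raises(ValueError, match="threshold"):
            filter_rare_taxa(m, threshold=1.5)

    def test_two_stage_removes_whole_rare_order(self):
        rows = []
        for site, big, small in [("A", 96.0, 4.0), ("B", 97.0, 3.0)]:
            rows.append(taxon_row(site, "zooplankton", "Diplostraca", "Daphnia",
                                  biomass=big))
            rows.append(taxon_row(site, "zooplankton", "Ploima", "Keratella",
                                  biomass=small))
        counts = pd.DataFrame(rows)
        out = filter_rare_two_stage(counts, "zooplankton")
        assert list(out.columns) == ["Diplostraca|Daphnia"]


class TestAggregateRank:
    def test_one_genus_per_order_is_identity(self):
        m = matrix([[1.0, 2.0]], taxa=["Ploima|Keratella", "Calanoida|Skisto"])
        out = aggregate_rank(m)
        assert sorted(out.columns) == ["Calanoida", "Ploima"]
        assert out.loc["S0", "Ploima"] == 1.0

    def test_orders_sum_their_genera(self):
        m = matrix([[10.0, 15.0]], taxa=["Ploima|Keratella", "Ploima|Brachionus"])
        out = aggregate_rank(m)
        assert out.loc["S0", "Ploima"] == 25.0

    def test_row_totals_conserved(self):
        rng = np.random.default_rng(13)
        taxa = ["Ploima|A", "Ploima|B", "Calanoida|C", "Diplostraca|D"]
        m = matrix(rng.gamma(1.0, size=(5, 4)), taxa=taxa)
        out = aggregate_rank(m)
        np.testing.assert_allclose(out.sum(axis=1), m.sum(axis=1))

    def test_unknown_order_raises(self):
        m = matrix([[1.0]], taxa=["MysteryGenus"])
        with pytest.raises(KeyError, match="MysteryGenus"):
            aggregate_rank(m)


class TestZPRatios:
    def test_simple_ratio(self):
        zoo = matrix([[50.0]], sites=["A"], taxa=["Diplostraca|Daphnia"])
        phyto = matrix([[100.0]], sites=["A"], taxa=["Nostocales|Dolichospermum"])
        out = zp_ratios(zoo, phyto).iloc[0]
        assert out["zp_ratio"] == pytest.approx(0.5)
        assert out["crustacean_zp_ratio"] == pytest.approx(0.5)
        assert out["rotifer_zp_ratio"] == pytest.approx(0.0)

    def test_all_rotifer_site_has_zero_crustacean_ratio(self):
        zoo = matrix([[30.0]], sites=["A"], taxa=["Ploima|Keratella"])
        phyto = matrix([[60.0]], sites=["A"], taxa=["Chlorellales|Chlorella"])
        out = zp_ratios(zoo, phyto).iloc[0]
        assert out["crustacean_zp_ratio"] == 0.0
        assert out["rotifer_zp_ratio"] == pytest.approx(0.5)

    def test_zero_phytoplankton_flagged_not_dropped(self):
        zoo = matrix([[30.0]], sites=["A"], taxa=["Ploima|Keratella"])
        phyto = matrix([[0.0]], sites=["A"], taxa=["Chlorellales|Chlorella"])
        out = zp_ratios(zoo, phyto)
        assert len(out) == 1
        assert not out.iloc[0]["ratio_defined"]
        assert np.isnan(out.iloc[0]["zp_ratio"])


class TestCommunityMatrix:
    def test_pivot_sums_within_cells(self):
        df = pd.DataFrame([
            taxon_row("A", "zooplankton", "Ploima", "Keratella", biomass=2.0),
            taxon_row("A", "zooplankton", "Ploima", "Keratella", mesh="coarse",
                      biomass=3.0),
        ])
        m = community_matrix(df, "zooplankton", rank="genus", value="biomass")
        assert m.loc["A", "Ploima|Keratella"] == 5.0
        assert m.attrs["rank"] == "genus"
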