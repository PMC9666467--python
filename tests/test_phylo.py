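from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from pelagos import (CountTable, SampleMetadata, asv_niche, beta_mntd,
                     beta_mntd_matrix, cophenetic_distances, mantel_correlogram,
                     phylo_signal_asv, simulate_traits, unweighted_unifrac)
from conftest import random_count_table
from oracles import beta_mntd_brute, cophenetic_brute, unifrac_brute


def tree_from(newick: str) -> TreeNode:
    return TreeNode.read(StringIO(newick))


class TestCophenetic:
    def test_two_tip_path_sum(self):
        coph = cophenetic_distances(tree_from("(a:0.1,b:0.2);"))
        assert coph[("a", "b")] == pytest.approx(0.3)

    def test_symmetric_zero_diagonal(self, random_tree_factory):
        coph = cophenetic_distances(random_tree_factory(12, seed=3))
        np.testing.assert_allclose(coph.data, coph.data.T)
        assert np.all(np.diag(coph.data) == 0)

    def test_matches_root_path_oracle(self, random_tree_factory):
        for seed in range(8):
            tree = random_tree_factory(10, seed=seed)
            coph = cophenetic_distances(tree)
            names, brute = cophenetic_brute(tree)
            got = coph.filter(names).data
            np.testing.assert_allclose(got, brute, atol=1e-12)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            cophenetic_distances(tree_from("(a:0.1,b);"))


class TestBetaMNTD:
    def test_identical_samples_zero(self, random_tree_factory):
        tree = random_tree_factory(6, seed=1)
        coph = cophenetic_distances(tree)
        row = pd.Series(1, index=[t.name for t in tree.tips()])
        assert beta_mntd(row, row, coph) == 0.0

    def test_single_pair_distance(self):
        coph = cophenetic_distances(tree_from("(x:0.1,y:0.3);"))
        assert beta_mntd(pd.Series({"x": 1}), pd.Series({"y": 1}), coph) == \
            pytest.approx(0.4)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force(self, rng, random_tree_factory, weighted):
        for seed in range(10):
            tree = random_tree_factory(6, seed=100 + seed)
            tips = [t.name for t in tree.tips()]
            coph = cophenetic_distances(tree)
            names, dmat = cophenetic_brute(tree)
            oracle_coph = dict(zip(names, range(len(names))))
            a = pd.Series(rng.integers(0, 5, size=6), index=tips)
            b = pd.Series(rng.integers(0, 5, size=6), index=tips)
            if a.sum() == 0 or b.sum() == 0:
                continue
            a[a.idxmin()] = max(a.min(), 1)  # ensure non-empty
            b[b.idxmin()] = max(b.min(), 1)
            expected = beta_mntd_brute(a.to_dict(), b.to_dict(), names, dmat,
                                       weighted=weighted)
            assert beta_mntd(a, b, coph, weighted=weighted) == \
                pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_weighted(self, rng, random_tree_factory):
        tree = random_tree_factory(8, seed=5)
        tips = [t.name for t in tree.tips()]
        coph = cophenetic_distances(tree)
        a = pd.Series(rng.integers(1, 9, size=8), index=tips)
        b = pd.Series(rng.integers(1, 9, size=8), index=tips)
        assert beta_mntd(a * 7, b, coph) == pytest.approx(beta_mntd(a, b, coph))

    def test_empty_sample_rejected(self, random_tree_factory):
        tree = random_tree_factory(4, seed=2)
        coph = cophenetic_distances(tree)
        tips = [t.name for t in tree.tips()]
        with pytest.raises(ValueError):
            beta_mntd(pd.Series(0, index=tips), pd.Series(1, index=tips), coph)


class TestUnweightedUnifrac:
    def test_identical_presence_zero(self, random_tree_factory):
        tree = random_tree_factory(6, seed=9)
        row = pd.Series(1, index=[t.name for t in tree.tips()])
        assert unweighted_unifrac(row, row, tree) == pytest.approx(0.0)

    def test_disjoint_cherries_are_maximal(self):
        tree = tree_from("((a:1,b:1):1,(c:1,d:1):1);")
        a = pd.Series({"a": 1, "b": 1})
        b = pd.Series({"c": 1, "d": 1})
        assert unweighted_unifrac(a, b, tree) == pytest.approx(1.0)

    def test_matches_branch_oracle(self, rng, random_tree_factory):
        for seed in range(10):
            tree = random_tree_factory(10, seed=200 + seed)
            tips = [t.name for t in tree.tips()]
            pa = set(rng.choice(tips, size=rng.integers(1, 8), replace=False))
            pb = set(rng.choice(tips, size=rng.integers(1, 8), replace=False))
            a = pd.Series({t: 1 for t in pa})
            b = pd.Series({t: 1 for t in pb})
            expected = unifrac_brute(pa, pb, tree)
            assert unweighted_unifrac(a, b, tree) == pytest.approx(expected, abs=1e-12)

    def test_range_and_both_empty(self, random_tree_factory):
        tree = random_tree_factory(5, seed=4)
        tips = [t.name for t in tree.tips()]
        with pytest.raises(ValueError):
            unweighted_unifrac(pd.Series(0, index=tips), pd.Series(0, index=tips), tree)


class TestAsvNiche:
    def test_single_occurrence_equals_sample_value(self, toy_metadata):
        counts = pd.DataFrame({"only": [0, 10, 0, 0], "bg": [5, 5, 5, 5]},
                              index=["s1", "s2", "s3", "s4"])
        niche = asv_niche(CountTable(counts), toy_metadata, ["temperature"])
        assert niche.loc["only", "temperature"] == pytest.approx(25.0)

    def test_equal_weights_average(self):
        meta = SampleMetadata(pd.DataFrame(
            {"temperature": [10.0, 20.0], "depth": [20.0, 20.0]},
            index=["s1", "s2"]))
        counts = pd.DataFrame({"x": [5, 5], "y": [5, 5]}, index=["s1", "s2"])
        niche = asv_niche(CountTable(counts), meta, ["temperature"])
        assert niche.loc["x", "temperature"] == pytest.approx(15.0)

    def test_matches_direct_weighted_mean(self, rng, toy_metadata):
        table = random_count_table(rng, 4, 6)
        table = CountTable(table.data.set_axis(["s1", "s2", "s3", "s4"], axis=0))
        niche = asv_niche(table, toy_metadata, ["temperature"])
        rel = table.data.div(table.data.sum(axis=1), axis=0)
        temp = toy_metadata.data["temperature"]
        for asv in niche.index:
            w = rel[asv]
            expected = (w * temp).sum() / w.sum()
            assert niche.loc[asv, "temperature"] == pytest.approx(expected)

    def test_niche_within_observed_range(self, rng, toy_metadata):
        table = random_count_table(rng, 4, 10)
        table = CountTable(table.data.set_axis(["s1", "s2", "s3", "s4"], axis=0))
        niche = asv_niche(table, toy_metadata, ["temperature"])
        t = toy_metadata.data["temperature"]
        assert ((niche["temperature"] >= t.min() - 1e-9) &
                (niche["temperature"] <= t.max() + 1e-9)).all()


class TestPhyloSignal:
    def test_identical_niches_all_zero(self, random_tree_factory):
        tree = random_tree_factory(20, seed=11)
        coph = cophenetic_distances(tree)
        niche = pd.Series(7.0, index=[t.name for t in tree.tips()])
        out = phylo_signal_asv(coph, niche, n_bins=10)
        assert (out["mean_abs_niche_diff"].dropna() == 0).all()

    def test_two_asvs_single_bin(self):
        coph = cophenetic_distances(tree_from("(a:0.5,b:0.5);"))
        niche = pd.Series({"a": 3.0, "b": 8.0})
        out = phylo_signal_asv(coph, niche, n_bins=1)
        assert out.loc[0, "mean_abs_niche_diff"] == pytest.approx(5.0)

    def test_brownian_signal_rises_over_short_distances(self, random_tree_factory):
        # under Brownian niches the shortest-distance bins have the smallest
        # mean |niche difference| -> positive rank correlation over the
        # lowest 20% of bins in the vast majority of replicates
        from scipy.stats import spearmanr

        wins = 0
        n_sims = 50
        for seed in range(n_sims):
            tree = random_tree_factory(40, seed=300 + seed)
            coph = cophenetic_distances(tree)
            niche = simulate_traits(tree, brownian_rate=25.0, root_value=0.0,
                                    seed=seed)
            out = phylo_signal_asv(coph, niche, n_bins=25)
            head = out.dropna(subset=["mean_abs_niche_diff"]).head(8)
            rho = spearmanr(head["bin"], head["mean_abs_niche_diff"])[0]
            wins += rho > 0
        assert wins >= 0.9 * n_sims

    def test_too_few_pairs_rejected(self):
        coph = cophenetic_distances(tree_from("(a:0.5,b:0.5);"))
        with pytest.raises(ValueError, match="n_bins"):
            phylo_signal_asv(coph, pd.Series({"a": 1.0, "b": 2.0}), n_bins=5)


class TestMantelCorrelogram:
    def _habitat_from(self, values):
        v = np.asarray(values, dtype=float)
        return np.abs(v[:, None] - v[None, :])

    def test_monotone_transform_gives_significant_first_bins(self, rng):
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            r = np.random.default_rng(s)
            x = r.normal(size=(25, 3))
            d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            ids = [str(i) for i in range(25)]
            d_phy = DistanceMatrix(d, ids)
            d_hab = DistanceMatrix(np.sqrt(d), ids)  # monotone transform
            out = mantel_correlogram(d_phy, d_hab, n_bins=8, n_perm=199, seed=s)
            hits += bool(out.loc[0, "significant"] and out.loc[0, "mantel_r"] > 0)
        assert hits >= 0.95 * n_sims

    def test_first_bin_type_one_error_calibrated(self):
        # independent habitat distances: raw first-bin p should be uniform
        rejections = 0
        n_sims = 100
        for s in range(n_sims):
            r = np.random.default_rng(1000 + s)
            ids = [str(i) for i in range(20)]
            d_phy = DistanceMatrix(self._habitat_from(r.normal(size=20)), ids)
            d_hab = DistanceMatrix(self._habitat_from(r.normal(size=20)), ids)
            out = mantel_correlogram(d_phy, d_hab, n_bins=6, n_perm=99, seed=s)
            rejections += bool(out.loc[0, "p_value"] < 0.05)
        # binomial 99% band around 0.05 for 100 sims: [0, 11]
        assert rejections <= 11

    def test_invalid_permutations(self):
        ids = ["a", "b", "c"]
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]), ids)
        with pytest.raises(ValueError):
            mantel_correlogram(d, d, n_bins=2, n_perm=0)


def test_beta_mntd_matrix_is_symmetric_distance(toy_table, random_tree_factory):
    tree = random_tree_factory(5, seed=21)
    tips = [t.name for t in tree.tips()]
    table = CountTable(toy_table.data.set_axis(tips, axis=1))
    coph = cophenetic_distances(tree)
    dm = beta_mntd_matrix(table, coph)
    assert np.allclose(dm.data, dm.data.T)
    assert dm.data.max() <= coph.data.max() + 1e-12
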