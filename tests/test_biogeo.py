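import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from pelagos import (CountTable, SampleMetadata, anosim, bray_curtis_matrix,
                     cluster_decay_curves, distance_decay_curve,
                     family_unifrac_decay_clusters, geographic_distance_matrix,
                     haversine_km, loess_fit, oligotype_zscore_clusters,
                     permanova_single_variable, permanova_table, simulate_tree)
from conftest import random_count_table
from oracles import permanova_f_brute


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        counts = pd.DataFrame([[3, 3, 0], [3, 3, 0], [0, 0, 9]],
                              index=["a", "b", "c"], columns=list("xyz"))
        dm = bray_curtis_matrix(CountTable(counts))
        assert dm[("a", "b")] == pytest.approx(0.0)
        assert dm[("a", "c")] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        counts = pd.DataFrame([[2, 0, 2], [1, 1, 0]], index=["a", "b"],
                              columns=list("xyz"))
        dm = bray_curtis_matrix(CountTable(counts), transform="none")
        assert dm[("a", "b")] == pytest.approx(4 / 6)

    def test_total_sum_sqrt_transform(self, rng):
        table = random_count_table(rng, 4, 6)
        dm = bray_curtis_matrix(table, transform="total_sum_sqrt")
        X = np.sqrt(table.counts() / table.counts().sum(axis=1, keepdims=True))
        exp = np.abs(X[0] - X[1]).sum() / (X[0] + X[1]).sum()
        assert dm.data[0, 1] == pytest.approx(exp)
        assert dm.data.max() <= 1.0 + 1e-12


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km(10, 20, 10, 20) == 0.0

    def test_quarter_circle(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(np.pi * 6371 / 2, rel=1e-6)

    def test_one_degree_meridian(self):
        assert haversine_km(0, 0, 1, 0) == pytest.approx(2 * np.pi * 6371 / 360,
                                                         rel=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)


class TestLoessAndDecay:
    def test_constant_reproduced(self, rng):
        x = rng.uniform(0, 100, size=60)
        y = np.full(60, 3.7)
        grid = np.linspace(5, 95, 20)
        np.testing.assert_allclose(loess_fit(x, y, grid), 3.7, atol=1e-9)

    def test_linear_reproduced(self, rng):
        x = np.sort(rng.uniform(0, 100, size=80))
        y = 0.8 * x + 2.0
        grid = np.linspace(10, 90, 25)
        np.testing.assert_allclose(loess_fit(x, y, grid), 0.8 * grid + 2.0,
                                   atol=1e-6)

    def test_bell_peak_located(self, rng):
        x = np.sort(rng.uniform(0, 100, size=300))
        y = np.exp(-((x - 40.0) ** 2) / 200)
        grid = np.linspace(0, 100, 51)
        fit = loess_fit(x, y, grid, span=0.3)
        peak = grid[np.argmax(fit)]
        assert abs(peak - 40.0) <= 2.0  # one grid step

    def test_affine_equivariance(self, rng):
        x = rng.uniform(0, 50, size=60)
        y = rng.normal(size=60)
        grid = np.linspace(1, 49, 10)
        base = loess_fit(x, y, grid)
        scaled = loess_fit(x, 3 * y + 1, grid)
        np.testing.assert_allclose(scaled, 3 * base + 1, atol=1e-9)

    def test_decay_curve_from_matrices(self, rng):
        n = 12
        ids = [str(i) for i in range(n)]
        pos = np.sort(rng.uniform(0, 5000, size=n))
        geo = DistanceMatrix(np.abs(pos[:, None] - pos[None, :]), ids)
        comm = DistanceMatrix(np.clip(np.abs(pos[:, None] - pos[None, :]) / 5000,
                                      0, 1), ids)
        curve = distance_decay_curve(comm, geo, grid_size=30)
        assert curve.grid_km.size == 30
        assert np.all(np.diff(curve.grid_km) > 0)
        assert np.all(np.isfinite(curve.fitted))

    def test_single_distance_rejected(self):
        ids = list("abcde")
        geo = DistanceMatrix(np.ones((5, 5)) - np.eye(5), ids)
        comm = DistanceMatrix(np.ones((5, 5)) - np.eye(5), ids)
        with pytest.raises(ValueError):
            distance_decay_curve(comm, geo)


class TestCurveClustering:
    def test_planted_two_shapes_recovered(self, rng):
        grid = np.linspace(0, 10000, 30)
        curves = {}
        for k in range(20):
            if k < 11:
                base = np.exp(-((grid - 5000) ** 2) / 4e6)   # bell
            else:
                base = grid / 10000.0                         # ramp
            curves[f"fam{k}"] = base + rng.normal(0, 0.02, size=30)
        frame = pd.DataFrame(curves).T
        out = cluster_decay_curves(frame, k_range=range(2, 8))
        assert out.attrs["k"] == 2
        labels = out["cluster"].to_numpy()
        planted = np.array([0] * 11 + [1] * 9)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(planted, labels) == 1.0


class TestPermanova:
    def _two_cluster_distance(self):
        # 4+4 samples, two internally identical, far-separated clusters
        n = 8
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if (i < 4) != (j < 4):
                    d[i, j] = 10.0
        return DistanceMatrix(d, [str(i) for i in range(n)])

    def test_exact_minimum_p_under_full_separation(self):
        d = self._two_cluster_distance()
        g = pd.Series(["a"] * 4 + ["b"] * 4)
        res = permanova_single_variable(d, g, n_perm=999, seed=0)
        # minimum achievable p with 999 permutations: ties occur only for
        # permutations reproducing the exact partition: 2*4!*4!/8! = 1/35
        assert res.p_value <= 1 / 35 + 0.02
        assert res.r_squared > 0.9

    def test_matches_brute_force_f(self, rng):
        n = 10
        x = rng.normal(size=n)
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [str(i) for i in range(n)])
        res = permanova_single_variable(dm, x, n_perm=9, seed=1)
        assert res.pseudo_f == pytest.approx(permanova_f_brute(d, x), rel=1e-9)

    def test_matches_skbio_for_categorical(self, rng):
        n = 12
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [str(i) for i in range(n)])
        g = ["a"] * 6 + ["b"] * 6
        ours = permanova_single_variable(dm, pd.Series(g), n_perm=99, seed=2)
        ref = skbio_permanova(dm, np.array(g), permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_sims = 200
        for s in range(n_sims):
            r = np.random.default_rng(5000 + s)
            pts = r.normal(size=(15, 3))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [str(i) for i in range(15)])
            x = r.normal(size=15)
            res = permanova_single_variable(dm, x, n_perm=199, seed=s)
            rejections += res.p_value < 0.05
        # binomial 99% CI around 0.05 for 200 sims -> [2, 18]
        assert 2 <= rejections <= 18

    def test_constant_variable_rejected(self):
        d = self._two_cluster_distance()
        with pytest.raises(ValueError, match="constant"):
            permanova_single_variable(d, pd.Series([1.0] * 8))

    def test_table_with_bh_correction(self, rng):
        n = 10
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(n)])
        meta = SampleMetadata(pd.DataFrame(
            {"temperature": pts[:, 0] + rng.normal(0, 0.1, n),
             "noise": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)]))
        out = permanova_table(dm, meta, ["temperature", "noise"],
                              n_perm=199, seed=3)
        assert set(out.columns) >= {"variable", "r_squared", "p_value", "p_bh",
                                    "retained"}
        assert (out["p_bh"] >= out["p_value"] - 1e-12).all()


class TestAnosim:
    def test_perfect_separation(self):
        n = 8
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if (i < 4) != (j < 4):
                    d[i, j] = 10.0
                elif i != j:
                    d[i, j] = 1.0
        dm = DistanceMatrix(d, [str(i) for i in range(n)])
        r, p = anosim(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_r_near_zero(self):
        small = 0
        n_sims = 50
        for s in range(n_sims):
            rng_ = np.random.default_rng(800 + s)
            pts = rng_.normal(size=(30, 3))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [str(i) for i in range(30)])
            g = rng_.permutation(["a"] * 15 + ["b"] * 15)
            r, _ = anosim(dm, g, n_perm=9, seed=s)
            small += abs(r) < 0.2
        assert small >= 0.9 * n_sims

    def test_singleton_groups_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]),
                            ["a", "b", "c"])
        with pytest.raises(ValueError):
            anosim(dm, ["g1", "g2", "g3"])


class TestOligotypeClusters:
    def test_zscore_identity(self, rng):
        table = random_count_table(rng, 12, 8, depth=300)
        z, assign = oligotype_zscore_clusters(table, k_range=range(2, 5))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_planted_opposite_blocks_recovered(self, rng):
        # two ASV blocks peaking at opposite transect ends (V-shaped pattern)
        n_samples = 20
        x = np.linspace(0, 1, n_samples)
        rows = {}
        for k in range(6):
            rows[f"south{k}"] = np.round(200 * np.exp(-((x - 0) ** 2) / 0.05)
                                         + rng.integers(0, 3, n_samples)).astype(int)
        for k in range(6):
            rows[f"north{k}"] = np.round(200 * np.exp(-((x - 1) ** 2) / 0.05)
                                         + rng.integers(0, 3, n_samples)).astype(int)
        counts = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)])
        table = CountTable(counts)
        _, assign = oligotype_zscore_clusters(table, k_range=range(2, 6))
        assert assign.attrs["k"] == 2
        from sklearn.metrics import adjusted_rand_score
        planted = [0 if a.startswith("south") else 1 for a in assign.index]
        assert adjusted_rand_score(planted, assign["cluster"]) == 1.0

    def test_single_variable_asv_rejected(self):
        counts = pd.DataFrame({"flat": [5, 5, 5], "only": [1, 5, 9]},
                              index=["a", "b", "c"])
        with pytest.raises(ValueError):
            oligotype_zscore_clusters(CountTable(counts))


class TestFamilyDecayClusters:
    def _build_dataset(self, rng, n_stations=14, n_fams=6, asvs_per_fam=12):
        lats = np.linspace(-50, 50, n_stations)
        meta = pd.DataFrame({
            "latitude": lats,
            "longitude": np.full(n_stations, 180.0),
            "depth": np.full(n_stations, 20.0),
            "size_fraction": ["FL_0.2_3"] * n_stations,
            "temperature": 25 - np.abs(lats) / 3,
        }, index=[f"st{i}" for i in range(n_stations)])
        tree = simulate_tree(n_fams * asvs_per_fam, seed=42)
        tips = [t.name for t in tree.tips()]
        taxonomy = pd.Series({tip: f"fam{k // asvs_per_fam}"
                              for k, tip in enumerate(tips)})
        counts = np.zeros((n_stations, len(tips)), dtype=int)
        for j, tip in enumerate(tips):
            occupied = rng.choice(n_stations, size=rng.integers(4, n_stations),
                                  replace=False)
            counts[occupied, j] = rng.integers(1, 50, size=len(occupied))
        table = CountTable(pd.DataFrame(counts, index=meta.index, columns=tips))
        return table, taxonomy, tree, SampleMetadata(meta)

    def test_runs_and_respects_filters(self, rng):
        table, taxonomy, tree, meta = self._build_dataset(rng)
        assignments, curves = family_unifrac_decay_clusters(
            table, taxonomy, tree, meta, min_asvs=10, min_span_km=5000,
            k_range=range(2, 5), grid_size=12)
        assert set(assignments.index) <= set(taxonomy.unique())
        assert curves.shape[1] == 12
        # z-scored inputs: each family's fitted curve is centred near zero
        assert np.abs(curves.to_numpy().mean(axis=1)).max() < 1.5

    def test_span_filter_excludes_local_family(self, rng):
        table, taxonomy, tree, meta = self._build_dataset(rng)
        # restrict one family to a single station
        fam0 = taxonomy.index[taxonomy == "fam0"]
        data = table.data.copy()
        data.loc[data.index[1:], fam0] = 0
        table2 = CountTable(data)
        assignments, _ = family_unifrac_decay_clusters(
            table2, taxonomy, tree, meta, min_asvs=10, min_span_km=5000,
            k_range=range(2, 5), grid_size=12)
        assert "fam0" not in assignments.index


def test_geographic_distance_uses_station_coordinates(toy_metadata):
    dm = geographic_distance_matrix(toy_metadata)
    # s1 (-40) to s4 (40): 80 degrees of latitude along the same meridian
    assert dm[("s1", "s4")] == pytest.approx(80 * 111.19, rel=1e-3)
    assert np.allclose(dm.data, dm.data.T)
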