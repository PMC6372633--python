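import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from metabotyper import multivariate as mv
from metabotyper.errors import SchemaError


def dist_from_points(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels if labels is not None else list(range(len(points)))
    return mv.DistanceMatrix(squareform(pdist(points)), labels)


def single_factor_meta(groups):
    idx = [f"s{i}" for i in range(len(groups))]
    return pd.DataFrame({"group": groups}, index=idx)


class TestEuclideanDistances:
    def test_identical_profiles_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        d = mv.euclidean_distances(df)
        assert d.matrix[0, 1] == 0

    def test_three_four_five(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = mv.euclidean_distances(df)
        assert d.matrix[0, 1] == pytest.approx(5.0)

    def test_averaging_identical_replicates(self):
        vals = pd.DataFrame(np.tile([[1.0, 2.0, 3.0]], (5, 1)),
                            index=[f"s{i}" for i in range(5)])
        meta = pd.DataFrame({"genotype": ["G1"] * 5}, index=vals.index)
        d = mv.euclidean_distances(vals, meta, average_by_genotype=True)
        assert d.n == 1

    def test_missing_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [1.0, 2.0]])
        with pytest.raises(SchemaError):
            mv.euclidean_distances(df)


class TestPermanova:
    def test_degenerate_flagged(self):
        pts = np.ones((4, 2))
        meta = single_factor_meta(["a", "a", "b", "b"])
        res = mv.permanova(dist_from_points(pts, meta.index.tolist()), meta,
                           terms=(("group",),), n_perm=99)
        assert res.degenerate

    def test_partition_sums_to_total(self, filtered_log2):
        completed, _ = mv.impute_pca(filtered_log2.values, n_components=3)
        d = mv.euclidean_distances(completed)
        res = mv.permanova(d, filtered_log2.meta, n_perm=30, seed=0)
        assert res.table["ss"].sum() + res.residual_ss == pytest.approx(
            res.total_ss, rel=1e-8
        )
        n = d.n
        assert res.table["df"].sum() + res.residual_df == n - 1

    def test_exhaustive_enumeration_oracle(self):
        """n=6, single factor: permutation p converges to enumeration p."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 0.8
        groups = ["a", "a", "a", "b", "b", "b"]
        meta = single_factor_meta(groups)
        d = dist_from_points(pts, meta.index.tolist())
        res = mv.permanova(d, meta, terms=(("group",),), n_perm=10_000, seed=1)
        f_obs = res.table["pseudo_f"].iloc[0]

        # oracle: brute-force F over all 720 label permutations
        g = mv._gower_center(d.matrix)
        labels = np.array(groups)
        fs = []
        for perm in itertools.permutations(range(6)):
            lab = labels[list(perm)]
            x = pd.get_dummies(lab).to_numpy(float)
            q = mv._orth_basis(np.column_stack([np.ones(6), x]))
            h = q @ q.T
            ss_g = np.trace((h - np.ones((6, 6)) / 6) @ g)
            ss_r = np.trace((np.eye(6) - h) @ g)
            fs.append((ss_g / 1) / (ss_r / 4))
        fs = np.array(fs)
        p_exact = np.mean(fs >= f_obs - 1e-12)
        assert abs(res.table["p_value"].iloc[0] - p_exact) < 0.02

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2))
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        meta1 = single_factor_meta(groups)
        meta2 = single_factor_meta(["x" if g == "b" else "y" for g in groups])
        d = dist_from_points(pts, meta1.index.tolist())
        r1 = mv.permanova(d, meta1, terms=(("group",),), n_perm=200, seed=3)
        r2 = mv.permanova(d, meta2, terms=(("group",),), n_perm=200, seed=3)
        assert r1.table["p_value"].iloc[0] == r2.table["p_value"].iloc[0]
        assert r1.table["pseudo_f"].iloc[0] == pytest.approx(r2.table["pseudo_f"].iloc[0])

    def test_full_factorial_terms_present(self, filtered_log2):
        completed, _ = mv.impute_pca(filtered_log2.values, n_components=3)
        d = mv.euclidean_distances(completed)
        res = mv.permanova(d, filtered_log2.meta, n_perm=10, seed=0)
        assert len(res.table) == 7
        assert res.table["term"].tolist()[0] == "genotype"


class TestImputePCA:
    def test_no_missing_identity(self):
        df = pd.DataFrame(np.arange(12, dtype=float).reshape(4, 3))
        out, info = mv.impute_pca(df)
        pd.testing.assert_frame_equal(out, df)
        assert info.n_iter == 0

    def test_rank1_recovery(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(1, 2, size=40)
        v = rng.uniform(1, 2, size=25)
        full = np.outer(u, v)
        x = full.copy()
        mask = rng.random(x.shape) < 0.1
        x[mask] = np.nan
        out, info = mv.impute_pca(pd.DataFrame(x), n_components=1, tol=1e-9)
        rel = np.abs(out.to_numpy()[mask] - full[mask]) / full[mask]
        assert rel.max() < 0.01

    def test_constant_column_missing_cell(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, np.nan]])
        out, _ = mv.impute_pca(pd.DataFrame(x), n_components=1)
        assert out.iloc[2, 1] == pytest.approx(5.0, abs=1e-6)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 6))
        x[0, 0] = np.nan
        df = pd.DataFrame(x)
        out, _ = mv.impute_pca(df, n_components=2)
        obs = ~np.isnan(x)
        np.testing.assert_array_equal(out.to_numpy()[obs], x[obs])


class TestPCA:
    def test_two_points_pc1_everything(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]])
        res = mv.pca(df, scale=False)
        assert res.explained[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, filtered_log2):
        completed, _ = mv.impute_pca(filtered_log2.values, n_components=3)
        res = mv.pca(completed, scale=True)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_gram_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(12, 5)))
        res = mv.pca(df, scale=False)
        xc = df.to_numpy() - df.to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.scores.to_numpy().T, xc @ xc.T, atol=1e-8
        )

    def test_zero_variance_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = mv.pca(df, scale=True)
        assert res.dropped == ["b"]


class TestWardClustering:
    def test_two_leaves_height_is_squared_distance(self):
        d = dist_from_points([[0.0], [2.0]])
        tree = mv.hcluster_ward_squared(d)
        assert tree.merges == [(0, 1)]
        assert tree.heights[0] == pytest.approx(4.0)  # d^2 = 2*deltaSSE

    def test_collinear_nearest_pair_first(self):
        d = dist_from_points([[0.0], [1.0], [10.0]])
        tree = mv.hcluster_ward_squared(d)
        assert tree.merges[0] == (0, 1)

    def test_single_leaf_errors(self):
        with pytest.raises(ValueError):
            mv.hcluster_ward_squared(mv.DistanceMatrix(np.zeros((1, 1)), ["a"]))

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pts = rng.normal(size=(9, 3))
            tree = mv.hcluster_ward_squared(dist_from_points(pts))
            assert all(a <= b + 1e-9 for a, b in zip(tree.heights, tree.heights[1:]))

    def test_matches_bruteforce_objective_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            pts = rng.normal(size=(n, 2))
            tree = mv.hcluster_ward_squared(dist_from_points(pts))
            bm, bh = brute_ward(pts)
            assert tree.merges == bm
            np.testing.assert_allclose(tree.heights, bh, rtol=1e-9)

    def test_newick_roundtrippable(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        tree = mv.hcluster_ward_squared(dist_from_points(pts, ["a", "b", "c"]))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "a" in nwk and "c" in nwk


def brute_ward(points):
    """Greedy minimum Ward-objective-increase agglomeration (oracle).

    Heights equal twice the SSE increase, i.e. the squared-scale
    between-cluster dissimilarity maintained by the Lance-Williams update.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    merges, heights = [], []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pa, pb = points[clusters[a]], points[clusters[b]]
            ca, cb = pa.mean(axis=0), pb.mean(axis=0)
            inc = len(pa) * len(pb) / (len(pa) + len(pb)) * np.sum((ca - cb) ** 2)
            if best is None or inc < best[0] - 1e-12:
                best = (inc, a, b)
        inc, a, b = best
        merges.append((a, b))
        heights.append(2 * inc)
        clusters[n + step] = clusters.pop(a) + clusters.pop(b)
    return merges, heights


class TestCutTree:
    def test_extremes(self):
        pts = np.random.default_rng(0).normal(size=(6, 2))
        tree = mv.hcluster_ward_squared(dist_from_points(pts))
        assert len(set(mv.cut_tree(tree, 1))) == 1
        assert len(set(mv.cut_tree(tree, 6))) == 6

    def test_nestedness(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.normal(size=(10, 2))
            tree = mv.hcluster_ward_squared(dist_from_points(pts))
            for k in range(2, 11):
                fine = mv.cut_tree(tree, k)
                coarse = mv.cut_tree(tree, k - 1)
                # every fine cluster maps into exactly one coarse cluster
                mapping = {}
                for f, c in zip(fine, coarse):
                    assert mapping.setdefault(f, c) == c

    def test_bad_k(self):
        pts = np.random.default_rng(0).normal(size=(4, 2))
        tree = mv.hcluster_ward_squared(dist_from_points(pts))
        with pytest.raises(ValueError):
            mv.cut_tree(tree, 0)
        with pytest.raises(ValueError):
            mv.cut_tree(tree, 5)


class TestBakersGamma:
    def test_identical_trees(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        tree = mv.hcluster_ward_squared(dist_from_points(pts, list("abcdefgh")))
        assert mv.bakers_gamma(tree, tree) == pytest.approx(1.0)

    def test_label_mismatch_errors(self):
        pts = np.random.default_rng(1).normal(size=(4, 2))
        t1 = mv.hcluster_ward_squared(dist_from_points(pts, list("abcd")))
        t2 = mv.hcluster_ward_squared(dist_from_points(pts, list("abce")))
        with pytest.raises(ValueError):
            mv.bakers_gamma(t1, t2)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        pts1, pts2 = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        labels = list("abcdef")
        t1 = mv.hcluster_ward_squared(dist_from_points(pts1, labels))
        t2 = mv.hcluster_ward_squared(dist_from_points(pts2, labels))
        g = mv.bakers_gamma(t1, t2)
        renamed = {lab: f"x{lab}" for lab in labels}
        t1b = mv.DendrogramTree(t1.merges, t1.heights, [renamed[c] for c in t1.labels])
        t2b = mv.DendrogramTree(t2.merges, t2.heights, [renamed[c] for c in t2.labels])
        assert mv.bakers_gamma(t1b, t2b) == pytest.approx(g)

    def test_leaf_order_alignment(self):
        """Gamma must align by labels, not positions."""
        pts = np.random.default_rng(2).normal(size=(6, 2))
        labels = list("abcdef")
        t1 = mv.hcluster_ward_squared(dist_from_points(pts, labels))
        shuffled = [3, 1, 4, 0, 5, 2]
        t2 = mv.hcluster_ward_squared(
            dist_from_points(pts[shuffled], [labels[i] for i in shuffled])
        )
        assert mv.bakers_gamma(t1, t2) == pytest.approx(1.0)


class TestGammaPermutationTest:
    def test_identical_trees_small_p(self):
        pts = np.random.default_rng(5).normal(size=(10, 3))
        tree = mv.hcluster_ward_squared(dist_from_points(pts, list("abcdefghij")))
        res = mv.gamma_permutation_test(tree, tree, n_perm=500, seed=1)
        assert res.gamma == pytest.approx(1.0)
        assert res.p_value <= 5 / 501

    def test_addone_lower_bound(self):
        rng = np.random.default_rng(8)
        t1 = mv.hcluster_ward_squared(dist_from_points(rng.normal(size=(7, 2))))
        t2 = mv.hcluster_ward_squared(dist_from_points(rng.normal(size=(7, 2))))
        res = mv.gamma_permutation_test(t1, t2, n_perm=99, seed=2)
        assert res.p_value >= 1 / 100
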