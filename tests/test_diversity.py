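import numpy as np
import pytest

from micronet.errors import ValidationError
from micronet import diversity as dv


class TestChao1:
    def test_no_singletons_equals_observed_richness(self):
        assert dv.chao1([2, 3, 5, 2]) == 4

    def test_hand_computed_value(self):
        # S_obs=5, F1=2, F2=1 -> 5 + 2*1/(2*2) = 5.5
        assert dv.chao1([1, 1, 2, 3, 5]) == pytest.approx(5.5)

    def test_zero_counts_do_not_change_estimate(self):
        assert dv.chao1([1, 1, 2, 3, 5, 0, 0]) == dv.chao1([1, 1, 2, 3, 5])

    def test_at_least_observed_richness(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 5, 50)
        c[0] = 1
        assert dv.chao1(c) >= (c > 0).sum()

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            dv.chao1([0, 0])

    def test_matches_scikit_bio(self):
        from skbio.diversity.alpha import chao1 as skbio_chao1
        rng = np.random.default_rng(1)
        for _ in range(5):
            c = rng.integers(0, 6, 40)
            c[0] = max(c[0], 1)
            assert dv.chao1(c) == pytest.approx(skbio_chao1(c))


class TestShannon:
    def test_single_taxon_is_zero(self):
        assert dv.shannon([7]) == 0

    def test_uniform_is_log_k(self):
        assert dv.shannon([3, 3, 3, 3]) == pytest.approx(np.log(4))

    def test_hand_computed_value(self):
        assert dv.shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_log2_flag(self):
        assert dv.shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            dv.shannon([0, 0, 0])


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        d = dv.bray_curtis([[1, 2, 3], [1, 2, 3]])
        assert d.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        d = dv.bray_curtis([[5, 0], [0, 7]])
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        d = dv.bray_curtis([[2, 0, 1], [1, 1, 1]])
        assert d.data[0, 1] == pytest.approx(1 / 3, abs=1e-4)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        d = dv.bray_curtis(rng.integers(0, 20, (10, 30)) + 1)
        assert d.data.min() >= 0 and d.data.max() <= 1

    def test_two_empty_samples_rejected(self):
        with pytest.raises(ValidationError):
            dv.bray_curtis([[0, 0], [0, 0], [1, 2]])


class TestPcoa:
    def test_collinear_points_recovered_on_axis_one(self):
        # three collinear points at 0, 1, 3 on a line
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = dv.pcoa(dv.DistanceMatrix(d, ["a", "b", "c"]))
        tol = 1e-9
        assert (res.eigenvalues > tol).sum() == 1
        axis = res.coordinates[:, 0]
        gaps = np.abs(np.diff(axis))
        assert gaps == pytest.approx([1.0, 2.0], abs=1e-9)

    def test_equidistant_points_give_equal_eigenvalues(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        res = dv.pcoa(dv.DistanceMatrix(d, list("abcde")))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == n - 1
        assert np.allclose(pos, pos[0])

    def test_distances_reconstructed_for_euclidean_input(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 3))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(x))
        res = dv.pcoa(dv.DistanceMatrix(d, [f"s{i}" for i in range(6)]))
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d, atol=1e-8)

    def test_proportions_sum_below_one(self):
        rng = np.random.default_rng(4)
        d = dv.bray_curtis(rng.integers(0, 30, (8, 20)) + 1)
        res = dv.pcoa(d)
        assert np.all(res.proportion_explained >= -1e-12)
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_axis_clipping_warns(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        with pytest.warns(UserWarning, match="clipping"):
            res = dv.pcoa(dv.DistanceMatrix(d, ["a", "b", "c"]), n_axes=3)
        assert res.coordinates.shape[1] == 1

    def test_matches_scikit_bio(self):
        import skbio
        rng = np.random.default_rng(5)
        d = dv.bray_curtis(rng.integers(0, 30, (9, 25)) + 1)
        ours = dv.pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.data, d.ids))
        k = min(3, ours.coordinates.shape[1])
        for ax in range(k):
            a = ours.coordinates[:, ax]
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)


class TestAnosim:
    def separated(self):
        # within-group distances all below any between-group distance
        d = np.array([
            [0, .1, .1, .9, .8, .9],
            [.1, 0, .1, .9, .9, .8],
            [.1, .1, 0, .85, .9, .9],
            [.9, .9, .85, 0, .1, .1],
            [.8, .9, .9, .1, 0, .1],
            [.9, .8, .9, .1, .1, 0]])
        return dv.DistanceMatrix(d, list("abcdef")), ["g1"] * 3 + ["g2"] * 3

    def test_perfect_separation_gives_r_one(self):
        dm, groups = self.separated()
        r, p = dv.anosim(dm, groups, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_r_centred_at_zero(self):
        rng = np.random.default_rng(6)
        groups = ["a"] * 5 + ["b"] * 5
        rs = []
        for _ in range(200):
            x = rng.standard_normal((10, 4))
            from scipy.spatial.distance import pdist, squareform
            dm = dv.DistanceMatrix(squareform(pdist(x)),
                                   [f"s{i}" for i in range(10)])
            r, _ = dv.anosim(dm, groups, n_perm=9, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_p_bounded_by_plus_one_estimator(self):
        dm, groups = self.separated()
        _, p = dv.anosim(dm, groups, n_perm=999, seed=0)
        assert p >= 1 / 1000

    def test_invariant_to_monotone_distance_transform(self):
        rng = np.random.default_rng(7)
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(rng.standard_normal((12, 4))))
        ids = [f"s{i}" for i in range(12)]
        groups = ["a"] * 6 + ["b"] * 6
        r1, _ = dv.anosim(dv.DistanceMatrix(d, ids), groups, 9, seed=1)
        r2, _ = dv.anosim(dv.DistanceMatrix(np.sqrt(d), ids), groups, 9, seed=1)
        assert r1 == pytest.approx(r2)

    def test_matches_scikit_bio_statistic(self):
        import skbio
        rng = np.random.default_rng(8)
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(rng.standard_normal((12, 4))))
        ids = [f"s{i}" for i in range(12)]
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours, _ = dv.anosim(dv.DistanceMatrix(d, ids), groups, 9, seed=0)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d, ids), groups, permutations=0)
        assert ours == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        dm, _ = self.separated()
        with pytest.raises(ValidationError):
            dv.anosim(dm, ["a"] * 5 + ["b"], n_perm=9)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        vals = [1, 2, 3, 4, 1, 2, 3, 4]
        groups = ["a"] * 4 + ["b"] * 4
        df = dv.group_compare(vals, groups)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        vals = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
        groups = ["a"] * 5 + ["b"] * 5
        df = dv.group_compare(vals, groups)
        assert df["p_value"].iloc[0] == pytest.approx(0.0079365, abs=1e-5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal(12)
        groups = ["a"] * 6 + ["b"] * 6
        p1 = dv.group_compare(vals, groups)["p_value"].iloc[0]
        p2 = dv.group_compare(np.exp(vals), groups)["p_value"].iloc[0]
        assert p1 == pytest.approx(p2)

    def test_constant_identical_groups_warn_p_one(self):
        with pytest.warns(UserWarning, match="identical constants"):
            df = dv.group_compare([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert df["p_value"].iloc[0] == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            dv.group_compare([1, 2, 3, 4], ["a", "a", "b", "b"])
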