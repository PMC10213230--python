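import numpy as np
import networkx as nx
import pytest

from micronet.errors import (EmptyNetworkError, NotEvaluableError,
                             ValidationError)
from micronet import network_construction as nc


class TestFillMissing:
    def test_taxon_without_zeros_unchanged(self):
        x = np.array([[0.5, 0.5], [0.4, 0.6], [0.3, 0.7]])
        assert np.array_equal(nc.fill_missing(x), x)

    def test_majority_nonzero_taxon_zeros_filled(self):
        col = np.array([0.1] * 7 + [0.0] * 3)
        x = np.column_stack([col, 1 - col])
        out = nc.fill_missing(x, fill=0.01)
        assert np.allclose(out[7:, 0], 1e-4)  # 0.01% as a fraction
        assert np.allclose(out[:7, 0], 0.1)

    def test_minority_taxon_left_alone(self):
        col = np.array([0.1] * 3 + [0.0] * 7)
        x = np.column_stack([col, 1 - col])
        out = nc.fill_missing(x)
        assert np.array_equal(out[:, 0], col)

    def test_zero_fill_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 4))
        x[x < 0.3] = 0
        assert np.array_equal(nc.fill_missing(x, fill=0.0), x)


class TestCorrelationMatrix:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(1)
        sim = nc.correlation_matrix(rng.random((8, 5)),
                                    [f"t{i}" for i in range(5)])
        assert np.allclose(np.diag(sim.corr), 1.0)

    def test_anticorrelated_pair(self):
        x = np.arange(8.0)
        mat = np.column_stack([x, -x, x ** 2])
        sim = nc.correlation_matrix(mat, ["a", "b", "c"])
        assert sim.corr[0, 1] == pytest.approx(-1.0)
        assert sim.similarity[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        mat = np.column_stack([[1, 2, 3, 4, 5], [2, 4, 5, 4, 5]])
        sim = nc.correlation_matrix(mat, ["a", "b"])
        assert sim.corr[0, 1] == pytest.approx(0.7746, abs=1e-4)

    def test_spearman_option(self):
        mat = np.column_stack([[1, 2, 3, 4, 5], [1, 4, 9, 16, 25]])
        sim = nc.correlation_matrix(mat, ["a", "b"], method="spearman")
        assert sim.corr[0, 1] == pytest.approx(1.0)

    def test_constant_column_removed_with_warning(self):
        mat = np.column_stack([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]])
        with pytest.warns(UserWarning, match="constant"):
            sim = nc.correlation_matrix(mat, ["a", "b", "c"])
        assert sim.taxon_ids == ["a", "c"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="4 samples"):
            nc.correlation_matrix(np.random.rand(3, 5),
                                  [f"t{i}" for i in range(5)])


class TestUnfoldSpectrum:
    def test_equally_spaced_eigenvalues_unit_spacings(self):
        spacings = nc.unfold_spectrum(np.linspace(0, 10, 50))
        assert np.allclose(spacings, 1.0, atol=0.05)

    def test_mean_spacing_near_one(self):
        rng = np.random.default_rng(2)
        h = rng.standard_normal((80, 80))
        eig = np.linalg.eigvalsh((h + h.T) / 2)
        spacings = nc.unfold_spectrum(eig)
        assert 0.9 <= spacings.mean() <= 1.1

    def test_degenerate_eigenvalues_collapsed(self):
        eig = np.concatenate([np.linspace(0, 5, 30),
                              np.linspace(0, 5, 30)])  # exact duplicates
        spacings = nc.unfold_spectrum(np.sort(eig))
        assert len(spacings) == 29

    def test_too_few_distinct_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            nc.unfold_spectrum(np.ones(50))


class TestNnsdTest:
    def test_exponential_spacings_fit_poisson(self):
        rng = np.random.default_rng(3)
        chi_p, chi_g, fits = nc.nnsd_test(rng.exponential(1.0, 500))
        assert fits and chi_p < chi_g

    def test_wigner_spacings_fit_goe(self):
        rng = np.random.default_rng(4)
        u = rng.random(500)
        w = np.sqrt(-4 * np.log(1 - u) / np.pi)  # Wigner surmise sampler
        chi_p, chi_g, fits = nc.nnsd_test(w)
        assert not fits and chi_g < chi_p

    def test_constant_spacings_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            nc.nnsd_test(np.full(100, 2.0))

    def test_too_few_spacings_rejected(self):
        with pytest.raises(ValidationError):
            nc.nnsd_test(np.random.rand(10))


def two_block_data(seed=0, n_samp=200, block=30, rho=0.95, noise=80):
    """Sampled data whose correlation matrix holds two planted blocks."""
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(2):
        f = rng.standard_normal(n_samp)
        cols.append(np.sqrt(rho) * f[:, None]
                    + np.sqrt(1 - rho) * rng.standard_normal((n_samp, block)))
    cols.append(rng.standard_normal((n_samp, noise)))
    x = np.hstack(cols)
    ids = [f"t{i}" for i in range(x.shape[1])]
    return x, ids, block


class TestRmtThresholdScan:
    def test_block_structure_recovered_as_two_components(self):
        x, ids, block = two_block_data(seed=0)
        sim = nc.correlation_matrix(x, ids)
        res = nc.rmt_threshold_scan(sim)
        assert res.chosen_threshold is not None
        net = nc.build_network(sim, res.chosen_threshold)
        comps = sorted(map(frozenset, nx.connected_components(net.graph)))
        expected = sorted([frozenset(ids[:block]),
                           frozenset(ids[block:2 * block])])
        assert comps == expected

    def test_grid_and_persistence_invariant(self):
        x, ids, _ = two_block_data(seed=3)
        res = nc.rmt_threshold_scan(nc.correlation_matrix(x, ids))
        thresholds = [r.threshold for r in res.records]
        assert thresholds == pytest.approx(list(np.round(
            np.arange(0.30, 1.0001, 0.01), 2)))
        if res.chosen_threshold is not None:
            later = [r for r in res.records
                     if r.evaluable and r.threshold >= res.chosen_threshold]
            assert all(r.poisson_fits for r in later)

    def test_pure_noise_scan_completes(self):
        rng = np.random.default_rng(5)
        sim = nc.correlation_matrix(rng.standard_normal((30, 300)),
                                    [f"t{i}" for i in range(300)])
        res = nc.rmt_threshold_scan(sim)
        assert any(r.evaluable for r in res.records)
        if res.chosen_threshold is not None:
            assert res.chosen_threshold >= 0.5

    def test_tiny_matrix_not_evaluable(self):
        corr = np.eye(5)
        with pytest.raises(ValidationError, match="more taxa"):
            nc.rmt_threshold_scan(nc.SimilarityMatrix(
                corr, [f"t{i}" for i in range(5)]))


class TestBuildNetwork:
    def sim_from(self, corr, ids=None):
        corr = np.asarray(corr, dtype=float)
        np.fill_diagonal(corr, 1.0)
        ids = ids or [f"t{i}" for i in range(corr.shape[0])]
        return nc.SimilarityMatrix(corr, ids)

    def test_path_of_two_edges(self):
        sim = self.sim_from([[1, 0.9, 0.5], [0.9, 1, 0.9], [0.5, 0.9, 1]])
        net = nc.build_network(sim, 0.88)
        assert net.n_nodes == 3 and net.n_links == 2

    def test_cutoff_above_max_similarity_errors(self):
        sim = self.sim_from([[1, 0.5], [0.5, 1]])
        with pytest.raises(EmptyNetworkError):
            nc.build_network(sim, 0.9)

    def test_zero_cutoff_complete_graph(self):
        rng = np.random.default_rng(6)
        c = rng.uniform(0.1, 0.9, (5, 5))
        sim = self.sim_from((c + c.T) / 2)
        net = nc.build_network(sim, 0.0)
        assert net.n_links == 10

    def test_edge_signs_follow_correlation(self):
        sim = self.sim_from([[1, -0.9, 0.95], [-0.9, 1, 0.2], [0.95, 0.2, 1]])
        net = nc.build_network(sim, 0.88)
        signs = {frozenset(e): d["sign"]
                 for *e, d in net.graph.edges(data=True)}
        assert signs[frozenset(("t0", "t1"))] == "-"
        assert signs[frozenset(("t0", "t2"))] == "+"

    def test_isolated_nodes_dropped(self):
        sim = self.sim_from([[1, 0.9, 0.1], [0.9, 1, 0.1], [0.1, 0.1, 1]])
        net = nc.build_network(sim, 0.88)
        assert "t2" not in net.graph

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(-1, 1, (12, 12))
        sim = self.sim_from((c + c.T) / 2)
        counts = []
        for cut in (0.2, 0.4, 0.6, 0.8):
            try:
                net = nc.build_network(sim, cut)
                counts.append((net.n_nodes, net.n_links))
            except EmptyNetworkError:
                counts.append((0, 0))
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cutoff_rejected(self):
        sim = self.sim_from([[1, 0.9], [0.9, 1]])
        with pytest.raises(ValidationError):
            nc.build_network(sim, 1.5)
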