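import numpy as np
import pytest
import scipy.sparse as sp

from lppi import (
    Graph,
    RefineConfig,
    TestVectors,
    build_hierarchy,
    coarsen_once,
    refine_all,
    refine_level,
    smooth_test_vectors,
    spectral_affinity,
)
from lppi.errors import ParameterError, ShapeError
from lppi.multilevel import MappingOperator


def _complete_graph(n):
    return Graph(n, np.ones((n, n)) - np.eye(n))


def _dense_laplacian(g):
    a = g.adjacency.toarray()
    return np.diag(a.sum(1)) - a


class TestSmoothing:
    def test_output_shape(self, path4):
        tv = smooth_test_vectors(path4, t=5, gs_iters=3, seed=0)
        assert tv.values.shape == (4, 5)
        assert np.all(np.isfinite(tv.values))

    def test_rayleigh_quotient_never_increases(self):
        rng = np.random.default_rng(0)
        a = np.triu(rng.random((20, 20)) < 0.3, 1).astype(float)
        g = Graph(20, a + a.T)
        lap = _dense_laplacian(g)
        raw = np.random.default_rng(42).standard_normal((20, 6))
        tv = smooth_test_vectors(g, t=6, gs_iters=4, seed=42)
        for j in range(6):
            x0, x1 = raw[:, j], tv.values[:, j]
            rq0 = x0 @ lap @ x0 / (x0 @ x0)
            rq1 = x1 @ lap @ x1 / (x1 @ x1)
            assert rq1 <= rq0 + 1e-12

    def test_complete_graph_leaves_only_constant_mode(self):
        # on K_6 every non-constant Laplacian eigenvalue is 6, so heavy
        # smoothing kills everything but the constant eigenvector; after
        # mean removal each column is numerically zero
        g = _complete_graph(6)
        tv = smooth_test_vectors(g, t=4, gs_iters=50, seed=1)
        assert np.max(np.abs(tv.values - tv.values.mean(0))) < 1e-6

    def test_parameter_validation(self, path4):
        with pytest.raises(ParameterError):
            smooth_test_vectors(path4, t=0)
        with pytest.raises(ParameterError):
            smooth_test_vectors(path4, gs_iters=0)

    def test_deterministic(self, path4):
        a = smooth_test_vectors(path4, seed=9).values
        b = smooth_test_vectors(path4, seed=9).values
        np.testing.assert_array_equal(a, b)


class TestAffinity:
    def _tv(self, rows):
        return TestVectors(np.asarray(rows, float), gs_iters=1, seed=0)

    def test_identical_rows(self):
        tv = self._tv([[1.0, 2.0], [1.0, 2.0]])
        assert spectral_affinity(tv, 0, 1) == pytest.approx(1.0)

    def test_orthogonal_rows(self):
        tv = self._tv([[1.0, 0.0], [0.0, 1.0]])
        assert spectral_affinity(tv, 0, 1) == 0.0

    def test_hand_computed(self):
        tv = self._tv([[1.0, 0.0], [1.0, 1.0]])
        assert spectral_affinity(tv, 0, 1) == pytest.approx(0.5)

    def test_zero_row_convention(self):
        tv = self._tv([[0.0, 0.0], [1.0, 1.0]])
        assert spectral_affinity(tv, 0, 1) == 0.0

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(5)
        tv = self._tv(rng.standard_normal((10, 4)))
        for p in range(10):
            for q in range(p + 1, 10):
                a = spectral_affinity(tv, p, q)
                assert 0.0 <= a <= 1.0 + 1e-15
                assert a == pytest.approx(spectral_affinity(tv, q, p))


class TestCoarsenOnce:
    def test_single_node_graph(self):
        g = Graph(1)
        tv = TestVectors(np.ones((1, 2)), 1, 0)
        coarse, h = coarsen_once(g, tv)
        assert coarse.n_nodes == 1
        assert h.assignment.tolist() == [0]

    def test_pairwise_merge_bound(self, fixture_a_data):
        g = fixture_a_data[0]
        tv = smooth_test_vectors(g, seed=0)
        coarse, h = coarsen_once(g, tv)
        assert coarse.n_nodes >= int(np.ceil(g.n_nodes / 2))
        assert coarse.n_nodes < g.n_nodes

    def test_hand_set_vectors_on_path(self, path4):
        # rows (1,0),(1,0),(0,1),(0,1): edge (0,1) and (2,3) have affinity 1,
        # edge (1,2) affinity 0 -> merge {0,1} and {2,3}
        tv = TestVectors(
            np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]]), 1, 0
        )
        coarse, h = coarsen_once(path4, tv)
        assert h.assignment.tolist() == [0, 0, 1, 1]
        assert coarse.n_nodes == 2
        # dense Galerkin oracle: only the old (1,2) edge survives off-diagonal
        hm = h.matrix().toarray()
        galerkin = hm.T @ path4.adjacency.toarray() @ hm
        assert coarse.weight(0, 1) == pytest.approx(galerkin[0, 1]) == 1.0

    def test_weight_conservation_including_diagonal(self, fixture_a_data):
        g = fixture_a_data[0]
        tv = smooth_test_vectors(g, seed=3)
        _, h = coarsen_once(g, tv)
        hm = h.matrix()
        galerkin = (hm.T @ g.adjacency @ hm).toarray()
        assert galerkin.sum() == pytest.approx(
            g.adjacency.sum(), abs=1e-9
        )


class TestHierarchy:
    def test_level_zero(self, path4):
        hier = build_hierarchy(path4, level=0)
        assert hier.depth == 0
        assert len(hier.levels) == 1
        assert hier.coarsest is path4

    def test_node_counts_strictly_decrease(self):
        from lppi import SBMSpec, simulate_sbm

        g, _ = simulate_sbm(SBMSpec(block_sizes=(16, 16, 16, 16), seed=2))
        hier = build_hierarchy(g, level=3, seed=0)
        counts = [lvl.n_nodes for lvl in hier.levels]
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_mapping_composition_is_total(self, fixture_a_data):
        g = fixture_a_data[0]
        hier = build_hierarchy(g, level=2, seed=1)
        assignment = np.arange(g.n_nodes)
        for h in hier.mappings:
            assignment = h.assignment[assignment]
        assert assignment.min() >= 0
        assert assignment.max() < hier.coarsest.n_nodes

    def test_deterministic_given_seed(self, fixture_a_data):
        g = fixture_a_data[0]
        h1 = build_hierarchy(g, level=2, seed=11)
        h2 = build_hierarchy(g, level=2, seed=11)
        assert h1.depth == h2.depth
        for a, b in zip(h1.levels, h2.levels):
            assert (a.adjacency != b.adjacency).nnz == 0
        for a, b in zip(h1.mappings, h2.mappings):
            np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_early_stop_on_edgeless_graph(self):
        hier = build_hierarchy(Graph(5), level=4)
        assert hier.depth == 0


class TestRefinement:
    def test_power_zero_is_pure_projection(self, path4):
        h = MappingOperator(np.array([0, 0, 1, 1]), 2)
        e_coarse = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = refine_level(e_coarse, h, path4, RefineConfig(power=0))
        np.testing.assert_array_equal(out, e_coarse[[0, 0, 1, 1]])

    def test_identity_mapping_matches_dense_operator(self, path4):
        h = MappingOperator(np.arange(4), 4)
        rng = np.random.default_rng(0)
        e = rng.standard_normal((4, 3))
        sigma = 1.0
        a = path4.adjacency.toarray() + sigma * np.eye(4)
        d = np.diag(1.0 / np.sqrt(path4.degrees() + sigma))
        expected = d @ a @ d @ e
        out = refine_level(e, h, path4, RefineConfig(power=1, sigma=sigma))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_smoothing_operator_spectrum_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for n in (10, 30, 50):
            a = np.triu(rng.random((n, n)) < 0.2, 1).astype(float)
            g = Graph(n, a + a.T)
            sigma = 1.0
            at = g.adjacency.toarray() + sigma * np.eye(n)
            dinv = np.diag(1.0 / np.sqrt(g.degrees() + sigma))
            eig = np.linalg.eigvalsh(dinv @ at @ dinv)
            assert eig.min() >= -1 - 1e-10
            assert eig.max() <= 1 + 1e-10

    def test_refinement_never_amplifies(self):
        rng = np.random.default_rng(4)
        a = np.triu(rng.random((30, 30)) < 0.2, 1).astype(float)
        g = Graph(30, a + a.T)
        tv = smooth_test_vectors(g, seed=0)
        coarse, h = coarsen_once(g, tv)
        e = rng.standard_normal((coarse.n_nodes, 5))
        projected = e[h.assignment]
        out = refine_level(e, h, g, RefineConfig(power=3))
        assert np.linalg.norm(out) <= np.linalg.norm(projected) + 1e-9

    def test_refine_all_depth_zero(self, path4):
        hier = build_hierarchy(path4, level=0)
        e = np.ones((4, 2))
        np.testing.assert_array_equal(refine_all(hier, e), e)

    def test_two_level_projection_composition(self, fixture_a_data):
        g = fixture_a_data[0]
        hier = build_hierarchy(g, level=2, seed=5)
        assert hier.depth == 2
        rng = np.random.default_rng(0)
        e = rng.standard_normal((hier.coarsest.n_nodes, 3))
        out = refine_all(hier, e, RefineConfig(power=0))
        ancestor = np.arange(g.n_nodes)
        for h in hier.mappings:
            ancestor = h.assignment[ancestor]
        np.testing.assert_array_equal(out, e[ancestor])

    def test_shape_errors(self, path4):
        h = MappingOperator(np.array([0, 0, 1, 1]), 2)
        with pytest.raises(ShapeError):
            refine_level(np.ones((3, 2)), h, path4)
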