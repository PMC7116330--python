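"""Eigenproblems, Fiedler pair, reordering, eigenmaps, RGB."""

import numpy as np
import pytest

from vbgrad import (
    AffinityMatrix,
    eigenmap_coords,
    fiedler,
    gradient_map,
    laplacian,
    rgb_map,
    solve_affinity,
    solve_eigenproblem,
    spectral_reorder,
)
from vbgrad.exceptions import DegenerateDegreeError, ParameterError

from conftest import random_affinity


class TestSolve:
    def test_four_node_standard_spectrum(self, graphs):
        sol = solve_affinity(graphs["fig1"], "standard")
        # characteristic polynomial of the printed L factors to {0,1,3,4}
        assert np.allclose(sol.eigenvalues, [0, 1, 3, 4], atol=1e-8)

    @pytest.mark.parametrize("problem", ["standard", "generalized",
                                         "symmetric_normalized", "random_walk"])
    def test_trivial_eigenpair_connected_graph(self, graphs, problem):
        sol = solve_affinity(graphs["fig1"], problem)
        assert sol.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)
        v0 = sol.eigenvectors[:, 0]
        if problem in ("standard", "generalized", "random_walk"):
            # constant eigenvector (up to normalization)
            assert np.allclose(v0, v0[0])

    def test_disconnected_graph_has_zero_connectivity(self, graphs):
        sol = solve_affinity(graphs["disjoint_edges"], "standard")
        assert sol.eigenvalues[1] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("problem", ["standard", "generalized"])
    def test_residual_contract(self, rng, problem):
        w = random_affinity(rng, 10)
        aff = AffinityMatrix(w)
        lap = laplacian(aff, "unnormalized")
        sol = solve_eigenproblem(lap, problem=problem)
        L = lap.matrix
        B = np.diag(lap.degrees.degrees) if problem == "generalized" else np.eye(10)
        for i in range(10):
            res = L @ sol.eigenvectors[:, i] - sol.eigenvalues[i] * (
                B @ sol.eigenvectors[:, i]
            )
            assert np.linalg.norm(res) <= 1e-6 * np.linalg.norm(L)

    def test_generalized_constraint_is_degree_weighted(self, rng):
        w = random_affinity(rng, 8)
        lap = laplacian(AffinityMatrix(w), "unnormalized")
        sol = solve_eigenproblem(lap, problem="generalized")
        D = np.diag(lap.degrees.degrees)
        for i in range(8):
            x = sol.eigenvectors[:, i]
            assert x @ D @ x == pytest.approx(1.0, abs=1e-8)

    def test_singular_degree_raises(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        lap = laplacian(AffinityMatrix(w), "unnormalized")
        with pytest.raises(DegenerateDegreeError):
            solve_eigenproblem(lap, problem="generalized")

    def test_sign_convention_deterministic(self, rng):
        w = random_affinity(rng, 7)
        s1 = solve_affinity(AffinityMatrix(w), "standard")
        s2 = solve_affinity(AffinityMatrix(w.copy()), "standard")
        assert np.array_equal(s1.eigenvectors, s2.eigenvectors)
        for i in range(7):
            col = s1.eigenvectors[:, i]
            assert col[np.argmax(np.abs(col))] > 0


class TestFiedler:
    def test_path_graph_closed_form(self, graphs):
        lam, vec = fiedler(solve_affinity(graphs["path3"], "standard"))
        assert lam == pytest.approx(1.0, abs=1e-8)
        # proportional to (1, 0, -1) up to sign convention
        assert vec[1] == pytest.approx(0.0, abs=1e-8)
        assert vec[0] == pytest.approx(-vec[2], abs=1e-8)

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_complete_graph_connectivity_equals_n(self, n):
        aff = AffinityMatrix(np.ones((n, n)) - np.eye(n))
        lam, _ = fiedler(solve_affinity(aff, "standard"))
        assert lam == pytest.approx(n, rel=1e-10)

    def test_disconnected_connectivity_zero(self, graphs):
        lam, _ = fiedler(solve_affinity(graphs["disjoint_edges"], "standard"))
        assert lam == pytest.approx(0.0, abs=1e-8)

    def test_degeneracy_flag_on_complete_graph(self):
        aff = AffinityMatrix(np.ones((5, 5)) - np.eye(5))
        sol = solve_affinity(aff, "standard")
        assert sol.degenerate_fiedler  # lambda_2 = ... = lambda_n = 5

    def test_block_affinity_sign_partitions_blocks(self, rng):
        # two blocks of 5, within-weight 1, cross-weight 0.1
        w = np.full((10, 10), 0.1)
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        np.fill_diagonal(w, 0.0)
        _, vec = fiedler(solve_affinity(AffinityMatrix(w), "standard"))
        signs = np.sign(vec)
        assert len(set(signs[:5])) == 1
        assert len(set(signs[5:])) == 1
        assert signs[0] != signs[5]


class TestVariationalOracles:
    def test_rayleigh_quotient_bounds_fiedler(self, rng):
        """lambda_2 minimizes v'Lv / v'Bv over the B-orthogonal complement
        of the trivial eigenvector."""
        for problem in ("standard", "generalized"):
            w = random_affinity(rng, 8)
            lap = laplacian(AffinityMatrix(w), "unnormalized")
            L = lap.matrix
            d = lap.degrees.degrees
            B = np.eye(8) if problem == "standard" else np.diag(d)
            sol = solve_eigenproblem(lap, problem=problem)
            lam2 = sol.eigenvalues[1]
            v0 = sol.eigenvectors[:, 0]
            for _ in range(100):
                v = rng.standard_normal(8)
                v -= (v @ B @ v0) / (v0 @ B @ v0) * v0
                q = (v @ L @ v) / (v @ B @ v)
                assert q >= lam2 - 1e-8

    def test_cost_identity_double_loop(self, rng):
        """x'Lx equals the weighted sum of squared embedding distances."""
        for _ in range(20):
            n = int(rng.integers(3, 9))
            w = random_affinity(rng, n)
            L = laplacian(AffinityMatrix(w), "unnormalized").matrix
            x = rng.standard_normal(n)
            direct = sum(
                w[i, j] * (x[i] - x[j]) ** 2
                for i in range(n)
                for j in range(i + 1, n)
            )
            assert x @ L @ x == pytest.approx(direct, abs=1e-8)

    def test_generalized_equals_random_walk_spectrum(self, rng):
        w = random_affinity(rng, 9)
        lap = laplacian(AffinityMatrix(w), "unnormalized")
        gen = solve_eigenproblem(lap, problem="generalized").eigenvalues
        d = lap.degrees.degrees
        rw = np.sort(np.linalg.eigvals(lap.matrix / d[:, None]).real)
        assert np.allclose(gen, rw, atol=1e-8)


class TestReorderAndMaps:
    def test_rank_examples(self):
        assert np.array_equal(spectral_reorder([0.3, -0.1, 0.7]), [2, 1, 3])

    def test_monotone_invariance(self, rng):
        v = rng.standard_normal(20)
        assert np.array_equal(spectral_reorder(v), spectral_reorder(np.exp(v)))

    def test_ties_broken_by_node_index(self):
        ranks = spectral_reorder([0.5, 0.2, 0.5, 0.1])
        # stable sort: first 0.5 (index 0) ranks before second (index 2)
        assert np.array_equal(ranks, [3, 2, 4, 1])

    def test_eigenmap_coords_slicing(self, graphs):
        sol = solve_affinity(graphs["fig1"], "standard")
        c1 = eigenmap_coords(sol, 1)
        assert np.array_equal(c1[:, 0], fiedler(sol)[1])
        c3 = eigenmap_coords(sol, 3)
        assert np.array_equal(c3, sol.eigenvectors[:, 1:4])
        with pytest.raises(ParameterError):
            eigenmap_coords(sol, 4)

    def test_full_basis_b_orthogonal(self, rng):
        w = random_affinity(rng, 7)
        sol = solve_affinity(AffinityMatrix(w), "generalized")
        coords = eigenmap_coords(sol, 6)
        D = np.diag(w.sum(axis=1))
        gram = coords.T @ D @ coords
        assert np.allclose(gram, np.eye(6), atol=1e-8)

    def test_rgb_scaling_rules(self):
        coords = np.array([[-1.0, 5.0, 0.0], [0.0, 5.0, 1.0], [1.0, 5.0, 2.0]])
        rgb = rgb_map(coords)
        assert np.allclose(rgb[:, 0], [0, 0.5, 1])
        assert np.allclose(rgb[:, 1], 0.5)  # constant column
        assert np.allclose(rgb[:, 2], [0, 0.5, 1])

    def test_rgb_permutation_equivariance(self, rng):
        coords = rng.standard_normal((10, 3))
        perm = rng.permutation(10)
        assert np.allclose(rgb_map(coords[perm]), rgb_map(coords)[perm])

    def test_gradient_map_bundle(self, rng):
        w = random_affinity(rng, 8)
        sol = solve_affinity(AffinityMatrix(w), "generalized")
        gm = gradient_map(sol, 3)
        assert gm.coords.shape == (8, 3)
        assert sorted(gm.ranks) == list(range(1, 9))
        assert gm.rgb.shape == (8, 3)
        assert gm.rgb.min() == 0.0 and gm.rgb.max() == 1.0
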