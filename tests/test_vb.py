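"""The VB index and its three analysis modes."""

import numpy as np
import pytest

from vbgrad import (
    AffinityMatrix,
    AffinityPolicy,
    SyntheticSpec,
    clustered_analysis,
    full_analysis,
    make_icosphere,
    one_ring,
    parcel_timeseries,
    parcellate_mesh,
    searchlight_analysis,
    vb_index,
)
from vbgrad.exceptions import ShapeError

from conftest import random_affinity


class TestVBIndex:
    @pytest.mark.parametrize("problem", ["standard", "generalized",
                                         "symmetric_normalized", "random_walk"])
    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_uniform_complete_graph_is_one(self, n, problem):
        # closed forms: spectrum {0, n, ..., n} (standard) and
        # {0, n/(n-1), ...} (generalized); the ratio is 1 in both
        aff = AffinityMatrix(np.ones((n, n)) - np.eye(n))
        assert vb_index(aff, problem) == pytest.approx(1.0, abs=1e-10)

    def test_disconnected_graph_is_zero(self, graphs):
        for problem in ("standard", "generalized"):
            assert vb_index(graphs["disjoint_edges"], problem) == pytest.approx(
                0.0, abs=1e-8
            )

    def test_four_node_graph_standard_value(self, graphs):
        # eigenvalues {0, 1, 3, 4}: 1 / mean(1, 3, 4) = 0.375
        assert vb_index(graphs["fig1"], "standard") == pytest.approx(0.375, abs=1e-10)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            w = random_affinity(rng, int(rng.integers(4, 10)))
            aff = AffinityMatrix(w)
            scale = float(rng.uniform(0.01, 100))
            for problem in ("standard", "generalized"):
                assert vb_index(AffinityMatrix(w * scale), problem) == pytest.approx(
                    vb_index(aff, problem), abs=1e-8
                )

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            w = random_affinity(rng, int(rng.integers(3, 12)),
                                density=float(rng.uniform(0.3, 1)))
            if w.sum() == 0:
                continue
            for problem in ("standard", "generalized"):
                if problem == "generalized" and np.any(w.sum(axis=1) == 0):
                    continue
                vb = vb_index(AffinityMatrix(w), problem)
                assert -1e-8 <= vb <= 1 + 1e-8

    def test_monotone_in_cross_block_weight(self):
        # two-block neighborhood: VB rises as the cross weight approaches
        # the within weight
        def two_block(c):
            w = np.full((6, 6), c)
            w[:3, :3] = 1.0
            w[3:, 3:] = 1.0
            np.fill_diagonal(w, 0.0)
            return AffinityMatrix(w)

        values = [vb_index(two_block(c), "generalized")
                  for c in np.linspace(0.0, 1.0, 11)]
        assert np.all(np.diff(values) > 0)
        assert values[0] == pytest.approx(0.0, abs=1e-8)
        assert values[-1] == pytest.approx(1.0, abs=1e-8)

    def test_isolated_node_means_disconnected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert vb_index(AffinityMatrix(w), "generalized") == 0.0

    def test_empty_graph_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no edges"):
            assert vb_index(AffinityMatrix(np.zeros((4, 4))), "standard") == 0.0

    def test_too_small_raises(self):
        with pytest.raises(ShapeError):
            vb_index(AffinityMatrix(np.array([[0.0, 1.0], [1.0, 0.0]])))


@pytest.fixture(scope="module")
def parcel_data():
    mesh = make_icosphere(2)  # 162 vertices
    labels = parcellate_mesh(mesh, 6, seed=7)
    feats = parcel_timeseries(labels, SyntheticSpec(seed=7, series_length=120))
    return mesh, labels, feats


class TestFullAnalysis:
    def test_six_parcels_give_six_fiedler_levels(self, parcel_data):
        _, labels, feats = parcel_data
        res = full_analysis(feats, problem="generalized", d=1)
        fv = np.sort(res.gradient.coords[:, 0])
        distinct = 1 + int((np.diff(fv) > 1e-6).sum())
        assert distinct == 6
        # piecewise constant within parcels
        for cid in labels.cluster_ids():
            vals = res.gradient.coords[labels.labels == cid, 0]
            assert np.ptp(vals) < 1e-6

    def test_identical_series_everywhere_give_vb_one(self, rng):
        feats = np.tile(rng.standard_normal(50), (10, 1))
        res = full_analysis(feats)
        assert res.vb == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_halves_give_vb_zero(self, rng):
        a = rng.standard_normal(40)
        a -= a.mean()
        b = rng.standard_normal(40)
        b -= b.mean()
        b -= (b @ a) / (a @ a) * a  # exactly centered-orthogonal
        feats = np.vstack([np.tile(a, (4, 1)), np.tile(b, (4, 1))])
        res = full_analysis(feats, problem="standard")
        assert res.vb == pytest.approx(0.0, abs=1e-6)


class TestClusteredAnalysis:
    def test_single_cluster_matches_full(self, parcel_data):
        _, _, feats = parcel_data
        full = full_analysis(feats)
        clus = clustered_analysis(feats, np.ones(feats.n, dtype=int))
        assert clus.vb[1] == pytest.approx(full.vb, abs=1e-10)

    def test_true_labels_give_unit_vb_per_cluster(self, parcel_data):
        _, labels, feats = parcel_data
        res = clustered_analysis(feats, labels.labels)
        assert set(res.vb) == set(labels.cluster_ids().tolist())
        for v in res.vb.values():
            assert v == pytest.approx(1.0, abs=1e-8)
        defined = ~np.isnan(res.vertex_vb)
        assert defined.all()
        assert np.allclose(res.vertex_vb, 1.0, atol=1e-8)

    def test_small_cluster_missing_with_warning(self, rng):
        feats = rng.standard_normal((8, 30))
        labels = np.array([1, 1, 1, 1, 1, 1, 2, 2])
        with pytest.warns(UserWarning, match="cluster 2"):
            res = clustered_analysis(feats, labels)
        assert np.isnan(res.vb[2])
        assert not np.isnan(res.vb[1])


class TestSearchlight:
    def test_interior_one_boundary_below_one(self, parcel_data):
        mesh, labels, feats = parcel_data
        res = searchlight_analysis(feats, mesh)
        ring = one_ring(mesh)
        lab = labels.labels
        interior = np.array(
            [np.all(lab[ring[v]] == lab[v]) for v in range(mesh.n_vertices)]
        )
        assert np.allclose(res.vertex_vb[interior], 1.0, atol=1e-6)
        # edge-detection contract: below-1 vertices are exactly the border set
        assert np.array_equal(res.vertex_vb < 1 - 1e-6, ~interior)

    def test_neighborhood_sizes_on_icosphere(self, parcel_data):
        mesh, _, feats = parcel_data
        res = searchlight_analysis(feats, mesh)
        assert set(res.neighborhood_sizes.tolist()) <= {6, 7}  # 5 or 6 + center

    def test_mask_borders_yield_missing_not_error(self, parcel_data):
        mesh, _, feats = parcel_data
        mask = np.ones(mesh.n_vertices, dtype=bool)
        mask[: mesh.n_vertices // 2] = False
        res = searchlight_analysis(feats, mesh, mask)
        assert np.all(np.isnan(res.vertex_vb[~mask]))
        assert np.isfinite(res.vertex_vb[mask]).sum() > 0

    def test_parallel_equals_serial(self, parcel_data):
        mesh, _, feats = parcel_data
        serial = searchlight_analysis(feats, mesh, jobs=1)
        parallel = searchlight_analysis(feats, mesh, jobs=2)
        assert np.array_equal(
            np.nan_to_num(serial.vertex_vb, nan=-1),
            np.nan_to_num(parallel.vertex_vb, nan=-1),
        )

    def test_feature_mesh_mismatch_raises(self, parcel_data, rng):
        mesh, _, _ = parcel_data
        with pytest.raises(ShapeError):
            searchlight_analysis(rng.standard_normal((10, 20)), mesh)


class TestNoiseSensitivity:
    def test_noise_strictly_lowers_interior_vb(self):
        mesh = make_icosphere(2)
        labels = parcellate_mesh(mesh, 4, seed=3)
        clean = parcel_timeseries(labels, SyntheticSpec(n_parcels=4, seed=3))
        noisy = parcel_timeseries(
            labels, SyntheticSpec(n_parcels=4, noise_sd=0.5, seed=3)
        )
        ring = one_ring(mesh)
        lab = labels.labels
        interior = np.array(
            [np.all(lab[ring[v]] == lab[v]) for v in range(mesh.n_vertices)]
        )
        vb_clean = searchlight_analysis(clean, mesh).vertex_vb
        vb_noisy = searchlight_analysis(noisy, mesh).vertex_vb
        assert np.nanmean(vb_noisy[interior]) < np.nanmean(vb_clean[interior])
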