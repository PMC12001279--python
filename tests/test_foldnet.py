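"""Curvature, fold masks, skeleton networks, metrics and thickness."""

import networkx as nx
import numpy as np
import pytest
import trimesh
from scipy.spatial import Delaunay

from morphofold import foldnet as fn


def _grid_sheet(f, xmax=2.0, ymax=1.0, nx=81, ny=41, flip_up=True):
    gx = np.linspace(0, xmax, nx)
    gy = np.linspace(0, ymax, ny)
    X, Y = np.meshgrid(gx, gy)
    V = np.c_[X.ravel(), Y.ravel(), f(X.ravel(), Y.ravel())]
    tri = Delaunay(V[:, :2]).simplices
    mesh = trimesh.Trimesh(V, tri, process=False)
    if flip_up and mesh.vertex_normals[:, 2].mean() < 0:
        mesh.invert()
    return mesh


@pytest.fixture(scope="module")
def sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="module")
def plane():
    return _grid_sheet(lambda x, y: np.zeros_like(x), xmax=1.0, nx=21, ny=21)


@pytest.fixture(scope="module")
def sine_sheet():
    A, k = 0.05, 2 * np.pi / 0.5
    return _grid_sheet(lambda x, y: A * np.sin(k * x))


class TestCurvature:
    def test_unit_sphere_outward_normals_positive_curvature(self, sphere):
        c = fn.min_principal_curvature(sphere)
        assert np.allclose(c.kappa_min, 1.0, atol=0.05)
        assert np.allclose(c.kappa_max, 1.0, atol=0.05)

    def test_plane_is_flat(self, plane):
        c = fn.min_principal_curvature(plane)
        assert np.abs(c.kappa_min).max() < 1e-8

    def test_sine_trough_curvature(self, sine_sheet):
        A, k = 0.05, 2 * np.pi / 0.5
        V = np.asarray(sine_sheet.vertices)
        c = fn.min_principal_curvature(sine_sheet)
        trough = (
            np.isclose(np.sin(k * V[:, 0]), -1, atol=0.02)
            & (V[:, 1] > 0.2)
            & (V[:, 1] < 0.8)
            & (V[:, 0] > 0.2)
            & (V[:, 0] < 1.8)
        )
        assert trough.sum() > 10
        assert c.kappa_min[trough].mean() == pytest.approx(-A * k**2, rel=0.15)

    def test_non_manifold_rejected(self):
        V = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]], dtype=float
        )
        F = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) in 3 faces
        with pytest.raises(ValueError, match="manifold"):
            fn.min_principal_curvature(trimesh.Trimesh(V, F, process=False))


class TestFoldMask:
    def test_plane_has_empty_mask(self, plane):
        c = fn.min_principal_curvature(plane)
        assert fn.extract_fold_mask(c, 0.3).sum() == 0

    def test_quantile_bounds_selection(self, sine_sheet):
        c = fn.min_principal_curvature(sine_sheet)
        mask = fn.extract_fold_mask(c, 0.3)
        assert 0 < mask.sum() <= 0.3 * len(mask) + 1

    def test_mask_bands_centred_on_troughs(self, sine_sheet):
        k = 2 * np.pi / 0.5
        V = np.asarray(sine_sheet.vertices)
        c = fn.min_principal_curvature(sine_sheet)
        mask = fn.extract_fold_mask(c, 0.3)
        # all masked vertices lie in the concave half of the wave
        assert np.all(np.sin(k * V[mask, 0]) < 0)


class TestSkeleton:
    def test_straight_band_gives_midline_edge(self):
        m = np.zeros((40, 120), dtype=bool)
        m[17:24, 8:112] = True
        net = fn.network_from_raster_mask(m, pixel_size=0.1)
        net = fn.simplify_network(net, spur_fraction=0.01)
        assert net.graph.number_of_edges() == 1
        (u, v) = list(net.graph.edges)[0]
        pl = fn.oriented_polyline(net.graph, u, v)
        # midline row is 20 -> y = 2.0, within one raster cell
        assert np.abs(pl[:, 1] - 2.0).max() <= 0.1 + 1e-9
        assert net.graph.edges[u, v]["length"] == pytest.approx(0.1 * 104, rel=0.08)

    def test_annulus_gives_single_cycle_with_right_perimeter(self):
        n = 201
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - 100, yy - 100)
        mask = (r > 55) & (r < 72)
        net = fn.simplify_network(
            fn.network_from_raster_mask(mask, pixel_size=0.01), 0.01
        )
        assert len(net.cycles) == 1
        assert net.total_cycle_perimeter == pytest.approx(
            2 * np.pi * 63.5 * 0.01, rel=0.05
        )
        assert net.total_incomplete_length == 0.0

    def test_empty_mask_gives_empty_network(self, plane):
        c = fn.min_principal_curvature(plane)
        mask = fn.extract_fold_mask(c, 0.3)
        net = fn.skeletonize_fold_mask(plane, mask, 2)
        assert net.graph.number_of_edges() == 0
        mv = fn.compute_metrics(net)
        assert (mv.c1, mv.c2) == (0.0, 0.0)


def _square_net(side=1.0, L=5.0):
    G = nx.Graph()
    sq = np.array([[0, 0], [side, 0], [side, side], [0, side]])
    for i in range(4):
        fn.add_network_edge(G, i, (i + 1) % 4, np.array([sq[i], sq[(i + 1) % 4]]))
    return fn.FoldNetwork(G, toepad_length=L)


def _chain_net(n_nodes=100, L=5.0):
    G = nx.Graph()
    xs = np.linspace(0, 2.0, n_nodes)
    for i in range(n_nodes - 1):
        fn.add_network_edge(
            G, i, i + 1, np.array([[xs[i], 0.3 * np.sin(xs[i])], [xs[i + 1], 0.3 * np.sin(xs[i + 1])]])
        )
    return fn.FoldNetwork(G, toepad_length=L)


class TestSimplify:
    def test_chain_merges_to_single_edge_conserving_length(self):
        net = _chain_net()
        total = net.total_length
        simp = fn.simplify_network(net, spur_fraction=0.001)
        assert simp.graph.number_of_edges() == 1
        assert simp.total_length == pytest.approx(total, abs=1e-9)

    def test_short_spur_pruned_cycle_kept(self):
        net = _square_net()
        G = net.graph.copy()
        fn.add_network_edge(G, 0, 99, np.array([[0.0, 0.0], [-0.02, -0.02]]))
        spurred = fn.FoldNetwork(G, net.toepad_length)
        simp = fn.simplify_network(spurred, spur_fraction=0.02)
        assert len(simp.cycles) == 1
        assert simp.total_incomplete_length == 0.0

    def test_idempotent(self):
        net = _chain_net(30)
        once = fn.simplify_network(net, 0.02)
        twice = fn.simplify_network(once, 0.02)
        assert once.graph.number_of_nodes() == twice.graph.number_of_nodes()
        assert once.total_length == pytest.approx(twice.total_length, abs=1e-12)


class TestMetrics:
    def test_square_cycle(self):
        mv = fn.compute_metrics(_square_net(side=1.0, L=5.0))
        assert (mv.c1, mv.c2) == (4.0 / 5.0, 0.0)

    def test_open_path(self):
        G = nx.Graph()
        fn.add_network_edge(G, 0, 1, np.array([[0, 0], [0.7, 0]]))
        mv = fn.compute_metrics(fn.FoldNetwork(G, 5.0))
        assert (mv.c1, mv.c2) == (0.0, 0.7 / 5.0)

    def test_empty_network(self):
        mv = fn.compute_metrics(fn.FoldNetwork(nx.Graph(), 5.0))
        assert (mv.c1, mv.c2) == (0.0, 0.0)

    def test_spur_inside_cycle_counts_as_incomplete(self):
        net = _square_net()
        G = net.graph.copy()
        fn.add_network_edge(G, 0, 50, np.array([[0.0, 0.0], [0.4, 0.4]]))
        mv = fn.compute_metrics(fn.FoldNetwork(G, 5.0))
        assert mv.c1 == pytest.approx(4.0 / 5.0)
        assert mv.c2 == pytest.approx(np.hypot(0.4, 0.4) / 5.0)

    def test_rigid_motion_invariance(self):
        base = _square_net()
        mv0 = fn.compute_metrics(base)
        for ang, shift in [(0.3, (2.0, -1.0)), (1.2, (0.0, 5.0)), (-0.7, (-3.0, 0.4))]:
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            G = nx.Graph()
            for u, v in base.graph.edges:
                pl = fn.oriented_polyline(base.graph, u, v) @ R.T + shift
                fn.add_network_edge(G, u, v, pl)
            mv = fn.compute_metrics(fn.FoldNetwork(G, base.toepad_length))
            assert mv.c1 == pytest.approx(mv0.c1, rel=1e-9)
            assert mv.c2 == pytest.approx(mv0.c2, rel=1e-9)

    def test_uniform_scaling_invariance(self):
        base = _square_net()
        mv0 = fn.compute_metrics(base)
        s = 3.7
        G = nx.Graph()
        for u, v in base.graph.edges:
            fn.add_network_edge(G, u, v, s * fn.oriented_polyline(base.graph, u, v))
        mv = fn.compute_metrics(fn.FoldNetwork(G, s * base.toepad_length))
        assert mv.c1 == pytest.approx(mv0.c1, rel=1e-12)
        assert mv.c2 == pytest.approx(mv0.c2, rel=1e-12)


class TestNormalizer:
    def _samples(self, rng):
        return [
            fn.MetricVector(c1=float(a), c2=float(b))
            for a, b in rng.uniform(0.1, 3.0, size=(6, 2))
        ]

    def test_fitting_set_standardized(self, rng):
        samples = self._samples(rng)
        norm = fn.fit_normalizer(samples)
        z = np.array([fn.normalize(s, norm).as_array() for s in samples])
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_identity_normalizer(self):
        norm = fn.Normalizer(mean=np.zeros(2), sd=np.ones(2))
        v = fn.MetricVector(1.3, 0.4)
        assert np.allclose(fn.normalize(v, norm).as_array(), v.as_array())

    def test_mean_maps_to_origin(self, rng):
        samples = self._samples(rng)
        norm = fn.fit_normalizer(samples)
        v = fn.MetricVector(*norm.mean)
        assert np.allclose(fn.normalize(v, norm).as_array(), 0.0)

    def test_too_few_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fn.fit_normalizer([fn.MetricVector(1, 2)])
        with pytest.raises(ValueError):
            fn.fit_normalizer([fn.MetricVector(1, 2), fn.MetricVector(1, 3)])


class TestDistance:
    def test_metric_properties(self, rng):
        norm = fn.Normalizer(mean=np.array([1.0, 0.5]), sd=np.array([0.7, 0.3]))
        vs = [fn.MetricVector(*xy) for xy in rng.uniform(0, 3, size=(12, 2))]
        for a in vs[:4]:
            assert fn.network_distance(a, a, norm) == 0.0
        for a, b, c in zip(vs[:4], vs[4:8], vs[8:12]):
            dab = fn.network_distance(a, b, norm)
            assert dab == pytest.approx(fn.network_distance(b, a, norm))
            assert dab >= 0
            assert dab <= fn.network_distance(a, c, norm) + fn.network_distance(
                c, b, norm
            ) + 1e-12


class TestLayerThickness:
    def test_concentric_spheres(self):
        outer = trimesh.creation.icosphere(3, radius=1.0)
        inner = trimesh.creation.icosphere(3, radius=0.9)
        t = fn.layer_thickness(outer, inner)
        assert np.allclose(t, 0.1, rtol=0.02)

    def test_identical_surfaces(self, plane):
        assert fn.layer_thickness(plane, plane).max() < 1e-12

    def test_parallel_planes(self):
        a = _grid_sheet(lambda x, y: np.zeros_like(x), xmax=1.0, nx=21, ny=21)
        b = _grid_sheet(lambda x, y: np.full_like(x, 0.25), xmax=1.0, nx=21, ny=21)
        t = fn.layer_thickness(a, b)
        assert np.allclose(t, 0.25, atol=1e-9)


class TestPipelineOnSlab:
    def test_unbuckled_slab_gives_zero_metrics(self, small_slab):
        surf = fn.epidermis_surface(small_slab, small_slab.points)
        net = fn.extract_fold_network(surf, quantile=0.3)
        mv = fn.compute_metrics(net)
        assert (mv.c1, mv.c2) == (0.0, 0.0)


class TestMetricScalingProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.05, 50.0))
    def test_joint_scaling_leaves_metrics_unchanged(self, scale):
        base = _square_net()
        G = nx.Graph()
        fn.add_network_edge(G, 10, 11, np.array([[2.0, 2.0], [2.9, 2.4]]))
        for u, v in base.graph.edges:
            fn.add_network_edge(G, u, v, fn.oriented_polyline(base.graph, u, v))
        mv0 = fn.compute_metrics(fn.FoldNetwork(G, 5.0))
        H = nx.Graph()
        for u, v in G.edges:
            fn.add_network_edge(H, u, v, scale * fn.oriented_polyline(G, u, v))
        mv = fn.compute_metrics(fn.FoldNetwork(H, scale * 5.0))
        assert mv.c1 == pytest.approx(mv0.c1, rel=1e-9)
        assert mv.c2 == pytest.approx(mv0.c2, rel=1e-9)
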