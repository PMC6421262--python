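"""Synthetic geometry: closedness, orientation, areas, geodesics, torso."""

import numpy as np
import pytest

from ectoloc import (
    HeartModel,
    TriangleMesh,
    generate_heart,
    generate_torso,
    geodesic_distance,
    geodesic_distances,
)
from ectoloc.geometry import RegionSpec, ellipsoid_surface


class TestGeneratedHeart:
    def test_closed_genus_zero_surface(self, small_heart):
        mesh = small_heart.mesh
        assert mesh.is_closed()
        assert mesh.euler_characteristic() == 2

    def test_outward_orientation(self, small_heart):
        assert small_heart.mesh.signed_volume() > 0

    def test_wall_volume_close_to_analytic_shells(self):
        h = generate_heart(n_subdiv=3, seed=0, jitter=0.0)
        analytic = 2.0 / 3.0 * np.pi * (50**2 * 90 - 40**2 * 80)
        assert abs(h.mesh.signed_volume() - analytic) / analytic < 0.05

    def test_deterministic_for_fixed_seed(self):
        a = generate_heart(n_subdiv=2, seed=42)
        b = generate_heart(n_subdiv=2, seed=42)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.triangles, b.mesh.triangles)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            generate_heart(long_axis=5.0, short_axis=50.0, wall_thickness=10.0)
        with pytest.raises(ValueError):
            generate_heart(wall_thickness=0.0)

    def test_labels_partition_and_transmural_flags(self, small_heart):
        labels = small_heart.mesh.vertex_labels
        assert set(labels) == {"epi", "endo", "unlabeled"}
        i, j = small_heart.edge_index.T
        trans = small_heart.edge_transmural
        pairs = np.stack([labels[i[trans]], labels[j[trans]]], axis=1)
        for a, b in pairs:
            assert {a, b} == {"epi", "endo"}

    def test_closedness_check_rejects_mesh_with_deleted_triangle(self, small_heart):
        mesh = small_heart.mesh
        broken = TriangleMesh(mesh.vertices, mesh.triangles[1:],
                              mesh.vertex_labels)
        assert not broken.is_closed()
        with pytest.raises(ValueError, match="closed"):
            HeartModel(mesh=broken)


class TestNodeAreas:
    def test_vertex_area_is_third_of_incident_triangles(self, small_heart):
        mesh = small_heart.mesh
        areas = mesh.triangle_areas()
        v = 17
        incident = np.any(mesh.triangles == v, axis=1)
        expected = areas[incident].sum() / 3.0
        assert np.isclose(small_heart.node_areas[v], expected, rtol=1e-12)

    def test_total_area_conserved(self, small_heart):
        total = small_heart.mesh.triangle_areas().sum()
        assert np.isclose(small_heart.node_areas.sum(), total, rtol=1e-9)
        assert np.all(small_heart.node_areas > 0)


def _bellman_ford(n, edges, source):
    """Independent exhaustive-relaxation oracle (no scipy)."""
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    for _ in range(n):
        changed = False
        for i, j, w in edges:
            if dist[i] + w < dist[j]:
                dist[j] = dist[i] + w
                changed = True
            if dist[j] + w < dist[i]:
                dist[i] = dist[j] + w
                changed = True
        if not changed:
            break
    return dist


class TestGeodesics:
    def test_identity_and_adjacent_edge(self, small_heart):
        assert geodesic_distance(small_heart, 5, 5) == 0.0
        i, j = small_heart.edge_index[10]
        if not small_heart.edge_transmural[10]:
            d = geodesic_distance(small_heart, int(i), int(j))
            assert d <= small_heart.edge_lengths[10] + 1e-12

    def test_matches_bellman_ford_oracle(self):
        heart = generate_heart(n_subdiv=1, seed=3)  # <= 200 nodes
        keep = ~heart.edge_transmural
        edges = [(int(i), int(j), float(w)) for (i, j), w in
                 zip(heart.edge_index[keep], heart.edge_lengths[keep])]
        for source in (0, 7, heart.n_nodes - 1):
            oracle = _bellman_ford(heart.n_nodes, edges, source)
            mine = geodesic_distances(heart, source)
            assert np.allclose(mine, oracle, rtol=1e-12, atol=1e-12)

    def test_symmetry_and_euclidean_lower_bound(self, small_heart):
        v = small_heart.mesh.vertices
        for i, j in [(0, 50), (10, 200), (3, 301)]:
            dij = geodesic_distance(small_heart, i, j)
            dji = geodesic_distance(small_heart, j, i)
            assert np.isclose(dij, dji, rtol=1e-12)
            assert dij >= np.linalg.norm(v[i] - v[j]) - 1e-9

    def test_triangle_inequality_exhaustive_small_mesh(self):
        heart = generate_heart(n_subdiv=1, seed=0)  # ~100 nodes
        n = heart.n_nodes
        d = np.vstack([geodesic_distances(heart, s) for s in range(n)])
        via = np.min(d[:, :, None] + d[None, :, :], axis=1)
        assert np.all(d <= via + 1e-9)

    def test_epi_to_endo_routes_through_rim_not_connectors(self, small_heart):
        labels = small_heart.mesh.vertex_labels
        epi = int(np.flatnonzero(labels == "epi")[0])
        endo = int(np.flatnonzero(labels == "endo")[10])
        geo = geodesic_distance(small_heart, epi, endo)
        assert np.isfinite(geo)
        # the direct wall crossing (~wall thickness) is excluded, so the
        # on-surface route must be much longer than the wall is thick
        assert geo > 10.0

    def test_out_of_range_indices(self, small_heart):
        with pytest.raises(IndexError):
            geodesic_distance(small_heart, -1, 2)
        with pytest.raises(IndexError):
            geodesic_distances(small_heart, small_heart.n_nodes)


class TestTorso:
    def test_electrode_counts_and_positions_outside(self, small_heart):
        torso = generate_torso(small_heart, n_electrodes=240, standoff=40.0, seed=0)
        assert torso.n_electrodes == 240
        from ectoloc.forward import point_inside_surface
        for e in torso.electrode_positions[::24]:
            assert not point_inside_surface(small_heart.mesh, e)

    def test_minimal_layout(self, small_heart):
        torso = generate_torso(small_heart, n_electrodes=2, standoff=40.0, seed=0)
        assert torso.n_electrodes == 2

    def test_deterministic(self, small_heart):
        a = generate_torso(small_heart, 16, 40.0, seed=9)
        b = generate_torso(small_heart, 16, 40.0, seed=9)
        assert np.array_equal(a.electrode_positions, b.electrode_positions)

    def test_invalid_parameters_rejected(self, small_heart):
        with pytest.raises(ValueError):
            generate_torso(small_heart, n_electrodes=1, standoff=40.0)
        with pytest.raises(ValueError):
            generate_torso(small_heart, n_electrodes=8, standoff=0.0)

    def test_torso_surface_closed(self, small_torso):
        assert small_torso.surface is not None
        assert small_torso.surface.is_closed()
        assert small_torso.surface.signed_volume() > 0


class TestRegionSpec:
    def test_contains_midpoint_semantics(self):
        r = RegionSpec(center=(0, 0, 0), radius=2.0, cv_factor=0.5)
        assert r.contains(np.array([[1.0, 0, 0], [3.0, 0, 0]])).tolist() == [True, False]

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec(center=(0, 0, 0), radius=0.0, cv_factor=1.0)
        with pytest.raises(ValueError):
            RegionSpec(center=(0, 0, 0), radius=1.0, cv_factor=-1.0)


def test_ellipsoid_surface_closed_and_oriented():
    m = ellipsoid_surface((1, 2, 3), (10, 12, 8), n_theta=10, n_phi=14)
    assert m.is_closed()
    assert m.euler_characteristic() == 2
    # volume within a few percent of the analytic ellipsoid
    analytic = 4.0 / 3.0 * np.pi * 10 * 12 * 8
    assert abs(m.signed_volume() - analytic) / analytic < 0.1
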