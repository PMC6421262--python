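"""Conduction graph, times matrix and activation sequences."""

import numpy as np
import pytest

from ectoloc import (
    ActivationSequence,
    RegionSpec,
    activation_from_focus,
    build_conduction_graph,
    combine_earliest,
    compute_times_matrix,
    geodesic_distances,
    scale_activation_duration,
)
from ectoloc.propagation import ConductionGraph, TimesMatrix


def _floyd_warshall(n, edge_index, edge_times):
    """Independent all-pairs oracle."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (i, j), t in zip(edge_index, edge_times):
        d[i, j] = min(d[i, j], t)
        d[j, i] = min(d[j, i], t)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


class TestEdgeTimes:
    def test_surface_edge_at_global_cv(self, small_heart):
        g = build_conduction_graph(small_heart, cv_global=0.8)
        surf = ~small_heart.edge_transmural
        # 0.8 m/s == 0.8 mm/ms, so a 0.8 mm edge costs exactly 1 ms
        expected = small_heart.edge_lengths[surf] / 0.8
        assert np.allclose(g.edge_times[surf], expected, rtol=1e-12)

    def test_transmural_edge_costs_twice_tangential(self, small_heart):
        g = build_conduction_graph(small_heart, cv_global=0.8,
                                   transmural_factor=0.5)
        trans = small_heart.edge_transmural
        tangential_equiv = small_heart.edge_lengths[trans] / 0.8
        assert np.allclose(g.edge_times[trans], 2.0 * tangential_equiv, rtol=1e-12)

    def test_slow_region_scales_by_reciprocal_factor(self, small_heart):
        g0 = build_conduction_graph(small_heart)
        v = small_heart.mesh.vertices
        mid = 0.5 * (v[small_heart.edge_index[:, 0]] + v[small_heart.edge_index[:, 1]])
        center = mid[0]
        region = RegionSpec(center=tuple(center), radius=15.0, cv_factor=1.0 / 3.0)
        g1 = build_conduction_graph(small_heart, regions=[region])
        inside = region.contains(mid)
        assert inside.any() and not inside.all()
        assert np.allclose(g1.edge_times[inside], 3.0 * g0.edge_times[inside],
                           rtol=1e-12)
        assert np.allclose(g1.edge_times[~inside], g0.edge_times[~inside],
                           rtol=1e-12)

    def test_invalid_parameters_rejected(self, small_heart):
        with pytest.raises(ValueError):
            build_conduction_graph(small_heart, cv_global=0.0)
        with pytest.raises(ValueError):
            build_conduction_graph(small_heart, transmural_factor=-1.0)


class TestTimesMatrix:
    def _chain(self):
        return ConductionGraph(edge_index=np.array([[0, 1], [1, 2]]),
                               edge_times=np.array([1.0, 1.0]),
                               n_nodes=3, cv_global=0.8)

    def test_three_node_chain(self):
        t = compute_times_matrix(self._chain())
        assert t.values[0, 2] == 2.0
        assert t.values[0, 1] == 1.0

    def test_equilateral_triangle(self):
        g = ConductionGraph(edge_index=np.array([[0, 1], [1, 2], [0, 2]]),
                            edge_times=np.ones(3), n_nodes=3, cv_global=0.8)
        t = compute_times_matrix(g).values
        off = t[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 50))
            m = int(rng.integers(n, 3 * n))
            edges = rng.integers(0, n, size=(m, 2))
            edges = edges[edges[:, 0] != edges[:, 1]]
            times = rng.uniform(0.1, 5.0, size=len(edges))
            # ensure connectivity with a spanning chain
            chain = np.column_stack([np.arange(n - 1), np.arange(1, n)])
            edge_index = np.vstack([chain, edges])
            edge_times = np.concatenate([rng.uniform(0.1, 5.0, n - 1), times])
            g = ConductionGraph(edge_index=edge_index, edge_times=edge_times,
                                n_nodes=n, cv_global=0.8)
            mine = compute_times_matrix(g).values
            oracle = _floyd_warshall(n, edge_index, edge_times)
            # tolerance covers float-summation order only; paths are identical
            assert np.allclose(mine, oracle, rtol=1e-9, atol=1e-9)

    def test_invariants_on_heart(self, small_times):
        t = small_times.values
        assert np.all(np.diag(t) == 0.0)
        assert np.allclose(t, t.T, rtol=1e-12)
        # triangle inequality on a sample of intermediate nodes
        for k in (0, 100, 250):
            assert np.all(t <= t[:, [k]] + t[[k], :] + 1e-9)

    def test_disconnected_pairs_signalled_as_inf(self):
        g = ConductionGraph(edge_index=np.array([[0, 1], [2, 3]]),
                            edge_times=np.array([1.0, 1.0]),
                            n_nodes=4, cv_global=0.8)
        t = compute_times_matrix(g).values
        assert np.isinf(t[0, 2])

    def test_slow_region_never_decreases_travel_times(self, small_heart):
        t0 = compute_times_matrix(build_conduction_graph(small_heart)).values
        center = small_heart.mesh.vertices.mean(axis=0)
        region = RegionSpec(center=tuple(center), radius=30.0, cv_factor=0.25)
        t1 = compute_times_matrix(
            build_conduction_graph(small_heart, regions=[region])).values
        assert np.all(t1 >= t0 - 1e-9)

    def test_uniform_cv_times_match_geodesics_within_surface(self, study_heart):
        """With uniform CV the fastest route between same-surface nodes is the
        on-surface geodesic (wall crossings at half speed are never shortcuts)."""
        times = compute_times_matrix(build_conduction_graph(study_heart, cv_global=0.8))
        labels = study_heart.mesh.vertex_labels
        epi = np.flatnonzero(labels == "epi")
        f = int(epi[3])
        geo = geodesic_distances(study_heart, f)
        tau = times.values[f]
        assert np.allclose(tau[epi], geo[epi] / 0.8, rtol=1e-9)


class TestActivationSequences:
    def test_from_focus_is_times_row(self, small_times):
        act = activation_from_focus(small_times, 7)
        assert act.tau[7] == 0.0
        assert np.array_equal(act.tau, small_times.values[7])

    def test_halving_cv_doubles_tau(self, small_heart):
        t1 = compute_times_matrix(build_conduction_graph(small_heart, cv_global=0.8))
        t2 = compute_times_matrix(build_conduction_graph(small_heart, cv_global=0.4))
        a1 = activation_from_focus(t1, 0)
        a2 = activation_from_focus(t2, 0)
        assert np.allclose(a2.tau, 2.0 * a1.tau, rtol=1e-9)

    def test_scaling_examples_and_order_preservation(self):
        act = ActivationSequence(tau=np.array([0.0, 1.0, 2.0]), focus=0)
        scaled = scale_activation_duration(act, 4.0)
        assert np.allclose(scaled.tau, [0.0, 2.0, 4.0])
        ident = scale_activation_duration(act, 2.0)
        assert np.allclose(ident.tau, act.tau)
        assert np.array_equal(np.argsort(scaled.tau), np.argsort(act.tau))

    def test_scaling_rejects_degenerate(self):
        act = ActivationSequence(tau=np.zeros(3), focus=1)
        with pytest.raises(ValueError):
            scale_activation_duration(act, 10.0)
        with pytest.raises(ValueError):
            scale_activation_duration(
                ActivationSequence(tau=np.array([0.0, 1.0]), focus=0), -1.0)

    def test_multi_focus_elementwise_minimum(self, small_times):
        a = activation_from_focus(small_times, 0)
        b = activation_from_focus(small_times, 100)
        combo = combine_earliest([a, b])
        assert np.array_equal(combo.tau, np.minimum(a.tau, b.tau))
        assert combo.tau[0] == 0.0 and combo.tau[100] == 0.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ActivationSequence(tau=np.array([1.0, 0.0]), focus=0)  # tau[focus] != 0
        with pytest.raises(ValueError):
            ActivationSequence(tau=np.array([0.0, -1.0]), focus=0)

    def test_focus_out_of_range(self, small_times):
        with pytest.raises(IndexError):
            activation_from_focus(small_times, small_times.n_nodes)
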