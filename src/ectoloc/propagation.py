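"""Fastest-route activation model on the heart's conduction graph.

Excitation is assumed to propagate along mesh edges at a global conduction
velocity (CV, m/s; numerically identical in mm/ms). Transmural connector edges
conduct at half speed by default, mimicking slower wall-crossing propagation,
and spherical regions can scale the local CV (a cv_factor of 1/3 slows the
wavefront three-fold). The times matrix holds the all-pairs fastest-route
travel times; taking its row at a focus node yields that focus's activation
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .geometry import HeartModel, RegionSpec

__all__ = [
    "ConductionGraph",
    "TimesMatrix",
    "ActivationSequence",
    "build_conduction_graph",
    "compute_times_matrix",
    "activation_from_focus",
    "scale_activation_duration",
    "combine_earliest",
]

DEFAULT_CV = 0.8  # m/s, the global conduction velocity
DEFAULT_TRANSMURAL_FACTOR = 0.5  # wall-crossing speed relative to tangential


@dataclass
class ConductionGraph:
    """Per-edge travel times (ms) over the heart's edge list."""

    edge_index: np.ndarray  # (E, 2)
    edge_times: np.ndarray  # (E,) ms, > 0
    n_nodes: int
    cv_global: float  # m/s

    def __post_init__(self) -> None:
        if np.any(self.edge_times <= 0):
            raise ValueError("all edge travel times must be positive")
        # canonicalize: undirected edges with i < j, parallel edges keep the
        # fastest time (csr assembly would otherwise sum duplicates)
        idx = np.sort(np.asarray(self.edge_index, dtype=np.int64), axis=1)
        uniq, inverse = np.unique(idx, axis=0, return_inverse=True)
        best = np.full(len(uniq), np.inf)
        np.minimum.at(best, inverse, np.asarray(self.edge_times, dtype=float))
        self.edge_index, self.edge_times = uniq, best

    def to_sparse(self) -> csr_matrix:
        i, j = self.edge_index.T
        t = self.edge_times
        return csr_matrix(
            (np.concatenate([t, t]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )


@dataclass
class TimesMatrix:
    """All-pairs fastest-route travel times (ms); zero diagonal, symmetric."""

    values: np.ndarray  # (N, N)
    cv_global: float  # m/s

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ActivationSequence:
    """Per-node activation times tau (ms) for a focal excitation."""

    tau: np.ndarray  # (N,) ms, >= 0
    focus: int

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau[self.focus] != 0.0:
            raise ValueError("tau at the focus must be 0")
        if np.any(self.tau < 0):
            raise ValueError("activation times must be nonnegative")

    @property
    def span(self) -> float:
        return float(np.max(self.tau[np.isfinite(self.tau)]))


def build_conduction_graph(
    heart: HeartModel,
    cv_global: float = DEFAULT_CV,
    transmural_factor: float = DEFAULT_TRANSMURAL_FACTOR,
    regions: tuple[RegionSpec, ...] | list[RegionSpec] = (),
) -> ConductionGraph:
    """Edge travel time = length / (cv * transmural_factor^[transmural] *
    cv_factor^[midpoint inside region]).

    Region membership is decided at the edge midpoint; overlapping regions
    multiply their factors.
    """
    if cv_global <= 0:
        raise ValueError("cv_global must be > 0")
    if transmural_factor <= 0:
        raise ValueError("transmural_factor must be > 0")
    speed = np.full(len(heart.edge_index), float(cv_global))  # mm/ms == m/s
    speed[heart.edge_transmural] *= transmural_factor
    if regions:
        v = heart.mesh.vertices
        mid = 0.5 * (v[heart.edge_index[:, 0]] + v[heart.edge_index[:, 1]])
        for region in regions:
            inside = region.contains(mid)
            speed[inside] *= region.cv_factor
    return ConductionGraph(
        edge_index=heart.edge_index,
        edge_times=heart.edge_lengths / speed,
        n_nodes=heart.n_nodes,
        cv_global=float(cv_global),
    )


def compute_times_matrix(graph: ConductionGraph) -> TimesMatrix:
    """All-pairs fastest-route times via Dijkstra on the conduction graph.

    Unreachable pairs (disconnected graph) are signalled as ``inf`` entries."""
    t = dijkstra(graph.to_sparse(), directed=False)
    return TimesMatrix(values=t, cv_global=graph.cv_global)


def activation_from_focus(times: TimesMatrix, focus: int) -> ActivationSequence:
    """The activation sequence when ``focus`` fires at t = 0: tau = T[focus, :]."""
    if not (0 <= focus < times.n_nodes):
        raise IndexError("focus node out of range")
    return ActivationSequence(tau=times.values[focus].copy(), focus=focus)


def scale_activation_duration(act: ActivationSequence, target_span: float
                              ) -> ActivationSequence:
    """Linearly rescale tau so the latest node activates at ``target_span`` ms.

    Preserves the activation order of the nodes (monotone map)."""
    if target_span <= 0:
        raise ValueError("target_span must be > 0")
    span = act.span
    if span <= 0:
        raise ValueError("cannot scale an all-zero activation sequence")
    tau = act.tau * (target_span / span)
    # guard against float round-up past the requested span
    tau[tau > target_span] = target_span
    return ActivationSequence(tau=tau, focus=act.focus)


def combine_earliest(sequences: list[ActivationSequence]) -> ActivationSequence:
    """Elementwise-minimum combination of several foci (forward simulation of a
    multi-focal beat; not part of the single-focus inverse search)."""
    if not sequences:
        raise ValueError("need at least one sequence")
    tau = np.min([s.tau for s in sequences], axis=0)
    return ActivationSequence(tau=tau, focus=sequences[0].focus)
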