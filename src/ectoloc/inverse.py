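"""Full-search inverse localization of a focal activation origin.

For every heart node taken as a candidate focus, the fastest-route activation
sequence is generated, linearly rescaled to the reference BSPM's duration,
pushed through the forward model, and compared with the (normalized) reference
map — either by a global Pearson correlation over the flattened
electrodes x samples matrices (the classic correlation-based full search) or
by the reciprocal DTW path cost 1/c_p* (the warping variant, which tolerates
local conduction-velocity errors that the uniform-CV candidate model cannot
represent). The candidate attaining the highest score is the estimated origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import scale as _sk_scale

from .dtw import dtw_cost
from .forward import BSPM, TransferMatrix, simulate_bspm
from .geometry import HeartModel, geodesic_distances
from .propagation import (
    ActivationSequence,
    ConductionGraph,
    TimesMatrix,
    activation_from_focus,
    compute_times_matrix,
    scale_activation_duration,
)

__all__ = [
    "SimilarityMap",
    "LocalizationResult",
    "normalize_bspm",
    "correlation_score",
    "reciprocal_map",
    "localize",
    "simulate_reference",
]

METHODS = ("fra_cc", "fra_dtw")


@dataclass
class SimilarityMap:
    """Per-node score surface; ``best_node`` attains the maximum (lowest index
    on ties, which are also reported in ``tied_nodes``)."""

    scores: np.ndarray  # (N,)
    kind: str  # {"correlation", "reciprocal_distance"}
    best_node: int
    tied_nodes: np.ndarray  # indices sharing the maximal score (incl. best_node)

    @property
    def is_tied(self) -> bool:
        return len(self.tied_nodes) > 1


@dataclass
class LocalizationResult:
    estimated_node: int
    true_node: int | None = None
    geodesic_error: float | None = None  # mm
    euclidean_error: float | None = None  # mm
    surface_match: bool | None = None


def normalize_bspm(bspm: BSPM) -> BSPM:
    """Zero-mean, unit-(population)-variance scaling of each time column
    across electrodes; constant columns map to all-zero columns.

    This removes the amplitude information that a homogeneous-conductor
    forward model cannot reproduce reliably, leaving the spatiotemporal
    pattern."""
    if bspm.n_electrodes < 2:
        raise ValueError("normalization needs at least 2 electrodes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sklearn warns on zero variance
        scaled = _sk_scale(bspm.potentials, axis=0)
    # columns that are constant up to float cancellation noise (e.g. the
    # fully-depolarized closed layer, analytically zero) must not have that
    # noise amplified to unit variance
    std = bspm.potentials.std(axis=0)
    negligible = std <= 1e-10 * (std.max() if std.max() > 0 else 1.0)
    scaled[:, negligible] = 0.0
    return BSPM(potentials=scaled, dt=bspm.dt)


def correlation_score(test: BSPM, ref: BSPM) -> float:
    """Pearson correlation of the two maps, flattened jointly over electrodes
    and samples; 0 (with a warning) if either side has zero variance."""
    if test.potentials.shape != ref.potentials.shape:
        raise ValueError("test and reference BSPMs must have equal shapes")
    a = test.potentials.ravel()
    b = ref.potentials.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance BSPM in correlation; returning 0")
        return 0.0
    r = np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb)
    return float(np.clip(r, -1.0, 1.0))


def reciprocal_map(distances: np.ndarray) -> SimilarityMap:
    """Scores 1/c_p*: a monotone order-reversing transform of the DTW costs.
    Zero distances (exact matches) map to +inf and dominate the argmax."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("DTW distances must be nonnegative")
    with np.errstate(divide="ignore"):
        scores = 1.0 / d
    best = int(np.argmax(scores))
    tied = np.flatnonzero(scores == scores[best])
    return SimilarityMap(scores=scores, kind="reciprocal_distance",
                         best_node=best, tied_nodes=tied)


def simulate_reference(
    heart: HeartModel,
    A: TransferMatrix,
    model: ConductionGraph | TimesMatrix,
    focus: int,
    dt: float = 1.0,
    span: float | None = None,
) -> tuple[BSPM, ActivationSequence]:
    """Forward-simulate a reference BSPM for a given focus.

    The activation sequence is rescaled so its duration is a whole number of
    sampling intervals (``span`` defaults to max(tau) rounded up), mirroring
    the duration matching applied to every test sequence; the returned map is
    NOT normalized.
    """
    times = model if isinstance(model, TimesMatrix) else compute_times_matrix(model)
    act = activation_from_focus(times, focus)
    if span is None:
        span = float(np.ceil(act.span / dt) * dt)
    act = scale_activation_duration(act, span)
    return simulate_bspm(A, act, heart.node_areas, dt=dt, span=span), act


def localize(
    heart: HeartModel,
    A: TransferMatrix,
    times: TimesMatrix,
    ref: BSPM,
    method: str = "fra_dtw",
    true_node: int | None = None,
) -> tuple[SimilarityMap, LocalizationResult]:
    """Full search over all heart nodes for the activation origin of ``ref``.

    Every candidate sequence is duration-matched to the reference span, so the
    DTW operates on equal-length sequences. Both the reference and every test
    map are normalized before scoring. Ties are broken toward the lowest node
    index and reported on the similarity map.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    n = heart.n_nodes
    if A.A.shape[1] != n or times.n_nodes != n:
        raise ValueError("heart, transfer matrix and times matrix are inconsistent")
    if ref.n_electrodes != A.A.shape[0]:
        raise ValueError("reference BSPM electrode count does not match A")
    span = ref.span
    if span <= 0:
        raise ValueError("reference BSPM must span a positive duration")

    ref_n = normalize_bspm(ref)
    aw = A.A * heart.node_areas[None, :]  # lead field with areas folded in
    t_grid = np.arange(ref.n_samples) * ref.dt
    tau_all = times.values
    finite_span = np.max(tau_all[np.isfinite(tau_all)], axis=None)
    if not np.all(np.isfinite(tau_all)):
        raise ValueError("times matrix has unreachable nodes; the search "
                         "requires a connected conduction graph")
    del finite_span

    scores = np.empty(n)
    for node in range(n):
        tau = tau_all[node]
        tmax = tau.max()
        if tmax <= 0:
            raise ValueError(f"degenerate activation sequence at node {node}")
        tau = tau * (span / tmax)
        tau[tau > span] = span  # same float-round-up guard as duration scaling
        sources = (t_grid[None, :] >= tau[:, None]).astype(float)
        test = BSPM(potentials=aw @ sources, dt=ref.dt)
        test_n = normalize_bspm(test)
        if method == "fra_cc":
            scores[node] = correlation_score(test_n, ref_n)
        else:
            scores[node] = dtw_cost(test_n.potentials, ref_n.potentials)

    if method == "fra_cc":
        best = int(np.argmax(scores))
        tied = np.flatnonzero(scores == scores[best])
        smap = SimilarityMap(scores=scores, kind="correlation",
                             best_node=best, tied_nodes=tied)
    else:
        smap = reciprocal_map(scores)
    if smap.is_tied:
        warnings.warn(f"similarity maximum tied across nodes {smap.tied_nodes.tolist()}; "
                      "reporting the lowest index")

    result = LocalizationResult(estimated_node=smap.best_node, true_node=true_node)
    if true_node is not None:
        geo = geodesic_distances(heart, true_node)
        result.geodesic_error = float(geo[smap.best_node])
        v = heart.mesh.vertices
        result.euclidean_error = float(
            np.linalg.norm(v[smap.best_node] - v[true_node])
        )
        lab = heart.mesh.vertex_labels
        if lab[smap.best_node] != "unlabeled" and lab[true_node] != "unlabeled":
            result.surface_match = bool(lab[smap.best_node] == lab[true_node])
    return smap, result
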