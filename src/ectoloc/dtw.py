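"""Multichannel dynamic time warping.

Aligns two equal-length multichannel sequences (here: BSPM matrices, one
column = the potentials of all electrodes at one time instant) by a warping
path p = (p_1, ..., p_L), p_l = (n_l, m_l), subject to

* boundary:      p_1 = (1, 1), p_L = (T, T)          (1-based indices),
* monotonicity:  n and m componentwise nondecreasing,
* step size:     p_{l+1} - p_l in {(1, 0), (0, 1), (1, 1)},

minimizing the summed local cost along the path. The local cost is the
euclidean norm of the column difference. The optimum is computed by the
classic dynamic program over the accumulated cost matrix D with a sentinel
row/column (D[0, 0] = 0, D[0, m>0] = D[n>0, 0] = +inf) and recovered by
backtracking from (T, T); ties in the backtracking argmin prefer the diagonal
predecessor, so identical inputs yield the plain diagonal path.

An exhaustive path-enumeration oracle (feasible only for tiny T; the path
count grows as the central Delannoy numbers 1, 3, 13, 63, 321, ...) is
provided for testing the dynamic program against brute force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = [
    "WarpingPath",
    "DtwResult",
    "local_cost",
    "cost_matrix",
    "accumulate",
    "backtrack",
    "dtw_distance",
    "dtw_cost",
    "check_warping_path",
    "enumerate_warping_paths",
    "oracle_dtw",
]

_ORACLE_MAX_T = 7


@dataclass
class WarpingPath:
    """A feasible warping path; ``pairs`` holds 1-based (n_l, m_l) rows."""

    pairs: np.ndarray  # (L, 2) int, 1-based

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)

    @property
    def L(self) -> int:
        return len(self.pairs)

    @property
    def pairs_zero_based(self) -> np.ndarray:
        return self.pairs - 1


@dataclass
class DtwResult:
    total_cost: float
    path: WarpingPath


def local_cost(test_column: np.ndarray, ref_column: np.ndarray) -> float:
    """Euclidean (L2) distance between two P-channel samples."""
    a = np.asarray(test_column, dtype=float).ravel()
    b = np.asarray(ref_column, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    return float(np.linalg.norm(a - b))


def cost_matrix(test: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """C[n, m] = ||test[:, n] - ref[:, m]||_2 for all sample pairs."""
    test = np.atleast_2d(np.asarray(test, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    return cdist(test.T, ref.T, metric="euclidean")


@njit(cache=True)
def _accumulate_jit(C: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    T = C.shape[0]
    D = np.empty((T + 1, T + 1))
    D[0, :] = np.inf
    D[:, 0] = np.inf
    D[0, 0] = 0.0
    for n in range(1, T + 1):
        for m in range(1, T + 1):
            d = D[n - 1, m - 1]
            if D[n - 1, m] < d:
                d = D[n - 1, m]
            if D[n, m - 1] < d:
                d = D[n, m - 1]
            D[n, m] = d + C[n - 1, m - 1]
    return D


def accumulate(C: np.ndarray) -> np.ndarray:
    """Accumulated cost matrix with sentinels, shape (T+1, T+1);
    D[T, T] is the optimal total cost."""
    C = np.ascontiguousarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("cost matrix must be square")
    if np.any(C < 0):
        raise ValueError("local costs must be nonnegative")
    return _accumulate_jit(C)


def backtrack(D: np.ndarray) -> WarpingPath:
    """Optimal path recovered from (T, T); on argmin ties the diagonal
    predecessor wins, then the vertical (n-1, m), then the horizontal."""
    T = D.shape[0] - 1
    n, m = T, T
    rev = [(n, m)]
    while (n, m) != (1, 1):
        if n == 1:
            n, m = 1, m - 1
        elif m == 1:
            n, m = n - 1, 1
        else:
            diag, vert, horiz = D[n - 1, m - 1], D[n - 1, m], D[n, m - 1]
            if diag <= vert and diag <= horiz:
                n, m = n - 1, m - 1
            elif vert <= horiz:
                n, m = n - 1, m
            else:
                n, m = n, m - 1
        rev.append((n, m))
    return WarpingPath(pairs=np.array(rev[::-1]))


def check_warping_path(path: WarpingPath, T: int) -> None:
    """Independent validity check of the boundary, monotonicity, step-size and
    length conditions; raises ValueError on any violation."""
    p = path.pairs
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("path must be a sequence of index pairs")
    if tuple(p[0]) != (1, 1):
        raise ValueError("boundary violated: path must start at (1, 1)")
    if tuple(p[-1]) != (T, T):
        raise ValueError(f"boundary violated: path must end at ({T}, {T})")
    steps = np.diff(p, axis=0)
    allowed = {(1, 0), (0, 1), (1, 1)}
    for s in map(tuple, steps):
        if s not in allowed:
            raise ValueError(f"illegal step {s}")
    if not (T <= len(p) <= 2 * T - 1):
        raise ValueError(f"path length {len(p)} outside [{T}, {2 * T - 1}]")


def _path_cost(C: np.ndarray, pairs: np.ndarray) -> float:
    """Sum of local costs along a (1-based) path, accumulated in path order."""
    total = 0.0
    for n, m in pairs:
        total += C[n - 1, m - 1]
    return total


def dtw_distance(test: np.ndarray, ref: np.ndarray) -> DtwResult:
    """Full DTW of two equal-shape multichannel sequences: local costs,
    dynamic program, backtracking, and an independent re-summation check of
    the total cost along the returned path."""
    C = cost_matrix(test, ref)
    D = accumulate(C)
    path = backtrack(D)
    check_warping_path(path, C.shape[0])
    total = float(D[-1, -1])
    resum = _path_cost(C, path.pairs)
    if not np.isclose(total, resum, rtol=1e-12, atol=1e-12):
        raise AssertionError(
            f"accumulated cost {total} disagrees with path re-summation {resum}"
        )
    return DtwResult(total_cost=total, path=path)


def dtw_cost(test: np.ndarray, ref: np.ndarray) -> float:
    """Total optimal cost only (no path recovery); used by the full search."""
    return float(accumulate(cost_matrix(test, ref))[-1, -1])


def enumerate_warping_paths(T: int) -> list[WarpingPath]:
    """All feasible warping paths for sequence length T (testing oracle)."""
    if not (1 <= T <= _ORACLE_MAX_T):
        raise ValueError(f"enumeration is tractable only for 1 <= T <= {_ORACLE_MAX_T}")
    out: list[WarpingPath] = []
    stack = [[(1, 1)]]
    while stack:
        p = stack.pop()
        n, m = p[-1]
        if (n, m) == (T, T):
            out.append(WarpingPath(pairs=np.array(p)))
            continue
        for dn, dm in ((1, 1), (1, 0), (0, 1)):
            nn, mm = n + dn, m + dm
            if nn <= T and mm <= T:
                stack.append(p + [(nn, mm)])
    return out


def oracle_dtw(test: np.ndarray, ref: np.ndarray) -> DtwResult:
    """Brute-force DTW by exhaustive path enumeration (testing oracle)."""
    C = cost_matrix(test, ref)
    best_cost, best_path = np.inf, None
    for path in enumerate_warping_paths(C.shape[0]):
        c = _path_cost(C, path.pairs)
        if c < best_cost:
            best_cost, best_path = c, path
    return DtwResult(total_cost=float(best_cost), path=best_path)
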