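"""Song path length: shortest open Hamiltonian path over cluster centroids.

A bird's syllable repertoire, embedded in 2-D and clustered, leaves k
cluster centroids.  The song's "path length" is the total
centroid-to-centroid distance along an ordering of all k clusters; since
there are k! orderings, the bird-level score is the minimum over them —
the shortest open Hamiltonian path.  A compact repertoire of
similar-sounding syllables gives a short path; a diverse repertoire
spreads its centroids and forces a long one.

Two exact solvers are provided: exhaustive enumeration (with reversal
symmetry, k!/2 candidate orders) for k <= 8 and a Held-Karp dynamic
program for k up to 15.  They agree on the overlapping range and both
break ties by the lexicographically smallest optimal order.  Four
metrics are supported: euclidean, cosine, manhattan, chebyshev.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.spatial import distance as _sdist

from .embed import CentroidSet

__all__ = [
    "PathLengthResult",
    "METRICS",
    "pairwise_distance",
    "distance_matrix",
    "path_length_for_order",
    "min_path_length",
    "path_contrast",
    "BRUTE_FORCE_MAX_K",
    "EXACT_MAX_K",
]

BRUTE_FORCE_MAX_K = 8  # enumerate k!/2 orders up to here
EXACT_MAX_K = 15  # Held-Karp bound: 2^k * k state table

_METRIC_FUNCS = {
    "euclidean": _sdist.euclidean,
    "cosine": _sdist.cosine,
    "manhattan": _sdist.cityblock,
    "chebyshev": _sdist.chebyshev,
}
METRICS = tuple(_METRIC_FUNCS)

_TIE_TOL = 1e-9  # relative tolerance when collecting co-optimal orders


@dataclass(frozen=True)
class PathLengthResult:
    """Minimum path length over cluster orderings, with provenance.

    ``argmin_order`` is the lexicographically smallest optimal ordering
    (optimal orders come in reversal pairs; both directions compete).
    ``per_order_lengths`` maps each canonical order (the lex-smaller of
    the pair) to its length when enumeration was used and requested.
    """

    k: int
    metric: str
    min_path: float
    argmin_order: tuple[int, ...]
    n_orders_considered: int
    per_order_lengths: dict[tuple[int, ...], float] | None = None


def pairwise_distance(a, b, metric: str = "euclidean") -> float:
    """Distance between two 2-D points under one of the four metrics."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("points must be finite")
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "cosine" and (not np.any(a) or not np.any(b)):
        raise ValueError("cosine distance undefined for a zero vector")
    return float(_METRIC_FUNCS[metric](a, b))


def distance_matrix(points: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise distance matrix for a set of points."""
    pts = np.asarray(points, dtype=np.float64)
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "cosine" and np.any(~pts.any(axis=1)):
        raise ValueError("cosine distance undefined for a zero vector")
    scipy_name = {"manhattan": "cityblock"}.get(metric, metric)
    return _sdist.squareform(_sdist.pdist(pts, metric=scipy_name))


def _validate_order(order: Sequence[int], k: int) -> tuple[int, ...]:
    order = tuple(int(i) for i in order)
    if sorted(order) != list(range(k)):
        raise ValueError(
            f"order {order} is not a permutation of all {k} clusters"
        )
    return order


def path_length_for_order(
    cs: CentroidSet, order: Sequence[int], metric: str = "euclidean"
) -> float:
    """Total distance along one ordering of all clusters (open path)."""
    order = _validate_order(order, cs.k)
    if cs.k == 1:
        return 0.0
    D = distance_matrix(cs.centroids, metric)
    idx = np.asarray(order)
    return float(D[idx[:-1], idx[1:]].sum())


def _canonical(order: tuple[int, ...]) -> tuple[int, ...]:
    rev = order[::-1]
    return order if order <= rev else rev


def _brute_force(D: np.ndarray, keep_orders: bool):
    k = D.shape[0]
    best = np.inf
    best_order: tuple[int, ...] | None = None
    table: dict[tuple[int, ...], float] | None = {} if keep_orders else None
    for perm in permutations(range(k)):
        if perm[0] > perm[-1]:  # reversal symmetry: keep one of each pair
            continue
        idx = np.asarray(perm)
        length = float(D[idx[:-1], idx[1:]].sum())
        if table is not None:
            table[_canonical(perm)] = length
        if best_order is None or length < best - _TIE_TOL * max(1.0, best):
            best, best_order = length, _canonical(perm)
        elif abs(length - best) <= _TIE_TOL * max(1.0, abs(best)):
            cand = _canonical(perm)
            if cand < best_order:
                best_order = cand
    return best, best_order, table


def _held_karp(D: np.ndarray):
    """Exact shortest open Hamiltonian path by dynamic programming.

    ``f[S][j]`` = cost of the cheapest path that starts at j and visits
    exactly the clusters in bitmask S (j in S).  The lexicographically
    smallest optimal order is reconstructed greedily from the front,
    which is valid because every optimal suffix choice is recorded in f.
    """
    k = D.shape[0]
    full = (1 << k) - 1
    f = np.full((full + 1, k), np.inf)
    for j in range(k):
        f[1 << j, j] = 0.0
    masks_by_size: list[list[int]] = [[] for _ in range(k + 1)]
    for S in range(1, full + 1):
        masks_by_size[S.bit_count()].append(S)
    for size in range(2, k + 1):
        for S in masks_by_size[size]:
            for j in range(k):
                if not S & (1 << j):
                    continue
                rest = S ^ (1 << j)
                vals = [D[j, l] + f[rest, l] for l in range(k) if rest & (1 << l)]
                f[S, j] = min(vals)
    best = float(f[full].min())
    tol = _TIE_TOL * max(1.0, abs(best))
    # reconstruct lex-smallest optimal order from the front
    start = min(j for j in range(k) if f[full, j] <= best + tol)
    order = [start]
    S, j = full, start
    while S.bit_count() > 1:
        rest = S ^ (1 << j)
        target = f[S, j]
        nxt = min(
            l
            for l in range(k)
            if rest & (1 << l) and D[j, l] + f[rest, l] <= target + tol
        )
        order.append(nxt)
        S, j = rest, nxt
    return best, tuple(order)


def min_path_length(
    cs: CentroidSet,
    metric: str = "euclidean",
    keep_orders: bool = False,
    force_solver: str | None = None,
) -> PathLengthResult:
    """Shortest open Hamiltonian path over all cluster centroids.

    Enumerates all k!/2 distinct orders for k <= 8 (set
    ``keep_orders=True`` to retain the full table) and switches to the
    Held-Karp dynamic program for 9 <= k <= 15; the two solvers give
    identical results where both apply (``force_solver`` in
    {"brute", "dp"} overrides the choice for cross-checking).  Exact
    computation beyond k = 15 is refused.
    """
    k = cs.k
    if k > EXACT_MAX_K:
        raise ValueError(
            f"k={k} exceeds the exact-computation bound {EXACT_MAX_K}; "
            "reduce the number of clusters (e.g. larger min cluster size)"
        )
    if k == 1:
        return PathLengthResult(
            k=1,
            metric=metric,
            min_path=0.0,
            argmin_order=(0,),
            n_orders_considered=1,
            per_order_lengths={(0,): 0.0} if keep_orders else None,
        )
    D = distance_matrix(cs.centroids, metric)
    solver = force_solver or ("brute" if k <= BRUTE_FORCE_MAX_K else "dp")
    if solver == "brute":
        if k > BRUTE_FORCE_MAX_K:
            raise ValueError(f"brute force limited to k <= {BRUTE_FORCE_MAX_K}")
        best, order, table = _brute_force(D, keep_orders)
    elif solver == "dp":
        best, order = _held_karp(D)
        table = None
    else:
        raise ValueError(f"unknown solver {force_solver!r}")
    n_orders = math.factorial(k) // 2
    return PathLengthResult(
        k=k,
        metric=metric,
        min_path=best,
        argmin_order=order,
        n_orders_considered=n_orders,
        per_order_lengths=table,
    )


def path_contrast(long: PathLengthResult, short: PathLengthResult) -> float:
    """Signed difference long.min_path - short.min_path (same metric)."""
    if long.metric != short.metric:
        raise ValueError(
            f"metric mismatch: {long.metric!r} vs {short.metric!r}"
        )
    return long.min_path - short.min_path
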