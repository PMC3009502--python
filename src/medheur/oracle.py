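"""Exact brute-force solvers and enumerators for small instances.

These are desk-scale ground truths: exhaustive minimization over all
2^n * n! signed permutations for the inversion median, branch and bound over
perfect matchings of the multiple breakpoint graph for the (relaxed) DCJ
median, and breadth-first search over the inversion graph for distances.
They exist to validate the heuristics and the closed-form distance, never to
scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _hpcore
from .asm import MatchingState, asm_median, build_mbg
from .distance import inverse_position_row, inversion_distance
from .genome import GenomeError, Inversion, SignedPermutation, apply_inversion

__all__ = [
    "MedianSet",
    "PathPermutationSet",
    "InstanceTooLargeError",
    "all_signed_permutations",
    "exact_inversion_median",
    "exact_dcj_median",
    "exact_dcj_median_enumerate",
    "optimal_path_permutations",
    "bfs_inversion_distance",
    "MAX_MEDIAN_N",
    "MAX_PATHS_N",
    "MAX_BFS_N",
]

MAX_MEDIAN_N = 8
MAX_PATHS_N = 6
MAX_BFS_N = 5


class InstanceTooLargeError(GenomeError):
    """The exact solver refuses instances beyond its enumeration bound."""


@dataclass(frozen=True)
class MedianSet:
    """The exact median score together with every permutation attaining it."""

    score: int
    medians: frozenset[SignedPermutation]


@dataclass(frozen=True)
class PathPermutationSet:
    """Permutations on at least one optimal pairwise sorting path."""

    members: frozenset[SignedPermutation]


def all_signed_permutations(n: int):
    """Yield all 2^n * n! signed permutations of {1..n} as tuples."""
    for order in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield tuple(o * s for o, s in zip(order, signs))


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(all_signed_permutations(n)), dtype=np.int64)


def _require(n: int, bound: int, what: str) -> None:
    if n > bound:
        raise InstanceTooLargeError(
            f"{what} enumerates exhaustively and is limited to n <= {bound} "
            f"(got n = {n})"
        )


def exact_inversion_median(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> MedianSet:
    """Exhaustive inversion median: score and the full median set."""
    n = a.n
    _require(n, MAX_MEDIAN_N, "exact_inversion_median")
    cands = _perm_matrix(n)
    rel = np.stack(
        [inverse_position_row(a), inverse_position_row(b), inverse_position_row(c)]
    )
    scores = _hpcore.triple_scores(cands, rel)
    best = int(scores.min())
    medians = frozenset(
        SignedPermutation.from_array(cands[k]) for k in np.flatnonzero(scores == best)
    )
    return MedianSet(score=best, medians=medians)


def _dcj_score_of_matching(adj: np.ndarray, color_adj, n: int) -> int:
    return 3 * (n + 1) - sum(
        int(_hpcore.count_alternating_cycles(adj, ca)) for ca in color_adj
    )


def exact_dcj_median(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> int:
    """Optimal relaxed DCJ median score via depth-first branch and bound.

    The bound uses the fact that each of the m remaining matching edges can
    close at most one cycle per color: score >= 3(n+1) - (cycles + 3m).
    Extra circular chromosomes (including a bare cap) are permitted.  The
    search is warm-started with the score of an ASM2 matching, which is
    achievable and therefore a valid initial upper bound.
    """
    n = a.n
    _require(n, MAX_MEDIAN_N, "exact_dcj_median")
    mbg = build_mbg(a, b, c)
    init = asm_median(a, b, c, variant="ASM2").dcj_score
    return int(
        _hpcore.dcj_median_branch_bound(np.stack(mbg.color_adj), int(init))
    )


def exact_dcj_median_enumerate(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> int:
    """Unpruned enumeration of every perfect matching of the MBG (n <= 4).

    Independent of :class:`MatchingState`: scores are recomputed from
    scratch per matching, serving as the oracle for the pruned solver.
    """
    n = a.n
    _require(n, 4, "exact_dcj_median_enumerate")
    mbg = build_mbg(a, b, c)
    V = mbg.n_vertices
    best = [3 * (n + 1)]
    adj = np.full(V, -1, dtype=np.int64)

    def rec() -> None:
        free = [x for x in range(V) if adj[x] < 0]
        if not free:
            best[0] = min(
                best[0], _dcj_score_of_matching(adj, mbg.color_adj, n)
            )
            return
        u = free[0]
        for v in free[1:]:
            adj[u], adj[v] = v, u
            rec()
            adj[u] = adj[v] = -1

    rec()
    return best[0]


def optimal_path_permutations(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> PathPermutationSet:
    """All permutations lying on an optimal sorting path of some input pair."""
    n = a.n
    _require(n, MAX_PATHS_N, "optimal_path_permutations")
    pairs = [(a, b), (a, c), (b, c)]
    dists = [inversion_distance(x, y) for x, y in pairs]
    members = set()
    for t in all_signed_permutations(n):
        p = SignedPermutation(t)
        for (x, y), dxy in zip(pairs, dists):
            if inversion_distance(x, p) + inversion_distance(p, y) == dxy:
                members.add(p)
                break
    return PathPermutationSet(members=frozenset(members))


def bfs_inversion_distance(a: SignedPermutation, b: SignedPermutation) -> int:
    """Breadth-first search over the inversion graph; exact by construction."""
    n = a.n
    _require(n, MAX_BFS_N, "bfs_inversion_distance")
    if a.n != b.n:
        raise GenomeError("gene sets differ")
    target = b.elements
    frontier = {a.elements}
    seen = {a.elements}
    d = 0
    rhos = [Inversion(i, j) for i in range(1, n + 1) for j in range(i, n + 1)]
    while target not in frontier:
        nxt = set()
        for t in frontier:
            p = SignedPermutation(t)
            for rho in rhos:
                q = apply_inversion(p, rho).elements
                if q not in seen:
                    seen.add(q)
                    nxt.add(q)
        frontier = nxt
        d += 1
        if not frontier:  # pragma: no cover - the inversion graph is connected
            raise RuntimeError("BFS exhausted the graph without reaching target")
    return d
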