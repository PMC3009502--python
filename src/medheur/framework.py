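"""Good-inversion median heuristics: HS, HSE, HP, HPE, MSS, MSP, trivial.

A *good inversion* on A with respect to B and C is an inversion lying on an
optimal sorting path from A to B and on one from A to C; equivalently it
decrements both d(A, B) and d(A, C) by exactly one.  The six heuristics
differ in how often the pair of reference permutations is updated:

* HS / HSE apply one good inversion per permutation per round, each step
  referring to the *latest* iterates (serial);
* HP / HPE do the same but refer to the round-start iterates (parallel);
* MSS / MSP drive each permutation all the way to a *maximal signature* (no
  good inversion left), serially or against the original inputs.

The extended variants (HSE, HPE) skip an exhausted permutation and stop only
when all three are exhausted; the plain variants stop the first time the
permutation whose turn it is has none.  All of them return the best of the
three final permutations by tree length with respect to the ORIGINAL inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _hpcore
from .distance import inversion_distance, relative_array, tree_length
from .genome import Inversion, SignedPermutation, apply_inversion

__all__ = [
    "MedianResult",
    "FRAMEWORK_SOLVERS",
    "good_inversions",
    "greedy_good_inversion",
    "maximal_signature",
    "run_heuristic",
    "trivial_median",
    "is_maximal_signature",
]

FRAMEWORK_SOLVERS = ("HS", "HSE", "HP", "HPE", "MSS", "MSP")


@dataclass(frozen=True)
class MedianResult:
    """Output of a median solver, scored against the original inputs."""

    solver: str
    median: SignedPermutation
    tree_length: int
    steps: int
    extras: int = 0
    dcj_score: Optional[int] = None


def good_inversions(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> set[Inversion]:
    """Inversions sorting a toward both b and c (may be empty)."""
    g = _hpcore.good_mask(relative_array(a, b), relative_array(a, c))
    ii, jj = np.nonzero(g)
    return {Inversion(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)}


def _greedy_cell(
    pab: np.ndarray, pac: np.ndarray, rng: Optional[np.random.Generator]
) -> Optional[tuple[int, int]]:
    """0-based (i, j) of the greedy good inversion, or None if none exists.

    Ties are broken lexicographically on (i, j) unless a generator is given,
    in which case a uniform choice among the maximizers is made.
    """
    counts = _hpcore.good_succ_counts(pab, pac)
    best = counts.max()
    if best < 0:
        return None
    ii, jj = np.nonzero(counts == best)
    if rng is None or len(ii) == 1:
        return int(ii[0]), int(jj[0])
    k = int(rng.integers(len(ii)))
    return int(ii[k]), int(jj[k])


def _random_cell(
    pab: np.ndarray, pac: np.ndarray, rng: np.random.Generator
) -> Optional[tuple[int, int]]:
    g = _hpcore.good_mask(pab, pac)
    ii, jj = np.nonzero(g)
    if len(ii) == 0:
        return None
    k = int(rng.integers(len(ii)))
    return int(ii[k]), int(jj[k])


def _select_cell(pab, pac, selection, rng) -> Optional[tuple[int, int]]:
    if selection == "greedy":
        return _greedy_cell(pab, pac, None)
    if selection == "greedy-random-ties":
        return _greedy_cell(pab, pac, rng)
    if selection == "random":
        if rng is None:
            rng = np.random.default_rng(0)
        return _random_cell(pab, pac, rng)
    raise ValueError(f"unknown selection rule {selection!r}")


def greedy_good_inversion(
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
    tiebreak: str = "lex",
    seed: Optional[int] = None,
) -> Optional[Inversion]:
    """The good inversion leaving the most good inversions available next.

    ``tiebreak`` is "lex" (smallest (i, j), the default and deterministic) or
    "random" (uniform among the maximizers, driven by ``seed``).
    """
    rng = np.random.default_rng(seed) if tiebreak == "random" else None
    cell = _greedy_cell(relative_array(a, b), relative_array(a, c), rng)
    if cell is None:
        return None
    return Inversion(cell[0] + 1, cell[1] + 1)


def maximal_signature(
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
    selection: str = "greedy",
    seed: Optional[int] = None,
    return_path: bool = False,
):
    """Drive a along good inversions (w.r.t. b, c) until none remains.

    After k steps the iterate A^k satisfies d(A^k, b) = d(a, b) - k and
    d(A^k, c) = d(a, c) - k, hence tree_length(A^k; a, b, c) =
    d(a, b) + d(a, c) - k.  With ``return_path`` the applied inversions are
    returned alongside the signature.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    pab = relative_array(a, b)
    pac = relative_array(a, c)
    cur = a
    path: list[Inversion] = []
    while True:
        cell = _select_cell(pab, pac, selection, rng)
        if cell is None:
            break
        i, j = cell
        _hpcore.reverse_inplace(pab, i, j)
        _hpcore.reverse_inplace(pac, i, j)
        rho = Inversion(i + 1, j + 1)
        cur = apply_inversion(cur, rho)
        path.append(rho)
    if return_path:
        return cur, path
    return cur


def _best_of(
    cands: list[tuple[str, SignedPermutation]],
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
) -> tuple[SignedPermutation, int]:
    best = None
    best_tl = None
    for _, x in cands:
        tl = tree_length(x, a, b, c)
        if best_tl is None or tl < best_tl:
            best, best_tl = x, tl
    return best, best_tl


class _RoundGuard:
    """Termination guard for the round-based heuristics.

    The serial variants strictly decrease the current pairwise-distance sum
    at every applied step and always terminate; the parallel variants apply
    inversions that are good with respect to *round-start* iterates, so the
    configuration can revisit itself and (with a deterministic selection
    rule) cycle forever.  The guard stops a run the first time a round-start
    configuration repeats, with a generous round cap as a backstop for
    randomized selection.
    """

    def __init__(self, a, b, c):
        perimeter = (
            inversion_distance(a, b)
            + inversion_distance(a, c)
            + inversion_distance(b, c)
        )
        self.max_rounds = 4 * (perimeter + 1)
        self.rounds = 0
        self.seen: set[tuple] = set()

    def proceed(self, cur) -> bool:
        key = tuple(p.elements for p in cur)
        if key in self.seen:
            return False
        self.seen.add(key)
        self.rounds += 1
        return self.rounds <= self.max_rounds


def _one_step(x, y, z, selection, rng) -> Optional[SignedPermutation]:
    cell = _select_cell(relative_array(x, y), relative_array(x, z), selection, rng)
    if cell is None:
        return None
    return apply_inversion(x, Inversion(cell[0] + 1, cell[1] + 1))


def run_heuristic(
    name: str,
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
    selection: str = "greedy",
    seed: Optional[int] = None,
) -> MedianResult:
    """Run one of the framework heuristics (HS, HSE, HP, HPE, MSS, MSP)."""
    name = name.upper()
    if name not in FRAMEWORK_SOLVERS:
        raise ValueError(
            f"unknown heuristic {name!r}; expected one of {FRAMEWORK_SOLVERS}"
        )
    rng = np.random.default_rng(seed) if seed is not None else None
    steps = 0

    if name in ("MSS", "MSP"):
        if name == "MSP":
            an, pa = maximal_signature(a, b, c, selection, seed, return_path=True)
            bn, pb = maximal_signature(b, a, c, selection, seed, return_path=True)
            cn, pc = maximal_signature(c, b, a, selection, seed, return_path=True)
        else:
            an, pa = maximal_signature(a, b, c, selection, seed, return_path=True)
            bn, pb = maximal_signature(b, an, c, selection, seed, return_path=True)
            cn, pc = maximal_signature(c, bn, an, selection, seed, return_path=True)
        steps = len(pa) + len(pb) + len(pc)
        final = [("A", an), ("B", bn), ("C", cn)]
    elif name in ("HS", "HP"):
        cur = [a, b, c]
        serial = name == "HS"
        guard = _RoundGuard(a, b, c)
        stopped = False
        while not stopped and guard.proceed(cur):
            snap = list(cur)
            for t in range(3):
                ref = cur if serial else snap
                others = [ref[u] for u in range(3) if u != t]
                nxt = _one_step(cur[t], others[0], others[1], selection, rng)
                if nxt is None:
                    stopped = True
                    break
                cur[t] = nxt
                steps += 1
        final = list(zip("ABC", cur))
    else:  # HSE, HPE
        cur = [a, b, c]
        serial = name == "HSE"
        guard = _RoundGuard(a, b, c)
        while guard.proceed(cur):
            snap = list(cur)
            applied = False
            for t in range(3):
                ref = cur if serial else snap
                others = [ref[u] for u in range(3) if u != t]
                nxt = _one_step(cur[t], others[0], others[1], selection, rng)
                if nxt is not None:
                    cur[t] = nxt
                    steps += 1
                    applied = True
            if not applied:
                break
        final = list(zip("ABC", cur))

    median, tl = _best_of(final, a, b, c)
    return MedianResult(solver=name, median=median, tree_length=tl, steps=steps)


def trivial_median(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> MedianResult:
    """The best of the three inputs used in lieu of a median."""
    median, tl = _best_of([("A", a), ("B", b), ("C", c)], a, b, c)
    return MedianResult(solver="trivial", median=median, tree_length=tl, steps=0)


def is_maximal_signature(
    cand: SignedPermutation,
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
) -> bool:
    """Check that ``cand`` is a maximal signature of a w.r.t. b and c.

    Requires (i) no good inversion from ``cand``, and (ii) an optimal sorting
    path from a to ``cand`` consisting only of good inversions w.r.t. (b, c);
    the path is found by depth-first search.
    """
    if good_inversions(cand, b, c):
        return False

    seen: set[tuple[int, ...]] = set()

    def dfs(x: SignedPermutation) -> bool:
        if x == cand:
            return True
        key = x.elements
        if key in seen:
            return False
        seen.add(key)
        dx = inversion_distance(x, cand)
        for rho in sorted(good_inversions(x, b, c)):
            nxt = apply_inversion(x, rho)
            if inversion_distance(nxt, cand) == dx - 1 and dfs(nxt):
                return True
        return False

    return dfs(a)
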