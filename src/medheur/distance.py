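"""Pairwise genome distances, sorting inversions, and median bounds.

The inversion distance is the Hannenhalli-Pevzner formula
``d = n + 1 - c + h + f`` on the breakpoint graph of one genome expressed in
the coordinates of the other (cycles c, hurdles h, fortress indicator f).
The DCJ distance is computed on the genomes circularized with a cap gene 0,
where it equals ``(n + 1) - C`` with C the number of color-alternating
cycles of the two adjacency sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _hpcore
from .genome import GeneSetMismatchError, Inversion, SignedPermutation

__all__ = [
    "BreakpointGraphStats",
    "breakpoint_graph_stats",
    "inversion_distance",
    "sorting_inversions",
    "dcj_distance",
    "tree_length",
    "median_lower_bound",
]


@dataclass(frozen=True)
class BreakpointGraphStats:
    """Cycle/hurdle/fortress decomposition behind an inversion distance."""

    cycles: int
    hurdles: int
    fortress: bool
    n: int

    @property
    def distance(self) -> int:
        return self.n + 1 - self.cycles + self.hurdles + (1 if self.fortress else 0)


def _check_same_genes(a: SignedPermutation, b: SignedPermutation) -> None:
    if a.n != b.n:
        raise GeneSetMismatchError(
            f"genomes have different gene sets (n={a.n} vs n={b.n})"
        )


def relative_array(a: SignedPermutation, b: SignedPermutation) -> np.ndarray:
    """The permutation ``b^-1 . a`` as an int64 array (identity iff a == b)."""
    _check_same_genes(a, b)
    n = a.n
    barr = b.to_array()
    sgnpos = np.empty(n + 1, dtype=np.int64)
    sgnpos[np.abs(barr)] = np.sign(barr) * (np.arange(n, dtype=np.int64) + 1)
    aarr = a.to_array()
    return np.sign(aarr) * sgnpos[np.abs(aarr)]


def inverse_position_row(b: SignedPermutation) -> np.ndarray:
    """Signed position of each gene in b (index 0 unused); see `triple_scores`."""
    n = b.n
    barr = b.to_array()
    row = np.zeros(n + 1, dtype=np.int64)
    row[np.abs(barr)] = np.sign(barr) * (np.arange(n, dtype=np.int64) + 1)
    return row


@lru_cache(maxsize=1 << 18)
def _hp_of_tuple(t: tuple[int, ...]) -> int:
    return int(_hpcore.hp_distance(np.array(t, dtype=np.int64)))


def inversion_distance(a: SignedPermutation, b: SignedPermutation) -> int:
    """Minimum number of inversions transforming a into b (symmetric)."""
    return _hp_of_tuple(tuple(relative_array(a, b)))


def breakpoint_graph_stats(
    a: SignedPermutation, b: SignedPermutation
) -> BreakpointGraphStats:
    c, h, f = _hpcore.hp_stats(relative_array(a, b))
    return BreakpointGraphStats(cycles=int(c), hurdles=int(h), fortress=bool(f), n=a.n)


def sorting_inversions(
    a: SignedPermutation, b: SignedPermutation
) -> set[Inversion]:
    """All inversions rho with d(a.rho, b) = d(a, b) - 1; empty iff a == b."""
    mask = _hpcore.sorting_mask(relative_array(a, b))
    ii, jj = np.nonzero(mask)
    return {Inversion(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)}


def circular_adjacency(p: SignedPermutation) -> np.ndarray:
    """Adjacency pairing of gene extremities after circularization with cap 0.

    Extremity encoding: gene g has tail 2g and head 2g+1, g = 0..n; the
    linear order 0, p_1, ..., p_n is closed into a circle through the cap.
    """
    n = p.n
    adj = np.empty(2 * (n + 1), dtype=np.int64)
    seq = (0,) + p.elements
    for k in range(n + 1):
        x = seq[k]
        y = seq[(k + 1) % (n + 1)]
        right = 2 * x + 1 if x >= 0 else -2 * x  # head if forward else tail
        left = 2 * y if y >= 0 else -2 * y + 1  # tail if forward else head
        adj[right] = left
        adj[left] = right
    return adj


def dcj_distance(a: SignedPermutation, b: SignedPermutation) -> int:
    """DCJ distance between the circularized genomes; <= inversion distance."""
    _check_same_genes(a, b)
    cyc = _hpcore.count_alternating_cycles(
        circular_adjacency(a), circular_adjacency(b)
    )
    return a.n + 1 - int(cyc)


def tree_length(
    x: SignedPermutation,
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
) -> int:
    """S(x) = d(x, a) + d(x, b) + d(x, c)."""
    return (
        inversion_distance(x, a)
        + inversion_distance(x, b)
        + inversion_distance(x, c)
    )


def median_lower_bound(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> int:
    """ceil of half the pairwise-distance perimeter: no median can do better."""
    per = (
        inversion_distance(a, b)
        + inversion_distance(a, c)
        + inversion_distance(b, c)
    )
    return -(-per // 2)
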