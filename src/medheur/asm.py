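"""The ASM heuristic family for DCJ-based inversion medians.

Linear genomes are closed into circles with a cap gene 0, and the three
inputs populate a multiple breakpoint graph (MBG): one vertex per gene
extremity (2(n+1) in all), and one colored perfect pairing of the vertices
per genome.  A (relaxed) DCJ median is a perfect matching of the vertices
maximizing the total number of color-alternating cycles; its DCJ median
score is 3(n+1) minus that total.

The heuristic grows the matching one edge at a time.  Whenever two unmatched
vertices are linked through two or more colors (the smallest adequate
subgraph), that edge is forced - it provably preserves optimality.
Otherwise an edge is chosen greedily from a candidate pool whose size gives
the family its variants: all unmatched pairs (ASM4), pairs containing the
lowest-ordered unmatched vertex (ASM3), or, among those, only pairs joined
by a surviving colored connection (ASM2).  The relaxed median may contain
extra circular chromosomes; these are merged back into the cap-containing
chromosome greedily, each merge being the DCJ operation that least increases
the total DCJ distance to the three inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._hpcore import count_alternating_cycles
from .distance import circular_adjacency, tree_length
from .framework import MedianResult
from .genome import GeneSetMismatchError, GenomeError, SignedPermutation

__all__ = [
    "CircularGenome",
    "MultipleBreakpointGraph",
    "MatchingState",
    "ASM_VARIANTS",
    "circularize",
    "linearize",
    "build_mbg",
    "detect_adequate_subgraph",
    "select_edge",
    "asm_median",
    "merge_extra_chromosomes",
]

ASM_VARIANTS = ("ASM2", "ASM3", "ASM4")

CAP_TAIL = 0  # extremity 0 = tail of cap gene 0
CAP_HEAD = 1


@dataclass
class CircularGenome:
    """A set of circular chromosomes on genes 0..n given by extremity pairing.

    ``adj[x]`` is the extremity adjacent to extremity x; gene g owns
    extremities 2g (tail) and 2g+1 (head).  Gene 0 is the cap closing an
    originally linear chromosome.
    """

    n: int
    adj: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adj, dtype=np.int64)
        V = 2 * (self.n + 1)
        if adj.shape != (V,) or not np.array_equal(adj[adj], np.arange(V)):
            raise GenomeError("adjacency array is not an involution on extremities")
        self.adj = adj

    def chromosomes(self) -> list[list[int]]:
        """Signed gene lists, one per circular chromosome (traversal order)."""
        seen = [False] * (self.n + 1)
        out: list[list[int]] = []
        for g in range(self.n + 1):
            if seen[g]:
                continue
            chrom: list[int] = []
            cur = g
            exit_ext = 2 * g + 1  # leave the start gene through its head
            while not seen[cur]:
                seen[cur] = True
                chrom.append(cur if exit_ext % 2 == 1 else -cur)
                nxt_ext = int(self.adj[exit_ext])
                cur = nxt_ext // 2
                exit_ext = nxt_ext ^ 1
            out.append(chrom)
        return out

    def extra_chromosome_count(self) -> int:
        """Chromosomes not containing the cap gene 0."""
        return sum(1 for ch in self.chromosomes() if 0 not in (abs(g) for g in ch))


def circularize(p: SignedPermutation) -> CircularGenome:
    """Close the linear order 0, p_1, ..., p_n, 0 into a circle."""
    return CircularGenome(n=p.n, adj=circular_adjacency(p))


def linearize(g: CircularGenome) -> SignedPermutation:
    """Open the circle at the cap gene, reading it tail-to-head.

    Inverse of :func:`circularize`; raises on multichromosomal input.
    """
    chroms = g.chromosomes()
    if len(chroms) != 1:
        raise GenomeError(
            f"cannot linearize: genome has {len(chroms)} chromosomes"
        )
    chrom = chroms[0]
    # the traversal starts at gene 0 leaving through its head, i.e. reads the
    # cap tail-to-head, so the remaining genes are already in order
    assert chrom[0] == 0
    return SignedPermutation(tuple(chrom[1:]))


@dataclass(frozen=True)
class MultipleBreakpointGraph:
    """Three colored extremity pairings on a shared vertex set."""

    n: int
    color_adj: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def n_vertices(self) -> int:
        return 2 * (self.n + 1)


def build_mbg(
    a: SignedPermutation, b: SignedPermutation, c: SignedPermutation
) -> MultipleBreakpointGraph:
    if not (a.n == b.n == c.n):
        raise GeneSetMismatchError("the three genomes must share one gene set")
    return MultipleBreakpointGraph(
        n=a.n,
        color_adj=(
            circular_adjacency(a),
            circular_adjacency(b),
            circular_adjacency(c),
        ),
    )


class MatchingState:
    """A growing median matching over an MBG, with per-color path contraction.

    For each color, ``far[c][v]`` maps an unmatched vertex v to the far end
    of the alternating (matching + color) path it terminates; adding a
    matching edge between the two ends of a path closes one cycle of that
    color.  Cycle counts are therefore maintained incrementally in O(1) per
    color per added edge.
    """

    def __init__(self, mbg: MultipleBreakpointGraph):
        self.n = mbg.n
        self.far = np.stack([adj.copy() for adj in mbg.color_adj])
        self.matched = np.zeros(mbg.n_vertices, dtype=bool)
        self.cycles = [0, 0, 0]
        self.pairs: list[tuple[int, int]] = []

    @property
    def edges(self) -> int:
        """l: number of matching edges chosen so far."""
        return len(self.pairs)

    @property
    def remaining(self) -> int:
        """m: matching edges still needed (2m vertices unmatched)."""
        return self.n + 1 - self.edges

    def unmatched_vertices(self) -> np.ndarray:
        return np.flatnonzero(~self.matched)

    def delta_cycles(self, u: int, v: int) -> tuple[int, int, int]:
        """Per-color cycle increments if the edge (u, v) were added."""
        if self.matched[u] or self.matched[v] or u == v:
            raise ValueError("both endpoints must be distinct unmatched vertices")
        return tuple(int(self.far[c, u] == v) for c in range(3))

    def add_edge(self, u: int, v: int) -> None:
        if self.matched[u] or self.matched[v] or u == v:
            raise ValueError("both endpoints must be distinct unmatched vertices")
        for c in range(3):
            x = int(self.far[c, u])
            y = int(self.far[c, v])
            if x == v:
                self.cycles[c] += 1
            else:
                self.far[c, x] = y
                self.far[c, y] = x
        self.matched[u] = True
        self.matched[v] = True
        self.pairs.append((min(u, v), max(u, v)))

    def copy(self) -> "MatchingState":
        st = object.__new__(MatchingState)
        st.n = self.n
        st.far = self.far.copy()
        st.matched = self.matched.copy()
        st.cycles = list(self.cycles)
        st.pairs = list(self.pairs)
        return st

    def to_genome(self) -> CircularGenome:
        if self.remaining != 0:
            raise ValueError("matching is not perfect yet")
        adj = np.empty(2 * (self.n + 1), dtype=np.int64)
        for u, v in self.pairs:
            adj[u] = v
            adj[v] = u
        return CircularGenome(n=self.n, adj=adj)


def detect_adequate_subgraph(state: MatchingState) -> Optional[tuple[int, int]]:
    """An unmatched pair joined through >= 2 colors (size-1 adequate subgraph).

    Such an edge closes at least two of the three possible cycles and can be
    forced without losing optimality.  Returns the lowest such pair in vertex
    order, or None; the cap self-edge (0_t, 0_h) is never proposed.
    """
    far = state.far
    for u in state.unmatched_vertices():
        best_v = -1
        for c in range(3):
            v = int(far[c, u])
            if v <= u or (u == CAP_TAIL and v == CAP_HEAD):
                continue
            hits = sum(1 for c2 in range(3) if int(far[c2, u]) == v)
            if hits >= 2 and (best_v < 0 or v < best_v):
                best_v = v
        if best_v >= 0:
            return int(u), best_v
    return None


def _candidate_matrix(state: MatchingState, unm: np.ndarray) -> np.ndarray:
    """Delta-cycle totals for every unmatched pair, -1 on the forbidden cells."""
    k = len(unm)
    delta = np.zeros((k, k), dtype=np.int64)
    for c in range(3):
        delta += state.far[c][unm][:, None] == unm[None, :]
    delta[np.tril_indices(k)] = -1
    if unm[0] == CAP_TAIL and k > 1 and unm[1] == CAP_HEAD:
        delta[0, 1] = -1
    return delta


def _adequacy_gain(state: MatchingState, u: int, v: int) -> int:
    """Size-1 adequate subgraphs created in the contracted graph by edge (u, v).

    Adding (u, v) splices, per color, the two alternating paths ending at u
    and at v; the only vertex pairs that can newly acquire >= 2 parallel
    colored connections are the spliced far-end pairs.  Counting them scores
    how adequate the remaining instance is left - the forced-edge detector
    will harvest each of them for two or three guaranteed cycles.
    """
    far = state.far
    merges: list[tuple[int, int, int]] = []
    for c in range(3):
        x = int(far[c, u])
        if x == v:
            continue
        y = int(far[c, v])
        merges.append((c, min(x, y), max(x, y)))
    gain = 0
    seen: set[tuple[int, int]] = set()
    for c, x, y in merges:
        if (x, y) in seen or (x == CAP_TAIL and y == CAP_HEAD):
            continue
        cnt = 0
        for c2 in range(3):
            pair_c2 = None
            touched = False
            for cm, xm, ym in merges:
                if cm == c2:
                    pair_c2 = (xm, ym)
                    touched = xm in (x, y) or ym in (x, y)
            if pair_c2 == (x, y):
                cnt += 1
            elif not touched and int(far[c2, x]) == y:
                cnt += 1
        if cnt >= 2:
            seen.add((x, y))
            gain += 1
    return gain


# cap on how many tied candidates get the adequacy lookahead (determinism:
# ties are enumerated in lexicographic vertex order before capping)
_LOOKAHEAD_CAP = 4096


def select_edge(
    state: MatchingState, variant: str = "ASM4", criterion: str = "adequacy"
) -> tuple[int, int]:
    """Pick the next matching edge under the variant's candidate pool.

    Both criteria first maximize the number of cycles the edge closes.  The
    ``adequacy`` criterion breaks ties by the number of size-1 adequate
    subgraphs the edge creates in the contracted instance
    (:func:`_adequacy_gain`), then by vertex order; the plain ``cycles``
    criterion goes straight to vertex order.  ASM2 degrades to the ASM3 pool
    for a step whose focus vertex has no surviving colored connection to an
    eligible partner.
    """
    if variant not in ASM_VARIANTS:
        raise ValueError(f"unknown ASM variant {variant!r}")
    if criterion not in ("adequacy", "cycles"):
        raise ValueError(f"unknown criterion {criterion!r}")
    unm = state.unmatched_vertices()
    if len(unm) < 2:
        raise ValueError("no candidate edges: fewer than 2 unmatched vertices")
    delta = _candidate_matrix(state, unm)

    if variant == "ASM4":
        dmax = int(delta.max())
        if dmax < 0:
            raise ValueError("no admissible candidate edge")
        ti, tj = np.nonzero(delta == dmax)
    else:
        row = delta[0]  # focus vertex = lowest-ordered unmatched vertex
        u0 = int(unm[0])
        if variant == "ASM2":
            allowed = np.zeros(len(unm), dtype=bool)
            for c in range(3):
                v = int(state.far[c, u0])
                if not (u0 == CAP_TAIL and v == CAP_HEAD):
                    allowed[np.searchsorted(unm, v)] = True
            if allowed.any():
                row = np.where(allowed, row, -1)
            # else: fall back to the full ASM3 row for this step
        dmax = int(row.max())
        if dmax < 0:
            raise ValueError("no admissible candidate edge")
        tj = np.nonzero(row == dmax)[0]
        ti = np.zeros(len(tj), dtype=np.int64)

    if criterion == "cycles" or len(ti) == 1:
        return int(unm[ti[0]]), int(unm[tj[0]])
    best = None
    for i, j in zip(ti[:_LOOKAHEAD_CAP], tj[:_LOOKAHEAD_CAP]):
        u, v = int(unm[i]), int(unm[j])
        gain = _adequacy_gain(state, u, v)
        if best is None or gain > best[0]:
            best = (gain, u, v)
    return best[1], best[2]


def merge_extra_chromosomes(
    g: CircularGenome,
    inputs: tuple[CircularGenome, CircularGenome, CircularGenome],
) -> CircularGenome:
    """Greedily merge non-cap chromosomes into the cap-containing one.

    Each merge is a DCJ operation cutting one adjacency in an extra
    chromosome and one in the main chromosome and rejoining across; among
    all candidates (both rejoinings) the one minimally increasing the total
    DCJ distance to the three inputs is applied, ties broken
    lexicographically on (extra adjacency, main adjacency, rejoining).
    """
    adj = g.adj.copy()
    n = g.n
    while True:
        cur = CircularGenome(n=n, adj=adj.copy())
        chroms = cur.chromosomes()
        if len(chroms) == 1:
            return cur
        main_genes = next(
            set(abs(x) for x in ch) for ch in chroms if 0 in (abs(x) for x in ch)
        )
        extra_adjs = []
        main_adjs = []
        for x in range(2 * (n + 1)):
            y = int(adj[x])
            if x >= y:
                continue
            if (x // 2) in main_genes:
                main_adjs.append((x, y))
            else:
                extra_adjs.append((x, y))
        best = None
        for p, q in sorted(extra_adjs):
            for r, s in sorted(main_adjs):
                for rejoin in (0, 1):
                    cand = adj.copy()
                    if rejoin == 0:
                        cand[p], cand[r] = r, p
                        cand[q], cand[s] = s, q
                    else:
                        cand[p], cand[s] = s, p
                        cand[q], cand[r] = r, q
                    total = sum(
                        n + 1 - int(count_alternating_cycles(cand, inp.adj))
                        for inp in inputs
                    )
                    key = (total, (p, q), (r, s), rejoin)
                    if best is None or key < best[0]:
                        best = (key, cand)
        adj = best[1]


def asm_median(
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
    variant: str = "ASM4",
    criterion: str = "adequacy",
) -> MedianResult:
    """Approximate inversion median via the relaxed DCJ median heuristic.

    The reported ``dcj_score`` is the pre-merge DCJ median score
    3(n+1) - total cycles; ``extras`` counts the pre-merge non-cap circular
    chromosomes; ``tree_length`` is the inversion tree length of the final
    (merged, linearized) genome against the original inputs.
    """
    mbg = build_mbg(a, b, c)
    state = MatchingState(mbg)
    while state.remaining > 0:
        unm = state.unmatched_vertices()
        if len(unm) == 2 and unm[0] == CAP_TAIL and unm[1] == CAP_HEAD:
            state.add_edge(CAP_TAIL, CAP_HEAD)
            break
        edge = detect_adequate_subgraph(state)
        if edge is None:
            edge = select_edge(state, variant, criterion)
        state.add_edge(*edge)
    dcj_score = 3 * (a.n + 1) - sum(state.cycles)
    genome = state.to_genome()
    extras = genome.extra_chromosome_count()
    if extras:
        genome = merge_extra_chromosomes(
            genome, (circularize(a), circularize(b), circularize(c))
        )
    median = linearize(genome)
    return MedianResult(
        solver=variant,
        median=median,
        tree_length=tree_length(median, a, b, c),
        steps=state.edges,
        extras=extras,
        dcj_score=dcj_score,
    )
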