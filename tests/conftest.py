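from collections import deque

import numpy as np
import pytest

from medheur.examples import (
    OBS1_A,
    OBS1_B,
    OBS1_C,
    OBS1_D,
    OBS2_A,
    OBS2_B,
    OBS2_C,
    OBS2_D,
    OBS2_E,
    OBS2_F,
)


@pytest.fixture
def counterexample():
    """The published 6-gene quadruple: D is one good inversion from A."""
    return OBS1_A, OBS1_B, OBS1_C, OBS1_D


@pytest.fixture
def signature_sextet():
    """The published sextet pairing three inputs with three signatures."""
    return OBS2_A, OBS2_B, OBS2_C, OBS2_D, OBS2_E, OBS2_F


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def bfs_distances_from_identity(n):
    """Distance of every signed permutation of {1..n} from the identity.

    Independent breadth-first search over the inversion graph, used as the
    ground truth for the closed-form distance (keys are permutations
    relative to their comparison target).
    """
    ident = tuple(range(1, n + 1))
    rhos = [(i, j) for i in range(n) for j in range(i, n)]

    def rev(t, i, j):
        return t[:i] + tuple(-x for x in reversed(t[i : j + 1])) + t[j + 1 :]

    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        cur = queue.popleft()
        for i, j in rhos:
            nxt = rev(cur, i, j)
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                queue.append(nxt)
    return dist


def recount_closed_cycles(state, color_adj):
    """Independent per-color recount of cycles closed by a partial matching.

    Walks matching+color alternating paths from scratch; a closed cycle is
    one whose walk returns to its start without meeting an unmatched vertex.
    """
    match = {}
    for u, v in state.pairs:
        match[u] = v
        match[v] = u
    counts = []
    for adj in color_adj:
        seen = set()
        c = 0
        for start in match:
            if start in seen:
                continue
            x = start
            closed = True
            cycle = []
            while True:
                cycle.append(x)
                y = int(adj[x])
                cycle.append(y)
                if y not in match:
                    closed = False
                    break
                x = match[y]
                if x == start:
                    break
                if x in seen:  # pragma: no cover - defensive
                    closed = False
                    break
            seen.update(cycle)
            if closed:
                c += 1
        counts.append(c)
    return counts
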