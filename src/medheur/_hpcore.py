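"""Compiled kernels for inversion-distance and good-inversion computations.

Everything here works on plain int64 arrays holding a signed permutation
*relative to its comparison target*, i.e. the permutation ``b^-1 . a`` whose
distance to the identity equals d(a, b).  The public modules translate to and
from :class:`medheur.genome.SignedPermutation` at their boundaries.

The distance is the full Hannenhalli-Pevzner formula d = n + 1 - c + h + f
(cycles, hurdles, fortress) on the breakpoint graph of the permutation framed
by 0 and n+1.  Component classification is quadratic; at the genome sizes the
heuristics target this is never the bottleneck, and the simple formulation is
easy to audit against the breadth-first-search oracle.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# breakpoint graph machinery
# ---------------------------------------------------------------------------


@njit(cache=True)
def _unsigned_ext(p):
    """Doubled unsigned representation framed by 0 and 2n+1.

    Gene +x becomes (2x-1, 2x) and -x becomes (2x, 2x-1); the result has
    length 2n+2.  Black (reality) edges join positions (2e, 2e+1); gray
    (desire) edges join values (2e, 2e+1), e = 0..n.
    """
    n = p.shape[0]
    u = np.empty(2 * n + 2, np.int64)
    u[0] = 0
    for k in range(n):
        v = p[k]
        if v > 0:
            u[2 * k + 1] = 2 * v - 1
            u[2 * k + 2] = 2 * v
        else:
            u[2 * k + 1] = -2 * v
            u[2 * k + 2] = -2 * v - 1
    u[2 * n + 1] = 2 * n + 1
    return u


@njit(cache=True)
def _cycle_structure(u):
    """Walk the alternating black/gray cycles of the breakpoint graph.

    Returns (ncycles, vcyc, bcyc, bdir, pos): cycle id per value vertex, cycle
    id and traversal direction per black edge, and the position of each value.
    ``bdir[e]`` is +1 when the walk crosses black edge e from u[2e] to
    u[2e+1], -1 otherwise; two black edges of one cycle support a
    cycle-splitting (distance-reducing, absent hurdles) reversal exactly when
    their directions differ.
    """
    V = u.shape[0]
    m = V // 2
    pos = np.empty(V, np.int64)
    for i in range(V):
        pos[u[i]] = i
    vcyc = np.full(V, -1, np.int64)
    bcyc = np.empty(m, np.int64)
    bdir = np.empty(m, np.int64)
    c = 0
    for s in range(V):
        if vcyc[s] >= 0:
            continue
        x = s
        while vcyc[x] < 0:
            vcyc[x] = c
            px = pos[x]
            e = px // 2
            if px % 2 == 0:
                y = u[px + 1]
                bdir[e] = 1
            else:
                y = u[px - 1]
                bdir[e] = -1
            bcyc[e] = c
            vcyc[y] = c
            x = y ^ 1  # follow the gray edge
        c += 1
    return c, vcyc, bcyc, bdir, pos


@njit(cache=True)
def _uf_find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def _uf_union(parent, a, b):
    ra = _uf_find(parent, a)
    rb = _uf_find(parent, b)
    if ra != rb:
        parent[rb] = ra


@njit(cache=True)
def _hurdles_fortress(u, pos, vcyc, ncyc):
    """Count hurdles and detect a fortress.

    Components are connected components of the interleaving graph on
    nontrivial cycles; a component is unoriented when none of its gray edges
    is oriented (endpoint positions of equal parity sum).  A hurdle is an
    unoriented component whose span occurs as a single contiguous run in the
    cyclic order of unoriented-component material; a fortress needs an odd
    number (>= 3) of hurdles, all of which protect another unoriented
    component (superhurdles).
    """
    V = u.shape[0]
    m = V // 2

    lo = np.empty(m, np.int64)
    hi = np.empty(m, np.int64)
    ori = np.zeros(m, np.bool_)
    triv = np.zeros(m, np.bool_)
    for e in range(m):
        a = pos[2 * e]
        b = pos[2 * e + 1]
        if a < b:
            lo[e] = a
            hi[e] = b
        else:
            lo[e] = b
            hi[e] = a
        ori[e] = ((a + b) % 2) == 0
        triv[e] = (hi[e] - lo[e] == 1) and (lo[e] % 2 == 0)

    # union-find over nontrivial gray edges: same cycle, or interleaving
    parent = np.arange(m)
    cyc_rep = np.full(ncyc, -1, np.int64)
    for e in range(m):
        if triv[e]:
            continue
        ce = vcyc[2 * e]
        if cyc_rep[ce] < 0:
            cyc_rep[ce] = e
        else:
            _uf_union(parent, cyc_rep[ce], e)
    for e1 in range(m):
        if triv[e1]:
            continue
        for e2 in range(e1 + 1, m):
            if triv[e2]:
                continue
            if (lo[e1] < lo[e2] < hi[e1] < hi[e2]) or (
                lo[e2] < lo[e1] < hi[e2] < hi[e1]
            ):
                _uf_union(parent, e1, e2)

    comp_oriented = np.zeros(m, np.bool_)
    comp_present = np.zeros(m, np.bool_)
    for e in range(m):
        if triv[e]:
            continue
        r = _uf_find(parent, e)
        comp_present[r] = True
        if ori[e]:
            comp_oriented[r] = True

    # cyclic sequence of unoriented-component ids along the positions
    seq = np.empty(V, np.int64)
    k = 0
    for i in range(V):
        e = u[i] // 2
        if triv[e]:
            continue
        r = _uf_find(parent, e)
        if comp_oriented[r]:
            continue
        if k > 0 and seq[k - 1] == r:
            continue
        seq[k] = r
        k += 1
    if k == 0:
        return 0, 0
    # collapse cyclically
    if k > 1 and seq[0] == seq[k - 1]:
        k -= 1

    count = np.zeros(m, np.int64)
    for t in range(k):
        count[seq[t]] += 1
    h = 0
    for r in range(m):
        if comp_present[r] and not comp_oriented[r] and count[r] == 1:
            h += 1

    if h < 3 or h % 2 == 0:
        return h, 0

    # fortress check: every hurdle must be a superhurdle
    all_super = True
    for r in range(m):
        if not (comp_present[r] and not comp_oriented[r] and count[r] == 1):
            continue
        # drop r from the collapsed sequence and re-collapse cyclically
        seq2 = np.empty(k, np.int64)
        k2 = 0
        for t in range(k):
            if seq[t] == r:
                continue
            if k2 > 0 and seq2[k2 - 1] == seq[t]:
                continue
            seq2[k2] = seq[t]
            k2 += 1
        if k2 > 1 and seq2[0] == seq2[k2 - 1]:
            k2 -= 1
        count2 = np.zeros(m, np.int64)
        for t in range(k2):
            count2[seq2[t]] += 1
        protects = False
        for r2 in range(m):
            if r2 == r:
                continue
            if (
                comp_present[r2]
                and not comp_oriented[r2]
                and count[r2] > 1
                and count2[r2] == 1
            ):
                protects = True
                break
        if not protects:
            all_super = False
            break
    return h, (1 if all_super else 0)


@njit(cache=True)
def hp_stats(p):
    """(cycles, hurdles, fortress) of the breakpoint graph of p vs identity."""
    u = _unsigned_ext(p)
    c, vcyc, bcyc, bdir, pos = _cycle_structure(u)
    h, f = _hurdles_fortress(u, pos, vcyc, c)
    return c, h, f


@njit(cache=True)
def hp_distance(p):
    """Hannenhalli-Pevzner inversion distance n + 1 - c + h + f."""
    n = p.shape[0]
    c, h, f = hp_stats(p)
    return n + 1 - c + h + f


# ---------------------------------------------------------------------------
# sorting inversions and greedy good inversions
# ---------------------------------------------------------------------------


@njit(cache=True)
def _reversed_copy(p, i, j):
    q = p.copy()
    for k in range(i, j + 1):
        q[k] = -p[j - (k - i)]
    return q


@njit(cache=True)
def reverse_inplace(p, i, j):
    l = i
    r = j
    while l < r:
        t = p[l]
        p[l] = -p[r]
        p[r] = -t
        l += 1
        r -= 1
    if l == r:
        p[l] = -p[l]


@njit(cache=True)
def sorting_mask(p):
    """Boolean matrix over 0-based (i, j), i <= j: reversals with d -> d - 1.

    When the instance has no hurdles, only reversals that split a cycle
    (same cycle, opposite black-edge directions) can reduce the distance, so
    the full recomputation is restricted to those; with hurdles present every
    candidate is rechecked (hurdle-cutting and -merging reversals do not
    split cycles).
    """
    n = p.shape[0]
    mask = np.zeros((n, n), np.bool_)
    u = _unsigned_ext(p)
    c, vcyc, bcyc, bdir, pos = _cycle_structure(u)
    h, f = _hurdles_fortress(u, pos, vcyc, c)
    d0 = n + 1 - c + h + f
    if d0 == 0:
        return mask
    prescreen = (h == 0) and (f == 0)
    for i in range(n):
        for j in range(i, n):
            if prescreen:
                e1 = i
                e2 = j + 1
                if bcyc[e1] != bcyc[e2] or bdir[e1] == bdir[e2]:
                    continue
            q = _reversed_copy(p, i, j)
            if hp_distance(q) == d0 - 1:
                mask[i, j] = True
    return mask


@njit(cache=True)
def good_mask(pab, pac):
    """Good inversions of a w.r.t. b and c, as a 0-based (i, j) mask.

    ``pab`` and ``pac`` are a relative to b and to c; a positional reversal
    acts identically on both, so the masks align and intersect directly.
    """
    return np.logical_and(sorting_mask(pab), sorting_mask(pac))


@njit(cache=True)
def good_succ_counts(pab, pac):
    """For every good inversion, the number of good inversions left after it.

    Returns an (n, n) int64 matrix with -1 at non-good cells; the greedy
    selection maximizes this count.
    """
    n = pab.shape[0]
    out = np.full((n, n), -1, np.int64)
    g = good_mask(pab, pac)
    for i in range(n):
        for j in range(i, n):
            if not g[i, j]:
                continue
            qab = _reversed_copy(pab, i, j)
            qac = _reversed_copy(pac, i, j)
            g2 = good_mask(qab, qac)
            cnt = 0
            for x in range(n):
                for y in range(x, n):
                    if g2[x, y]:
                        cnt += 1
            out[i, j] = cnt
    return out


@njit(cache=True)
def count_alternating_cycles(adj1, adj2):
    """Cycles of the union of two perfect matchings on the same vertex set."""
    V = adj1.shape[0]
    visited = np.zeros(V, np.bool_)
    c = 0
    for s in range(V):
        if visited[s]:
            continue
        x = s
        while not visited[x]:
            visited[x] = True
            y = adj1[x]
            visited[y] = True
            x = adj2[y]
        c += 1
    return c


@njit(cache=True)
def dcj_median_branch_bound(color_adj, init_best):
    """Exact relaxed DCJ median score by depth-first branch and bound.

    ``color_adj`` is the (3, 2(n+1)) adjacency stack of the three
    circularized genomes; ``init_best`` must be an achievable score (it is
    returned unchanged if nothing better exists).  The search always extends
    the lowest unmatched vertex, tries partners in decreasing order of the
    cycles they close, and prunes with score >= 3(n+1) - (cycles + 3m),
    since each of the m remaining matching edges closes at most one
    alternating cycle per color.
    """
    V = color_adj.shape[1]
    m0 = V // 2
    far = color_adj.copy()
    matched = np.zeros(V, np.bool_)
    total3 = 3 * m0
    cycles_tot = 0
    best = init_best

    ubase = np.empty(m0, np.int64)
    uv = np.empty(m0, np.int64)
    plist = np.empty((m0, V), np.int64)
    pcnt = np.zeros(m0, np.int64)
    pidx = np.zeros(m0, np.int64)
    u_closed = np.zeros((m0, 3), np.bool_)
    u_x = np.zeros((m0, 3), np.int64)
    u_y = np.zeros((m0, 3), np.int64)

    depth = 0
    fresh = True
    while True:
        backtrack = False
        if fresh:
            fresh = False
            m = m0 - depth
            if m == 0:
                sc = total3 - cycles_tot
                if sc < best:
                    best = sc
                backtrack = True
            elif (total3 - cycles_tot) - 3 * m >= best:
                backtrack = True
            else:
                u = 0
                while matched[u]:
                    u += 1
                ubase[depth] = u
                cnt = 0
                for want in range(3, -1, -1):
                    for v in range(u + 1, V):
                        if matched[v]:
                            continue
                        d = 0
                        for c in range(3):
                            if far[c, u] == v:
                                d += 1
                        if d == want:
                            plist[depth, cnt] = v
                            cnt += 1
                pcnt[depth] = cnt
                pidx[depth] = 0

        if not backtrack and pidx[depth] >= pcnt[depth]:
            backtrack = True

        if backtrack:
            depth -= 1
            if depth < 0:
                return best
            # undo the edge applied at this depth
            u = ubase[depth]
            v = uv[depth]
            matched[u] = False
            matched[v] = False
            for c in range(3):
                if u_closed[depth, c]:
                    cycles_tot -= 1
                else:
                    far[c, u_x[depth, c]] = u
                    far[c, u_y[depth, c]] = v
            continue

        u = ubase[depth]
        v = plist[depth, pidx[depth]]
        pidx[depth] += 1
        for c in range(3):
            x = far[c, u]
            if x == v:
                u_closed[depth, c] = True
                cycles_tot += 1
            else:
                y = far[c, v]
                u_closed[depth, c] = False
                u_x[depth, c] = x
                u_y[depth, c] = y
                far[c, x] = y
                far[c, y] = x
        matched[u] = True
        matched[v] = True
        uv[depth] = v
        depth += 1
        fresh = True


@njit(cache=True)
def triple_scores(cands, rel):
    """Sum of the three inversion distances for a batch of candidate medians.

    ``cands`` is (K, n) signed permutations; ``rel`` is (3, n+1) where
    ``rel[t, g]`` is the signed position of gene g in target t (the inverse
    permutation), so that row-wise composition gives the relative permutation
    whose HP distance is d(candidate, target).
    """
    K, n = cands.shape
    out = np.empty(K, np.int64)
    q = np.empty(n, np.int64)
    for k in range(K):
        s = 0
        for t in range(3):
            for x in range(n):
                v = cands[k, x]
                if v > 0:
                    q[x] = rel[t, v]
                else:
                    q[x] = -rel[t, -v]
            s += hp_distance(q)
        out[k] = s
    return out
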