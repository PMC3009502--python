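# Methods

This note records the models, algorithmic choices and their rationale, the
simulation protocol, and the known limitations of `medheur`.

## Genome model

A genome is a signed permutation of `{1..n}`: unichromosomal, equal gene
content across genomes, no duplications or losses. These assumptions match
standard practice in rearrangement phylogenetics (realistic for syntenic
blocks more than for raw genes). Indices in the public API are 1-based and
inclusive, so `rho(i, j)` reverses the block `p_i..p_j` and flips its
signs. Transpositions move a block `[i..j]` to just after position `k`
(`i <= j < k <= n`) without inverting it; inverted transpositions are
deliberately excluded, as nothing downstream depends on them.

## Inversion distance

`d(A,B)` is the Hannenhalli–Pevzner formula `n + 1 − c + h + f` evaluated
on `B⁻¹∘A` framed by `0` and `n+1`:

* `c` — cycles of the breakpoint graph, counted by walking the alternating
  black/gray structure of the doubled unsigned representation.
* `h` — hurdles. Components are connected components of the interleaving
  relation on nontrivial cycles; a component is unoriented when none of its
  gray edges has endpoint positions of even sum; a hurdle is an unoriented
  component occurring as a single contiguous run in the cyclic order of
  unoriented material.
* `f` — fortress: an odd number (≥ 3) of hurdles, all of which protect
  another unoriented component (deleting the hurdle turns it into one).

The component classification is quadratic rather than linear. That is a
deliberate trade: at the genome sizes the heuristics target (≤ a few
thousand genes per call here) the distance is never the asymptotic
bottleneck, and the simple formulation is easy to audit — the
implementation is validated against an independent breadth-first-search
oracle, exhaustively for n = 3 and on hundreds of random pairs at n = 5,
plus spot checks at n = 6.

Sorting inversions are found by the naive scan: try all `n(n+1)/2`
candidates and keep those with `d → d − 1`. When the instance has no
hurdles, a candidate can only reduce the distance by splitting a cycle, so
the scan first classifies every candidate in O(1) (same cycle, opposite
black-edge traversal directions) and recomputes the distance only for the
survivors; with hurdles present every candidate is rechecked, since
hurdle-cutting and hurdle-merging inversions do not split cycles. The scan,
and the greedy good-inversion search built on it, are numba-compiled: the
greedy framework heuristics perform on the order of 10⁵–10⁶ distance
evaluations per n = 50 median call, which sets the package's practical
scale.

## The good-inversion framework

A good inversion for `A` w.r.t. `B` and `C` decrements both `d(A,B)` and
`d(A,C)`; it is the intersection of the two sorting-inversion sets at
matching positions. Greedy selection maximizes the number of good
inversions available afterwards, breaking ties by smallest `(i, j)` — a
deterministic rule chosen for reproducibility (a seeded random tie-break
and fully random selection are available). The six heuristics:

* **HS / HSE** (serial): one good inversion per permutation per round,
  each step referring to the latest iterates.
* **HP / HPE** (parallel): as above, but each round's steps refer to the
  round-start iterates.
* **MSS / MSP** (signatures): each permutation is driven to a *maximal
  signature* (no good inversion remains). MSP computes all three
  signatures against the original inputs; MSS re-anchors serially.

Plain variants stop the first time the permutation whose turn it is has no
good inversion; extended variants skip it and stop when a whole round
applies nothing. The output is always the best of the three final
permutations by tree length **with respect to the original inputs**.

Signature accounting: each good inversion decrements both reference
distances by exactly one, so after `k` steps
`S(A^k) = d(A,B) + d(A,C) − k`; the tests assert this identity along every
path. It implies MSP never scores worse than the trivial median.

**Termination guard.** The serial variants strictly decrease the current
pairwise-distance sum with every applied inversion and always terminate.
The parallel variants do not have this monotonicity — their steps are good
with respect to round-*start* iterates — and with deterministic greedy
selection the configuration can revisit itself and cycle forever (observed
on random 6-gene triples). All round-based variants therefore stop when a
round-start configuration repeats (exact for deterministic selection),
with a round cap of `4 × (initial pairwise perimeter + 1)` as a backstop
for randomized selection. MSS/MSP need no guard.

A caution the package's own fixtures demonstrate: good inversions are not
median-preserving. For the 6-gene fixture triple, one good inversion maps
`A` to `D`, both triples have median score 9, yet the median sets are
disjoint and routing through `D` costs tree length 10.

## The ASM heuristic

Linear genomes are closed into circles with a cap gene `0`; the three
circular genomes populate a multiple breakpoint graph on the `2(n+1)` gene
extremities, one colored perfect pairing per genome. A relaxed DCJ median
is a perfect matching maximizing the total number of color-alternating
cycles; its score is `3(n+1) − Σ cycles`, and it lower-bounds the
inversion median score. The matching is grown one edge at a time over a
contracted representation: per color, each unmatched vertex maps to the
far end of its alternating (matching + color) path, so the cycles an edge
closes are read off in O(1) per color and updated in O(1) per added edge.

* **Forced edges.** Two unmatched vertices connected through ≥ 2 colors
  form the size-1 adequate subgraph; choosing that edge preserves
  optimality, so such edges are applied whenever one exists. Larger
  adequate subgraphs are not enumerated; the greedy selection below covers
  their absence.
* **Candidate pools.** ASM4 scans all unmatched pairs (quartic overall),
  ASM3 only pairs containing the lowest-ordered unmatched vertex (cubic),
  ASM2 only those of them with a surviving colored connection (quadratic;
  if the focus vertex has none, that step falls back to the ASM3 pool).
  Extremities are ordered by gene then tail-before-head. The cap self-edge
  `(0_t, 0_h)` is excluded unless it is the only pair left.
* **Criteria.** Both criteria first maximize the number of cycles the edge
  closes. The `adequacy` criterion (default) breaks ties by the number of
  size-1 adequate subgraphs the edge *creates* in the contracted instance —
  a one-step lookahead computed from the spliced path ends, at O(1) extra
  cost per tied candidate. The rationale: adequacy measures guaranteed
  cycles per matching edge, and an edge that leaves forced edges behind
  buys ≥ 2 cycles each for free on subsequent steps. This reading is the
  package's own resolution of an under-specified criterion, and it is
  load-bearing: with it, ASM4 matched the exact relaxed DCJ median on
  100/100 random 4–6-gene triples (vs ~60–70 % with plain lexicographic
  tie-breaking). The `cycles` criterion goes straight to vertex order.
* **Merging.** The relaxed median may contain circular chromosomes without
  the cap. Each is removed by the DCJ operation cutting one adjacency in
  an extra chromosome and one in the cap-containing chromosome that
  minimally increases the total DCJ distance to the three inputs (both
  rejoinings considered; ties broken lexicographically). One merge removes
  one extra, so the loop terminates. Reported `extras` counts pre-merge
  chromosomes; `dcj_score` is also pre-merge, preserving its lower-bound
  meaning.

## Exact oracles

* `exact_inversion_median` enumerates all `2^n·n!` signed permutations
  (refused above n = 8) with the batch distance kernel, returning the full
  median set — needed for the median-set-disjointness observations.
* `exact_dcj_median` is a depth-first branch and bound over perfect
  matchings: always extends the lowest unmatched vertex, tries partners by
  decreasing cycle gain, prunes with `score ≥ 3(n+1) − (cycles + 3m)`
  (each remaining edge closes ≤ 1 cycle per color), and warm-starts from
  an ASM2 matching, whose score is achievable and hence a valid upper
  bound. It deliberately does not use adequate-subgraph forcing, so the
  test that forced edges preserve optimality compares two independent
  routes. An unpruned full enumerator (n ≤ 4) validates the pruning.
* `optimal_path_permutations` classifies permutations by the betweenness
  test `d(X,P) + d(P,Y) = d(X,Y)` per input pair (n ≤ 6).
* `bfs_inversion_distance` (n ≤ 5) is the distance ground truth.

## Simulation protocol and benchmark scales

A simulated dataset is a 3-leaf tree with the identity ancestor at the
internal node; leaf *i* is produced by `l_i` events. The evolutionary rate
is `r = (l₁+l₂+l₃)/n`; symmetric trees use per-edge length
`round(r·n/3)`. With a transposition fraction `f`, each edge applies
`round(f·l)` transpositions and the rest inversions, interleaved in
uniformly random order (the ordering is unspecified in the protocol the
package follows; interleaving avoids burn-in artifacts). Event parameters
are uniform over their valid index sets; all randomness flows through
explicit seeds, and identical seeds give identical outputs.

Reference points the test suite reproduces at these scales: mean tree
lengths over uniformly random triples of MSP ≈ 46.6, MSS ≈ 47.4,
HS ≈ 48.8, trivial ≈ 55.8 at n = 30 (per-instance std ≈ 1.3–1.6), and
MSP ≈ 80.3 at n = 50; ASM4 leaves ≈ 0.00 extra circular chromosomes on
100-gene symmetric trees at r = 0.1, and its inversion tree length
typically *equals* its DCJ lower bound on 200-gene trees up to r = 0.8
(gap ≤ 1 % on average), i.e. it returns certified-optimal inversion
medians on most such instances. Test and acceptance runs use 30–1000
replicates per cell and genome sizes 30–200: large enough for the stated
standard errors, small enough for a single-core desk run. The benchmark
drivers accept larger grids (sizes, rates, replicates) where more
precision is wanted. The published means being sample means over 1000
triples, the tests compare via the two-sample standard error.

What the simulator does not emulate: rearrangement hotspots, length-biased
inversions, unequal gene content, duplications/losses, and multichromosomal
genomes. Passing tests therefore certify algorithmic correctness and
behavior under the uniform-events model, not biological realism of any
particular reconstruction.

## Known limitations and deviations

* The per-instance dominance of MSP over the other framework heuristics
  (best score on *every* instance, not just on average) does not hold
  universally under this implementation's selection rules: on ~10 % of
  random n = 30 triples MSP loses by 1–2 inversions to MSS/HS/HSE, and
  exploration over tie-break and selection variants shows no rule
  recovering dominance on some instances. The corresponding acceptance
  check is left failing rather than weakened; the averages themselves
  reproduce.
* One published sextet of signature examples reproduces its median-set
  disjointness but not the claimed maximal-signature property of its three
  derived permutations (BFS-verified distances contradict the required
  accounting under every base/reference assignment); the corresponding
  acceptance sub-assertion is likewise left failing. The quadruple
  counterexample verifies fully.
* Exact solvers are desk-scale only (n ≤ 8); the framework heuristics are
  practical to n ≈ 50–100 in this implementation (the O(n⁵) greedy
  selection dominates); ASM handles thousands of genes, its cost driven by
  the ASM4 scan and, at high rates, the merge step.
* The unichromosomal-constrained DCJ median is out of scope; the relaxed
  median plus greedy merging stands in for it, which is exactly the ASM
  design premise.
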