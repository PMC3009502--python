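# medheur — median solvers for unichromosomal gene orders

Given three genomes with the same genes, the **median problem** asks for a
fourth genome minimizing the sum of its pairwise rearrangement distances to
the three — the basic step of distance-based ancestral reconstruction and
small-phylogeny analysis. With genomes modelled as signed permutations of
`{1..n}` and inversions as the evolutionary event, the pairwise distance
`d(A,B)` is computable exactly (Hannenhalli–Pevzner:
`d = n + 1 − c + h + f`, with `c` breakpoint-graph cycles, `h` hurdles and
`f` a fortress indicator), but the median problem is NP-hard, so practical
work relies on heuristics.

`medheur` is a toolkit for this problem aimed at people studying
rearrangement phylogenetics:

* **Distances** — exact inversion distance (full HP formula, validated
  exhaustively against breadth-first search), DCJ distance on circularized
  genomes, sorting-inversion enumeration, tree length
  `S(X) = d(X,A) + d(X,B) + d(X,C)`, and the perimeter lower bound
  `⌈(d(A,B)+d(A,C)+d(B,C))/2⌉`.
* **The good-inversion framework** — an inversion is *good* for `A` w.r.t.
  `B` and `C` if it lies on optimal sorting paths toward both. Six
  heuristics differ only in how often the reference pair is updated:
  serial/parallel stepwise variants (`HS`, `HSE`, `HP`, `HPE`) and the
  maximal-signature variants (`MSS`, `MSP`) that drive each input to a
  permutation with no good inversion left. Greedy selection (maximize the
  number of good inversions remaining) is the default.
* **ASM (`ASM2`/`ASM3`/`ASM4`)** — a fast DCJ-based heuristic. The three
  genomes are closed into circles with a cap gene `0` and entered into a
  multiple breakpoint graph; a relaxed DCJ median is a perfect matching of
  gene extremities maximizing color-alternating cycles. Forced edges
  (size-1 adequate subgraphs: vertex pairs linked through ≥ 2 colors) are
  applied whenever present; otherwise an edge is chosen greedily from a
  pool whose size gives the variant its name and cost. Leftover circular
  chromosomes are merged back greedily. The reported DCJ median score is a
  certified lower bound on the inversion median score, so the gap between
  the two bounds the solution's suboptimality.
* **Exact small-instance oracles** — exhaustive inversion-median
  enumeration (`n ≤ 8`), branch-and-bound relaxed DCJ median, optimal-path
  permutation sets, and BFS distances, used as ground truth by the tests.
* **Simulation & benchmarks** — uniform random signed permutations and
  3-leaf trees evolved from an identity ancestor at a chosen rate
  `r = events/n` with an optional transposition admixture, plus drivers
  that tabulate mean tree lengths, DCJ scores, distances to the true
  ancestor, and extra-chromosome counts.

## Worked example

The 6-gene triple shipped in `fixtures/counterexample.txt` has pairwise
distances 5, 6, 6, so no median can beat
`⌈(5+6+6)/2⌉ = 9`:

```python
import medheur as mh

genomes = dict(mh.read_genomes("fixtures/counterexample.txt"))
a, b, c = genomes["A"], genomes["B"], genomes["C"]

mh.exact_inversion_median(a, b, c)
# MedianSet(score=9, medians=frozenset({SignedPermutation((3, -6, 4, -1, -5, -2))}))

mh.asm_median(a, b, c)
# MedianResult(solver='ASM4', median=SignedPermutation(elements=(3, -6, 4, -1, -5, -2)),
#              tree_length=9, steps=7, extras=1, dcj_score=9)
```

The exact solver proves the median score is 9 and that the median is
unique; ASM4 finds that same genome. Its `dcj_score=9` says the relaxed
DCJ median also scores 9 — since the DCJ score lower-bounds the inversion
score, the heuristic's answer is certified optimal here. `extras=1` means
the raw DCJ matching contained one extra circular chromosome that was
merged back before reporting. The same run from the shell:

```
$ medheur median --solver ASM4 fixtures/counterexample.txt
solver  tree_length  steps  extras  dcj_score
ASM4    9            7      1       9
# median: 3 -6 4 -1 -5 -2
```

This triple is also a cautionary tale about good inversions: applying the
good inversion `rho(1,6)` to `A` gives `D = (2 -5 3 -4 6 -1)`
(`fixtures/counterexample_d.txt`), and `(D,B,C)` still has median score 9 —
but none of its medians is a median of `(A,B,C)`; the best of them has tree
length 10 w.r.t. the original triple. Good inversions are not
median-preserving, which is why the heuristics that keep referring to the
*original* inputs (MSP, ASM) outscore the ones that iterate away from them.

Benchmarks at larger sizes, e.g. mean tree lengths over random triples:

```
$ medheur bench-random --sizes 30 --replicates 100 --solvers MSP,trivial --seed 1
```

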