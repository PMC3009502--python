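"""Benchmark drivers: random-permutation and simulated-evolution grids.

``bench_random`` reproduces the random-permutation comparison of the
good-inversion heuristics (mean tree length per solver and genome size);
``bench_simulated`` runs the symmetric 3-leaf-tree protocol (identity
ancestor, per-edge event count round(r*n/3)) and additionally records the
DCJ median score, the inversion distance back to the true ancestor, and the
number of extra circular chromosomes for the ASM solvers.  Every row is
reproducible from (seed, n, rate, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .asm import ASM_VARIANTS, asm_median
from .distance import inversion_distance
from .framework import (
    FRAMEWORK_SOLVERS,
    MedianResult,
    run_heuristic,
    trivial_median,
)
from .genome import SignedPermutation, make_triple, random_permutation

__all__ = ["BenchmarkConfig", "ALL_SOLVERS", "solve", "bench_random", "bench_simulated", "summarize"]

ALL_SOLVERS = FRAMEWORK_SOLVERS + ASM_VARIANTS + ("trivial",)


@dataclass
class BenchmarkConfig:
    """Experiment grid for the benchmark drivers."""

    sizes: Sequence[int]
    replicates: int = 100
    solvers: Sequence[str] = ("MSP",)
    rates: Sequence[float] = ()
    transposition_fraction: float = 0.0
    selection: str = "greedy"
    criterion: str = "adequacy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for s in self.solvers:
            if s not in ALL_SOLVERS:
                raise ValueError(f"unknown solver {s!r}; choose from {ALL_SOLVERS}")


def solve(
    name: str,
    a: SignedPermutation,
    b: SignedPermutation,
    c: SignedPermutation,
    selection: str = "greedy",
    criterion: str = "adequacy",
    seed: Optional[int] = None,
) -> MedianResult:
    """Dispatch to a framework heuristic, an ASM variant, or the trivial median."""
    if name in FRAMEWORK_SOLVERS:
        return run_heuristic(name, a, b, c, selection=selection, seed=seed)
    if name in ASM_VARIANTS:
        return asm_median(a, b, c, variant=name, criterion=criterion)
    if name == "trivial":
        return trivial_median(a, b, c)
    raise ValueError(f"unknown solver {name!r}; choose from {ALL_SOLVERS}")


def _replicate_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def bench_random(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Tree lengths on uniformly random triples, one row per replicate."""
    rows = []
    for ni, n in enumerate(cfg.sizes):
        for rep in range(cfg.replicates):
            rng = _replicate_rng(cfg.seed, 0, ni, rep)
            triple = tuple(random_permutation(n, rng) for _ in range(3))
            for solver in cfg.solvers:
                res = solve(
                    solver,
                    *triple,
                    selection=cfg.selection,
                    criterion=cfg.criterion,
                    seed=cfg.seed,
                )
                rows.append(
                    {
                        "n": n,
                        "solver": solver,
                        "replicate": rep,
                        "seed": cfg.seed,
                        "tree_length": res.tree_length,
                        "steps": res.steps,
                    }
                )
    return pd.DataFrame(rows)


def bench_simulated(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Symmetric 3-leaf trees at the configured evolutionary rates."""
    rows = []
    for ni, n in enumerate(cfg.sizes):
        for ri, r in enumerate(cfg.rates):
            edge = round(r * n / 3)
            for rep in range(cfg.replicates):
                sub = int(
                    _replicate_rng(cfg.seed, 1, ni, ri, rep).integers(0, 2**31 - 1)
                )
                triple = make_triple(
                    n,
                    (edge, edge, edge),
                    transposition_fraction=cfg.transposition_fraction,
                    seed=sub,
                )
                for solver in cfg.solvers:
                    res = solve(
                        solver,
                        *triple.leaves,
                        selection=cfg.selection,
                        criterion=cfg.criterion,
                        seed=cfg.seed,
                    )
                    rows.append(
                        {
                            "n": n,
                            "rate": r,
                            "edge_length": edge,
                            "solver": solver,
                            "replicate": rep,
                            "seed": cfg.seed,
                            "tree_length": res.tree_length,
                            "dcj_score": res.dcj_score,
                            "dist_to_ancestor": inversion_distance(
                                res.median, triple.ancestor
                            ),
                            "extras": res.extras,
                        }
                    )
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean/std of the numeric outcome columns per experiment cell."""
    keys = [k for k in ("n", "rate", "solver") if k in df.columns]
    vals = [
        k
        for k in ("tree_length", "dcj_score", "dist_to_ancestor", "extras")
        if k in df.columns
    ]
    out = df.groupby(keys)[vals].agg(["mean", "std"]).round(2)
    out.columns = ["_".join(col) for col in out.columns]
    return out.reset_index()
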