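"""Signed gene orders: data model, rearrangement events, simulation, and I/O.

A unichromosomal genome with ``n`` genes is a signed permutation of
``{1, ..., n}``: the order gives the gene order along the chromosome and the
sign gives the strand.  An inversion ``rho(i, j)`` (1-based, inclusive)
reverses the block between positions ``i`` and ``j`` and flips its signs; a
transposition moves a block elsewhere without changing signs.

The evolutionary simulator applies a seeded random mix of inversions and
transpositions to the identity ancestor, producing the 3-leaf-tree instances
used to benchmark median solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SignedPermutation",
    "Inversion",
    "SimulatedTriple",
    "GenomeError",
    "InvalidInversionError",
    "InvalidTranspositionError",
    "GenomeParseError",
    "GeneSetMismatchError",
    "apply_inversion",
    "apply_transposition",
    "random_permutation",
    "evolve",
    "make_triple",
    "read_genomes",
    "write_genomes",
]


class GenomeError(ValueError):
    """Base class for errors raised by this package on invalid genome input."""


class InvalidInversionError(GenomeError):
    """Inversion indices out of range for the permutation."""


class InvalidTranspositionError(GenomeError):
    """Transposition indices invalid (need 1 <= i <= j < k <= n)."""


class GenomeParseError(GenomeError):
    """Malformed genome file; the message names the offending line."""


class GeneSetMismatchError(GenomeError):
    """Two genomes passed to a comparison do not share the same gene set."""


@dataclass(frozen=True)
class SignedPermutation:
    """A signed permutation of {1..n} representing a unichromosomal genome."""

    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        elems = tuple(int(v) for v in self.elements)
        object.__setattr__(self, "elements", elems)
        n = len(elems)
        if sorted(abs(v) for v in elems) != list(range(1, n + 1)):
            raise GenomeError(
                f"not a signed permutation of 1..{n}: {elems!r} "
                "(each absolute value 1..n must occur exactly once; no zeros)"
            )

    @property
    def n(self) -> int:
        return len(self.elements)

    @classmethod
    def identity(cls, n: int) -> "SignedPermutation":
        return cls(tuple(range(1, n + 1)))

    @classmethod
    def from_array(cls, arr: Sequence[int]) -> "SignedPermutation":
        return cls(tuple(int(v) for v in arr))

    def to_array(self) -> np.ndarray:
        return np.array(self.elements, dtype=np.int64)

    def apply(self, rho: "Inversion") -> "SignedPermutation":
        return apply_inversion(self, rho)

    def __str__(self) -> str:
        return " ".join(str(v) for v in self.elements)


class Inversion(NamedTuple):
    """The inversion rho(i, j), 1-based and inclusive on both ends."""

    i: int
    j: int


@dataclass(frozen=True)
class SimulatedTriple:
    """A symmetric-or-not 3-leaf tree instance: identity ancestor, 3 leaves.

    ``rate`` is the total number of simulated events divided by the genome
    size n; ``mix`` is the fraction of events that were transpositions.
    """

    ancestor: SignedPermutation
    leaves: tuple[SignedPermutation, SignedPermutation, SignedPermutation]
    edge_lengths: tuple[int, int, int]
    rate: float
    mix: float
    seed: int


def apply_inversion(p: SignedPermutation, rho: Inversion) -> SignedPermutation:
    """Return ``p . rho(i, j)``: block p_i..p_j reversed with signs flipped."""
    i, j = rho
    n = p.n
    if not (1 <= i <= j <= n):
        raise InvalidInversionError(f"rho({i},{j}) invalid for n={n}")
    e = p.elements
    block = tuple(-v for v in reversed(e[i - 1 : j]))
    return SignedPermutation(e[: i - 1] + block + e[j:])


def apply_transposition(
    p: SignedPermutation, i: int, j: int, k: int
) -> SignedPermutation:
    """Move block p_i..p_j to just after position k (signs unchanged).

    Requires 1 <= i <= j < k <= n, so the block always moves rightward past
    at least one gene; every transposition can be written this way.
    """
    n = p.n
    if not (1 <= i <= j < k <= n):
        raise InvalidTranspositionError(
            f"transposition (i={i}, j={j}, k={k}) invalid for n={n}"
        )
    e = p.elements
    out = e[: i - 1] + e[j:k] + e[i - 1 : j] + e[k:]
    return SignedPermutation(out)


def _as_rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_permutation(
    n: int, seed: "int | np.random.Generator"
) -> SignedPermutation:
    """A uniform draw from the 2^n * n! signed permutations of {1..n}."""
    if n < 1:
        raise GenomeError(f"need n >= 1, got {n}")
    rng = _as_rng(seed)
    order = rng.permutation(n) + 1
    signs = rng.integers(0, 2, size=n) * 2 - 1
    return SignedPermutation.from_array(order * signs)


def _random_inversion(n: int, rng: np.random.Generator) -> Inversion:
    # uniform over the n(n+1)/2 index pairs i <= j
    t = int(rng.integers(0, n * (n + 1) // 2))
    i = 1
    while t >= n - i + 1:
        t -= n - i + 1
        i += 1
    return Inversion(i, i + t)


def _random_transposition(n: int, rng: np.random.Generator) -> tuple[int, int, int]:
    if n < 2:
        raise InvalidTranspositionError("no legal transposition for n < 2")
    # rejection sampling: uniform over {(i, j, k) : 1 <= i <= j < k <= n}
    while True:
        i, j, k = (int(v) for v in rng.integers(1, n + 1, size=3))
        if i <= j < k:
            return i, j, k


def evolve(
    p: SignedPermutation,
    n_inv: int,
    n_transp: int,
    seed: "int | np.random.Generator",
) -> SignedPermutation:
    """Apply ``n_inv`` random inversions and ``n_transp`` random
    transpositions, interleaved in uniformly random order."""
    if n_inv < 0 or n_transp < 0:
        raise GenomeError("event counts must be nonnegative")
    rng = _as_rng(seed)
    events = np.array([0] * n_inv + [1] * n_transp)
    rng.shuffle(events)
    cur = p
    for ev in events:
        if ev == 0:
            cur = apply_inversion(cur, _random_inversion(cur.n, rng))
        else:
            i, j, k = _random_transposition(cur.n, rng)
            cur = apply_transposition(cur, i, j, k)
    return cur


def make_triple(
    n: int,
    edge_lengths: tuple[int, int, int],
    transposition_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedTriple:
    """Simulate a 3-leaf tree: identity ancestor, one leaf per edge.

    Each leaf is produced by ``edge_lengths[i]`` events; a fraction
    ``transposition_fraction`` of each edge's events (rounded) are
    transpositions, the rest inversions.
    """
    if n < 1:
        raise GenomeError(f"need n >= 1, got {n}")
    f = float(transposition_fraction)
    if not (0.0 <= f <= 1.0):
        raise GenomeError("transposition_fraction must be in [0, 1]")
    lengths = tuple(int(l) for l in edge_lengths)
    if any(l < 0 for l in lengths):
        raise GenomeError("edge lengths must be nonnegative")
    ancestor = SignedPermutation.identity(n)
    children = np.random.SeedSequence(seed).spawn(3)
    leaves = []
    for l, child in zip(lengths, children):
        n_tr = round(f * l)
        n_iv = l - n_tr
        leaves.append(evolve(ancestor, n_iv, n_tr, np.random.default_rng(child)))
    rate = sum(lengths) / n
    return SimulatedTriple(
        ancestor=ancestor,
        leaves=tuple(leaves),
        edge_lengths=lengths,
        rate=rate,
        mix=f,
        seed=seed,
    )


def read_genomes(path) -> list[tuple[str, SignedPermutation]]:
    """Read named genomes from a GRAPPA-style plain-text file.

    A line starting with ``>`` names a genome; the following line(s) hold
    whitespace-separated signed integers.  A trailing ``$`` terminator is
    tolerated and ignored.
    """
    genomes: list[tuple[str, SignedPermutation]] = []
    name: str | None = None
    values: list[int] = []
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal name, values
        if name is None:
            return
        try:
            perm = SignedPermutation(tuple(values))
        except GenomeError as exc:
            raise GenomeParseError(
                f"{path}: genome {name!r} starting at line {start_line}: {exc}"
            ) from exc
        genomes.append((name, perm))
        name, values = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].strip() or f"genome{len(genomes) + 1}"
                start_line = line_no
                continue
            if name is None:
                raise GenomeParseError(
                    f"{path}: line {line_no}: data before any '>' header"
                )
            for tok in line.replace("$", " ").split():
                try:
                    v = int(tok)
                except ValueError:
                    raise GenomeParseError(
                        f"{path}: line {line_no}: bad token {tok!r}"
                    ) from None
                if v == 0:
                    raise GenomeParseError(
                        f"{path}: line {line_no}: zero is not a valid gene"
                    )
                values.append(v)
        flush(line_no=-1)
    return genomes


def write_genomes(path, genomes: Iterable[tuple[str, SignedPermutation]]) -> None:
    """Write named genomes in the dialect accepted by :func:`read_genomes`."""
    with open(path, "w") as fh:
        for name, perm in genomes:
            fh.write(f">{name}\n{perm}\n")
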