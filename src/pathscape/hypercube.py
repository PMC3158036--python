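"""Genotypes, the binary hypercube, and landscape topography.

A genotype over ``L`` biallelic loci is a length-``L`` vector of 0/1 alleles
(1 = mutation present).  Genotypes are stored as integers ``0 .. 2**L - 1``
with bit ``i`` holding the allele at locus ``i`` (little-endian), which makes
single-locus mutations XOR operations and allows dense fitness storage.  All
public functions also accept genotypes written as bit sequences (tuples,
lists, or strings such as ``"0101"``, read left to right as locus 0, 1, ...).

A :class:`Landscape` maps every genotype on the ``L``-cube to a finite real
fitness.  Zero fitness encodes a non-viable (lethal) genotype wherever
viability matters; topographic operations only ever compare fitnesses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "TieError",
    "Landscape",
    "as_index",
    "as_bits",
    "hamming_distance",
    "antipode",
    "neighbors",
    "global_maximum",
    "local_maxima",
    "greedy_walk",
    "basins",
    "enumerate_shortest_paths",
]


class TieError(ValueError):
    """Raised when an operation requires strictly distinguishable fitnesses.

    Fitness ties are not silently broken: a tie for a global maximum or
    among the best improving neighbors of a greedy walk is surfaced so that
    empirical data with duplicated measurements cannot be misinterpreted.
    """


GenotypeLike = int | Sequence[int] | str


def as_index(g: GenotypeLike, L: int | None = None) -> int:
    """Return the integer index of a genotype.

    Bit sequences are read with position 0 as locus 0.  ``L`` is only used
    for validation when ``g`` is already an integer.
    """
    if isinstance(g, (int, np.integer)):
        idx = int(g)
        if idx < 0:
            raise ValueError(f"negative genotype index {idx}")
        if L is not None and idx >= (1 << L):
            raise ValueError(f"genotype index {idx} out of range for L={L}")
        return idx
    bits = [int(b) for b in g]
    if any(b not in (0, 1) for b in bits):
        raise ValueError(f"non-binary genotype {g!r}")
    if L is not None and len(bits) != L:
        raise ValueError(f"genotype length {len(bits)} != L={L}")
    return sum(b << i for i, b in enumerate(bits))


def as_bits(g: GenotypeLike, L: int) -> tuple[int, ...]:
    """Return the genotype as a tuple of ``L`` alleles (locus 0 first)."""
    idx = as_index(g, L)
    return tuple((idx >> i) & 1 for i in range(L))


def _lengths(a: GenotypeLike, b: GenotypeLike) -> int | None:
    la = len(a) if not isinstance(a, (int, np.integer)) else None
    lb = len(b) if not isinstance(b, (int, np.integer)) else None
    if la is not None and lb is not None and la != lb:
        raise ValueError(f"genotype length mismatch: {la} != {lb}")
    return la if la is not None else lb


def hamming_distance(a: GenotypeLike, b: GenotypeLike) -> int:
    """Number of loci at which two genotypes differ."""
    L = _lengths(a, b)
    return (as_index(a, L) ^ as_index(b, L)).bit_count()


def antipode(g: GenotypeLike, L: int | None = None) -> GenotypeLike:
    """The genotype differing from ``g`` at every locus.

    For integer input ``L`` is required; sequence/string input is returned
    in its own representation.
    """
    if isinstance(g, (int, np.integer)):
        if L is None:
            raise ValueError("antipode of an integer genotype requires L")
        return as_index(g, L) ^ ((1 << L) - 1)
    flipped = [1 - int(b) for b in g]
    if isinstance(g, str):
        return "".join(str(b) for b in flipped)
    return type(g)(flipped) if isinstance(g, (list, tuple)) else tuple(flipped)


def neighbors(g: GenotypeLike, L: int | None = None) -> set[int]:
    """The ``L`` genotypes one point mutation away, as integer indices."""
    if not isinstance(g, (int, np.integer)):
        L = len(g)
    if L is None:
        raise ValueError("neighbors of an integer genotype requires L")
    idx = as_index(g, L)
    return {idx ^ (1 << i) for i in range(L)}


@dataclass(frozen=True)
class Landscape:
    """A fitness landscape on the ``L``-dimensional binary hypercube.

    Parameters
    ----------
    L : int
        Number of loci (``L >= 1``).
    fitness : ndarray of shape ``(2**L,)``
        Fitness of every genotype, indexed by genotype integer.  Values must
        be finite; ``fitness > 0`` defines viability where it matters.
    locus_names : tuple of str, optional
        Labels for the loci, in bit order.  Defaults to ``locus0 ..``.
    meta : dict, optional
        Free-form provenance (model name, parameters, interaction sets).
    """

    L: int
    fitness: np.ndarray
    locus_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        f = np.asarray(self.fitness, dtype=float)
        if f.shape != (1 << self.L,):
            raise ValueError(
                f"fitness must have shape ({1 << self.L},), got {f.shape}"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError("fitness values must be finite")
        object.__setattr__(self, "fitness", f)
        names = tuple(self.locus_names) or tuple(
            f"locus{i}" for i in range(self.L)
        )
        if len(names) != self.L:
            raise ValueError("locus_names length must equal L")
        object.__setattr__(self, "locus_names", names)

    @property
    def n_genotypes(self) -> int:
        return 1 << self.L

    @property
    def full_mask(self) -> int:
        return (1 << self.L) - 1

    def fitness_of(self, g: GenotypeLike) -> float:
        return float(self.fitness[as_index(g, self.L)])

    def viable(self) -> np.ndarray:
        """Boolean viability (fitness strictly positive) per genotype."""
        return self.fitness > 0


def _neighbor_fitness_matrix(lsc: Landscape) -> np.ndarray:
    """Fitness of the i-th neighbor of every genotype, shape (2**L, L)."""
    idx = np.arange(lsc.n_genotypes)
    cols = [lsc.fitness[idx ^ (1 << i)] for i in range(lsc.L)]
    return np.stack(cols, axis=1)


def global_maximum(lsc: Landscape) -> int:
    """Genotype with the strictly largest fitness.

    Raises
    ------
    TieError
        If the maximal fitness is attained by more than one genotype.
    """
    f = lsc.fitness
    top = np.flatnonzero(f == f.max())
    if top.size > 1:
        raise TieError(
            f"global maximum tied among genotypes {top.tolist()} "
            f"(fitness {f.max()!r})"
        )
    return int(top[0])


def local_maxima(lsc: Landscape) -> set[int]:
    """All genotypes strictly fitter than every one-mutant neighbor."""
    nf = _neighbor_fitness_matrix(lsc)
    mask = np.all(lsc.fitness[:, None] > nf, axis=1)
    return set(np.flatnonzero(mask).tolist())


def greedy_walk(lsc: Landscape, start: GenotypeLike) -> list[int]:
    """Steepest-ascent adaptive walk from ``start`` to a local maximum.

    At each step the walk moves to the fittest neighbor provided it is
    strictly fitter than the current genotype, and stops otherwise.  The
    returned path includes the start; a walk started on a local maximum has
    length one.

    Raises
    ------
    TieError
        If the best improving move is tied between several neighbors.
    """
    g = as_index(start, lsc.L)
    f = lsc.fitness
    path = [g]
    while True:
        nbrs = [g ^ (1 << i) for i in range(lsc.L)]
        nf = f[nbrs]
        best = nf.max()
        if best <= f[g]:
            return path
        winners = [n for n, fn in zip(nbrs, nf) if fn == best]
        if len(winners) > 1:
            raise TieError(
                f"greedy walk tie at genotype {g}: neighbors {winners} "
                f"share fitness {best!r}"
            )
        g = winners[0]
        path.append(g)


def basins(lsc: Landscape) -> dict[int, int]:
    """Map every genotype to the local maximum its greedy walk reaches.

    Implemented by computing each genotype's single steepest-ascent move and
    then following the resulting successor pointers, so the whole landscape
    is resolved in O(2^L · L).
    """
    f = lsc.fitness
    nf = _neighbor_fitness_matrix(lsc)
    best = nf.max(axis=1)
    improving = best > f
    # tie = more than one neighbor achieving the best improving fitness
    n_best = np.sum(nf == best[:, None], axis=1)
    tied = np.flatnonzero(improving & (n_best > 1))
    if tied.size:
        raise TieError(
            f"greedy walk tie at genotype(s) {tied.tolist()[:5]}"
        )
    idx = np.arange(lsc.n_genotypes)
    arg = np.argmax(nf, axis=1)
    succ = np.where(improving, idx ^ (1 << arg), idx)
    # pointer jumping: walks have at most 2^L steps, doubling converges fast
    while True:
        nxt = succ[succ]
        if np.array_equal(nxt, succ):
            break
        succ = nxt
    return {int(g): int(m) for g, m in enumerate(succ)}


def enumerate_shortest_paths(
    a: GenotypeLike, b: GenotypeLike, L: int | None = None
) -> Iterator[list[int]]:
    """Yield every shortest path between two genotypes.

    If ``a`` and ``b`` differ at ``D`` loci there are exactly ``D!`` shortest
    paths, one per order in which the differing loci can be flipped; each is
    yielded as a list of ``D + 1`` genotype indices starting at ``a``.
    Factorial growth makes this practical only for ``D`` up to about 8.
    """
    if not isinstance(a, (int, np.integer)):
        L = len(a)
    ai, bi = as_index(a, L), as_index(b, L)
    diff = [i for i in range(max(ai ^ bi, 1).bit_length()) if (ai ^ bi) >> i & 1]
    for order in itertools.permutations(diff):
        path = [ai]
        g = ai
        for i in order:
            g ^= 1 << i
            path.append(g)
        yield path
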