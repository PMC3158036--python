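"""Exact accessible-path counting and ensemble statistics.

A shortest path between two genotypes at Hamming distance D flips each of
the D differing loci exactly once; there are D! of them.  A path is
*selectively accessible* when fitness increases strictly at every step, so
a population under strong selection and weak mutation can traverse it
without ever declining in fitness.  Equal fitnesses never count as an
increase, so measurement ties conservatively block a step.

Counting uses an iterative depth-first backtracking search over the
sub-hypercube spanned by the differing loci (an explicit stack, no
recursion).  Existence queries short-circuit on the first complete path and
memoize dead ends, which reduces the worst case from D! path extensions to
O(2^D · D) and makes large genotype spaces tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable

import numpy as np

from .hypercube import GenotypeLike, Landscape, antipode, as_index, global_maximum

__all__ = [
    "PathStats",
    "count_accessible_paths",
    "has_accessible_path",
    "count_antipodal",
    "count_lethal_free_paths",
    "ensemble_stats",
    "cumulative",
]


def count_accessible_paths(
    lsc: Landscape, start: GenotypeLike, end: GenotypeLike
) -> int:
    """Number of shortest paths from ``start`` to ``end`` along which
    fitness strictly increases at every step.

    The result lies in ``[0, D!]`` for endpoints at Hamming distance D;
    coincident endpoints give 1 (the empty path).
    """
    s = as_index(start, lsc.L)
    e = as_index(end, lsc.L)
    if s == e:
        return 1
    f = lsc.fitness
    count = 0
    # stack holds (genotype, iterator position) pairs; moves flip one of
    # the bits still differing from the end genotype
    stack: list[tuple[int, int]] = [(s, 0)]
    while stack:
        g, i = stack.pop()
        diff = g ^ e
        # resume scanning candidate loci from position i
        advanced = False
        while i < lsc.L:
            bit = 1 << i
            i += 1
            if diff & bit:
                nxt = g ^ bit
                if f[nxt] > f[g]:
                    if nxt == e:
                        count += 1
                    else:
                        stack.append((g, i))  # backtrack point
                        stack.append((nxt, 0))
                        advanced = True
                        break
        if advanced:
            continue
    return count


def has_accessible_path(
    lsc: Landscape, start: GenotypeLike, end: GenotypeLike
) -> bool:
    """Whether at least one accessible shortest path exists.

    Equivalent to ``count_accessible_paths(...) >= 1`` but stops at the
    first complete path and memoizes genotypes proven to be dead ends.
    """
    s = as_index(start, lsc.L)
    e = as_index(end, lsc.L)
    if s == e:
        return True
    f = lsc.fitness
    dead: set[int] = set()
    stack: list[tuple[int, int]] = [(s, 0)]
    while stack:
        g, i = stack.pop()
        diff = g ^ e
        advanced = False
        while i < lsc.L:
            bit = 1 << i
            i += 1
            if diff & bit:
                nxt = g ^ bit
                if nxt not in dead and f[nxt] > f[g]:
                    if nxt == e:
                        return True
                    stack.append((g, i))
                    stack.append((nxt, 0))
                    advanced = True
                    break
        if not advanced:
            # every continuation from g failed: g can never lead to the end
            dead.add(g)
    return False


def count_antipodal(lsc: Landscape) -> int:
    """Accessible paths from the antipode of the global maximum to the
    global maximum (the longest, least accessible direct paths).

    Raises :class:`~pathscape.hypercube.TieError` if the global maximum is
    not unique.
    """
    gm = global_maximum(lsc)
    return count_accessible_paths(lsc, antipode(gm, lsc.L), gm)


def count_lethal_free_paths(
    lsc: Landscape, start: GenotypeLike, end: GenotypeLike
) -> int:
    """Number of shortest paths on which every genotype, endpoints
    included, is viable (fitness > 0); fitness order along the path is
    ignored.

    Computed by dynamic programming over the sub-hypercube between the
    endpoints, summing path multiplicities level by level.
    """
    s = as_index(start, lsc.L)
    e = as_index(end, lsc.L)
    f = lsc.fitness
    if f[s] <= 0 or f[e] <= 0:
        return 0
    if s == e:
        return 1
    diff = s ^ e
    loci = [i for i in range(lsc.L) if diff >> i & 1]
    ways = {s: 1}
    for _ in loci:
        nxt: dict[int, int] = {}
        for g, w in ways.items():
            remaining = g ^ e
            for i in loci:
                bit = 1 << i
                if remaining & bit:
                    ng = g ^ bit
                    if f[ng] > 0:
                        nxt[ng] = nxt.get(ng, 0) + w
        ways = nxt
    return ways.get(e, 0)


@dataclass(frozen=True)
class PathStats:
    """Distribution of accessible-path counts over a landscape ensemble.

    ``histogram`` maps a path count n to its estimated probability P(n).
    ``p_zero`` is P(0), the probability that no accessible path exists.
    In existence-only mode the histogram and mean are unavailable (None).
    """

    n_realizations: int
    p_zero: float
    p_zero_se: float
    histogram: dict[int, float] | None = None
    mean: float | None = None
    mean_se: float | None = None

    def cumulative(self, n: int) -> float:
        """P_c(n): probability of at least ``n`` accessible paths."""
        if self.histogram is None:
            if n <= 0:
                return 1.0
            if n == 1:
                return 1.0 - self.p_zero
            raise ValueError("full histogram required for cumulative(n>1)")
        if n <= 0:
            return 1.0
        return float(sum(p for m, p in self.histogram.items() if m >= n))


def cumulative(stats: PathStats, n: int) -> float:
    """Module-level alias for :meth:`PathStats.cumulative`."""
    return stats.cumulative(n)


def ensemble_stats(
    sampler: Callable[[np.random.Generator], Landscape],
    reps: int,
    seed: int | None = None,
    mode: str = "count",
    counter: Callable[[Landscape], int] | None = None,
    exists: Callable[[Landscape], bool] | None = None,
) -> PathStats:
    """Monte-Carlo statistics of accessible-path counts over an ensemble.

    Parameters
    ----------
    sampler : callable
        ``sampler(rng) -> Landscape``; called once per realization with an
        independent substream spawned from ``seed``.
    reps : int
        Number of realizations (``>= 1``).
    mode : {"count", "exists"}
        ``"count"`` tallies the full distribution P(n) with its mean;
        ``"exists"`` only estimates P(0) using the early-exit search,
        which is much faster and scales to larger genotype spaces.
    counter, exists : callable, optional
        Per-landscape statistic.  Defaults to the antipodal accessible-path
        count / existence (global maximum vs. its antipode).  Pass e.g. a
        lethal-free counter for holey ensembles, which have no fitness
        ordering.

    Standard errors are the binomial error for P(0) and the sample standard
    error for the mean.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("count", "exists"):
        raise ValueError(f"unknown mode {mode!r}")
    streams = np.random.SeedSequence(seed).spawn(reps)
    if mode == "exists":
        check = exists or (lambda lsc: has_accessible_path(
            lsc, antipode(global_maximum(lsc), lsc.L), global_maximum(lsc)))
        zeros = 0
        for ss in streams:
            lsc = sampler(np.random.default_rng(ss))
            if not check(lsc):
                zeros += 1
        p0 = zeros / reps
        return PathStats(
            n_realizations=reps,
            p_zero=p0,
            p_zero_se=float(np.sqrt(p0 * (1 - p0) / reps)),
        )
    count = counter or count_antipodal
    counts = np.empty(reps, dtype=np.int64)
    for r, ss in enumerate(streams):
        lsc = sampler(np.random.default_rng(ss))
        counts[r] = count(lsc)
    values, freq = np.unique(counts, return_counts=True)
    hist = {int(v): float(c) / reps for v, c in zip(values, freq)}
    p0 = hist.get(0, 0.0)
    return PathStats(
        n_realizations=reps,
        p_zero=p0,
        p_zero_se=float(np.sqrt(p0 * (1 - p0) / reps)),
        histogram=hist,
        mean=float(counts.mean()),
        mean_se=float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
    )


def max_paths(D: int) -> int:
    """D!: the total number of shortest paths between genotypes at
    Hamming distance D."""
    return factorial(D)
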