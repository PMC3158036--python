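"""Random-landscape ensembles: House of Cards, Rough Mount Fuji, LK, holey.

All samplers take either an integer seed or a ``numpy.random.Generator`` and
are deterministic given the seed.  Ensemble drivers derive one independent
substream per realization from a master seed (see
:func:`pathscape.accessibility.ensemble_stats`), so results are reproducible
and independent of evaluation order.

Model conventions
-----------------
* House of Cards (HoC): i.i.d. fitness values.  Only fitness ranks matter
  for accessibility, so the base distribution is uniform(0, 1).
* Rough Mount Fuji (RMF): an additive slope of strength ``c`` toward a
  designated optimum (the all-zeros genotype) plus i.i.d. noise,
  ``F(g) = -c * d(g) + eta_g`` with ``d`` the Hamming distance to the
  optimum.  Noise is standard normal by default; standard Gumbel is
  available to match the exactly solvable case.  ``c = 0`` recovers HoC.
  Stored fitnesses are shifted to be strictly positive; accessibility is
  invariant under a common shift.
* LK (a.k.a. NK): each locus i contributes an amount depending on its own
  allele and the alleles of K epistatic partner loci; contributions are
  i.i.d. uniform(0, 1) table entries, and total fitness is their sum.
  ``K = 0`` is purely additive, ``K = L - 1`` is equivalent to HoC.
* Holey: each genotype is independently viable (fitness 1) with probability
  ``p`` or lethal (fitness 0); accessibility becomes a percolation question.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import Landscape

__all__ = [
    "RMFParams",
    "LKParams",
    "HoleyParams",
    "sample_hoc",
    "sample_rmf",
    "sample_lk",
    "sample_holey",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _hamming_weights(L: int) -> np.ndarray:
    idx = np.arange(1 << L, dtype=np.uint64)
    w = np.zeros(1 << L, dtype=np.int64)
    for i in range(L):
        w += ((idx >> np.uint64(i)) & np.uint64(1)).astype(np.int64)
    return w


@dataclass(frozen=True)
class RMFParams:
    """Rough-Mount-Fuji parameters: ``L`` loci, slope ``c >= 0``, noise law."""

    L: int
    c: float
    noise: str = "normal"  # "normal" | "gumbel"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.c < 0:
            raise ValueError("slope c must be >= 0")
        if self.noise not in ("normal", "gumbel"):
            raise ValueError(f"unknown noise {self.noise!r}")


@dataclass(frozen=True)
class LKParams:
    """LK-model parameters.

    ``scheme`` selects how each locus's K partners are chosen: ``"random"``
    draws K distinct partners uniformly (resampled for every realization),
    ``"adjacent"`` uses the K cyclically following loci.  The literature uses
    both conventions; quantitative curves can shift slightly between them.
    """

    L: int
    K: int
    scheme: str = "random"  # "random" | "adjacent"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0 <= self.K <= self.L - 1:
            raise ValueError(f"K must satisfy 0 <= K <= L-1, got K={self.K}")
        if self.scheme not in ("random", "adjacent"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class HoleyParams:
    """Holey-landscape parameters: viability probability ``p`` in [0, 1]."""

    L: int
    p: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def sample_hoc(
    L: int,
    seed: int | np.random.Generator | None = None,
    condition_antipode_min: bool = False,
    method: str = "relocate",
) -> Landscape:
    """Draw a House-of-Cards landscape: 2**L i.i.d. uniform(0, 1) fitnesses.

    With ``condition_antipode_min`` the landscape is conditioned on the
    antipode of the global maximum being the global minimum.  By
    exchangeability of i.i.d. values this conditioning is realized exactly
    by relocating the smallest value to the antipode of the maximum
    (``method="relocate"``); ``method="rejection"`` redraws whole landscapes
    until the condition holds, as a cross-check.
    """
    rng = _rng(seed)
    while True:
        f = rng.random(1 << L)
        if not condition_antipode_min:
            break
        imax = int(np.argmax(f))
        imin = int(np.argmin(f))
        anti = imax ^ ((1 << L) - 1)
        if method == "relocate":
            f[anti], f[imin] = f[imin], f[anti]
            break
        if method == "rejection":
            if imin == anti:
                break
        else:
            raise ValueError(f"unknown method {method!r}")
    return Landscape(L, f, meta={"model": "hoc",
                                 "conditioned": condition_antipode_min})


def sample_rmf(
    params: RMFParams, seed: int | np.random.Generator | None = None
) -> Landscape:
    """Draw a Rough-Mount-Fuji landscape with optimum at the all-zeros
    genotype."""
    rng = _rng(seed)
    L, c = params.L, params.c
    if params.noise == "normal":
        eta = rng.standard_normal(1 << L)
    else:
        eta = rng.gumbel(0.0, 1.0, 1 << L)
    f = -c * _hamming_weights(L) + eta
    f = f - f.min() + 1e-9  # shift to strictly positive; order-preserving
    return Landscape(L, f, meta={"model": "rmf", "c": c,
                                 "noise": params.noise})


def sample_lk(
    params: LKParams, seed: int | np.random.Generator | None = None
) -> Landscape:
    """Draw an LK landscape.

    Each locus i has a contribution table with one i.i.d. uniform(0, 1)
    entry per state of (allele_i, alleles of its K partners); total fitness
    is the sum of the L contributions.  The partner sets used are recorded
    in ``meta["partners"]``.
    """
    rng = _rng(seed)
    L, K = params.L, params.K
    if params.scheme == "adjacent":
        partners = [
            tuple((i + j) % L for j in range(1, K + 1)) for i in range(L)
        ]
    else:
        partners = []
        for i in range(L):
            others = [j for j in range(L) if j != i]
            partners.append(
                tuple(sorted(rng.choice(others, size=K, replace=False)))
            )
    tables = rng.random((L, 1 << (K + 1)))
    idx = np.arange(1 << L, dtype=np.int64)
    f = np.zeros(1 << L)
    for i in range(L):
        state = (idx >> i) & 1
        for pos, j in enumerate(partners[i]):
            state = state | (((idx >> j) & 1) << (pos + 1))
        f += tables[i, state]
    return Landscape(
        L, f, meta={"model": "lk", "K": K, "scheme": params.scheme,
                    "partners": tuple(partners)}
    )


def sample_holey(
    params: HoleyParams,
    seed: int | np.random.Generator | None = None,
    condition_endpoints_viable: bool = False,
) -> Landscape:
    """Draw a holey landscape (i.i.d. viable/lethal genotypes).

    With ``condition_endpoints_viable`` the all-zeros genotype and its
    antipode are forced viable, the convention used when asking whether two
    antipodal genotypes are connected by a viable shortest path.
    """
    rng = _rng(seed)
    L = params.L
    f = (rng.random(1 << L) < params.p).astype(float)
    if condition_endpoints_viable:
        f[0] = 1.0
        f[(1 << L) - 1] = 1.0
    return Landscape(L, f, meta={"model": "holey", "p": params.p,
                                 "conditioned": condition_endpoints_viable})
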