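"""Closed-form predictions for accessible-path statistics.

The expected number of accessible antipodal paths follows from order
statistics.  In a House-of-Cards landscape each of the L! shortest paths
visits L + 1 genotypes whose fitnesses, apart from the terminal global
maximum, are exchangeable, so exactly one of the L! orderings of the L free
values is monotone and E[n] = L! / L! = 1 for every L.  Conditioning the
starting antipode to be the global minimum leaves (L - 1)! free orderings
per path, giving E[n] = L.  For Rough-Mount-Fuji landscapes the additive
slope tilts the ordering probability of the values along a path; this
module provides the first-order (small-c) expansion for arbitrary noise
densities and the exact expression for standard-Gumbel noise, both for the
probability that one fixed antipodal path is accessible (its terminal
genotype being the global maximum, only the L preceding values must be
ordered).  For holey landscapes the expected number of viable antipodal
connections is L! p^(L-1) (the L - 1 interior genotypes of each path must
be viable; endpoints are conditioned viable).

The lethality model used for the empirical analysis assigns each mutation i
an independent per-strain probability p_i of causing lethality, acting
multiplicatively across mutations: a genotype with mutation set S is viable
with probability prod_{i in S} (1 - p_i).  Two parameters suffice: a common
p for the ordinary loci and a separate p_focal for one focal high-lethality
locus.  From this the expected number of fully viable subgraphs and the
expected number of lethal-free paths per subgraph follow in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp, expm1, factorial, log, sqrt, pi

import numpy as np
from scipy import integrate, stats

__all__ = [
    "LethalityModel",
    "hoc_expected_paths",
    "rmf_path_prob_first_order",
    "rmf_path_prob_gumbel",
    "gumbel_denominator_constant",
    "holey_expected_paths",
    "expected_vsg",
    "expected_lethal_free",
    "missed_genotype_stats",
    "simulate_heterogeneous_detection",
]

#: integral of the squared density, lambda = int rho(x)^2 dx, for the
#: built-in noise choices; this is the only property of the noise entering
#: the first-order path probability
_LAMBDA = {
    "normal": 1.0 / (2.0 * sqrt(pi)),
    "gumbel": 0.25,
}


def hoc_expected_paths(L: int, conditioned: bool = False) -> float:
    """Expected number of accessible antipodal paths in the HoC model.

    Unconditioned: 1 for every L.  With the antipode conditioned to be the
    global minimum: L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return float(L) if conditioned else 1.0


def rmf_path_prob_first_order(L: int, c: float, noise="normal") -> float:
    """Probability that one fixed antipodal path is accessible in the RMF
    model, to first order in the slope c:

        P = (1/L!) * (1 + c * lambda * L * (L - 1)),   lambda = int rho^2.

    ``noise`` may be ``"normal"``, ``"gumbel"``, or a density callable
    (integrated numerically).  At c = 0 this is the HoC value 1/L!.
    The expansion is accurate only for small c.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if callable(noise):
        lam = integrate.quad(lambda x: noise(x) ** 2, -np.inf, np.inf)[0]
    else:
        try:
            lam = _LAMBDA[noise]
        except KeyError:
            raise ValueError(f"unknown noise {noise!r}") from None
    return (1.0 + c * lam * L * (L - 1)) / factorial(L)


def rmf_path_prob_gumbel(L: int, c: float) -> float:
    """Exact probability that one fixed antipodal path is accessible in the
    RMF model with standard-Gumbel noise:

        P(L, c) = (1 - e^{-c})^{L-1} / prod_{k=2}^{L} (1 - e^{-ck}).

    Shifted Gumbel variables obey a Plackett-Luce ranking law with weights
    e^{ck}, from which the ordering probability of the L values preceding
    the global maximum follows in product form.  The c -> 0 limit is 1/L!;
    for large L the denominator tends to a constant
    (:func:`gumbel_denominator_constant`), so P decays exponentially with
    rate -ln(1 - e^{-c}).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if c < 0:
        raise ValueError("slope c must be >= 0")
    if c == 0.0:
        return 1.0 / factorial(L)
    # log-space for numerical stability at large L / small c
    log_num = (L - 1) * log(-expm1(-c))
    log_den = sum(log(-expm1(-c * k)) for k in range(2, L + 1))
    return exp(log_num - log_den)


def gumbel_denominator_constant(c: float, tol: float = 1e-15) -> float:
    """The large-L limit prod_{k=2}^{inf} (1 - e^{-ck}) of the denominator
    in :func:`rmf_path_prob_gumbel`."""
    if c <= 0:
        raise ValueError("slope c must be > 0")
    log_p = 0.0
    k = 2
    while True:
        term = log(-expm1(-c * k))
        log_p += term
        if abs(term) < tol:
            return exp(log_p)
        k += 1


def holey_expected_paths(L: int, p: float) -> float:
    """Expected number of viable antipodal connections in a holey landscape
    with endpoints conditioned viable: L! * p^(L-1).

    Factorial growth beats the exponential decay of p^(L-1), so the
    expectation diverges with L for any p > 0.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return factorial(L) * p ** (L - 1)


@dataclass(frozen=True)
class LethalityModel:
    """Two-parameter multiplicative lethality model.

    ``p_common`` applies to each of the ``L0 - 1`` ordinary loci and
    ``p_focal`` to the single focal high-lethality locus; a genotype is
    viable with probability prod (1 - p_i) over its mutations,
    independently across genotypes.
    """

    p_common: float
    p_focal: float
    L0: int = 8

    def __post_init__(self) -> None:
        for name in ("p_common", "p_focal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.L0 < 2:
            raise ValueError("L0 must be >= 2")

    def viability_prob(self, n_common: int, focal: bool) -> float:
        """Viability probability of a genotype carrying ``n_common``
        ordinary mutations and optionally the focal one."""
        return (1.0 - self.p_common) ** n_common * (
            (1.0 - self.p_focal) if focal else 1.0
        )


def expected_vsg(model: LethalityModel, L: int) -> float:
    """Expected number of fully viable subgraphs of size L.

    Viable subgraphs effectively exclude the focal locus (its lethality is
    near certain across a subgraph's many genotypes), so the count depends
    only on ``p_common``: a focal-free size-L subgraph is fully viable iff
    each of its 2^L - 1 mutation-carrying genotypes is viable, and genotype
    sizes over the subgraph sum to L * 2^(L-1):

        E[#VSG] = C(L0 - 1, L) * (1 - p_common)^(L * 2^(L-1)).
    """
    if not 1 <= L <= model.L0 - 1:
        raise ValueError(f"L must be in [1, {model.L0 - 1}]")
    return comb(model.L0 - 1, L) * (1.0 - model.p_common) ** (
        L * (1 << (L - 1))
    )


def expected_lethal_free(model: LethalityModel, L: int) -> float:
    """Expected number of lethal-free wildtype-to-L-fold-mutant paths per
    size-L subgraph, averaged over the full subgraph ensemble.

    A path visits genotypes of sizes 1 .. L (the wildtype is always
    viable).  For a focal-free subgraph every path survives with
    probability (1 - p)^(L(L+1)/2).  When the subgraph contains the focal
    locus the path's survival depends on the step m (counted from the
    mutant end) at which the focal mutation enters, giving a geometric sum
    in r = (1 - p_focal)/(1 - p):

        E = (1-p)^(L(L+1)/2) * [ C(L0-1, L) L!
              + C(L0-1, L-1) (L-1)! sum_{m=1}^{L} r^m ] / C(L0, L).
    """
    if not 1 <= L <= model.L0:
        raise ValueError(f"L must be in [1, {model.L0}]")
    p, pf, L0 = model.p_common, model.p_focal, model.L0
    base = (1.0 - p) ** (L * (L + 1) // 2)
    if p == 1.0:
        return 0.0
    r = (1.0 - pf) / (1.0 - p)
    geo = sum(r**m for m in range(1, L + 1))
    num = comb(L0 - 1, L) * factorial(L) + comb(L0 - 1, L - 1) * factorial(
        L - 1
    ) * geo
    return base * num / comb(L0, L)


def missed_genotype_stats(
    G: int, N_seg: int, k: int = 0
) -> tuple[float, float, float]:
    """Poisson statistics of genotypes missed when sampling segregants.

    Assuming each of the G genotypes is equally likely to be drawn, the
    probability that a given genotype is absent from ``N_seg`` independent
    draws is q = (1 - 1/G)^N_seg, the number of missed genotypes is
    approximately Poisson with mean lambda = G q, and the probability that
    at most k were missed is the Poisson CDF at k.

    Returns ``(q, lam, P(<= k missed))``.  Computed in log space so large
    N_seg does not underflow.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if N_seg < 0:
        raise ValueError("N_seg must be >= 0")
    log_q = N_seg * np.log1p(-1.0 / G) if G > 1 else (
        0.0 if N_seg == 0 else -np.inf
    )
    q = float(np.exp(log_q))
    lam = G * q
    return q, lam, float(stats.poisson.cdf(k, lam))


def simulate_heterogeneous_detection(
    G: int,
    N_seg: int,
    low_frac: float = 0.1,
    reps: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo distribution of missed-genotype counts when genotypes
    have unequal detection probabilities.

    Per realization the G detection probabilities are drawn uniformly on
    the interval [low_frac/G, (2 - low_frac)/G] (mean 1/G) and normalized,
    ``N_seg`` segregants are drawn multinomially, and the number of
    genotypes never drawn is recorded.  ``low_frac = 1`` is the
    homogeneous limit.  Returns an integer array of length ``reps``.
    """
    if not 0.0 < low_frac <= 1.0:
        raise ValueError("low_frac must be in (0, 1]")
    if G < 1 or N_seg < 0 or reps < 1:
        raise ValueError("G >= 1, N_seg >= 0, reps >= 1 required")
    rng = np.random.default_rng(seed)
    missed = np.empty(reps, dtype=np.int64)
    lo, hi = low_frac / G, (2.0 - low_frac) / G
    for r in range(reps):
        probs = rng.uniform(lo, hi, G)
        probs /= probs.sum()
        counts = rng.multinomial(N_seg, probs)
        missed[r] = int(np.sum(counts == 0))
    return missed
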