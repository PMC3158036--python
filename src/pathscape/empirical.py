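"""Subgraph analysis of an empirical genotype-fitness table.

The expected input is a combinatorially complete (up to missing strains)
fitness assay over ``L0`` marker mutations, of the kind produced for the
*Aspergillus niger* 8-locus marker-strain collection: one row per measured
genotype giving the presence/absence of each mutation and its mean relative
fitness, with genotypes never recovered among the segregants treated as
non-viable (fitness 0).

The analysis slices the full landscape into the C(L0, L) subgraphs spanned
by the wildtype and one L-subset of the mutations, and summarizes, per
subgraph size: how many subgraphs contain no lethal genotype (viable
subgraphs, VSGs), how many wildtype-to-L-fold-mutant paths survive if only
lethals could block them, and the mean number and zero-probability of fully
accessible (monotonically fitness-increasing) antipodal paths.  A
two-parameter multiplicative lethality model is estimated from the viable
counts by the method of moments and supplies the closed-form predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .accessibility import (
    count_accessible_paths,
    count_antipodal,
    count_lethal_free_paths,
)
from .analytic import LethalityModel, expected_lethal_free, expected_vsg
from .hypercube import Landscape, TieError

__all__ = [
    "EmpiricalDataset",
    "SubgraphRow",
    "read_fitness_table",
    "subgraph",
    "enumerate_subgraphs",
    "is_viable_subgraph",
    "estimate_lethality",
    "subgraph_table",
    "resample",
    "resampled_table",
]

MISSING_SENTINEL = "x"


@dataclass(frozen=True)
class EmpiricalDataset:
    """A complete genotype-to-mean-fitness map over ``L0`` loci.

    ``fitness`` holds the mean relative fitness of every genotype (indexed
    as in :mod:`pathscape.hypercube`); genotypes absent from the assay are
    flagged in ``missing`` and carry fitness 0.  ``replicates`` optionally
    holds the individual replicate measurements (NaN where missing) and
    ``replicate_sigma`` the common per-measurement standard deviation
    estimated from replicate disagreement.
    """

    locus_names: tuple[str, ...]
    fitness: np.ndarray
    missing: np.ndarray
    replicate_sigma: float | None = None
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        L0 = len(self.locus_names)
        f = np.asarray(self.fitness, dtype=float)
        m = np.asarray(self.missing, dtype=bool)
        if f.shape != (1 << L0,) or m.shape != (1 << L0,):
            raise ValueError("fitness/missing must have length 2**L0")
        if np.any(f < 0):
            raise ValueError("negative fitness values")
        if np.any(f[m] != 0):
            raise ValueError("missing genotypes must carry fitness 0")
        if np.any((f == 0) & ~m):
            raise ValueError("measured genotypes must have fitness > 0")
        object.__setattr__(self, "fitness", f)
        object.__setattr__(self, "missing", m)

    @property
    def L0(self) -> int:
        return len(self.locus_names)

    @property
    def n_measured(self) -> int:
        return int(np.sum(~self.missing))

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.missing))

    def landscape(self) -> Landscape:
        return Landscape(self.L0, self.fitness, self.locus_names)

    def reorder_loci(self, order: Sequence[int]) -> "EmpiricalDataset":
        """Dataset with loci permuted: new locus j is old locus order[j]."""
        L0 = self.L0
        if sorted(order) != list(range(L0)):
            raise ValueError("order must be a permutation of the loci")
        src = np.zeros(1 << L0, dtype=np.int64)
        for g in range(1 << L0):
            s = 0
            for j, i in enumerate(order):
                s |= ((g >> j) & 1) << i
            src[g] = s
        return replace(
            self,
            locus_names=tuple(self.locus_names[i] for i in order),
            fitness=self.fitness[src],
            missing=self.missing[src],
            replicates=None if self.replicates is None else
            self.replicates[src],
        )


def read_fitness_table(path) -> EmpiricalDataset:
    """Read a tab-separated genotype-fitness table.

    Dialect: a header row with the ``L0`` locus names followed by
    ``fitness`` (and optionally ``fitness_rep1``, ``fitness_rep2``); one
    row per genotype with 0/1 allele columns.  Genotypes absent from the
    file, or whose fitness field is the sentinel ``x`` (or 0), are the
    missing (non-viable) set.  Duplicated genotypes, non-binary allele
    fields and negative fitnesses are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "fitness" not in cols:
        raise ValueError("table must have a 'fitness' column")
    locus_names = tuple(cols[: cols.index("fitness")])
    L0 = len(locus_names)
    if L0 < 1:
        raise ValueError("no locus columns before 'fitness'")
    rep_cols = [c for c in ("fitness_rep1", "fitness_rep2") if c in cols]

    fitness = np.zeros(1 << L0)
    missing = np.ones(1 << L0, dtype=bool)
    replicates = np.full((1 << L0, 2), np.nan) if len(rep_cols) == 2 else None
    seen: set[int] = set()
    for _, row in df.iterrows():
        bits = []
        for name in locus_names:
            v = str(row[name]).strip()
            if v not in ("0", "1"):
                raise ValueError(f"non-binary allele {v!r} in column {name}")
            bits.append(int(v))
        g = sum(b << i for i, b in enumerate(bits))
        if g in seen:
            raise ValueError(f"duplicate genotype row {''.join(map(str, bits))}")
        seen.add(g)
        raw = str(row["fitness"]).strip()
        if raw.lower() == MISSING_SENTINEL:
            continue
        f = float(raw)
        if f < 0:
            raise ValueError(f"negative fitness {f} for genotype {g}")
        if f == 0:
            continue
        fitness[g] = f
        missing[g] = False
        if replicates is not None:
            replicates[g] = [float(row[c]) for c in rep_cols]

    sigma = None
    if replicates is not None:
        d = replicates[~missing, 0] - replicates[~missing, 1]
        if d.size:
            sigma = float(np.sqrt(np.mean(d**2) / 2.0))
    return EmpiricalDataset(locus_names, fitness, missing, sigma, replicates)


def subgraph(lsc: Landscape, loci: Sequence[int]) -> Landscape:
    """Landscape restricted to a subset of loci, all others fixed to the
    wildtype allele (0).

    Bit j of the subgraph corresponds to locus ``loci[j]`` of the parent.
    """
    loci = tuple(loci)
    if not loci:
        raise ValueError("locus subset must be non-empty")
    if any(not 0 <= i < lsc.L for i in loci) or len(set(loci)) != len(loci):
        raise ValueError(f"invalid locus subset {loci} for L={lsc.L}")
    L = len(loci)
    embed = np.zeros(1 << L, dtype=np.int64)
    for g in range(1 << L):
        s = 0
        for j, i in enumerate(loci):
            s |= ((g >> j) & 1) << i
        embed[g] = s
    return Landscape(
        L,
        lsc.fitness[embed],
        tuple(lsc.locus_names[i] for i in loci),
        meta={"parent_loci": loci},
    )


def enumerate_subgraphs(L0: int, L: int) -> list[tuple[int, ...]]:
    """All C(L0, L) locus subsets of size L, in lexicographic order."""
    if not 1 <= L <= L0:
        raise ValueError(f"L must be in [1, {L0}]")
    return list(itertools.combinations(range(L0), L))


def is_viable_subgraph(sub: Landscape) -> bool:
    """Whether every genotype of the subgraph is viable (fitness > 0)."""
    return bool(np.all(sub.fitness > 0))


def estimate_lethality(ds: EmpiricalDataset, focal: str) -> LethalityModel:
    """Method-of-moments estimate of the two-parameter lethality model.

    Under the model the expected number of viable genotypes among those
    not carrying the focal mutation is (2 - p)^(L0-1), and the expected
    total is (2 - p_focal)(2 - p)^(L0-1).  Matching both to the observed
    counts gives

        p = 2 - V0^(1/(L0-1)),      p_focal = 2 - V / V0,

    where V0 and V are the focal-free and total viable counts.
    """
    if focal not in ds.locus_names:
        raise ValueError(f"unknown focal locus {focal!r}")
    fi = ds.locus_names.index(focal)
    viable = ds.fitness > 0
    idx = np.arange(1 << ds.L0)
    no_focal = (idx >> fi) & 1 == 0
    V0 = int(np.sum(viable & no_focal))
    V = int(np.sum(viable))
    if V0 == 0:
        raise ValueError("no viable focal-free genotypes; model unidentifiable")
    p = 2.0 - V0 ** (1.0 / (ds.L0 - 1))
    pf = 2.0 - V / V0
    eps = 1e-12
    if not -eps <= p <= 1 + eps or not -eps <= pf <= 1 + eps:
        raise ValueError(
            f"no lethality solution in [0,1]: p={p:.4f}, p_focal={pf:.4f}"
        )
    return LethalityModel(min(max(p, 0.0), 1.0), min(max(pf, 0.0), 1.0),
                          ds.L0)


@dataclass(frozen=True)
class SubgraphRow:
    """One row of the subgraph summary table."""

    L: int
    n_subgraphs: int
    n_vsg: int
    vsg_predicted: float
    lethal_free_mean: float
    lethal_free_predicted: float
    mean_paths: float
    p_zero: float
    n_tie_skipped: int = 0


def _accessible_count(sub: Landscape, axis: str) -> int:
    if axis == "wildtype":
        # fixed wildtype <-> full-mutant axis; wildtype is the target
        return count_accessible_paths(sub, sub.full_mask, 0)
    return count_antipodal(sub)


def subgraph_table(
    ds: EmpiricalDataset,
    focal: str,
    sizes: Iterable[int] = range(2, 7),
    axis: str = "global_max",
    model: LethalityModel | None = None,
) -> list[SubgraphRow]:
    """Summary of the subgraph ensembles of the dataset.

    Per size L: the number of subgraphs and of viable subgraphs (with the
    lethality-model prediction), the mean number of lethal-free
    wildtype-to-mutant paths (with prediction), and the mean number and
    zero-fraction of accessible paths.

    ``axis`` selects the endpoints for the accessible-path count:
    ``"global_max"`` (default) uses each subgraph's global fitness maximum
    and its antipode; ``"wildtype"`` uses the full mutant to wildtype.
    Subgraphs whose required maximum is tied are skipped and counted in
    ``n_tie_skipped``.
    """
    if axis not in ("global_max", "wildtype"):
        raise ValueError(f"unknown axis {axis!r}")
    lsc = ds.landscape()
    model = model or estimate_lethality(ds, focal)
    rows = []
    for L in sizes:
        subsets = enumerate_subgraphs(ds.L0, L)
        n_vsg = 0
        lethal_free = []
        acc = []
        skipped = 0
        for loci in subsets:
            sub = subgraph(lsc, loci)
            if is_viable_subgraph(sub):
                n_vsg += 1
            lethal_free.append(
                count_lethal_free_paths(sub, 0, sub.full_mask)
            )
            try:
                acc.append(_accessible_count(sub, axis))
            except TieError:
                skipped += 1
        acc_arr = np.asarray(acc, dtype=float)
        rows.append(
            SubgraphRow(
                L=L,
                n_subgraphs=len(subsets),
                n_vsg=n_vsg,
                vsg_predicted=expected_vsg(model, L),
                lethal_free_mean=float(np.mean(lethal_free)),
                lethal_free_predicted=expected_lethal_free(model, L),
                mean_paths=float(acc_arr.mean()) if acc_arr.size else np.nan,
                p_zero=float(np.mean(acc_arr == 0)) if acc_arr.size else np.nan,
                n_tie_skipped=skipped,
            )
        )
    return rows


def table_frame(rows: Sequence[SubgraphRow]) -> pd.DataFrame:
    """Subgraph table as a pandas DataFrame (column order as printed)."""
    return pd.DataFrame([vars(r) for r in rows])


def resample(
    ds: EmpiricalDataset,
    sigma: float | None = None,
    reps: int = 1000,
    seed: int | None = None,
) -> Iterator[Landscape]:
    """Yield fitness landscapes with measurement noise re-injected.

    Each realization adds independent normal noise with standard deviation
    ``sigma`` (default: the dataset's replicate-derived sigma) to every
    viable genotype's mean fitness; non-viable genotypes stay exactly 0.
    Values are not truncated: viability is frozen at the measured
    classification, and accessibility only compares fitness values.
    """
    if sigma is None:
        sigma = ds.replicate_sigma
        if sigma is None:
            raise ValueError("no sigma given and dataset has no replicates")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    viable = ds.fitness > 0
    for _ in range(reps):
        f = ds.fitness.copy()
        f[viable] += sigma * rng.standard_normal(int(viable.sum()))
        yield Landscape(ds.L0, f, ds.locus_names)


def resampled_table(
    ds: EmpiricalDataset,
    focal: str,
    sizes: Iterable[int] = range(2, 7),
    axis: str = "global_max",
    sigma: float | None = None,
    reps: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean and standard deviation of the accessibility columns over the
    resampled landscape ensemble.

    Returns one row per subgraph size with columns ``mean_paths``,
    ``mean_paths_sd``, ``p_zero``, ``p_zero_sd`` (ensemble mean and spread
    across resampled realizations).
    """
    sizes = list(sizes)
    per_rep_mean = {L: [] for L in sizes}
    per_rep_p0 = {L: [] for L in sizes}
    for lsc in resample(ds, sigma=sigma, reps=reps, seed=seed):
        for L in sizes:
            counts = []
            for loci in enumerate_subgraphs(ds.L0, L):
                sub = subgraph(lsc, loci)
                try:
                    counts.append(_accessible_count(sub, axis))
                except TieError:
                    continue
            arr = np.asarray(counts, dtype=float)
            per_rep_mean[L].append(arr.mean())
            per_rep_p0[L].append(np.mean(arr == 0))
    out = []
    for L in sizes:
        m = np.asarray(per_rep_mean[L])
        z = np.asarray(per_rep_p0[L])
        out.append(
            {
                "L": L,
                "mean_paths": m.mean(),
                "mean_paths_sd": m.std(ddof=1),
                "p_zero": z.mean(),
                "p_zero_sd": z.std(ddof=1),
            }
        )
    return pd.DataFrame(out)
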