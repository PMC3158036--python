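"""Synthetic genotype-fitness datasets with known ground truth.

The generator emulates the structure of an 8-locus marker-strain fitness
assay: each genotype is independently lethal according to a two-parameter
multiplicative lethality model (one focal high-lethality locus, a common
small per-mutation lethality for the rest); viable genotypes receive
correlated fitness values from an additive-slope-plus-noise (Rough Mount
Fuji) landscape with the wildtype as the designated optimum, affinely
rescaled to relative growth-rate units on (0, 1] with the best strain at 1;
and every viable genotype is measured twice with independent normal
replicate noise, the stored fitness being the replicate mean.

The generated data are a testing device: they reproduce the lethality
structure, fitness correlation and measurement noise that the empirical
pipeline must cope with, not any particular organism's biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .empirical import MISSING_SENTINEL, EmpiricalDataset

__all__ = ["SyntheticConfig", "generate_dataset", "write_dataset",
           "DEFAULT_LOCUS_NAMES"]

#: marker-mutation labels in the canonical (chromosomal) order of the
#: A. niger strain collection; the lysine-deficiency marker at index 5 is
#: the focal high-lethality locus
DEFAULT_LOCUS_NAMES = (
    "fwnA1", "argH12", "pyrA5", "leuA1", "pheA1", "lysD25", "oliC2",
    "crnB12",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for a synthetic dataset.

    Defaults mirror the empirical study conditions: 8 loci, a common
    per-mutation lethality probability of 0.02 with a focal locus at 0.45,
    slope c = 0.3 of the viable-fitness landscape relative to unit noise,
    and replicate measurement noise of 0.02 on the relative-fitness scale.
    """

    L0: int = 8
    p_common: float = 0.02
    p_focal: float = 0.45
    focal_index: int = 5
    c: float = 0.3
    noise_sd: float = 1.0
    replicate_sd: float = 0.02
    min_viable_fitness: float = 0.05
    locus_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("p_common", "p_focal"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("noise_sd", "replicate_sd", "c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.focal_index < self.L0:
            raise ValueError("focal_index out of range")
        if not 0.0 < self.min_viable_fitness < 1.0:
            raise ValueError("min_viable_fitness must be in (0, 1)")

    def names(self) -> tuple[str, ...]:
        if self.locus_names is not None:
            if len(self.locus_names) != self.L0:
                raise ValueError("locus_names length must equal L0")
            return tuple(self.locus_names)
        if self.L0 == 8:
            return DEFAULT_LOCUS_NAMES
        return tuple(f"locus{i}" for i in range(self.L0))


def generate_dataset(
    cfg: SyntheticConfig, seed: int | None = None
) -> EmpiricalDataset:
    """Draw one synthetic dataset.

    Viability: genotype g with n ordinary mutations (and possibly the
    focal one) survives with probability
    ``(1 - p_common)**n * (1 - p_focal)**focal``.  Viable fitness: RMF
    values ``-c * |g| + noise_sd * N(0,1)`` over the viable genotypes,
    affinely mapped to [min_viable_fitness, 1] (order-preserving, so the
    accessibility structure is unchanged).  Replicates: two independent
    normal perturbations of the true fitness; the dataset fitness is their
    mean, floored at a tiny positive value so a viable genotype can never
    masquerade as lethal.
    """
    rng = np.random.default_rng(seed)
    L0 = cfg.L0
    n = 1 << L0
    idx = np.arange(n)
    weight = np.zeros(n, dtype=np.int64)
    for i in range(L0):
        weight += (idx >> i) & 1
    has_focal = (idx >> cfg.focal_index) & 1 == 1
    n_common = weight - has_focal.astype(np.int64)

    p_viable = (1.0 - cfg.p_common) ** n_common * np.where(
        has_focal, 1.0 - cfg.p_focal, 1.0
    )
    viable = rng.random(n) < p_viable

    raw = -cfg.c * weight + cfg.noise_sd * rng.standard_normal(n)
    raw[~viable] = 0.0
    v = raw[viable]
    if v.size == 0:
        raise ValueError("no viable genotypes drawn; lower the lethalities")
    lo, hi = v.min(), v.max()
    span = hi - lo
    if span == 0:
        scaled = np.ones_like(v)
    else:
        scaled = cfg.min_viable_fitness + (1.0 - cfg.min_viable_fitness) * (
            v - lo
        ) / span

    fitness = np.zeros(n)
    fitness[viable] = scaled
    replicates = np.full((n, 2), np.nan)
    replicates[viable] = fitness[viable, None] + cfg.replicate_sd * (
        rng.standard_normal((int(viable.sum()), 2))
    )
    mean = replicates[viable].mean(axis=1)
    fitness[viable] = np.maximum(mean, 1e-6)

    d = replicates[viable, 0] - replicates[viable, 1]
    sigma = float(np.sqrt(np.mean(d**2) / 2.0)) if d.size > 1 else None
    return EmpiricalDataset(
        cfg.names(), fitness, ~viable, sigma, replicates
    )


def write_dataset(
    ds: EmpiricalDataset, path, dialect: str = "omit"
) -> None:
    """Write a dataset in the tab-separated table dialect.

    ``dialect="omit"`` leaves missing genotypes out of the file;
    ``dialect="sentinel"`` writes them with ``x`` in the fitness column.
    Both round-trip through
    :func:`pathscape.empirical.read_fitness_table`.
    """
    if dialect not in ("omit", "sentinel"):
        raise ValueError(f"unknown dialect {dialect!r}")
    L0 = ds.L0
    has_reps = ds.replicates is not None
    rows = []
    for g in range(1 << L0):
        if ds.missing[g] and dialect == "omit":
            continue
        row = {name: (g >> i) & 1 for i, name in enumerate(ds.locus_names)}
        if ds.missing[g]:
            row["fitness"] = MISSING_SENTINEL
            if has_reps:
                row["fitness_rep1"] = MISSING_SENTINEL
                row["fitness_rep2"] = MISSING_SENTINEL
        else:
            row["fitness"] = repr(float(ds.fitness[g]))
            if has_reps:
                row["fitness_rep1"] = repr(float(ds.replicates[g, 0]))
                row["fitness_rep2"] = repr(float(ds.replicates[g, 1]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
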