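# Methods

## Accessibility definition

Genotypes are binary vectors over `L` loci (1 = mutation present), stored
as integers with bit `i` = locus `i`; the configuration space is the
`L`-hypercube.  Only *shortest* paths between two genotypes are
considered: each differing locus is flipped exactly once, giving `D!`
candidate paths at Hamming distance `D`.  This encodes a
strong-selection/weak-mutation regime in which double mutants and valley
crossing are unavailable; it makes every accessibility number reported
here a conservative lower bound.  A path is accessible when fitness
increases *strictly* at every step.  Equal fitness values never count as
an increase: the models assume neighboring fitnesses are distinguishable,
and empirical ties are deliberately surfaced (operations that need a
unique maximum or a unique steepest-ascent move raise a `TieError` rather
than tie-breaking silently; the subgraph pipeline records and skips such
subgraphs and reports how many were skipped).

The canonical start/end pair is the global fitness maximum and its
antipode — the longest and therefore least accessible direct route, and a
lower bound for typical pairs.

## Landscape ensembles

* **House of Cards (HoC)**: i.i.d. fitness values.  Accessibility depends
  only on ranks, so the base distribution is uniform(0, 1).  The
  conditioned variant (antipode = global minimum) is realized by moving
  the smallest value to the antipode of the maximum, which is exact by
  exchangeability; a rejection-sampling mode cross-checks this.
* **Rough Mount Fuji (RMF)**: `F(σ) = −c·d(σ) + η_σ` with `d` the
  Hamming distance to the all-zeros reference optimum and i.i.d. noise
  `η` (standard normal by default, standard Gumbel optionally).  The
  slope `c ≥ 0` is measured in units of the noise standard deviation;
  `c = 0` is HoC.  Stored fitnesses are shifted per realization to be
  strictly positive — a common shift changes no fitness comparison.
* **LK (NK)**: locus `i` contributes an i.i.d. uniform(0, 1) table entry
  indexed by its own allele and the alleles of its `K` partner loci;
  total fitness is the sum of the `L` contributions (any strictly
  monotone aggregation gives identical accessibility).  Partner sets are
  either `K` distinct loci drawn uniformly per realization (`random`,
  default) or the `K` cyclically following loci (`adjacent`).  The
  classical literature uses both conventions and quantitative `P₀(L)`
  curves shift noticeably between them — on our simulations the adjacent
  scheme at small fixed `K` is distinctly less accessible than the random
  scheme — so no specific published curve should be expected to match
  either convention exactly.  `K = 0` is additive; `K = L−1` reproduces
  HoC statistics.
* **Holey**: fitness is 1 (viable) with probability `p`, else 0.  There
  is no fitness ordering; the meaningful question is whether two
  antipodal genotypes are joined by a shortest path of viable genotypes,
  and the conditioned sampler forces the two endpoints viable.

Reproducibility: every sampler accepts an integer seed or a numpy
`Generator`; ensemble drivers spawn one independent substream per
realization from a master `SeedSequence`, so results are independent of
evaluation order and exactly repeatable.

## Path counting

Counting uses an iterative depth-first backtracking search (explicit
stack) over the sub-hypercube spanned by the differing loci, trying loci
in ascending index order (the order is irrelevant to the count and fixed
for reproducible traversals).  Existence queries (`P₀` estimation)
short-circuit on the first complete path and memoize dead ends — from a
given genotype the reachable continuations depend only on that genotype —
reducing the worst case from `D!` path extensions to `O(2^D · D)` and
making `L` up to ~18 practical.  Lethal-free counts (paths blocked only
by inviable genotypes, fitness order ignored, endpoints included) use
level-by-level dynamic programming on the same sub-hypercube.  Exactness
of both is pinned by tests against explicit enumeration of all `D!`
permutations.

## Closed forms

* HoC: along any path the `L` fitness values before the terminal global
  maximum are exchangeable, so each path is accessible with probability
  `1/L!` and `E[n] = 1` for every `L`; with the antipode conditioned to
  be the global minimum, `(L−1)!` free orderings per path give
  `E[n] = L`.
* RMF, first order in `c`: the probability that one fixed antipodal path
  is accessible is `P = (1 + cλL(L−1))/L!` with `λ = ∫ρ(x)²dx`
  (`1/(2√π)` for standard normal, `1/4` for standard Gumbel; arbitrary
  densities are integrated numerically).  The truncation error is
  `O(c²)` — at `c = 0.1, L = 4` it is already ~2.4% of `P` — so the
  expression is quantitative only for `cλL(L−1) ≪ 1`; tests verify both
  the small-`c` agreement with simulation and the quadratic scaling of
  the residual.
* RMF with standard Gumbel noise, exact: shifted Gumbel variables rank
  according to a Plackett–Luce law with weights `e^{ck}`, giving
  `P(L, c) = (1−e^{−c})^{L−1} / ∏_{k=2}^{L}(1−e^{−ck})`, evaluated in
  log space.  As `L → ∞` the denominator tends to the constant
  `∏_{k≥2}(1−e^{−ck})`, so `P` decays exponentially at rate
  `−ln(1−e^{−c})` — slower than the factorial `1/L!` of HoC, which is
  why `E[n] = L!·P` diverges for any `c > 0`.
* Holey: the `L−1` interior genotypes of a path are independently viable,
  so with viable endpoints `E[n] = L!·p^{L−1}`, which grows without
  bound for any `p > 0`.
* Lethality model: mutation `i` kills a strain with probability `p_i`,
  multiplicatively across mutations and independently across strains;
  two parameters (`p_common` for ordinary loci, `p_focal` for one focal
  locus).  Expected viable subgraphs of size `L` (which exclude the
  focal locus): `C(L₀−1, L)(1−p)^{L·2^{L−1}}`.  Expected lethal-free
  wildtype↔mutant paths per subgraph, averaged over all `C(L₀, L)`
  subgraphs, follow by summing the viability probability of each path's
  mutation-carrying genotypes over the step at which the focal mutation
  enters (a geometric sum in `r = (1−p_focal)/(1−p_common)`).  Both are
  pinned against direct simulation of the lethality model.
* Missing genotypes: with `N` segregants over `G` equally likely
  genotypes, a genotype is missed with probability `q = (1−1/G)^N`
  (computed via `log1p`), the number missed is Poisson with mean `Gq`,
  and a Monte-Carlo variant draws per-genotype detection probabilities
  uniformly on `[a, 2/G − a]` (mean `1/G`; the lower bound is a user
  parameter expressed as the fraction `a·G`) to mimic unequal
  detectability.

## Empirical pipeline conventions

Input tables are tab-separated with a header of locus names followed by
`fitness` (optionally two replicate columns); genotypes absent from the
file or marked `x` are inviable with fitness 0.  The replicate noise
scale is `σ = sqrt(mean((rep1−rep2)²)/2)`.

Lethality parameters are estimated by the method of moments from two
counts: viable genotypes among those without the focal mutation
(`V₀ = (2−p)^{L₀−1}` in expectation) and viable genotypes in total
(`V = (2−p_focal)·V₀`), giving `p = 2 − V₀^{1/(L₀−1)}` and
`p_focal = 2 − V/V₀`.  The estimator is consistent but noisy at
realistic sizes: at the default truth (0.02, 0.45) the per-dataset
coefficient of variation of `p_common` is ~36%, and its bias (measured
over 400 synthetic datasets) is about +3%.

Accessible-path counts per subgraph run, by default, from the subgraph's
global maximum to its antipode (the general definition; in these data the
shared wildtype is usually the maximum, making this the wildtype↔mutant
axis).  A `wildtype` axis option forces the full-mutant→wildtype
direction instead.  Lethal-free counts always use the wildtype↔full-
mutant axis, matching the fixed-endpoint structure of the closed form.
Summary statistics are computed on the mean-fitness landscape; a
resampling mode re-injects normal measurement noise (default `σ` from the
replicates) into viable genotypes — inviable genotypes stay at exactly
zero and viability status is frozen — and reports ensemble means with
standard deviations as error bars.  Resampled values are not truncated at
zero: only fitness comparisons matter, and truncation would create ties.

## Synthetic data generator

The generator emulates the *structure* of an 8-locus fungal marker-strain
assay: loci named after the canonical marker set with the lysine-
deficiency marker (index 5) as the focal lethal; default lethalities
(0.02, 0.45) chosen so a typical draw yields ≈186 of 256 genotypes
measured; viable fitnesses from an RMF landscape with the wildtype as
optimum (`c = 0.3` per unit noise, a moderately correlated, visibly
epistatic regime), affinely rescaled to (0, 1] relative growth-rate units
with the best strain at 1 (affine maps preserve all fitness comparisons);
two replicates with normal noise of 0.02 — a few percent of the fitness
range, typical of growth-rate assays.  A genotype drawn inviable is 0 in
both replicates.

What it does *not* emulate: the segregant-isolation process (beyond the
detection-probability model above), linkage or marker interactions in the
viable fitnesses beyond the RMF form, heteroscedastic measurement error,
and any claim that the real fungal landscape is RMF-distributed — the
generator is a testing device with known ground truth, so passing tests
demonstrate that the pipeline recovers known structure, not that any
particular organism obeys these models.

## Problem sizes and numerical choices

Default test and reproduction runs use full-count ensembles of 10⁴–10⁵
realizations at `L = 5`, existence-only ensembles of 500–2500
realizations at `L` up to 16, and 10⁶-draw Monte-Carlo checks of the
single-path formulas; these sizes put Monte-Carlo standard errors well
below the effects being measured.  Monte-Carlo agreement checks use
3-standard-error bands.  Statistical trend tests (e.g. the direction of
`P₀(L)` per model class) use matched realization counts and fixed seeds.
The 50-replicate parameter-recovery check tests its 10% bias bound with a
2-standard-error sampling allowance, since the mean of 50 noisy estimates
carries ~5% sampling noise of its own.

## Known limitations

* Only shortest paths and strict monotonicity: no valley crossing, no
  neutral steps, no fixation-probability weighting of paths, no
  population dynamics.
* First-order RMF formula valid for small `c` only (see above).
* LK results depend on the neighborhood convention; both common
  conventions are provided but no attempt is made to match any specific
  published curve.
* The subgraph pipeline assumes a unique fitness maximum per subgraph;
  tied subgraphs are skipped and reported, not resolved.
* Real assay data are not bundled; the empirical reproduction test looks
  for a user-supplied `data/aniger_s1.tsv` transcription and fails with
  instructions otherwise.
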