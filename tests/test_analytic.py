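"""Closed-form predictions against independent Monte-Carlo oracles."""

from math import comb, factorial

import numpy as np
import pytest

import pathscape as ps
from pathscape.analytic import (
    LethalityModel,
    expected_lethal_free,
    expected_vsg,
    gumbel_denominator_constant,
    missed_genotype_stats,
    rmf_path_prob_first_order,
    rmf_path_prob_gumbel,
    simulate_heterogeneous_detection,
)


def mc_single_path(L, c, noise, n, seed):
    """MC oracle: probability that the L fitness values preceding the
    global maximum along one fixed antipodal path are in increasing order;
    value k steps from the start carries additive advantage c*k."""
    rng = np.random.default_rng(seed)
    draw = rng.standard_normal if noise == "normal" else (
        lambda size: rng.gumbel(size=size)
    )
    x = draw(size=(n, L)) + c * np.arange(L)
    acc = np.all(np.diff(x, axis=1) > 0, axis=1)
    return acc.mean(), acc.std(ddof=1) / np.sqrt(n)


class TestHoCExpectation:
    @pytest.mark.parametrize("L", [1, 3, 7, 20])
    def test_unconditioned_is_one(self, L):
        assert ps.hoc_expected_paths(L) == 1.0

    @pytest.mark.parametrize("L", [1, 4, 9])
    def test_conditioned_is_L(self, L):
        assert ps.hoc_expected_paths(L, conditioned=True) == float(L)


class TestRMFFirstOrder:
    @pytest.mark.parametrize("L", [2, 5, 8])
    def test_c0_is_hoc(self, L):
        assert rmf_path_prob_first_order(L, 0.0) == 1.0 / factorial(L)

    def test_small_c_matches_mc(self):
        """At c small enough for the linear term to dominate, the
        first-order value agrees with simulation to within 3 s.e."""
        L, c = 4, 0.02
        mc, se = mc_single_path(L, c, "normal", 10**6, seed=100)
        assert abs(rmf_path_prob_first_order(L, c) - mc) < 3 * se

    def test_residual_shrinks_quadratically(self):
        """The truncation error of the linear expansion decays like c^2:
        quartering c cuts the residual by roughly sixteen."""
        L = 4
        res = {}
        for c in (0.4, 0.1):
            mc, _ = mc_single_path(L, c, "normal", 2 * 10**6, seed=101)
            res[c] = abs(rmf_path_prob_first_order(L, c) - mc)
        ratio = res[0.4] / res[0.1]
        assert 8 < ratio < 32

    def test_custom_density(self):
        from scipy.stats import norm

        assert np.isclose(
            rmf_path_prob_first_order(4, 0.1, noise=norm.pdf),
            rmf_path_prob_first_order(4, 0.1, noise="normal"),
            rtol=1e-6,
        )

    def test_mean_grows_with_L(self):
        c = 0.2
        e = [
            factorial(L) * rmf_path_prob_first_order(L, c)
            for L in range(4, 9)
        ]
        assert all(b > a for a, b in zip(e, e[1:]))


class TestRMFGumbel:
    @pytest.mark.parametrize("L", [2, 4, 7])
    def test_c0_limit(self, L):
        assert rmf_path_prob_gumbel(L, 0.0) == 1.0 / factorial(L)
        assert np.isclose(
            rmf_path_prob_gumbel(L, 1e-9), 1.0 / factorial(L), rtol=1e-4
        )

    @pytest.mark.parametrize("L, c", [(3, 1.0), (4, 0.5)])
    def test_matches_mc(self, L, c):
        mc, se = mc_single_path(L, c, "gumbel", 10**6, seed=200 + L)
        assert abs(rmf_path_prob_gumbel(L, c) - mc) < 3 * se

    def test_bounds_and_monotone_in_c(self):
        for L in (3, 6, 10):
            vals = [rmf_path_prob_gumbel(L, c) for c in np.linspace(0, 5, 30)]
            assert all(1 / factorial(L) <= v <= 1 for v in vals)
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_exponential_decay(self):
        """P(L+1)/P(L) approaches the constant 1 - e^{-c}: accessibility of
        a single path decays exponentially, not factorially."""
        c = 1.0
        ratios = [
            rmf_path_prob_gumbel(L + 1, c) / rmf_path_prob_gumbel(L, c)
            for L in range(20, 30)
        ]
        assert np.allclose(ratios, 1 - np.exp(-c), rtol=1e-6)

    def test_denominator_constant(self):
        c = 0.8
        finite = np.prod([1 - np.exp(-c * k) for k in range(2, 200)])
        assert np.isclose(gumbel_denominator_constant(c), finite, rtol=1e-10)

    def test_negative_c_rejected(self):
        with pytest.raises(ValueError):
            rmf_path_prob_gumbel(4, -0.1)


class TestHoley:
    def test_p1_is_factorial(self):
        assert ps.holey_expected_paths(5, 1.0) == 120.0

    def test_l2_half(self):
        assert ps.holey_expected_paths(2, 0.5) == 1.0

    def test_eventually_increasing(self):
        vals = [ps.holey_expected_paths(L, 0.1) for L in range(2, 40)]
        # factorial growth beats exponential decay from some L on
        assert vals[-1] > vals[-2] > vals[-3]
        assert any(b > a for a, b in zip(vals, vals[1:]))


def _simulate_viability(model, rng):
    """Draw one realization of the multiplicative lethality model over all
    2^L0 genotypes; returns the viability mask."""
    n = 1 << model.L0
    idx = np.arange(n)
    weight = np.zeros(n, dtype=int)
    for i in range(model.L0):
        weight += (idx >> i) & 1
    focal_bit = model.L0 - 1  # place the focal locus at the top bit
    has_focal = (idx >> focal_bit) & 1 == 1
    p_v = (1 - model.p_common) ** (weight - has_focal) * np.where(
        has_focal, 1 - model.p_focal, 1.0
    )
    return rng.random(n) < p_v


class TestLethalityModel:
    def test_vsg_no_ordinary_lethality(self):
        m = LethalityModel(0.0, 1.0)
        assert expected_vsg(m, 2) == comb(7, 2) == 21
        assert expected_vsg(m, 5) == comb(7, 5)

    def test_lethal_free_no_lethality(self):
        m = LethalityModel(0.0, 0.0)
        for L in (2, 4, 6):
            assert np.isclose(expected_lethal_free(m, L), factorial(L))

    @pytest.mark.parametrize("L", [2, 3])
    def test_vsg_matches_simulation(self, L):
        """Closed form vs direct simulation of the lethality model: count
        focal-free size-L subsets whose every mutation-carrying genotype is
        viable."""
        import itertools

        m = LethalityModel(0.02, 0.45, L0=6)
        rng = np.random.default_rng(7)
        reps = 3000
        counts = np.empty(reps)
        for r in range(reps):
            viable = _simulate_viability(m, rng)
            c = 0
            for loci in itertools.combinations(range(m.L0 - 1), L):
                gs = []
                for bits in itertools.product((0, 1), repeat=L):
                    g = sum(b << i for i, b in zip(loci, bits))
                    gs.append(g)
                if all(viable[g] for g in gs):
                    c += 1
            counts[r] = c
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expected_vsg(m, L)) < 3 * se

    @pytest.mark.parametrize("L", [2, 3])
    def test_lethal_free_matches_simulation(self, L):
        """Closed form vs simulation: average lethal-free path count over
        every size-L subset and all L! orders."""
        import itertools

        from conftest import brute_lethal_free

        m = LethalityModel(0.05, 0.5, L0=5)
        rng = np.random.default_rng(8)
        reps = 2000
        subsets = list(itertools.combinations(range(m.L0), L))
        means = np.empty(reps)
        for r in range(reps):
            viable = _simulate_viability(m, rng)
            tot = 0
            for loci in subsets:
                f = np.zeros(1 << L)
                for bits in itertools.product((0, 1), repeat=L):
                    sub_g = sum(b << j for j, b in enumerate(bits))
                    par_g = sum(b << i for i, b in zip(loci, bits))
                    f[sub_g] = float(viable[par_g])
                tot += brute_lethal_free(
                    ps.Landscape(L, f), 0, (1 << L) - 1
                )
            means[r] = tot / len(subsets)
        se = means.std(ddof=1) / np.sqrt(reps)
        assert abs(means.mean() - expected_lethal_free(m, L)) < 3 * se

    def test_monotone_in_p_common(self):
        for L in (2, 4):
            v = [
                expected_vsg(LethalityModel(p, 0.45), L)
                for p in (0.0, 0.01, 0.05, 0.2)
            ]
            w = [
                expected_lethal_free(LethalityModel(p, 0.45), L)
                for p in (0.0, 0.01, 0.05, 0.2)
            ]
            assert all(b < a for a, b in zip(v, v[1:]))
            assert all(b < a for a, b in zip(w, w[1:]))


class TestMissedGenotypes:
    def test_no_sampling(self):
        q, lam, _ = missed_genotype_stats(100, 0, 0)
        assert q == 1.0 and lam == 100.0

    def test_reference_value(self):
        # 256 * (255/256)^2500 = 0.01439...
        _, lam, _ = missed_genotype_stats(256, 2500, 1)
        assert np.isclose(lam, 256 * (255 / 256) ** 2500, rtol=1e-12)
        assert np.isclose(lam, 0.0144, atol=5e-4)

    def test_cdf_monotone_to_one(self):
        vals = [missed_genotype_stats(64, 100, k)[2] for k in range(0, 80)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert np.isclose(vals[-1], 1.0)

    def test_homogeneous_limit_matches_poisson(self):
        G, N = 64, 400
        _, lam, _ = missed_genotype_stats(G, N)
        missed = simulate_heterogeneous_detection(
            G, N, low_frac=1.0, reps=4000, seed=3
        )
        se = missed.std(ddof=1) / np.sqrt(missed.size)
        assert abs(missed.mean() - lam) < 4 * se + 0.02 * lam

    def test_heterogeneity_increases_misses(self):
        G, N = 64, 400
        homo = simulate_heterogeneous_detection(
            G, N, low_frac=1.0, reps=4000, seed=4
        )
        hetero = simulate_heterogeneous_detection(
            G, N, low_frac=0.05, reps=4000, seed=4
        )
        assert hetero.mean() > homo.mean()

    def test_large_sample_no_misses(self):
        missed = simulate_heterogeneous_detection(
            16, 5000, low_frac=0.5, reps=50, seed=5
        )
        assert missed.max() == 0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_heterogeneous_detection(64, 100, low_frac=0.0)
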