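import numpy as np
import pytest

import pathscape as ps


def brute_count(lsc, start, end):
    """Independent accessible-path oracle: enumerate all D! flip orders and
    check strict fitness increase explicitly."""
    n = 0
    for path in ps.enumerate_shortest_paths(start, end, lsc.L):
        f = lsc.fitness[path]
        if np.all(np.diff(f) > 0):
            n += 1
    return n


def brute_lethal_free(lsc, start, end):
    """Independent lethal-free oracle: enumerate all flip orders and check
    viability of every genotype on the path."""
    n = 0
    for path in ps.enumerate_shortest_paths(start, end, lsc.L):
        if np.all(lsc.fitness[path] > 0):
            n += 1
    return n


@pytest.fixture
def oracle_count():
    return brute_count


@pytest.fixture
def oracle_lethal_free():
    return brute_lethal_free


@pytest.fixture
def l2_example():
    """The worked 2-locus landscape: f(00)=0.10, f(10)=0.05, f(01)=0.20,
    f(11)=0.30 (indices little-endian in locus order)."""
    return ps.Landscape(2, np.array([0.10, 0.05, 0.20, 0.30]))


def additive_landscape(L):
    """Additive landscape with distinct positive locus effects (so greedy
    walks never tie): monotone along every upward path, optimum all-ones."""
    idx = np.arange(1 << L)
    w = np.zeros(1 << L)
    for i in range(L):
        w += (1.0 + 0.1 * i) * ((idx >> i) & 1)
    return ps.Landscape(L, w + 1.0)  # +1 keeps everything viable


@pytest.fixture
def make_additive():
    return additive_landscape
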