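"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from expdiv.phylo import Phylogeny, TreeEnsemble
from expdiv.synth import SynthConfig, simulate_trees

#: worked three-leaf tree used throughout: ((A:1,B:1):1,C:2)
T3_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def t3() -> Phylogeny:
    return Phylogeny.from_newick(T3_NEWICK)


@pytest.fixture
def two_leaf() -> Phylogeny:
    return Phylogeny.from_newick("(A:1,B:1);")


def random_phylogeny(n_leaves: int, seed: int) -> Phylogeny:
    """A random ultrametric tree on n_leaves tips (input generator only)."""
    cfg = SynthConfig(n_species=n_leaves, seed=seed)
    return simulate_trees(cfg, 1)[0]


def brute_expected_pd(tree: Phylogeny, p: np.ndarray) -> float:
    """Independent expected-PD oracle: enumerate all survival outcomes.

    Sums, over every one of the 2^n extinction patterns, the rooted Faith
    PD of the surviving leaf set weighted by the pattern's probability.
    Exponential-time; usable only for tiny trees.
    """
    n = tree.n_leaves
    total = 0.0
    for pattern in itertools.product([0, 1], repeat=n):  # 1 = survives
        prob = 1.0
        for i, survive in enumerate(pattern):
            prob *= (1.0 - p[i]) if survive else p[i]
        if prob == 0.0:
            continue
        survivors = np.asarray(pattern, dtype=float)
        touched = tree.leaf_matrix @ survivors
        total += prob * float(tree.branch_lengths[touched > 0].sum())
    return total


def two_eval_hedge(tree: Phylogeny, p: np.ndarray, i: int) -> float:
    """HEDGE by its two-evaluation definition expPD(p_i->0) - expPD(p)."""
    from expdiv.species_scores import expected_pd

    secured = p.copy()
    secured[i] = 0.0
    return expected_pd(tree, secured) - expected_pd(tree, p)


def two_eval_ledge(tree: Phylogeny, p: np.ndarray, i: int) -> float:
    """LEDGE by its two-evaluation definition expPD(p) - expPD(p_i->1)."""
    from expdiv.species_scores import expected_pd

    lost = p.copy()
    lost[i] = 1.0
    return expected_pd(tree, p) - expected_pd(tree, lost)
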