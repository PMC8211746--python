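"""Per-species conservation scores built on expected phylogenetic diversity.

Expected PD under independent species extinctions with probabilities
``p_i`` is

    expPD(p) = sum over branches b of  len(b) * (1 - prod_{i in leaves(b)} p_i),

i.e. each branch survives iff at least one descendant survives.  The
species scores are finite differences of this quantity:

* HEDGE_i = expPD(p with p_i -> 0) - expPD(p): the gain in expected PD if
  species i is secured.  Per branch this collapses to
  ``sum_{b ∋ i} len(b) * prod_{j in leaves(b)} p_j``.
* LEDGE_i = expPD(p) - expPD(p with p_i -> 1): the loss in expected PD if
  species i goes extinct; per branch
  ``sum_{b ∋ i} len(b) * (1 - p_i) * prod_{j in leaves(b), j != i} p_j``.

ED is the fair-proportion partition of total PD (each branch split evenly
among its descendants) and EDGE combines it with the Red List weight GE as
``ln(1 + ED) + GE * ln 2``.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import Phylogeny, TreeEnsemble

__all__ = [
    "expected_pd",
    "hedge_scores",
    "ledge_scores",
    "evolutionary_distinctiveness",
    "edge_score",
    "median_over_trees",
    "top_fraction",
    "rank_correlation",
    "set_overlap",
]


def _pvector(tree: Phylogeny, p) -> np.ndarray:
    """Align an extinction-probability mapping/array to the tree's leaves."""
    if isinstance(p, Mapping) or isinstance(p, pd.Series):
        getter = p.__getitem__
        try:
            vec = np.asarray([float(getter(lab)) for lab in tree.labels])
        except KeyError as exc:
            raise KeyError(f"no extinction probability for species {exc.args[0]!r}")
    else:
        vec = np.asarray(p, dtype=float)
        if vec.shape != (tree.n_leaves,):
            raise ValueError(
                f"probability vector length {vec.shape} != n_leaves {tree.n_leaves}"
            )
    if np.any((vec < 0) | (vec > 1)):
        raise ValueError("extinction probabilities must lie in [0, 1]")
    return vec


def _branch_survival_terms(tree: Phylogeny, pvec: np.ndarray):
    """Per-branch q_b = prod_{i in leaves(b)} p_i, handled safely at p=0.

    Returns (q, logsum, zero_count) where logsum is the sum of log p over
    the branch's *non-zero* leaves and zero_count the number of zero-p
    leaves, so q = exp(logsum) when zero_count == 0 else 0.
    """
    M = tree.leaf_matrix
    zero = (pvec == 0).astype(float)
    logp = np.where(pvec > 0, np.log(np.where(pvec > 0, pvec, 1.0)), 0.0)
    zero_count = M @ zero
    logsum = M @ logp
    q = np.where(zero_count > 0, 0.0, np.exp(logsum))
    return q, logsum, zero_count


def expected_pd(tree: Phylogeny, p) -> float:
    """Expected PD surviving the horizon, given extinction probabilities."""
    pvec = _pvector(tree, p)
    q, _, _ = _branch_survival_terms(tree, pvec)
    return float(np.sum(tree.branch_lengths * (1.0 - q)))


def hedge_scores(tree: Phylogeny, p) -> pd.Series:
    """Gain in expected PD per species if it alone were secured (p_i -> 0)."""
    pvec = _pvector(tree, p)
    q, _, _ = _branch_survival_terms(tree, pvec)
    per_species = tree.leaf_matrix.T @ (tree.branch_lengths * q)
    return pd.Series(per_species, index=list(tree.labels), name="HEDGE")


def ledge_scores(tree: Phylogeny, p) -> pd.Series:
    """Loss in expected PD per species if it alone went extinct (p_i -> 1)."""
    pvec = _pvector(tree, p)
    q, logsum, zero_count = _branch_survival_terms(tree, pvec)
    lengths = tree.branch_lengths
    # prod over the branch's leaves excluding i:
    #  - p_i > 0: q_b / p_i  (zero whenever another leaf has p=0, via q_b=0)
    #  - p_i = 0: exp(logsum_b) if i is the branch's only zero, else 0
    pos_part = tree.leaf_matrix.T @ (lengths * q)
    single_zero = np.where(zero_count == 1.0, np.exp(logsum), 0.0)
    zero_part = tree.leaf_matrix.T @ (lengths * single_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        excl = np.where(pvec > 0, pos_part / np.where(pvec > 0, pvec, 1.0), zero_part)
    vals = (1.0 - pvec) * excl
    return pd.Series(vals, index=list(tree.labels), name="LEDGE")


def evolutionary_distinctiveness(tree: Phylogeny) -> pd.Series:
    """Fair-proportion ED: each branch's length split evenly among its leaves.

    Sums exactly to the tree's total PD.
    """
    counts = np.asarray([len(lv) for lv in tree.branch_leaves], dtype=float)
    per_species = tree.leaf_matrix.T @ (tree.branch_lengths / counts)
    return pd.Series(per_species, index=list(tree.labels), name="ED")


def edge_score(ed, ge) -> float | np.ndarray:
    """EDGE = ln(1 + ED) + GE * ln 2, with GE the Red List weight 0-4."""
    ed_arr = np.asarray(ed, dtype=float)
    ge_arr = np.asarray(ge, dtype=float)
    if np.any(ed_arr < 0):
        raise ValueError("ED must be >= 0")
    if np.any((ge_arr < 0) | (ge_arr > 4) | (ge_arr != np.round(ge_arr))):
        raise ValueError("GE must be an integer in 0..4")
    out = np.log1p(ed_arr) + ge_arr * math.log(2.0)
    return float(out) if out.ndim == 0 else out


def median_over_trees(
    ensemble: TreeEnsemble,
    score_fn: Callable[..., pd.Series],
    *args,
    **kwargs,
) -> pd.Series:
    """Per-species median of a per-tree score over a posterior ensemble.

    Mirrors the robustness workflow of computing each score on every tree
    of the posterior sample and taking the species-wise median (even
    counts: mean of the two central values).
    """
    per_tree = []
    for tree in ensemble:
        s = score_fn(tree, *args, **kwargs)
        if set(s.index) != set(ensemble.labels):
            missing = sorted(set(ensemble.labels) ^ set(s.index))
            raise ValueError(f"score table species mismatch: {missing}")
        per_tree.append(s.reindex(list(ensemble.labels)))
    stacked = pd.concat(per_tree, axis=1)
    med = stacked.median(axis=1)
    med.name = per_tree[0].name
    return med


def top_fraction(scores: pd.Series, fraction: float) -> set:
    """The floor(fraction * n) highest-scoring species.

    Ties are broken deterministically (score descending, label ascending),
    and exactly ``floor(fraction * n)`` members are returned even when the
    cut falls inside a tie block.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(scores) == 0:
        raise ValueError("empty score table")
    k = math.floor(fraction * len(scores))
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {label for label, _ in order[:k]}


def rank_correlation(a: pd.Series, b: pd.Series) -> float:
    """Spearman rank correlation (mid-rank ties) between two score tables."""
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"score tables cover different species: {diff}")
    b = b.reindex(a.index)
    rho = stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic
    return float(rho)


def set_overlap(a: Iterable, b: Iterable) -> float:
    """Percent overlap 100 * |a ∩ b| / |a| between two equal-size top sets."""
    a, b = set(a), set(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap of empty sets is undefined")
    if len(a) != len(b):
        raise ValueError("top sets must have equal size")
    return 100.0 * len(a & b) / len(a)
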