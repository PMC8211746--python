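"""Rooted phylogeny model, Newick/NEXUS ensemble I/O and branch-leaf indexing.

All downstream scores are sums over branches of ``length x f(descendant
leaves)``, so the tree is stored in "branch form": a vector of branch
lengths plus, for every branch, the set of leaves below it.  Branch lengths
are in millions of years (Ma), the unit of every phylogenetic-diversity
quantity in this package.

The phylogenetic-diversity convention is *rooted* PD: the PD of a leaf
subset is the total length of all branches on the paths from those leaves
up to the root of the full tree.  A root edge above the basal split, if
present in the source Newick, is ignored.  This makes single-species PD
well defined (the species' root-path length) and makes fair-proportion
evolutionary distinctiveness sum exactly to total PD.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import sparse

__all__ = [
    "Phylogeny",
    "TreeEnsemble",
    "read_newick",
    "write_newick",
    "sample_trees",
    "branch_leaf_index",
    "total_pd",
]


class NewickParseError(ValueError):
    """Raised when a tree in an ensemble file cannot be parsed."""


class LeafSetMismatchError(ValueError):
    """Raised when trees of an ensemble do not share a leaf set."""


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with branch lengths, stored in branch form.

    Parameters
    ----------
    labels
        Leaf labels in a fixed (sorted) order; index ``i`` in every
        per-species vector refers to ``labels[i]``.
    branch_lengths
        Length of each branch in Ma, shape ``(n_branches,)``.
    branch_leaves
        For each branch, the sorted integer indices of its descendant
        leaves.  Pendant branches have singleton arrays.  The sets form a
        laminar family (any two are disjoint or nested).
    """

    labels: tuple[str, ...]
    branch_lengths: np.ndarray
    branch_leaves: tuple[np.ndarray, ...]
    _leaf_matrix: sparse.csr_matrix = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("leaf labels must be unique")
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        n = len(self.labels)
        for lv in self.branch_leaves:
            if len(lv) == 0:
                raise ValueError("every branch must have >= 1 descendant leaf")
            if lv.min() < 0 or lv.max() >= n:
                raise ValueError("branch leaf index out of range")
        rows, cols = [], []
        for b, lv in enumerate(self.branch_leaves):
            rows.extend([b] * len(lv))
            cols.extend(lv.tolist())
        mat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(self.branch_leaves), n),
        )
        object.__setattr__(self, "_leaf_matrix", mat)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        labels = tuple(sorted(t.label for t in tree.taxon_namespace if t))
        index = {lab: i for i, lab in enumerate(labels)}
        lengths: list[float] = []
        leaf_sets: list[np.ndarray] = []
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue  # root edge ignored by convention
            leaves = sorted(
                index[lf.taxon.label] for lf in node.leaf_iter()
            )
            lengths.append(float(node.edge.length or 0.0))
            leaf_sets.append(np.asarray(leaves, dtype=np.int64))
        return cls(labels, np.asarray(lengths, dtype=float), tuple(leaf_sets))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    # -- basic queries ------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return frozenset(self.labels)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)

    @property
    def leaf_matrix(self) -> sparse.csr_matrix:
        """Sparse (n_branches x n_leaves) 0/1 membership matrix."""
        return self._leaf_matrix

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def leaf_indices(self, subset: Iterable[str]) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.asarray(sorted(index[s] for s in subset), dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not on tree") from None

    def species_branches(self) -> list[np.ndarray]:
        """For each leaf, the indices of the branches on its root path."""
        csc = self._leaf_matrix.tocsc()
        return [csc.indices[csc.indptr[i]:csc.indptr[i + 1]].astype(np.int64)
                for i in range(self.n_leaves)]


@dataclass(frozen=True)
class TreeEnsemble:
    """An ordered collection of phylogenies over one shared leaf set."""

    trees: tuple[Phylogeny, ...]

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise ValueError("ensemble must contain >= 1 tree")
        ref = self.trees[0].leaves
        for i, t in enumerate(self.trees[1:], start=1):
            if t.leaves != ref:
                diff = sorted(t.leaves ^ ref)
                raise LeafSetMismatchError(
                    f"tree {i} leaf set differs from tree 0; "
                    f"symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.trees[0].labels

    @property
    def leaves(self) -> frozenset:
        return self.trees[0].leaves


def _detect_schema(path: Path) -> str:
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "newick"


def read_newick(path: str | Path) -> TreeEnsemble:
    """Read a tree ensemble from a Newick (one tree per line) or NEXUS file.

    Raises
    ------
    NewickParseError
        If a tree cannot be parsed; the message names the failing tree index.
    LeafSetMismatchError
        If trees do not share an identical leaf set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = _detect_schema(path)
    if schema == "nexus":
        try:
            tree_list = dendropy.TreeList.get(path=str(path), schema="nexus")
        except Exception as exc:
            raise NewickParseError(f"failed to parse NEXUS file {path}: {exc}") from exc
        trees = [Phylogeny.from_dendropy(t) for t in tree_list]
    else:
        trees = []
        with open(path) as fh:
            idx = 0
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    trees.append(Phylogeny.from_newick(line))
                except Exception as exc:
                    raise NewickParseError(
                        f"failed to parse tree {idx} in {path}: {exc}"
                    ) from exc
                idx += 1
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return TreeEnsemble(tuple(trees))


def write_newick(ensemble: TreeEnsemble, path: str | Path) -> None:
    """Write an ensemble as one-tree-per-line Newick with branch lengths."""
    with open(path, "w") as fh:
        for tree in ensemble:
            fh.write(_to_newick(tree) + "\n")


def _to_newick(tree: Phylogeny) -> str:
    # Rebuild the topology from the laminar branch family: parent of a
    # branch is the shortest strict superset.
    order = sorted(
        range(tree.n_branches),
        key=lambda b: len(tree.branch_leaves[b]),
        reverse=True,
    )
    children: dict[int, list[int]] = {-1: []}
    sets = [frozenset(lv.tolist()) for lv in tree.branch_leaves]
    for pos, b in enumerate(order):
        parent = -1
        best = None
        for other in order[:pos]:
            if sets[b] < sets[other]:
                if best is None or len(sets[other]) < len(sets[best]):
                    best = other
        if best is not None:
            parent = best
        children.setdefault(parent, []).append(b)
        children.setdefault(b, [])

    def render(b: int) -> str:
        kids = children[b]
        if not kids:
            (leaf,) = tree.branch_leaves[b]
            return f"{tree.labels[leaf]}:{tree.branch_lengths[b]:.10g}"
        inner = ",".join(render(k) for k in sorted(kids))
        if b == -1:
            return f"({inner})"
        return f"({inner}):{tree.branch_lengths[b]:.10g}"

    return render(-1) + ";"


def sample_trees(ensemble: TreeEnsemble, k: int, seed: int) -> TreeEnsemble:
    """Sample ``k`` trees without replacement, reproducibly for a fixed seed."""
    if not 1 <= k <= len(ensemble):
        raise ValueError(f"k={k} outside [1, {len(ensemble)}]")
    rng = random.Random(seed)
    picks = rng.sample(range(len(ensemble)), k)
    return TreeEnsemble(tuple(ensemble.trees[i] for i in picks))


def branch_leaf_index(tree: Phylogeny) -> dict[int, frozenset]:
    """Map each branch id to the frozenset of its descendant leaf labels."""
    return {
        b: frozenset(tree.labels[i] for i in lv)
        for b, lv in enumerate(tree.branch_leaves)
    }


def total_pd(tree: Phylogeny, subset: Iterable[str]) -> float:
    """Faith's PD of a leaf subset under the rooted convention.

    Sum of the lengths of all branches on the paths from the subset to the
    root; the empty subset scores 0 by convention.
    """
    subset = set(subset)
    if not subset:
        return 0.0
    idx = tree.leaf_indices(subset)
    present = np.zeros(tree.n_leaves, dtype=float)
    present[idx] = 1.0
    touched = tree.leaf_matrix @ present  # per-branch count of subset leaves
    return float(tree.branch_lengths[touched > 0].sum())
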