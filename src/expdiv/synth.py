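"""Seeded generators emulating the pipeline's four real-data inputs.

The real analysis consumes (a) a posterior sample of ultrametric
phylogenies, (b) a Red List status table with a data-deficient fraction,
(c) gridded presence/absence range maps on the equal-area reference grid
and (d) a per-cell protected-surface percentage derived from the global
protected-area network.  Each generator here produces one of these with
the statistical structure the analysis assumes, as a pure function of its
configuration and seed, so every pipeline stage is testable offline.

Defaults mirror the study conditions where stated (Red List composition
of extant mammals with a ~14% DD fraction; heavy-tailed range-size
distribution; ~15% mean protected coverage) and are documented choices
otherwise.  Trees are pure-birth (Yule), the simplest ultrametric model
that exercises every score; range maps are spreading-dye growths
(4-connected contiguous patches) with log-normal target sizes; coverage
is a field of random rectangular blobs calibrated to a target mean.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .phylo import Phylogeny, TreeEnsemble
from .spatial import EqualAreaGrid
from .protection import CoverageGrid

__all__ = [
    "SynthConfig",
    "simulate_trees",
    "simulate_statuses",
    "simulate_ranges",
    "simulate_protection",
]

#: Red List composition of extant mammals, including the DD fraction.
DEFAULT_STATUS_FREQUENCIES: Mapping[str, float] = {
    "LC": 0.56,
    "NT": 0.07,
    "VU": 0.09,
    "EN": 0.08,
    "CR": 0.05,
    "DD": 0.15,
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for all synthetic-input generators.

    range_size_median / range_size_log_sd parameterise the log-normal
    target range-size distribution in cells (heavy-tailed, as empirical
    range-size distributions are).  protection_target_mean is the global
    mean percent coverage the blob field is calibrated to, and
    protection_n_blobs / protection_blob_cells control its granularity.
    """

    n_species: int = 200
    seed: int = 0
    birth_rate: float = 1.0  # per Ma
    status_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_FREQUENCIES)
    )
    range_size_median: float = 20.0
    range_size_log_sd: float = 1.5
    protection_target_mean: float = 15.0
    protection_n_blobs: int = 200
    protection_blob_cells: float = 6.0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        total = sum(self.status_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"status frequencies sum to {total}, not 1")
        if self.birth_rate <= 0 or self.range_size_median <= 0:
            raise ValueError("rates and sizes must be positive")

    def species_labels(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{i:0{width}d}" for i in range(1, self.n_species + 1)]


def simulate_trees(cfg: SynthConfig, n_trees: int) -> TreeEnsemble:
    """Simulate ``n_trees`` ultrametric pure-birth trees on shared labels.

    Branch lengths are in Ma (rate ``birth_rate`` per Ma); all trees carry
    the identical label set ``sp0001..``, as a posterior sample over one
    taxon set does.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    labels = cfg.species_labels()
    master = random.Random(cfg.seed)
    trees = []
    for _ in range(n_trees):
        rng = random.Random(master.randrange(2**31))
        dtree = treesim.birth_death_tree(
            birth_rate=cfg.birth_rate,
            death_rate=0.0,
            num_extant_tips=cfg.n_species,
            rng=rng,
        )
        tips = sorted(dtree.leaf_node_iter(), key=lambda n: n.taxon.label)
        for tip, lab in zip(tips, labels):
            tip.taxon.label = lab
        trees.append(Phylogeny.from_dendropy(dtree))
    return TreeEnsemble(tuple(trees))


def simulate_statuses(cfg: SynthConfig) -> pd.DataFrame:
    """Draw a Red List category per species from the configured frequencies."""
    rng = np.random.default_rng(cfg.seed + 1)
    cats = sorted(cfg.status_frequencies)
    probs = np.asarray([cfg.status_frequencies[c] for c in cats])
    draws = rng.choice(len(cats), size=cfg.n_species, p=probs / probs.sum())
    return pd.DataFrame(
        {
            "species": cfg.species_labels(),
            "category": [cats[i] for i in draws],
        }
    )


def _spreading_dye(
    rng: np.random.Generator, grid: EqualAreaGrid, target: int
) -> np.ndarray:
    """Grow a 4-connected contiguous patch of ``target`` cells.

    Starts from a uniformly drawn seed cell and repeatedly occupies a
    uniformly chosen frontier neighbour; the grid is non-periodic (no
    wrap-around), matching raster semantics.
    """
    nr, nc = grid.n_rows, grid.n_cols
    start = int(rng.integers(nr * nc))
    occupied = {start}
    frontier = []
    def neighbours(cid):
        r, c = divmod(cid, nc)
        if r > 0:
            yield cid - nc
        if r < nr - 1:
            yield cid + nc
        if c > 0:
            yield cid - 1
        if c < nc - 1:
            yield cid + 1
    frontier = [n for n in neighbours(start) if n not in occupied]
    while len(occupied) < target and frontier:
        k = int(rng.integers(len(frontier)))
        cell = frontier.pop(k)
        if cell in occupied:
            continue
        occupied.add(cell)
        for n in neighbours(cell):
            if n not in occupied:
                frontier.append(n)
    return np.fromiter(sorted(occupied), dtype=np.int64)


def simulate_ranges(cfg: SynthConfig, grid: EqualAreaGrid):
    """Contiguous ranges with log-normal target sizes on the reference grid.

    Returns a PresenceMatrix.  Target sizes are drawn from a log-normal
    with the configured median and log-sd, clipped to [1, n_cells].
    """
    from .spatial import assemble_presence

    rng = np.random.default_rng(cfg.seed + 2)
    labels = cfg.species_labels()
    occurrences: dict[str, np.ndarray] = {}
    for lab in labels:
        size = float(
            cfg.range_size_median * np.exp(cfg.range_size_log_sd * rng.standard_normal())
        )
        target = int(np.clip(round(size), 1, grid.n_cells))
        occurrences[lab] = _spreading_dye(rng, grid, target)
    return assemble_presence(grid, occurrences, species=labels)


def simulate_protection(cfg: SynthConfig, grid: EqualAreaGrid) -> CoverageGrid:
    """A per-cell percent-protected field from random rectangular blobs.

    The raw blob field is rescaled (iteratively, because values clip at
    100) until its global mean is within ±2 percentage points of
    ``protection_target_mean``.
    """
    target = float(cfg.protection_target_mean)
    if not 0.0 <= target <= 100.0:
        raise ValueError("protection target mean must be in [0, 100]")
    if target == 0.0:
        return CoverageGrid(grid=grid, percent=np.zeros(grid.n_cells))
    if target == 100.0:
        return CoverageGrid(grid=grid, percent=np.full(grid.n_cells, 100.0))
    rng = np.random.default_rng(cfg.seed + 3)
    nr, nc = grid.n_rows, grid.n_cols
    fld = np.zeros((nr, nc))
    for _ in range(cfg.protection_n_blobs):
        h = max(1, int(round(rng.exponential(cfg.protection_blob_cells))))
        w = max(1, int(round(rng.exponential(cfg.protection_blob_cells))))
        r0 = int(rng.integers(nr))
        c0 = int(rng.integers(nc))
        fld[r0:r0 + h, c0:c0 + w] += rng.uniform(20.0, 100.0)
    flat = fld.ravel()
    if flat.sum() == 0:
        flat[0] = 1.0
    vals = np.clip(flat, 0.0, 100.0)
    # calibrate the global mean to the target; multiplicative rescaling,
    # with an additive floor-lift when clipping at 100 makes it stall
    for _ in range(200):
        mean = vals.mean()
        if abs(mean - target) <= 1e-9:
            break
        if mean > target:
            vals = vals * (target / mean)
        else:
            before = mean
            vals = np.clip(vals * (target / mean), 0.0, 100.0)
            if vals.mean() - before < 1e-6:
                vals = np.clip(vals + (target - vals.mean()), 0.0, 100.0)
    return CoverageGrid(grid=grid, percent=vals)
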