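"""Equal-area reference grid, presence assembly and per-cell scores.

The reference grid is a cylindrical equal-area (Behrmann, standard
parallels 30°N/S) raster on the WGS84 ellipsoid.  Column count is the
world width at the standard parallel divided by the cell size, rounded to
the nearest integer; row count likewise for the projected height of the
latitude band.  With the 96.5 km cells, 30° standard parallel and the
90°N-60°S band this reproduces the 360 x 142 = 51,120-cell grid on which
the mammal range maps are distributed.  Cells are squares of exactly
``cell_size²`` in the projected plane; ids are row-major integers with
row 0 at the northern edge.

Twelve scores are computed per cell from a presence/absence matrix, a
phylogeny and a species risk table:

    i    SR    species richness
    ii   TSR   threatened (VU/EN/CR) species richness
    iii  RSR   rare species richness (range size strictly below the
               median range size over all species)
    iv   SWR   species-weighted rarity: sum of 1/range_size over species
               present (weighted endemism)
    v    PD    Faith's PD of the species present (rooted convention)
    vi   TPD   PD of the threatened species present
    vii  RPD   PD of the rare species present
    viii PWR   phylogenetic-weighted rarity (phylogenetic endemism):
               sum over branches present of len(b)/range(b), with
               range(b) the number of cells where the branch occurs
    ix,x       richness in a TOP set of species (e.g. TOP 25% HEDGE)
    xi   GexpPD gain in expected PD if every species present were secured
    xii  LexpPD loss in expected PD if every species present went extinct
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .phylo import Phylogeny
from .risk import THREATENED
from .species_scores import _branch_survival_terms, _pvector

logger = logging.getLogger(__name__)

__all__ = [
    "EqualAreaGrid",
    "PresenceMatrix",
    "build_reference_grid",
    "assemble_presence",
    "read_presence_csv",
    "write_presence_csv",
    "range_sizes",
    "species_cell_scores",
    "pd_cell_scores",
    "phylogenetic_endemism",
    "top_set_richness",
    "gexp_pd",
    "lexp_pd",
    "proportion_map",
    "hotspots",
]

# WGS84 ellipsoid
_A_KM = 6378.137
_F = 1.0 / 298.257223563
_E2 = 2.0 * _F - _F * _F
_E = math.sqrt(_E2)


def _q_auth(lat_rad: float) -> float:
    """Snyder's q for the ellipsoidal cylindrical equal-area projection."""
    s = math.sin(lat_rad)
    return (1.0 - _E2) * (
        s / (1.0 - _E2 * s * s)
        - (1.0 / (2.0 * _E)) * math.log((1.0 - _E * s) / (1.0 + _E * s))
    )


@dataclass(frozen=True)
class EqualAreaGrid:
    """A cylindrical equal-area raster grid with square cells.

    Cell ids are row-major integers, row 0 at the top (north).  Every cell
    has identical area ``cell_size_km²``.
    """

    cell_size_km: float
    standard_parallel: float
    lat_max: float
    lat_min: float
    n_rows: int
    n_cols: int

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km ** 2

    @property
    def k0(self) -> float:
        phi = math.radians(self.standard_parallel)
        return math.cos(phi) / math.sqrt(1.0 - _E2 * math.sin(phi) ** 2)

    def y_of_lat(self, lat_deg: float) -> float:
        """Projected northing (km) of a latitude."""
        return _A_KM * _q_auth(math.radians(lat_deg)) / (2.0 * self.k0)

    @property
    def x_min(self) -> float:
        return -0.5 * self.n_cols * self.cell_size_km

    @property
    def y_top(self) -> float:
        return self.y_of_lat(self.lat_max)

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        if not 0 <= cell_id < self.n_cells:
            raise ValueError(f"cell id {cell_id} outside grid")
        return divmod(cell_id, self.n_cols)

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of a cell in projected km."""
        row, col = self.rowcol(cell_id)
        x0 = self.x_min + col * self.cell_size_km
        y1 = self.y_top - row * self.cell_size_km
        return (x0, y1 - self.cell_size_km, x0 + self.cell_size_km, y1)


def build_reference_grid(
    cell_size_km: float = 96.5,
    standard_parallel: float = 30.0,
    lat_max: float = 90.0,
    lat_min: float = -60.0,
) -> EqualAreaGrid:
    """Build the equal-area reference grid for a latitude band.

    Column count = round(world width at the standard parallel / cell size);
    row count = round(projected band height / cell size).  The defaults
    reproduce the 51,120-cell (360 x 142) Behrmann grid used for global
    mammal range maps.
    """
    if cell_size_km <= 0:
        raise ValueError("cell size must be > 0")
    if lat_min >= lat_max:
        raise ValueError("degenerate latitude extent")
    phi = math.radians(standard_parallel)
    k0 = math.cos(phi) / math.sqrt(1.0 - _E2 * math.sin(phi) ** 2)
    width = 2.0 * math.pi * _A_KM * k0
    height = _A_KM * (_q_auth(math.radians(lat_max)) - _q_auth(math.radians(lat_min))) / (
        2.0 * k0
    )
    n_cols = round(width / cell_size_km)
    n_rows = round(height / cell_size_km)
    if n_cols < 1 or n_rows < 1:
        raise ValueError("cell size too large for the requested extent")
    return EqualAreaGrid(
        cell_size_km=cell_size_km,
        standard_parallel=standard_parallel,
        lat_max=lat_max,
        lat_min=lat_min,
        n_rows=n_rows,
        n_cols=n_cols,
    )


@dataclass(frozen=True)
class PresenceMatrix:
    """Sparse boolean occurrence of species (columns) in grid cells (rows)."""

    grid: EqualAreaGrid
    species: tuple[str, ...]
    matrix: sparse.csr_matrix  # (n_cells, n_species), 0/1

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match grid "
                f"({self.grid.n_cells} cells) x species ({len(self.species)})"
            )
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"species {label!r} not in presence matrix") from None

    def occupied_cells(self) -> np.ndarray:
        return np.flatnonzero(self.matrix.getnnz(axis=1) > 0)


def assemble_presence(
    grid: EqualAreaGrid,
    occurrences: Iterable[tuple[str, int]] | pd.DataFrame | Mapping[str, Iterable[int]],
    species: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Assemble a presence matrix from per-species occurrence records.

    ``occurrences`` may be a long-format table with columns
    ``species,row,col`` (0-based, row-major), an iterable of
    ``(species, cell_id)`` pairs, or a mapping species -> cell ids.
    Duplicate records are deduplicated.  ``species`` fixes the column
    order and keeps zero-range species; it defaults to the sorted set of
    species seen in the records.  Out-of-grid coordinates raise.
    """
    pairs: list[tuple[str, int]] = []
    if isinstance(occurrences, pd.DataFrame):
        required = {"species", "row", "col"}
        if not required <= set(occurrences.columns):
            raise ValueError(f"occurrence table must have columns {sorted(required)}")
        rows = occurrences["row"].to_numpy()
        cols = occurrences["col"].to_numpy()
        if (
            (rows < 0).any()
            or (rows >= grid.n_rows).any()
            or (cols < 0).any()
            or (cols >= grid.n_cols).any()
        ):
            raise ValueError("occurrence coordinates fall outside the grid")
        pairs = list(
            zip(occurrences["species"], (rows * grid.n_cols + cols).tolist())
        )
    elif isinstance(occurrences, Mapping):
        for sp, cells in occurrences.items():
            for c in cells:
                pairs.append((sp, int(c)))
    else:
        pairs = [(sp, int(c)) for sp, c in occurrences]

    for _, c in pairs:
        if not 0 <= c < grid.n_cells:
            raise ValueError(f"cell id {c} outside grid with {grid.n_cells} cells")

    if species is None:
        species = sorted({sp for sp, _ in pairs})
    species = tuple(species)
    index = {sp: j for j, sp in enumerate(species)}
    unknown = {sp for sp, _ in pairs} - set(species)
    if unknown:
        raise KeyError(f"occurrence records for unlisted species: {sorted(unknown)}")

    uniq = sorted({(index[sp], c) for sp, c in pairs})
    cols_j = np.asarray([j for j, _ in uniq], dtype=np.int64)
    rows_c = np.asarray([c for _, c in uniq], dtype=np.int64)
    mat = sparse.csr_matrix(
        (np.ones(len(uniq)), (rows_c, cols_j)),
        shape=(grid.n_cells, len(species)),
    )
    empties = [sp for sp in species if index[sp] not in set(cols_j.tolist())]
    if empties:
        logger.warning("species with zero occupied cells retained: %s", empties)
    return PresenceMatrix(grid=grid, species=species, matrix=mat)


def read_presence_csv(path: str | Path, grid: EqualAreaGrid,
                      species: Sequence[str] | None = None) -> PresenceMatrix:
    df = pd.read_csv(path, comment="#")
    return assemble_presence(grid, df, species=species)


def write_presence_csv(pm: PresenceMatrix, path: str | Path) -> None:
    coo = pm.matrix.tocoo()
    rows, cols = np.divmod(coo.row, pm.grid.n_cols)
    df = pd.DataFrame(
        {
            "species": [pm.species[j] for j in coo.col],
            "row": rows,
            "col": cols,
        }
    ).sort_values(["species", "row", "col"], kind="mergesort")
    df.to_csv(path, index=False)


def range_sizes(pm: PresenceMatrix) -> pd.Series:
    """Occupied-cell count per species (column sums of the matrix)."""
    counts = np.asarray(pm.matrix.sum(axis=0)).ravel().astype(int)
    if (counts == 0).any():
        zero = [pm.species[j] for j in np.flatnonzero(counts == 0)]
        logger.warning("species with range size 0: %s", zero)
    return pd.Series(counts, index=list(pm.species), name="range_size")


def _species_indicator(pm: PresenceMatrix, mask: np.ndarray) -> np.ndarray:
    return mask.astype(float)


def species_cell_scores(pm: PresenceMatrix, risk: pd.DataFrame) -> pd.DataFrame:
    """SR, TSR, RSR and SWR for every grid cell.

    Rarity uses range size strictly below the median range size over all
    species in the risk table (mid-point convention for even counts);
    SWR weights use occupied-cell counts from the presence matrix itself.
    """
    risk = risk.set_index("species") if "species" in risk.columns else risk
    missing = set(pm.species) - set(risk.index)
    if missing:
        raise KeyError(f"species missing from risk table: {sorted(missing)}")
    cats = risk.loc[list(pm.species), "category"]
    if (cats == "DD").any():
        raise ValueError("risk table contains DD categories: impute first")

    ones = np.ones(pm.n_species)
    sr = pm.matrix @ ones
    thr = cats.isin(THREATENED).to_numpy().astype(float)
    tsr = pm.matrix @ thr

    rs_all = risk["range_size"].astype(float)
    median_range = float(rs_all.median())
    rare = (risk.loc[list(pm.species), "range_size"] < median_range).to_numpy()
    rsr = pm.matrix @ rare.astype(float)

    occ = np.asarray(pm.matrix.sum(axis=0)).ravel()
    inv = np.divide(1.0, occ, out=np.zeros_like(occ, dtype=float), where=occ > 0)
    swr = pm.matrix @ inv

    return pd.DataFrame(
        {"SR": sr, "TSR": tsr, "RSR": rsr, "SWR": swr},
        index=pd.RangeIndex(pm.grid.n_cells, name="cell_id"),
    )


def _branch_presence(pm: PresenceMatrix, tree: Phylogeny,
                     columns: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse (n_cells x n_branches) 0/1: does branch b occur in cell c?

    A branch occurs in a cell iff at least one of its descendant species
    does.  ``columns`` optionally restricts to a species subset (boolean
    mask over pm.species).
    """
    unknown = set(pm.species) - tree.leaves
    if unknown:
        raise KeyError(f"species not on tree: {sorted(unknown)}")
    tree_pos = {lab: i for i, lab in enumerate(tree.labels)}
    # map presence columns into tree leaf indices
    col_map = np.asarray([tree_pos[sp] for sp in pm.species], dtype=np.int64)
    mat = pm.matrix
    if columns is not None:
        sel = sparse.diags(columns.astype(float))
        mat = (mat @ sel).tocsr()
        mat.eliminate_zeros()
    # (n_cells x n_leaves) in tree ordering
    proj = sparse.csr_matrix(
        (mat.data, col_map[mat.indices], mat.indptr),
        shape=(pm.grid.n_cells, tree.n_leaves),
    )
    touched = proj @ tree.leaf_matrix.T  # counts per (cell, branch)
    touched.data = (touched.data > 0).astype(float)
    touched.eliminate_zeros()
    return touched.tocsr()


def pd_cell_scores(
    pm: PresenceMatrix, tree: Phylogeny, risk: pd.DataFrame
) -> pd.DataFrame:
    """Faith's PD (rooted), threatened-only PD and rare-only PD per cell."""
    risk = risk.set_index("species") if "species" in risk.columns else risk
    missing = set(pm.species) - set(risk.index)
    if missing:
        raise KeyError(f"species missing from risk table: {sorted(missing)}")
    cats = risk.loc[list(pm.species), "category"]
    median_range = float(risk["range_size"].astype(float).median())
    thr_mask = cats.isin(THREATENED).to_numpy()
    rare_mask = (risk.loc[list(pm.species), "range_size"] < median_range).to_numpy()

    out = {}
    for name, mask in (
        ("PD", None),
        ("TPD", thr_mask),
        ("RPD", rare_mask),
    ):
        ind = _branch_presence(pm, tree, columns=mask)
        out[name] = ind @ tree.branch_lengths
    return pd.DataFrame(out, index=pd.RangeIndex(pm.grid.n_cells, name="cell_id"))


def phylogenetic_endemism(pm: PresenceMatrix, tree: Phylogeny) -> pd.DataFrame:
    """Phylogenetic-weighted rarity (phylogenetic endemism) per cell.

    Each branch contributes its length divided by the number of cells in
    which it occurs, to every cell where it occurs; summed over cells this
    returns the total PD of the occurring branches.
    """
    ind = _branch_presence(pm, tree)
    branch_range = np.asarray(ind.sum(axis=0)).ravel()
    absent = branch_range == 0
    if absent.any():
        logger.warning(
            "%d branches with no occurring descendants excluded from PWR",
            int(absent.sum()),
        )
    weights = np.divide(
        tree.branch_lengths,
        branch_range,
        out=np.zeros_like(tree.branch_lengths),
        where=~absent,
    )
    pwr = ind @ weights
    return pd.DataFrame(
        {"PWR": pwr}, index=pd.RangeIndex(pm.grid.n_cells, name="cell_id")
    )


def top_set_richness(pm: PresenceMatrix, top_set: Iterable[str],
                     name: str = "TOP") -> pd.DataFrame:
    """Per-cell count of species belonging to a designated top set."""
    top_set = set(top_set)
    unknown = top_set - set(pm.species)
    if unknown:
        raise KeyError(f"top-set species not in presence matrix: {sorted(unknown)}")
    mask = np.asarray([sp in top_set for sp in pm.species], dtype=float)
    vals = pm.matrix @ mask
    return pd.DataFrame(
        {name: vals}, index=pd.RangeIndex(pm.grid.n_cells, name="cell_id")
    )


def gexp_pd(pm: PresenceMatrix, tree: Phylogeny, p) -> pd.DataFrame:
    """Gain in expected PD per cell if all species present were secured.

    Securing the cell's species zeroes their extinction probabilities, so
    every branch with a descendant in the cell becomes certain to survive;
    the gain collapses to ``sum over branches present in the cell of
    len(b) * prod_{j in leaves(b)} p_j``.
    """
    pvec = _pvector(tree, p)
    q, _, _ = _branch_survival_terms(tree, pvec)
    ind = _branch_presence(pm, tree)
    vals = ind @ (tree.branch_lengths * q)
    return pd.DataFrame(
        {"GexpPD": vals}, index=pd.RangeIndex(pm.grid.n_cells, name="cell_id")
    )


def lexp_pd(pm: PresenceMatrix, tree: Phylogeny, p) -> pd.DataFrame:
    """Loss in expected PD per cell if all species present went extinct.

    Per branch b occurring in cell c the loss is
    ``len(b) * prod_{j in b, j not in c} p_j * (1 - prod_{j in b ∩ c} p_j)``;
    branches with no descendant in the cell are unaffected.  Computed
    cell-by-cell over occupied cells only.
    """
    pvec = _pvector(tree, p)
    _, logsum_all, zeros_all = _branch_survival_terms(tree, pvec)
    lengths = tree.branch_lengths
    tree_pos = {lab: i for i, lab in enumerate(tree.labels)}
    unknown = set(pm.species) - tree.leaves
    if unknown:
        raise KeyError(f"species not on tree: {sorted(unknown)}")
    col_to_leaf = np.asarray([tree_pos[sp] for sp in pm.species], dtype=np.int64)
    sp_branches = tree.species_branches()

    logp = np.where(pvec > 0, np.log(np.where(pvec > 0, pvec, 1.0)), 0.0)
    is_zero = (pvec == 0).astype(np.int64)

    vals = np.zeros(pm.grid.n_cells)
    csr = pm.matrix
    for c in pm.occupied_cells():
        cols = csr.indices[csr.indptr[c]:csr.indptr[c + 1]]
        leaves = col_to_leaf[cols]
        branch_lists = [sp_branches[i] for i in leaves]
        cat = np.concatenate(branch_lists)
        branches = np.unique(cat)
        nb = tree.n_branches
        # per-branch: sum of log p and zero count over the cell's species
        l_in = np.bincount(cat, weights=np.concatenate(
            [np.full(len(bl), logp[i]) for bl, i in zip(branch_lists, leaves)]
        ), minlength=nb)[branches]
        z_in = np.bincount(cat, weights=np.concatenate(
            [np.full(len(bl), float(is_zero[i])) for bl, i in zip(branch_lists, leaves)]
        ), minlength=nb)[branches]
        p_in = np.where(z_in > 0, 0.0, np.exp(l_in))
        z_out = zeros_all[branches] - z_in
        p_out = np.where(z_out > 0, 0.0, np.exp(logsum_all[branches] - l_in))
        vals[c] = float(np.sum(lengths[branches] * p_out * (1.0 - p_in)))
    return pd.DataFrame(
        {"LexpPD": vals}, index=pd.RangeIndex(pm.grid.n_cells, name="cell_id")
    )


def proportion_map(numerator: pd.Series, denominator: pd.Series) -> pd.Series:
    """Element-wise ratio with zero-denominator cells masked (NaN), not 0."""
    if not numerator.index.equals(denominator.index):
        raise ValueError("numerator and denominator are on different grids")
    num = numerator.astype(float)
    den = denominator.astype(float)
    out = num / den.where(den != 0)
    out.name = f"{numerator.name}/{denominator.name}" if numerator.name else None
    return out


def hotspots(scores: pd.Series, fraction: float = 0.025) -> set:
    """The floor(fraction * n_defined) cells with the highest values.

    Masked (NaN) cells are excluded from the ranking and from the count
    basis.  Ties are broken deterministically (value descending, cell id
    ascending); a tie crossing the cut boundary emits a warning.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    defined = scores.dropna()
    if defined.empty:
        raise ValueError("all cells undefined: no hotspot ranking possible")
    k = math.floor(fraction * len(defined))
    order = sorted(defined.items(), key=lambda kv: (-kv[1], kv[0]))
    if 0 < k < len(order) and order[k - 1][1] == order[k][1]:
        warnings.warn(
            "tie at the hotspot boundary broken by cell id", stacklevel=2
        )
    return {cell for cell, _ in order[:k]}
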