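"""Configuration-driven orchestration of the three analyses.

Three stages mirror the study design: per-species scores (ED, EDGE,
HEDGE, LEDGE medians over the tree ensemble, TOP-fraction sets and their
pairwise Spearman correlations), per-cell spatial scores (the twelve cell
scores, proportion maps and hotspot sets), and the protection overlay
(per-hotspot-set coverage summaries).  A fourth entry point compares two
species-score runs, the workflow used to test robustness to a different
source phylogeny.

Every output table carries provenance metadata (a hash of the run
configuration, the seed and the tree count) as a leading comment line, so
re-running a command with identical config and seed produces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import phylo, risk, species_scores as sp, spatial, protection, synth

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_simulation",
    "run_species_analysis",
    "run_spatial_analysis",
    "run_protection_analysis",
    "compare_runs",
]

SPECIES_SCORES = ("ED", "EDGE", "HEDGE", "LEDGE")
CELL_SCORES = (
    "SR", "TSR", "RSR", "SWR",
    "PD", "TPD", "RPD", "PWR",
    "TOP_HEDGE", "TOP_LEDGE", "GexpPD", "LexpPD",
)


@dataclass(frozen=True)
class RunConfig:
    """Paths, analysis constants and the extinction model for one run."""

    trees: str | None = None
    species: str | None = None
    presence: str | None = None
    coverage: str | None = None
    out: str = "results"
    seed: int = 0
    n_trees: int | None = None  # subsample size from the posterior file
    top_species_fraction: float = 0.25
    hotspot_fraction: float = 0.025
    heavy_threshold: float = 50.0
    cell_size_km: float = 96.5
    standard_parallel: float = 30.0
    lat_max: float = 90.0
    lat_min: float = -60.0
    extinction_model: risk.ExtinctionModel = risk.IUCN50

    def __post_init__(self) -> None:
        if not 0 < self.top_species_fraction <= 1:
            raise ValueError("top_species_fraction must be in (0, 1]")
        if not 0 < self.hotspot_fraction < 1:
            raise ValueError("hotspot_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("extinction_model"), Mapping):
            raw["extinction_model"] = risk.ExtinctionModel.from_dict(
                raw["extinction_model"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extinction_model"] = self.extinction_model.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def grid(self) -> spatial.EqualAreaGrid:
        return spatial.build_reference_grid(
            self.cell_size_km, self.standard_parallel, self.lat_max, self.lat_min
        )


def _provenance_line(cfg: RunConfig, n_trees: int | None) -> str:
    return (
        f"# provenance: config={cfg.config_hash()} seed={cfg.seed} "
        f"n_trees={n_trees if n_trees is not None else 'NA'}"
    )


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                 n_trees: int | None, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(cfg, n_trees) + "\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


class _OutputSet:
    """Tracks files written by a stage; removes them if the stage fails."""

    def __init__(self) -> None:
        self.paths: list[Path] = []

    def add(self, path: Path) -> Path:
        self.paths.append(path)
        return path

    def rollback(self) -> None:
        for p in self.paths:
            p.unlink(missing_ok=True)


def _load_ensemble(cfg: RunConfig) -> phylo.TreeEnsemble:
    if cfg.trees is None:
        raise ValueError("no tree ensemble path configured")
    ens = phylo.read_newick(cfg.trees)
    if cfg.n_trees is not None and cfg.n_trees < len(ens):
        ens = phylo.sample_trees(ens, cfg.n_trees, cfg.seed)
    return ens


def _load_risk(cfg: RunConfig) -> pd.DataFrame:
    if cfg.species is None:
        raise ValueError("no species table path configured")
    table = risk.read_species_table(cfg.species)
    table = risk.impute_dd(table)
    return risk.assign_probabilities(table, cfg.extinction_model)


def _median_species_scores(
    ensemble: phylo.TreeEnsemble, risk_table: pd.DataFrame
) -> pd.DataFrame:
    """ED/EDGE/HEDGE/LEDGE species medians over a tree ensemble.

    HEDGE and LEDGE are computed per tree and median-aggregated; EDGE is
    applied once to the median ED because the GE weight is tree-independent.
    """
    p = risk_table.set_index("species")["p_ext"]
    ed = sp.median_over_trees(ensemble, sp.evolutionary_distinctiveness)
    hedge = sp.median_over_trees(ensemble, sp.hedge_scores, p)
    ledge = sp.median_over_trees(ensemble, sp.ledge_scores, p)
    ge = risk_table.set_index("species")["category"].map(risk.ge_weight)
    ge = ge.reindex(ed.index)
    edge = pd.Series(
        sp.edge_score(ed.to_numpy(), ge.to_numpy()), index=ed.index, name="EDGE"
    )
    out = pd.DataFrame({"ED": ed, "EDGE": edge, "HEDGE": hedge, "LEDGE": ledge})
    out.index.name = "species"
    return out


def _dense_ranks(scores: pd.Series) -> pd.Series:
    """1-based ranks, 1 = highest score; ties broken by label (ascending)."""
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        {label: r for r, (label, _) in enumerate(order, start=1)},
        name=f"rank_{scores.name}",
    ).reindex(scores.index)


def run_species_analysis(cfg: RunConfig) -> dict:
    """Species scores, ranks, TOP-fraction sets and score correlations."""
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = _OutputSet()
    try:
        ensemble = _load_ensemble(cfg)
        risk_table = _load_risk(cfg)
        missing = set(ensemble.labels) - set(risk_table["species"])
        if missing:
            raise KeyError(f"species on trees but absent from table: {sorted(missing)}")
        risk_table = risk_table[risk_table["species"].isin(ensemble.labels)]
        scores = _median_species_scores(ensemble, risk_table)

        table = scores.copy()
        tops: dict[str, set] = {}
        for name in SPECIES_SCORES:
            table[f"rank_{name}"] = _dense_ranks(scores[name])
            tops[name] = sp.top_fraction(scores[name], cfg.top_species_fraction)
            table[f"top_{name}"] = table.index.isin(tops[name])
        table = table.sort_index()

        corr = pd.DataFrame(
            [
                [sp.rank_correlation(scores[a], scores[b]) for b in SPECIES_SCORES]
                for a in SPECIES_SCORES
            ],
            index=list(SPECIES_SCORES),
            columns=list(SPECIES_SCORES),
        )
        overlaps = {
            f"{a}_vs_{b}": sp.set_overlap(tops[a], tops[b])
            for a in SPECIES_SCORES
            for b in SPECIES_SCORES
            if a < b
        }
        summary = {
            "n_species": int(len(table)),
            "n_trees": len(ensemble),
            "top_fraction": cfg.top_species_fraction,
            "top_set_size": len(tops["HEDGE"]),
            "spearman": {
                f"{a}_vs_{b}": float(corr.loc[a, b])
                for a in SPECIES_SCORES
                for b in SPECIES_SCORES
                if a < b
            },
            "top_set_overlap_percent": overlaps,
            "provenance": {
                "config": cfg.config_hash(),
                "seed": cfg.seed,
                "n_trees": len(ensemble),
            },
        }
        _write_table(table, outputs.add(outdir / "species_scores.csv"), cfg,
                     len(ensemble))
        _write_table(corr, outputs.add(outdir / "species_score_correlations.csv"),
                     cfg, len(ensemble))
        _write_json(summary, outputs.add(outdir / "species_summary.json"))
    except Exception:
        outputs.rollback()
        raise
    return {"scores": table, "correlations": corr, "tops": tops, "summary": summary}


def _median_cell_scores(
    ensemble: phylo.TreeEnsemble,
    pm: spatial.PresenceMatrix,
    risk_table: pd.DataFrame,
    tops: Mapping[str, set],
) -> pd.DataFrame:
    """All twelve cell scores, phylogeny-based ones median-aggregated."""
    p = risk_table.set_index("species")["p_ext"]
    base = spatial.species_cell_scores(pm, risk_table)
    base["TOP_HEDGE"] = spatial.top_set_richness(
        pm, tops["HEDGE"] & set(pm.species)
    )["TOP"]
    base["TOP_LEDGE"] = spatial.top_set_richness(
        pm, tops["LEDGE"] & set(pm.species)
    )["TOP"]

    per_tree: dict[str, list[pd.Series]] = {
        k: [] for k in ("PD", "TPD", "RPD", "PWR", "GexpPD", "LexpPD")
    }
    for tree in ensemble:
        pdt = spatial.pd_cell_scores(pm, tree, risk_table)
        for k in ("PD", "TPD", "RPD"):
            per_tree[k].append(pdt[k])
        per_tree["PWR"].append(spatial.phylogenetic_endemism(pm, tree)["PWR"])
        per_tree["GexpPD"].append(spatial.gexp_pd(pm, tree, p)["GexpPD"])
        per_tree["LexpPD"].append(spatial.lexp_pd(pm, tree, p)["LexpPD"])
    for k, cols in per_tree.items():
        base[k] = pd.concat(cols, axis=1).median(axis=1)
    return base[list(CELL_SCORES)]


def run_spatial_analysis(cfg: RunConfig) -> dict:
    """Cell scores, proportion maps, hotspot sets and their comparisons."""
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = _OutputSet()
    try:
        ensemble = _load_ensemble(cfg)
        risk_table = _load_risk(cfg)
        grid = cfg.grid()
        if cfg.presence is None:
            raise ValueError("no presence path configured")
        pm = spatial.read_presence_csv(cfg.presence, grid,
                                       species=list(ensemble.labels))
        if pm.matrix.nnz == 0:
            raise ValueError("presence matrix is empty: nothing to analyse")
        risk_table = risk_table[risk_table["species"].isin(pm.species)]

        scores = _median_species_scores(ensemble, risk_table)
        tops = {
            name: sp.top_fraction(scores[name], cfg.top_species_fraction)
            for name in ("HEDGE", "LEDGE")
        }
        cells = _median_cell_scores(ensemble, pm, risk_table, tops)

        proportions = pd.DataFrame(index=cells.index)
        for num, den in (
            ("TSR", "SR"), ("RSR", "SR"), ("SWR", "SR"),
            ("TPD", "PD"), ("RPD", "PD"), ("PWR", "PD"),
            ("TOP_HEDGE", "SR"), ("TOP_LEDGE", "SR"),
        ):
            proportions[f"{num}_over_{den}"] = spatial.proportion_map(
                cells[num], cells[den]
            )

        hotspot_sets = {
            name: spatial.hotspots(cells[name], cfg.hotspot_fraction)
            for name in CELL_SCORES
        }
        masks = pd.DataFrame(
            {
                name: cells.index.isin(sorted(cell_set))
                for name, cell_set in hotspot_sets.items()
            },
            index=cells.index,
        )
        corr = pd.DataFrame(
            [
                [sp.rank_correlation(cells[a], cells[b]) for b in CELL_SCORES]
                for a in CELL_SCORES
            ],
            index=list(CELL_SCORES),
            columns=list(CELL_SCORES),
        )
        overlaps = {
            f"{a}_vs_{b}": sp.set_overlap(hotspot_sets[a], hotspot_sets[b])
            for a in CELL_SCORES
            for b in CELL_SCORES
            if a < b and hotspot_sets[a] and hotspot_sets[b]
        }
        summary = {
            "n_cells": int(grid.n_cells),
            "n_occupied_cells": int(len(pm.occupied_cells())),
            "hotspot_fraction": cfg.hotspot_fraction,
            "hotspot_size": len(hotspot_sets["GexpPD"]),
            "hotspot_overlap_percent": overlaps,
            "provenance": {
                "config": cfg.config_hash(),
                "seed": cfg.seed,
                "n_trees": len(ensemble),
            },
        }
        _write_table(cells, outputs.add(outdir / "cell_scores.csv"), cfg,
                     len(ensemble))
        _write_table(proportions, outputs.add(outdir / "cell_proportions.csv"),
                     cfg, len(ensemble))
        _write_table(masks, outputs.add(outdir / "hotspot_masks.csv"), cfg,
                     len(ensemble))
        _write_table(corr, outputs.add(outdir / "cell_score_correlations.csv"),
                     cfg, len(ensemble))
        _write_json(summary, outputs.add(outdir / "spatial_summary.json"))
    except Exception:
        outputs.rollback()
        raise
    return {
        "cells": cells,
        "proportions": proportions,
        "hotspots": hotspot_sets,
        "correlations": corr,
        "summary": summary,
    }


def read_coverage_csv(path: str | Path, grid: spatial.EqualAreaGrid) -> protection.CoverageGrid:
    df = pd.read_csv(path, comment="#")
    if not {"cell_id", "percent"} <= set(df.columns):
        raise ValueError("coverage CSV must have columns cell_id,percent")
    percent = np.zeros(grid.n_cells)
    if len(df):
        percent[df["cell_id"].to_numpy(dtype=np.int64)] = df["percent"].to_numpy(
            dtype=float
        )
    return protection.CoverageGrid(grid=grid, percent=percent)


def write_coverage_csv(cov: protection.CoverageGrid, path: str | Path) -> None:
    nz = np.flatnonzero(cov.percent > 0)
    pd.DataFrame({"cell_id": nz, "percent": cov.percent[nz]}).to_csv(
        path, index=False
    )


def run_protection_analysis(
    cfg: RunConfig, hotspot_masks: pd.DataFrame | None = None
) -> dict:
    """Protection overlay for every hotspot score set.

    ``hotspot_masks`` defaults to the ``hotspot_masks.csv`` written by the
    spatial stage into ``cfg.out``.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = _OutputSet()
    try:
        grid = cfg.grid()
        if cfg.coverage is None:
            raise ValueError("no coverage path configured")
        coverage = read_coverage_csv(cfg.coverage, grid)
        if hotspot_masks is None:
            masks_path = outdir / "hotspot_masks.csv"
            if not masks_path.exists():
                raise FileNotFoundError(
                    f"{masks_path} not found: run the spatial analysis first"
                )
            hotspot_masks = pd.read_csv(masks_path, comment="#", index_col=0)

        summaries = {}
        rows = []
        for name in hotspot_masks.columns:
            cells = hotspot_masks.index[hotspot_masks[name].astype(bool)]
            if len(cells) == 0:
                continue
            s = protection.overlay_summary(coverage, cells, cfg.heavy_threshold)
            summaries[name] = s
            cls = s.classification.rename("class").reset_index()
            cls.insert(0, "score", name)
            rows.append(cls)
        if not summaries:
            raise ValueError("no non-empty hotspot sets to overlay")
        classification = pd.concat(rows, ignore_index=True)
        summary = {
            "heavy_threshold": cfg.heavy_threshold,
            "overlays": {k: v.to_dict() for k, v in summaries.items()},
            "provenance": {"config": cfg.config_hash(), "seed": cfg.seed},
        }
        _write_table(classification,
                     outputs.add(outdir / "hotspot_protection_classes.csv"),
                     cfg, None, index=False)
        _write_json(summary, outputs.add(outdir / "protection_summary.json"))
    except Exception:
        outputs.rollback()
        raise
    return {"summaries": summaries, "classification": classification,
            "summary": summary}


def compare_runs(
    dir_a: str | Path,
    dir_b: str | Path,
    fraction: float = 0.25,
    out: str | Path | None = None,
) -> dict:
    """Compare two species-score runs (e.g. two source phylogenies).

    Reports, per score, the Spearman correlation across runs and the
    percent overlap of the TOP-fraction sets, computed on the species
    common to both runs (with a logged warning if the runs differ).
    """
    a = pd.read_csv(Path(dir_a) / "species_scores.csv", comment="#",
                    index_col="species")
    b = pd.read_csv(Path(dir_b) / "species_scores.csv", comment="#",
                    index_col="species")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("runs share no species")
    if len(shared) < len(a.index) or len(shared) < len(b.index):
        logger.warning(
            "runs cover different species; comparing on the %d shared "
            "(%.1f%% of run A, %.1f%% of run B)",
            len(shared),
            100 * len(shared) / len(a.index),
            100 * len(shared) / len(b.index),
        )
    report: dict = {
        "n_shared": int(len(shared)),
        "coverage_a_percent": 100.0 * len(shared) / len(a.index),
        "coverage_b_percent": 100.0 * len(shared) / len(b.index),
        "spearman": {},
        "top_set_overlap_percent": {},
    }
    for name in SPECIES_SCORES:
        if name not in a.columns or name not in b.columns:
            continue
        sa, sb = a.loc[shared, name], b.loc[shared, name]
        report["spearman"][name] = sp.rank_correlation(sa, sb)
        top_a = sp.top_fraction(sa, fraction)
        top_b = sp.top_fraction(sb, fraction)
        if top_a:
            report["top_set_overlap_percent"][name] = sp.set_overlap(top_a, top_b)
    if out is not None:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        _write_json(report, Path(out))
    return report


def run_simulation(
    synth_cfg: synth.SynthConfig,
    cfg: RunConfig,
    n_trees: int = 10,
) -> dict:
    """Generate the four synthetic inputs and write them into ``cfg.out``.

    Writes ``trees.nwk``, ``species.csv`` (categories plus occupied-cell
    range sizes), ``presence.csv`` and ``coverage.csv`` in the same
    formats the analysis stages read, so synthetic runs are
    indistinguishable from real-data runs.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = cfg.grid()
    ensemble = synth.simulate_trees(synth_cfg, n_trees)
    statuses = synth.simulate_statuses(synth_cfg)
    pm = synth.simulate_ranges(synth_cfg, grid)
    coverage = synth.simulate_protection(synth_cfg, grid)

    species = statuses.copy()
    species["range_size"] = spatial.range_sizes(pm).reindex(
        species["species"]
    ).to_numpy()

    phylo.write_newick(ensemble, outdir / "trees.nwk")
    risk.write_species_table(species, outdir / "species.csv")
    spatial.write_presence_csv(pm, outdir / "presence.csv")
    write_coverage_csv(coverage, outdir / "coverage.csv")
    return {
        "ensemble": ensemble,
        "species": species,
        "presence": pm,
        "coverage": coverage,
        "paths": {
            "trees": str(outdir / "trees.nwk"),
            "species": str(outdir / "species.csv"),
            "presence": str(outdir / "presence.csv"),
            "coverage": str(outdir / "coverage.csv"),
        },
    }
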