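"""Red List categories, extinction-probability models and DD imputation.

Categories follow the IUCN Red List vocabulary restricted to extant
species: LC, NT, VU, EN, CR, plus DD (data deficient).  DD species carry
no usable risk information and must be imputed to a concrete category
before any scoring; Extinct / Extinct-in-the-Wild are out of vocabulary
and rejected on input.

The extinction-probability model maps each category to the probability
that a species in it goes extinct within a fixed time horizon.  The
shipped default, ``IUCN50``, is the standard 50-year transformation of
the Red List criteria thresholds (extrapolating the CR/EN/VU probability
criteria to a common 50-year horizon):

    LC 0.0009, NT 0.0071, VU 0.0513, EN 0.4276, CR 0.9688

The mapping is a named, editable configuration entry — any strictly
increasing LC..CR table on [0, 1] is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SCORED_CATEGORIES",
    "THREATENED",
    "ExtinctionModel",
    "IUCN50",
    "ge_weight",
    "is_threatened",
    "extinction_probability",
    "impute_dd",
    "assign_probabilities",
    "read_species_table",
    "write_species_table",
]

SCORED_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")
CATEGORIES = SCORED_CATEGORIES + ("DD",)
THREATENED = frozenset({"VU", "EN", "CR"})

_GE = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}


def ge_weight(category: str) -> int:
    """Red List endangerment weight GE: LC=0, NT=1, VU=2, EN=3, CR=4."""
    if category == "DD":
        raise ValueError("DD has no GE weight: impute first")
    try:
        return _GE[category]
    except KeyError:
        raise ValueError(f"unknown Red List category {category!r}") from None


def is_threatened(category: str) -> bool:
    """True for the threatened categories VU, EN and CR."""
    if category == "DD":
        raise ValueError("DD has no threat status: impute first")
    if category not in _GE:
        raise ValueError(f"unknown Red List category {category!r}")
    return category in THREATENED


@dataclass(frozen=True)
class ExtinctionModel:
    """Category -> extinction probability over a fixed horizon.

    Probabilities must be strictly increasing from LC to CR and lie in
    [0, 1].
    """

    horizon_years: float
    prob_by_category: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [c for c in SCORED_CATEGORIES if c not in self.prob_by_category]
        if missing:
            raise ValueError(f"model missing categories: {missing}")
        probs = [self.prob_by_category[c] for c in SCORED_CATEGORIES]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("extinction probabilities must be in [0, 1]")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError(
                "extinction probabilities must increase strictly LC < NT < VU < EN < CR"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExtinctionModel":
        return cls(
            horizon_years=float(d.get("horizon_years", 50)),
            prob_by_category=dict(d["prob_by_category"]),
            name=str(d.get("name", "custom")),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon_years": self.horizon_years,
            "prob_by_category": dict(self.prob_by_category),
        }


#: 50-year Red List transformation (criteria thresholds projected to 50 yr).
IUCN50 = ExtinctionModel(
    horizon_years=50,
    prob_by_category={
        "LC": 0.0009,
        "NT": 0.0071,
        "VU": 0.0513,
        "EN": 0.4276,
        "CR": 0.9688,
    },
    name="IUCN50",
)


def extinction_probability(category: str, model: ExtinctionModel) -> float:
    if category == "DD":
        raise ValueError("DD has no extinction probability: impute first")
    try:
        return float(model.prob_by_category[category])
    except KeyError:
        raise ValueError(
            f"category {category!r} absent from model {model.name!r}"
        ) from None


# ---------------------------------------------------------------------------
# Species risk tables
# ---------------------------------------------------------------------------

#: severity order used by the default imputation rule (most severe first)
_SEVERITY = ("CR", "EN", "VU", "NT", "LC")


def read_species_table(path: str | Path) -> pd.DataFrame:
    """Read a ``species,category,range_size`` CSV/TSV into a risk table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"species", "category", "range_size"}
    if not required <= set(df.columns):
        raise ValueError(f"species table must have columns {sorted(required)}")
    return validate_species_table(df)


def validate_species_table(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(
            f"out-of-vocabulary Red List categories {sorted(bad)}; "
            "only extant-species categories LC/NT/VU/EN/CR/DD are accepted"
        )
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species labels: {dups}")
    if (df["range_size"] < 0).any():
        raise ValueError("range sizes must be >= 0")
    return df.reset_index(drop=True)


def write_species_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _quantile_match_rule(
    dd_ranges: np.ndarray, known_categories: np.ndarray, known_ranges: np.ndarray
) -> np.ndarray:
    """Default imputation: quantile-matching on log range size.

    The known (non-DD) species define both a log-range-size distribution
    and a category composition.  A DD species at range-size quantile ``u``
    (small ranges = low ``u``) is assigned the category occupying that
    quantile of the composition ordered from most severe (CR, smallest
    ranges) to least severe (LC), encoding the assumption that threat
    decreases with range size.
    """
    log_known = np.log1p(known_ranges.astype(float))
    n = len(log_known)
    freq = {c: float(np.mean(known_categories == c)) for c in _SEVERITY}
    edges = np.cumsum([freq[c] for c in _SEVERITY])
    out = []
    for r in dd_ranges:
        lr = math.log1p(float(r))
        less = float(np.sum(log_known < lr))
        equal = float(np.sum(log_known == lr))
        u = (less + 0.5 * equal) / n
        k = int(np.searchsorted(edges, u, side="right"))
        out.append(_SEVERITY[min(k, len(_SEVERITY) - 1)])
    return np.asarray(out, dtype=object)


def impute_dd(
    table: pd.DataFrame,
    rule: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Replace every DD category with a concrete one, from range size alone.

    ``rule(dd_ranges, known_categories, known_ranges)`` returns one
    category per DD species; the default is quantile-matching on log
    range size (see :func:`_quantile_match_rule`).  Non-DD rows are
    returned unchanged; the operation is idempotent.
    """
    table = validate_species_table(table)
    dd_mask = table["category"] == "DD"
    if not dd_mask.any():
        return table.copy()
    known = table.loc[~dd_mask]
    if known.empty:
        raise ValueError("cannot impute: every species is DD (nothing to calibrate on)")
    rule = rule or _quantile_match_rule
    imputed = rule(
        table.loc[dd_mask, "range_size"].to_numpy(),
        known["category"].to_numpy(),
        known["range_size"].to_numpy(),
    )
    out = table.copy()
    out.loc[dd_mask, "category"] = imputed
    if (out["category"] == "DD").any():
        raise ValueError("imputation rule left DD categories in the table")
    return out


def assign_probabilities(
    table: pd.DataFrame, model: ExtinctionModel = IUCN50
) -> pd.DataFrame:
    """Add/overwrite the ``p_ext`` column from the active extinction model."""
    if (table["category"] == "DD").any():
        raise ValueError("impute DD categories before assigning probabilities")
    out = table.copy()
    out["p_ext"] = [extinction_probability(c, model) for c in out["category"]]
    return out
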