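"""Yield-component arithmetic and treatment comparisons for cottonseed.

Cottonseed yield decomposes into boll density (bolls ha^-1), seeds per boll
and single-seed weight (carried as g per 100 seeds, the field convention).
Oil and protein yields follow by partitioning: seed yield x embryo fraction
(embryo dry weight / seed weight) x embryo oil or protein content.

Treatment contrasts between conventional management (CM) and an integrated
management strategy (IMS) are reported with two denominators, which are *not*
interchangeable:

* increase over CM  = 100 (IMS - CM) / CM
* changing amplitude = 100 (IMS - CM) / IMS

Both are always computed side by side; values are kept at full precision
internally and rounded half-away-from-zero only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

#: Kjeldahl nitrogen-to-protein conversion factor.
N_TO_PROTEIN_FACTOR = 6.25

__all__ = [
    "N_TO_PROTEIN_FACTOR",
    "PlotHarvest",
    "SeedComposition",
    "TreatmentComparison",
    "cottonseed_yield",
    "reserve_yields",
    "n_to_protein",
    "compare_treatments",
    "treatment_means",
    "round_half_away",
]


@dataclass(frozen=True)
class PlotHarvest:
    """Yield components measured on one plot."""

    boll_density: float  # bolls per hectare
    seeds_per_boll: float
    seed_weight_100: float  # g per 100 seeds

    def __post_init__(self):
        for name in ("boll_density", "seeds_per_boll", "seed_weight_100"):
            v = getattr(self, name)
            if not (v > 0) or not np.isfinite(v):
                raise InvalidInputError(f"{name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class SeedComposition:
    """Embryo fraction of seed weight and embryo oil/protein mass fractions."""

    embryo_fraction: float
    oil_content: float
    protein_content: float

    def __post_init__(self):
        for name in ("embryo_fraction", "oil_content", "protein_content"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidInputError(f"{name} must lie in (0, 1), got {v!r}")
        if self.oil_content + self.protein_content >= 1.0:
            raise InvalidInputError("oil_content + protein_content must be < 1")


@dataclass(frozen=True)
class TreatmentComparison:
    """CM-vs-IMS contrast under both denominator conventions (percent)."""

    cm_value: float
    ims_value: float
    increase_over_cm: float  # 100 (ims - cm) / cm
    changing_amplitude: float  # 100 (ims - cm) / ims


def cottonseed_yield(harvest: PlotHarvest) -> float:
    """Cottonseed yield in kg ha^-1 from the three yield components."""
    grams_per_seed = harvest.seed_weight_100 / 100.0
    return harvest.boll_density * harvest.seeds_per_boll * grams_per_seed / 1000.0


def reserve_yields(seed_yield: float, comp: SeedComposition) -> dict[str, float]:
    """Oil and protein yields (kg ha^-1) from seed yield and embryo composition."""
    if not (seed_yield > 0) or not np.isfinite(seed_yield):
        raise InvalidInputError(f"seed_yield must be positive, got {seed_yield!r}")
    base = seed_yield * comp.embryo_fraction
    return {
        "oil_yield": base * comp.oil_content,
        "protein_yield": base * comp.protein_content,
    }


def n_to_protein(n_fraction: float) -> float:
    """Convert a nitrogen mass fraction to a protein mass fraction (factor 6.25)."""
    if not (0.0 <= n_fraction <= 0.16):
        raise InvalidInputError(
            f"n_fraction must lie in [0, 0.16] so protein <= 1, got {n_fraction!r}"
        )
    return N_TO_PROTEIN_FACTOR * n_fraction


def compare_treatments(cm: float, ims: float) -> TreatmentComparison:
    """Contrast an IMS value against the CM baseline under both conventions."""
    if not (cm > 0) or not (ims > 0):
        raise InvalidInputError("cm and ims values must be positive")
    return TreatmentComparison(
        cm_value=cm,
        ims_value=ims,
        increase_over_cm=100.0 * (ims - cm) / cm,
        changing_amplitude=100.0 * (ims - cm) / ims,
    )


def treatment_means(
    table: pd.DataFrame,
    by: Iterable[str],
    value_cols: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Unweighted arithmetic means of value columns per factor combination.

    Every combination of the observed factor levels must be populated (a fully
    crossed table); an empty cell is an error naming the missing combination.
    The output carries an ``n`` column with the cell count.
    """
    by = list(by)
    if not by:
        raise InvalidInputError("at least one grouping column is required")
    missing_cols = set(by) - set(table.columns)
    if missing_cols:
        raise InvalidInputError(f"grouping columns not in table: {sorted(missing_cols)}")
    if value_cols is None:
        value_cols = [
            c
            for c in table.columns
            if c not in by and pd.api.types.is_numeric_dtype(table[c])
        ]
    value_cols = list(value_cols)
    if table.empty:
        raise InvalidInputError("cannot average an empty table")

    grouped = table.groupby(by, sort=True)
    levels = [sorted(table[c].unique().tolist()) for c in by]
    expected = int(np.prod([len(lv) for lv in levels]))
    if grouped.ngroups != expected:
        observed = set(grouped.groups.keys())
        for combo in pd.MultiIndex.from_product(levels, names=by):
            key = combo if len(by) > 1 else combo[0]
            if key not in observed:
                raise InvalidInputError(
                    f"empty cell for combination {dict(zip(by, np.atleast_1d(combo)))}"
                )
    out = grouped[value_cols].mean().reset_index()
    out["n"] = grouped.size().to_numpy()
    return out


def round_half_away(x: float, decimals: int = 2) -> float:
    """Presentation rounding: half-away-from-zero at the given decimals."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)
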