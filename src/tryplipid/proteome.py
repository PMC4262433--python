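"""Two-genotype label-free proteome comparison.

Given per-protein mean normalized abundances for wild type and a
knockout, the pipeline keeps proteins quantified by at least two
peptides, forms WT/KO ratios (with a floor on the denominator so an
ablated protein's residual noise-floor signal yields a finite ratio),
classifies each protein against the 2-fold bands of the abundance
scatter, and checks that the proteome is unchanged apart from the
knocked-out gene product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_quantifiable",
    "abundance_ratio",
    "classify_two_fold",
    "unchanged_proteome_check",
    "ProteomeCheck",
]

_REQUIRED = {"protein_id", "abundance_wt", "abundance_ko", "peptides"}


def _validate(table: pd.DataFrame) -> None:
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ValueError(f"proteome table missing columns: {sorted(missing)}")
    if len(table) and (
        (table["abundance_wt"] < 0).any() or (table["abundance_ko"] < 0).any()
    ):
        raise ValueError("abundances must be >= 0")
    if len(table) and (table["peptides"] < 1).any():
        raise ValueError("peptide counts must be >= 1")


def filter_quantifiable(
    table: pd.DataFrame, min_peptides: int = 2
) -> tuple[pd.DataFrame, int]:
    """Keep proteins quantified by at least ``min_peptides`` peptides.

    Returns the filtered table and the number of rows removed.
    Idempotent: re-filtering removes nothing.
    """
    _validate(table)
    keep = table["peptides"] >= min_peptides
    return table[keep].reset_index(drop=True), int((~keep).sum())


def abundance_ratio(table: pd.DataFrame, floor_fraction: float = 1e-3) -> pd.DataFrame:
    """WT/KO abundance ratio per protein with a denominator floor.

    The floor is ``floor_fraction`` times the median of all nonzero
    abundances (both genotypes pooled); KO abundances below it are
    raised to it, keeping ratios finite for ablated proteins while
    leaving ordinary proteins untouched.  Rows with zero abundance in
    both genotypes are flagged not-quantifiable (NaN ratio).  Adds
    columns ``ratio_wt_ko, log10_ratio, log10_wt, log10_ko, floored,
    quantifiable``.
    """
    _validate(table)
    out = table.copy()
    if len(out) == 0:
        for col in (
            "ratio_wt_ko",
            "log10_ratio",
            "log10_wt",
            "log10_ko",
            "floored",
            "quantifiable",
        ):
            out[col] = pd.Series(dtype=float)
        return out
    pooled = np.concatenate(
        [out["abundance_wt"].to_numpy(), out["abundance_ko"].to_numpy()]
    )
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        raise ValueError("no nonzero abundances in table")
    floor = floor_fraction * float(np.median(pooled))
    wt = out["abundance_wt"].to_numpy(dtype=float)
    ko = out["abundance_ko"].to_numpy(dtype=float)
    quantifiable = ~((wt == 0) & (ko == 0))
    ko_floored = np.maximum(ko, floor)
    ratio = np.where(quantifiable, wt / ko_floored, np.nan)
    with np.errstate(divide="ignore"):
        out["ratio_wt_ko"] = ratio
        out["log10_ratio"] = np.log10(ratio)
        out["log10_wt"] = np.log10(np.where(wt > 0, wt, np.nan))
        out["log10_ko"] = np.log10(ko_floored)
    out["floored"] = ko < floor
    out["quantifiable"] = quantifiable
    return out


def classify_two_fold(table: pd.DataFrame) -> pd.DataFrame:
    """Classify each ratio against the 2-fold bands (boundaries inclusive).

    ``within`` when 0.5 <= ratio <= 2, ``above`` when ratio > 2 (WT
    excess), ``below`` when ratio < 0.5.  Adds a ``two_fold_class``
    column; non-quantifiable rows get an empty class.
    """
    if "ratio_wt_ko" not in table.columns:
        table = abundance_ratio(table)
    out = table.copy()
    r = out["ratio_wt_ko"]
    out["two_fold_class"] = np.select(
        [r.isna(), r > 2.0, r < 0.5], ["", "above", "below"], default="within"
    )
    return out


@dataclass(frozen=True)
class ProteomeCheck:
    """Result of the unchanged-proteome check."""

    unchanged: bool
    offenders: tuple[str, ...]
    n_checked: int


def unchanged_proteome_check(
    table: pd.DataFrame, excluded_ids: set[str] | None = None
) -> ProteomeCheck:
    """Is every protein (bar the excluded ones) within the 2-fold band?

    The knocked-out protein is the natural exclusion; any other
    offender indicates an altered proteome and is listed.
    """
    excluded_ids = set(excluded_ids or ())
    classified = classify_two_fold(table)
    checked = classified[~classified["protein_id"].isin(excluded_ids)]
    offenders = tuple(
        checked.loc[checked["two_fold_class"] != "within", "protein_id"]
    )
    return ProteomeCheck(
        unchanged=len(offenders) == 0, offenders=offenders, n_checked=len(checked)
    )
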