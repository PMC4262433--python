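"""Specific-activity bookkeeping for subcellular fractionation.

Enrichment of an enzyme activity in a glycosome-enriched fraction over
the whole-cell extract (WCE) is the classic localization argument: a
genuine glycosomal marker (GPDH) enriches strongly, so an activity
that barely enriches cannot be predominantly glycosomal.  Only summary
statistics (mean +/- SEM of n experiments, mU/mg protein) are
available, so contrasts are ratios of means with independently
propagated relative errors, and "significantly different" is
operationalized as non-overlap of the mean +/- 2 SEM intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ActivityContrast", "enrichment_factor", "genotype_contrast", "glucose_contrast"]

_COLUMNS = {"genotype", "fraction", "glucose", "enzyme", "mean_mU_per_mg", "sem", "n"}


@dataclass(frozen=True)
class ActivityContrast:
    """Ratio of two specific activities with propagated error."""

    ratio: float
    relative_error: float  # sqrt of summed squared relative SEMs
    numerator: tuple[float, float]  # (mean, sem)
    denominator: tuple[float, float]
    indistinguishable: bool  # mean +/- 2 SEM intervals overlap

    @property
    def error(self) -> float:
        return self.ratio * self.relative_error


def _lookup(table: pd.DataFrame, **key: str) -> tuple[float, float]:
    if missing := _COLUMNS - set(table.columns):
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    mask = pd.Series(True, index=table.index)
    for col, val in key.items():
        mask &= table[col] == val
    rows = table[mask]
    if len(rows) != 1:
        raise KeyError(
            f"expected exactly one activity row for {key}, found {len(rows)}"
        )
    mean = float(rows["mean_mU_per_mg"].iloc[0])
    sem = float(rows["sem"].iloc[0])
    if mean <= 0 or sem < 0:
        raise ValueError(f"invalid activity summary for {key}: {mean} +/- {sem}")
    return mean, sem


def _contrast(num: tuple[float, float], den: tuple[float, float]) -> ActivityContrast:
    (m1, s1), (m2, s2) = num, den
    ratio = m1 / m2
    rel = math.sqrt((s1 / m1) ** 2 + (s2 / m2) ** 2)
    overlap = (m1 - 2 * s1) <= (m2 + 2 * s2) and (m2 - 2 * s2) <= (m1 + 2 * s1)
    return ActivityContrast(
        ratio=ratio,
        relative_error=rel,
        numerator=num,
        denominator=den,
        indistinguishable=overlap,
    )


def enrichment_factor(
    table: pd.DataFrame, enzyme: str, genotype: str, glucose: str
) -> ActivityContrast:
    """Glycosomal-fraction over whole-cell-extract activity ratio.

    A marker enzyme's factor calibrates the purification; a candidate
    activity enriching well below the marker is not glycosomal.
    """
    glyco = _lookup(table, enzyme=enzyme, genotype=genotype, glucose=glucose, fraction="glyco")
    wce = _lookup(table, enzyme=enzyme, genotype=genotype, glucose=glucose, fraction="WCE")
    return _contrast(glyco, wce)


def genotype_contrast(
    table: pd.DataFrame, enzyme: str, fraction: str, glucose: str
) -> ActivityContrast:
    """WT over KO activity ratio in one fraction and glucose condition."""
    wt = _lookup(table, enzyme=enzyme, fraction=fraction, glucose=glucose, genotype="WT")
    ko = _lookup(table, enzyme=enzyme, fraction=fraction, glucose=glucose, genotype="KO")
    return _contrast(wt, ko)


def glucose_contrast(
    table: pd.DataFrame, enzyme: str, genotype: str, fraction: str
) -> ActivityContrast:
    """+glucose over -glucose activity ratio for one genotype/fraction."""
    plus = _lookup(table, enzyme=enzyme, genotype=genotype, fraction=fraction, glucose="+gluc")
    minus = _lookup(table, enzyme=enzyme, genotype=genotype, fraction=fraction, glucose="-gluc")
    return _contrast(plus, minus)
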