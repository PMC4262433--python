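"""TAG species parsing, internal-standard normalization and class sums.

Shotgun lipidomics reports triacylglycerol (TAG) species either as
carbon:double-bond classes ("54:3" — 54 acyl carbons, 3 double bonds
summed over the three chains) or chain-resolved
("TAG17:0/17:0/17:0").  Intensities are made comparable across samples
by dividing every peak by the intensity of a spiked internal standard
(TAG 17:0/17:0/17:0, absent from the biological sample), after which
acyl isomers are summed into their C:D class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TagSpeciesKey",
    "parse_species_label",
    "normalize_to_standard",
    "aggregate_by_class",
    "compare_conditions",
    "LipidomeError",
]


class LipidomeError(ValueError):
    """Malformed lipidome table or species label."""


# unicode ratio colon U+2236 appears in typeset species names
_COLON = r"[:∶]"
_CHAIN = rf"(\d+){_COLON}(\d+)"
_CLASS_RE = re.compile(rf"^(?:TAG\s*)?{_CHAIN}$")
_CHAINS_RE = re.compile(rf"^(?:TAG\s*)?{_CHAIN}/{_CHAIN}/{_CHAIN}$")


@dataclass(frozen=True)
class TagSpeciesKey:
    """A TAG species identified by total acyl carbons and double bonds.

    ``chains`` is populated only when the label was chain-resolved; the
    chain sums then equal the totals by construction.
    """

    total_carbons: int
    total_double_bonds: int
    chains: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise LipidomeError("total_carbons must be > 0")
        if self.total_double_bonds < 0:
            raise LipidomeError("total_double_bonds must be >= 0")
        if self.chains is not None:
            c = sum(ch[0] for ch in self.chains)
            d = sum(ch[1] for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise LipidomeError(
                    f"chain sums {c}:{d} do not match totals "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )

    @property
    def class_label(self) -> str:
        """ASCII C:D class label, e.g. ``'54:3'``."""
        return f"{self.total_carbons}:{self.total_double_bonds}"


def parse_species_label(label: str) -> TagSpeciesKey:
    """Parse a TAG species label into a :class:`TagSpeciesKey`.

    Accepts the class form ``"54:3"`` and the chain-resolved form
    ``"17:0/17:0/17:0"``, with an optional ``TAG`` prefix and either
    the ASCII or the typographic ratio colon.

    >>> parse_species_label("54:3").class_label
    '54:3'
    >>> parse_species_label("TAG17:0/17:0/17:0").chains
    ((17, 0), (17, 0), (17, 0))
    """
    text = str(label).strip()
    m = _CHAINS_RE.match(text)
    if m:
        nums = [int(g) for g in m.groups()]
        chains = tuple((nums[i], nums[i + 1]) for i in range(0, 6, 2))
        return TagSpeciesKey(
            total_carbons=sum(c for c, _ in chains),
            total_double_bonds=sum(d for _, d in chains),
            chains=chains,
        )
    m = _CLASS_RE.match(text)
    if m:
        return TagSpeciesKey(int(m.group(1)), int(m.group(2)))
    raise LipidomeError(f"malformed TAG species label: {label!r}")


def _require_columns(table: pd.DataFrame, cols: set[str]) -> None:
    missing = cols - set(table.columns)
    if missing:
        raise LipidomeError(f"lipidome table missing columns: {sorted(missing)}")


def normalize_to_standard(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every intensity by the internal standard's intensity.

    The input needs columns ``species_label, intensity, is_standard``
    (``intensity`` may already be the normalized column of a previous
    call — normalization is idempotent).  Exactly one standard row is
    required.  Species rows at zero intensity are dropped (only
    detected species are reported); all remaining intensities must be
    positive.  Adds a ``normalized_intensity`` column; the standard's
    normalized intensity is 1 by construction.
    """
    _require_columns(table, {"species_label", "intensity", "is_standard"})
    table = table[(table["is_standard"] == 1) | (table["intensity"] != 0)].copy()
    std = table[table["is_standard"] == 1]
    if len(std) != 1:
        raise LipidomeError(
            f"exactly one internal-standard row required, found {len(std)}"
        )
    denom = float(std["intensity"].iloc[0])
    if denom <= 0:
        raise LipidomeError("internal standard intensity must be > 0")
    if (table["intensity"] <= 0).any():
        raise LipidomeError("species intensities must be > 0")
    out = table.copy()
    out["normalized_intensity"] = out["intensity"] / denom
    return out


def aggregate_by_class(table: pd.DataFrame) -> pd.DataFrame:
    """Sum normalized intensities of acyl isomers into C:D classes.

    Normalizes first if ``normalized_intensity`` is absent.  The
    standard is excluded; the class sums conserve the species total.
    Returns ``class_label, normalized_intensity`` sorted by intensity
    descending (label as tie-break for determinism).
    """
    if len(table) == 0:
        return pd.DataFrame(columns=["class_label", "normalized_intensity"])
    if "normalized_intensity" not in table.columns:
        table = normalize_to_standard(table)
    species = table[table["is_standard"] != 1].copy()
    species["class_label"] = [
        parse_species_label(lab).class_label for lab in species["species_label"]
    ]
    out = (
        species.groupby("class_label", as_index=False)["normalized_intensity"]
        .sum()
        .sort_values(
            ["normalized_intensity", "class_label"],
            ascending=[False, True],
            ignore_index=True,
        )
    )
    return out


def compare_conditions(fed: pd.DataFrame, unfed: pd.DataFrame) -> pd.DataFrame:
    """Per-class fed/unfed intensity ratios.

    Both inputs are lipidome tables (normalized internally).  Classes
    present in only one condition get a NaN ratio rather than a
    fabricated value.  Returns ``class_label, fed, unfed, ratio``
    sorted by fed intensity descending.
    """
    f = aggregate_by_class(fed).set_index("class_label")["normalized_intensity"]
    u = aggregate_by_class(unfed).set_index("class_label")["normalized_intensity"]
    merged = pd.DataFrame({"fed": f, "unfed": u})
    merged["ratio"] = np.where(
        merged["fed"].notna() & merged["unfed"].notna(),
        merged["fed"] / merged["unfed"],
        np.nan,
    )
    merged = merged.sort_values("fed", ascending=False, na_position="last")
    return merged.reset_index().rename(columns={"index": "class_label"})
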