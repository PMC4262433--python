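"""Delimited-text schemas shared by the generators and the pipeline.

All tables travel as comma-separated UTF-8 text with a header row and
"." decimals.  ``read_table``/``write_table`` validate the fixed column
schema by dataset name.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table"]

SCHEMAS: dict[str, list[str]] = {
    "ld_counts": ["cell_id", "condition", "count"],
    "flow": ["cell_id", "condition", "intensity"],
    "growth": ["time_h", "density_cells_per_ml"],
    "decay": ["time_h", "replicate", "signal"],
    "lipidome": ["species_label", "intensity", "is_standard"],
    "proteome": ["protein_id", "abundance_wt", "abundance_ko", "peptides", "confidence"],
    "activity": ["genotype", "fraction", "glucose", "enzyme", "mean_mU_per_mg", "sem", "n"],
    "tlc": ["condition", "replicate", "rf", "area"],
}


def _check(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{schema} table missing columns: {sorted(missing)}")
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read one of the package's CSV schemas, validating columns."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    return _check(pd.read_csv(path), schema)


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a schema table as CSV (columns ordered per schema first)."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    _check(df, schema)
    ordered = SCHEMAS[schema] + [c for c in df.columns if c not in SCHEMAS[schema]]
    df[ordered].to_csv(path, index=False)
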