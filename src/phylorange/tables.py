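"""Trait-table I/O and validation.

Species trait tables are plain pandas DataFrames indexed by species label;
this module only adds loading conventions (CSV/TSV, a configurable species
column) and a validator that enforces the package's schema expectations:
unique species, numeric trait columns, and species labels matchable to a
tree's tips after canonicalisation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .trees import PhyloTree, canonical_label

__all__ = ["load_trait_table", "validate_trait_table", "match_species"]


def load_trait_table(
    path: "str | Path",
    species_col: Optional[str] = None,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a delimited trait table and index it by species.

    The delimiter is inferred from the extension unless given; the species
    column defaults to the first column (or one literally named
    ``species``).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if species_col is None:
        species_col = "species" if "species" in df.columns else df.columns[0]
    if species_col not in df.columns:
        raise KeyError(f"species column {species_col!r} not found")
    df = df.set_index(species_col)
    df.index = df.index.astype(str)
    df.index.name = "species"
    return validate_trait_table(df)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema invariants; returns the (unmodified) table.

    Raises on duplicate species (after canonicalisation) and non-numeric
    trait columns.
    """
    canon = [canonical_label(str(s)) for s in df.index]
    if len(set(canon)) != len(canon):
        dupes = sorted({c for c in canon if canon.count(c) > 1})
        raise ValueError(f"duplicate species in trait table: {dupes}")
    bad = [c for c in df.columns
           if not pd.api.types.is_numeric_dtype(pd.to_numeric(df[c], errors="coerce"))
           or pd.to_numeric(df[c], errors="coerce").isna().all() and df[c].notna().any()]
    if bad:
        raise ValueError(f"non-numeric trait columns: {bad}")
    return df


def match_species(df: pd.DataFrame, tree: PhyloTree) -> tuple[list[str], list[str]]:
    """Split table species into (in_tree, not_in_tree) by canonical label."""
    tips = {canonical_label(t) for t in tree.tip_names}
    in_tree, missing = [], []
    for s in df.index:
        (in_tree if canonical_label(str(s)) in tips else missing).append(str(s))
    return in_tree, missing
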