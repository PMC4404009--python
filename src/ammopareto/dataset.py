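"""Genus-table input/output and validation.

The interchange format is a plain CSV with header columns
``genus, era, D, S, W, diameter_cm`` (``S`` and ``diameter_cm`` optional).
Rows violating the trait invariants (0 <= D < 1, W >= 1, S > 0, positive
diameter) are rejected individually with per-row diagnostics rather than
failing the whole file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MorphoDataset", "read_dataset", "write_dataset", "validate_rows"]

REQUIRED = ("D", "W")
OPTIONAL = ("S", "diameter_cm")


@dataclass(frozen=True)
class MorphoDataset:
    """A validated genus-level trait table."""

    table: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)
    diagnostics: tuple = ()

    @property
    def has_S(self) -> bool:
        return "S" in self.table.columns

    @property
    def has_diameter(self) -> bool:
        return "diameter_cm" in self.table.columns

    @property
    def eras(self) -> tuple:
        if "era" not in self.table.columns:
            return ()
        return tuple(pd.unique(self.table["era"]))

    def traits(self, with_S: bool | None = None) -> np.ndarray:
        """Trait matrix in (D, S, W) order (or (D, W) for 2-trait data)."""
        use_S = self.has_S if with_S is None else with_S
        cols = ["D", "S", "W"] if use_S else ["D", "W"]
        return self.table[cols].to_numpy(dtype=float)

    def by_era(self) -> dict:
        return {era: self.table[self.table["era"] == era] for era in self.eras}

    def __len__(self) -> int:
        return len(self.table)


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, tuple]:
    """Split a raw table into valid and rejected rows with diagnostics."""
    diags = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask & ~bad]:
            diags.append(f"row {i}: {reason}")
        bad[mask] = True

    flag(~df["D"].between(0, 1 - 1e-12), "D outside [0, 1)")
    flag(df["W"] < 1, "W below 1")
    if "S" in df.columns:
        flag(~(df["S"] > 0), "S not positive")
    if "diameter_cm" in df.columns:
        flag(df["diameter_cm"].notna() & ~(df["diameter_cm"] > 0),
             "diameter_cm not positive")
    for col in [c for c in ("D", "W", "S") if c in df.columns]:
        flag(df[col].isna(), f"missing {col}")
    if "genus" in df.columns:
        flag(df["genus"].duplicated(keep="first"), "duplicate genus id")
    return df[~bad].copy(), df[bad].copy(), tuple(diags)


def read_dataset(path: str | Path, require_S: bool = False) -> MorphoDataset:
    """Read and validate a genus CSV.

    Raises on missing required columns or an empty file; invalid rows are
    dropped and reported in ``dataset.diagnostics``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    needed = set(REQUIRED) | ({"S"} if require_S else set())
    missing = sorted(needed - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    good, rejected, diags = validate_rows(df)
    if good.empty:
        raise ValueError(f"{path}: no valid rows ({len(rejected)} rejected)")
    return MorphoDataset(table=good.reset_index(drop=True), rejected=rejected,
                         diagnostics=diags)


def write_dataset(table: pd.DataFrame | MorphoDataset, path: str | Path) -> Path:
    """Write a genus table to CSV (the single interchange format)."""
    df = table.table if isinstance(table, MorphoDataset) else table
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
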