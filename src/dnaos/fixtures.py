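"""Packaged reference tables of the 980-bp interferon alpha 17 study.

Three delimited-text tables ship with the package:

* ``table1.csv`` — CSNB counts per critical energy, gene part and pair
  class, plus the baseline open-state probability column P0 (x1e-5);
* ``table2.csv`` — part boundaries, lengths and A-T/G-C percentages;
* ``table3.csv`` — Maximum-range (nmax) counts with the P0 and Pimax
  columns (x1e-5).

The tables are transcriptions of published results, kept verbatim as
evidence (including the known internal inconsistencies of the source);
the P0/Pimax columns are data, not recomputed values.  Critical energies
are in units of 1e-22 N m on the 0.581-0.589 grid with step 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["FixtureTables", "load_tables", "part_class_sum"]

ECRH_GRID = tuple(round(0.581 + 0.001 * k, 3) for k in range(9))


def _read(name: str) -> pd.DataFrame:
    with resources.files("dnaos.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class FixtureTables:
    """The three packaged tables as tidy DataFrames."""

    table1: pd.DataFrame  # ecrh, p0e5, part, at, gc
    table2: pd.DataFrame  # part, start, end, length, at_pct, gc_pct
    table3: pd.DataFrame  # ecrh, p0e5, pimaxe5, part, at, gc

    def __post_init__(self):
        g1 = tuple(sorted(self.table1["ecrh"].unique()))
        g3 = tuple(sorted(self.table3["ecrh"].unique()))
        if g1 != ECRH_GRID or g3 != ECRH_GRID:
            raise ValueError("fixture energy grids must match 0.581..0.589 step 0.001")
        for t in (self.table1, self.table3):
            if (t[["at", "gc"]].to_numpy() < 0).any():
                raise ValueError("fixture counts must be non-negative")

    def gene_size(self) -> int:
        return int(self.table2["length"].sum())

    def part_lengths(self) -> pd.Series:
        return self.table2.set_index("part")["length"]

    def at_gc_ratio(self) -> pd.Series:
        """Per-part A-T/G-C percentage ratio, the composition covariate."""
        t2 = self.table2.set_index("part")
        return t2["at_pct"] / t2["gc_pct"]

    def p0(self) -> pd.Series:
        """Baseline P0 (x1e-5) per energy, from table 1."""
        return self.table1.groupby("ecrh")["p0e5"].first()


def load_tables() -> FixtureTables:
    """Load the packaged tables."""
    return FixtureTables(_read("table1.csv"), _read("table2.csv"), _read("table3.csv"))


def part_class_sum(
    table: pd.DataFrame,
    parts: "set[str] | tuple[str, ...]" = ("I", "II", "III"),
    classes: "set[str] | tuple[str, ...]" = ("at", "gc"),
    energies: tuple[float, float] = (0.581, 0.589),
) -> int:
    """Sum the selected count cells of a fixture table.

    ``energies`` is an inclusive (low, high) interval on the 1e-22 N m
    scale; ``classes`` selects the 'at' and/or 'gc' columns.
    """
    lo, hi = energies
    sel = table[(table["ecrh"] >= lo - 1e-9) & (table["ecrh"] <= hi + 1e-9)]
    sel = sel[sel["part"].isin(set(parts))]
    cols = [c for c in ("at", "gc") if c in {c.lower() for c in classes}]
    if sel.empty or not cols:
        raise ValueError("empty selection")
    return int(sel[cols].to_numpy().sum())
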