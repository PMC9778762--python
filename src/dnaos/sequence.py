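"""Gene sequences as ordered base pairs with a three-part partition.

A double-stranded gene is represented by its first-strand letters (5'->3');
the complementary strand is implied by Watson-Crick pairing.  The gene is
conventionally divided into three contiguous parts (I, II, III) by serial
nucleotide number; for the 980-bp case the parts are 1-327, 328-653 and
654-980.  Synthetic sequences with prescribed per-part A-T content can be
generated reproducibly from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
PART_LABELS = ("I", "II", "III")


def default_tripartition(n: int) -> tuple[tuple[int, int], ...]:
    """Three contiguous 1-based inclusive ranges covering 1..n.

    The middle part takes the deficit when n is not divisible by 3, so
    n=980 yields the conventional 327/326/327 split.
    """
    if n < 3:
        raise ValueError(f"need at least 3 base pairs to tripartition, got {n}")
    q, r = divmod(n, 3)
    sizes = [q + (1 if r >= 1 else 0), q, q + (1 if r == 2 else 0)]
    bounds = []
    start = 1
    for s in sizes:
        bounds.append((start, start + s - 1))
        start += s
    return tuple(bounds)


@dataclass(frozen=True)
class GeneSequence:
    """Ordered base pairs given by first-strand letters, with part bounds."""

    pairs: tuple[str, ...]
    part_bounds: tuple[tuple[int, int], ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        bad = set(self.pairs) - set("ACGT")
        if bad:
            raise ValueError(f"invalid character(s) in sequence: {sorted(bad)}")
        if not self.pairs:
            raise ValueError("empty sequence")
        if self.part_bounds is None:
            object.__setattr__(self, "part_bounds", default_tripartition(len(self.pairs)))
        bounds = self.part_bounds
        if len(bounds) != 3:
            raise ValueError("exactly three parts required")
        expect = 1
        for lo, hi in bounds:
            if lo != expect or hi < lo:
                raise ValueError(f"part bounds {bounds} are not contiguous over 1..{self.n}")
            expect = hi + 1
        if expect != self.n + 1:
            raise ValueError(f"part bounds {bounds} do not cover 1..{self.n}")

    @property
    def n(self) -> int:
        return len(self.pairs)

    def base(self, i: int, strand: int = 1) -> str:
        """Base letter at 1-based pair index ``i`` on strand 1 or 2."""
        if not 1 <= i <= self.n:
            raise IndexError(f"pair index {i} out of range 1..{self.n}")
        b = self.pairs[i - 1]
        return b if strand == 1 else COMPLEMENT[b]

    def part_of(self, i: int) -> str:
        """Part label {I, II, III} of the pair with serial number ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"pair index {i} out of range 1..{self.n}")
        for label, (lo, hi) in zip(PART_LABELS, self.part_bounds):
            if lo <= i <= hi:
                return label
        raise AssertionError("unreachable: bounds cover 1..n")

    def is_at(self, i: int) -> bool:
        """True if pair ``i`` is an A-T (or T-A) pair."""
        return self.base(i) in "AT"

    def pair_classes(self) -> np.ndarray:
        """Array of 'AT'/'GC' class labels, one per pair."""
        return np.array(["AT" if b in "AT" else "GC" for b in self.pairs])

    def part_labels(self) -> np.ndarray:
        """Array of part labels, one per pair."""
        out = np.empty(self.n, dtype=object)
        for label, (lo, hi) in zip(PART_LABELS, self.part_bounds):
            out[lo - 1 : hi] = label
        return out

    def pair_counts(self) -> pd.DataFrame:
        """A-T and G-C pair counts per part (rows I, II, III + 'gene')."""
        parts = self.part_labels()
        classes = self.pair_classes()
        rows = []
        for label in PART_LABELS:
            sel = parts == label
            rows.append(
                {
                    "part": label,
                    "length": int(sel.sum()),
                    "AT": int((classes[sel] == "AT").sum()),
                    "GC": int((classes[sel] == "GC").sum()),
                }
            )
        rows.append(
            {
                "part": "gene",
                "length": self.n,
                "AT": int((classes == "AT").sum()),
                "GC": int((classes == "GC").sum()),
            }
        )
        return pd.DataFrame(rows).set_index("part")

    def to_fasta(self, path: str | Path, name: str = "gene") -> None:
        record = SeqRecord(Seq("".join(self.pairs)), id=name, description="")
        SeqIO.write([record], str(path), "fasta")


def read_sequence(path: str | Path, format: str = "fasta") -> GeneSequence:
    """Read a gene from a FASTA or plain-text file of first-strand letters."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        letters = str(records[0].seq).upper()
    elif format == "plain":
        letters = "".join(path.read_text().split()).upper()
    else:
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'plain'")
    if not letters:
        raise ValueError("empty sequence")
    bad = set(letters) - set("ACGT")
    if bad:
        raise ValueError(f"invalid character(s) in sequence: {sorted(bad)}")
    return GeneSequence(tuple(letters))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class PartComposition:
    """Length and A-T content of one gene part (count or percent)."""

    length: int
    at_count: int | None = None
    at_fraction: float | None = None  # percent, 0..100

    def resolved_at_count(self) -> int:
        if self.at_count is not None:
            c = int(self.at_count)
        elif self.at_fraction is not None:
            if not 0.0 <= self.at_fraction <= 100.0:
                raise ValueError(f"A-T fraction {self.at_fraction} outside [0, 100]")
            c = _round_half_away(self.at_fraction / 100.0 * self.length)
        else:
            raise ValueError("part composition needs at_count or at_fraction")
        if not 0 <= c <= self.length:
            raise ValueError(f"A-T count {c} exceeds part length {self.length}")
        return c


@dataclass(frozen=True)
class CompositionSpec:
    """Per-part composition targets plus the generator seed."""

    parts: tuple[PartComposition, PartComposition, PartComposition]
    seed: int = 0

    @classmethod
    def ifna17_like(cls, seed: int = 0) -> "CompositionSpec":
        """Composition emulating the studied 980-bp interferon alpha 17 gene.

        Per-part A-T counts (163/186/236 over lengths 327/326/327) match the
        saturation counts of the studied gene's three parts; the percentages
        49.8/57.1/72.2 round to the same counts.
        """
        return cls(
            parts=(
                PartComposition(327, at_count=163),
                PartComposition(326, at_count=186),
                PartComposition(327, at_count=236),
            ),
            seed=seed,
        )


def synthesize_gene(spec: CompositionSpec) -> GeneSequence:
    """Generate a random gene whose parts have exactly the requested A-T counts.

    Pair positions within each part and the strand orientation of each pair
    (A-T vs T-A, G-C vs C-G) are drawn uniformly from a PCG64 stream seeded
    with ``spec.seed``; the same spec therefore always yields the same gene.
    """
    rng = np.random.default_rng(spec.seed)
    letters: list[str] = []
    bounds = []
    start = 1
    for part in spec.parts:
        n_at = part.resolved_at_count()
        is_at = np.zeros(part.length, dtype=bool)
        is_at[rng.choice(part.length, size=n_at, replace=False)] = True
        for at in is_at:
            if at:
                letters.append("A" if rng.random() < 0.5 else "T")
            else:
                letters.append("G" if rng.random() < 0.5 else "C")
        bounds.append((start, start + part.length - 1))
        start += part.length
    return GeneSequence(tuple(letters), tuple(bounds))
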