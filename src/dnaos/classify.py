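"""Modified Basov-Jimack classification of substitution sites.

Given the site-wise open-state probabilities P_i and the baseline P0 at one
critical energy, sites are classified into:

* range "Maximum" (nmax): sites whose P_i clears a branch-dependent high
  threshold.  With Pimax = max_i P_i and Pimin = min_i P_i, and provided
  Pimax > P0 >= Pimin >= 0:

    - branch 1, if Pimax - (1/10)(Pimax - Pimin) >= P0 + (1/2)(Pimax - P0):
      threshold = Pimax - (1/10)(Pimax - Pimin);
    - branch 2, otherwise: threshold = Pimax - (1/4)(Pimax - P0);

  membership is P_i >= threshold.  If Pimax <= P0 or P0 < Pimin the range
  is empty.

* range "Minimum" (CSNB, closed state of nitrogenous bases): sites with
  P_i = 0 exactly — the pair never opens during the simulated interval.

The new-approach weighting corrects the raw per-part CSNB count nx for the
gene-wide closure saturation: nCSNB = nx * (1 - ngCSNB/ng)^2, where ngCSNB
is the whole-gene CSNB count and ng the gene size.  Reported sums truncate
toward zero; continuous values are kept for correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import trunc

import numpy as np
import pandas as pd

from .parameters import ENERGY_UNIT
from .scan import OpenStateScanResult
from .sequence import GeneSequence, PART_LABELS

__all__ = [
    "MaximumRange",
    "maximum_range_count",
    "csnb_count",
    "weighted_csnb",
    "minimum_q2q4_range",
    "PartClassificationTable",
    "classify_scan",
]


@dataclass(frozen=True)
class MaximumRange:
    """Outcome of the Maximum-range rule at one critical energy."""

    threshold: float | None
    members: tuple[int, ...]  # 1-based site indices
    nmax: int
    branch: int  # 1 or 2; 0 when the range is empty


def maximum_range_count(P: np.ndarray, P0: float) -> MaximumRange:
    """Apply the branch-dependent Maximum-range rule to one energy column."""
    P = np.asarray(P, dtype=float)
    if P.size == 0:
        raise ValueError("empty probability vector")
    if (P < 0).any() or P0 < 0:
        raise ValueError("probabilities must be non-negative")
    Pimax = float(P.max())
    Pimin = float(P.min())
    if not (Pimax > P0 >= Pimin >= 0.0):
        return MaximumRange(threshold=None, members=(), nmax=0, branch=0)
    thr1 = Pimax - 0.1 * (Pimax - Pimin)
    if thr1 >= P0 + 0.5 * (Pimax - P0):
        threshold, branch = thr1, 1
    else:
        threshold, branch = Pimax - 0.25 * (Pimax - P0), 2
    members = tuple(int(i) + 1 for i in np.flatnonzero(P >= threshold))
    return MaximumRange(threshold=threshold, members=members, nmax=len(members), branch=branch)


def csnb_count(P: np.ndarray, gene: GeneSequence) -> pd.DataFrame:
    """Count sites with P_i = 0 per part and pair class.

    Exact zero is used: P_i is an arithmetic mean of non-negative fractions
    q_j and is zero iff no break was ever sampled, so no epsilon is needed.
    """
    P = np.asarray(P, dtype=float)
    if len(P) != gene.n:
        raise ValueError(f"P has length {len(P)}, gene has {gene.n} pairs")
    zero = P == 0.0
    parts = gene.part_labels()
    classes = gene.pair_classes()
    rows = []
    for label in PART_LABELS:
        sel = parts == label
        rows.append(
            {
                "part": label,
                "AT": int((zero & sel & (classes == "AT")).sum()),
                "GC": int((zero & sel & (classes == "GC")).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("part")


def weighted_csnb(nx: float, ngCSNB: float, ng: int, truncate: bool = False) -> float:
    """New-approach weighted CSNB count nx * (1 - ngCSNB/ng)^2.

    Returns 0 when ngCSNB = 0 (no closed state anywhere: the correction is
    defined only on the highest critical energy range, where at least one
    CSNB exists).  With ``truncate`` the value is truncated toward zero.
    """
    if nx < 0 or ngCSNB < 0 or ng <= 0:
        raise ValueError("counts must be non-negative and ng positive")
    if ngCSNB > ng:
        raise ValueError(f"whole-gene CSNB count {ngCSNB} exceeds gene size {ng}")
    if nx > ngCSNB:
        raise ValueError(f"part count {nx} exceeds whole-gene count {ngCSNB}")
    if ngCSNB == 0:
        return 0.0
    w = nx * (1.0 - ngCSNB / ng) ** 2
    return float(trunc(w)) if truncate else float(w)


def minimum_q2q4_range(P: np.ndarray, P0: float, Pimin: float | None = None) -> tuple[int, ...]:
    """Sites in the Q2-min..Q4-min range: P_i <= Pimin + (3/4)(P0 - Pimin).

    Meaningful in the sub-saturation regime where P0 > 0; with P0 = 0 it
    coincides with the CSNB rule.
    """
    P = np.asarray(P, dtype=float)
    if Pimin is None:
        Pimin = float(P.min())
    if P0 < Pimin:
        raise ValueError(f"P0={P0} below Pimin={Pimin}")
    threshold = Pimin + 0.75 * (P0 - Pimin)
    return tuple(int(i) + 1 for i in np.flatnonzero(P <= threshold))


@dataclass
class PartClassificationTable:
    """Per-energy, per-part, per-class nmax and CSNB counts with weights.

    ``table`` columns: ecrh (in 1e-22 N m), part, class ('AT'/'GC'),
    nmax, csnb, csnb_weighted (continuous).  All weighted values use the
    whole-gene CSNB count (all classes, all parts) in the damping factor
    (1 - ngCSNB/ng)^2; class-resolved rows share their part's factor.
    Truncation toward zero, when requested for reported sums, is applied
    to part totals, not per class.
    """

    table: pd.DataFrame
    gene_size: int

    def part_totals(self, column: str = "csnb") -> pd.DataFrame:
        """Sum a column over classes, energies as rows and parts as columns."""
        return self.table.pivot_table(
            index="ecrh", columns="part", values=column, aggfunc="sum"
        )

    def gene_csnb(self) -> pd.Series:
        """Whole-gene CSNB count per energy."""
        return self.table.groupby("ecrh")["csnb"].sum()

    def weighted_part_totals(self, truncate: bool = False) -> pd.DataFrame:
        """New-approach weighted CSNB per (energy, part), on part totals."""
        raw = self.part_totals("csnb")
        ngc = self.gene_csnb()
        out = raw.copy().astype(float)
        for e in raw.index:
            for p in raw.columns:
                out.loc[e, p] = weighted_csnb(
                    float(raw.loc[e, p]), float(ngc.loc[e]), self.gene_size, truncate
                )
        return out


def classify_scan(scan: OpenStateScanResult, gene: GeneSequence) -> PartClassificationTable:
    """Classify every energy column of a scan into nmax and CSNB counts."""
    if scan.n != gene.n:
        raise ValueError(f"scan has {scan.n} sites, gene has {gene.n} pairs")
    parts = gene.part_labels()
    classes = gene.pair_classes()
    rows = []
    for e_idx, e in enumerate(scan.energies):
        P = scan.P[:, e_idx]
        if np.isnan(P).any():
            raise ValueError("scan has unscanned sites (NaN); classify needs a full scan")
        P0 = float(scan.P0[e_idx])
        mx = maximum_range_count(P, P0)
        member_mask = np.zeros(gene.n, dtype=bool)
        for s in mx.members:
            member_mask[s - 1] = True
        csnb = csnb_count(P, gene)
        ng_csnb = int(csnb.to_numpy().sum())
        for label in PART_LABELS:
            sel = parts == label
            for cls in ("AT", "GC"):
                cls_sel = sel & (classes == cls)
                nx = int(csnb.loc[label, cls])
                rows.append(
                    {
                        "ecrh": e / ENERGY_UNIT,
                        "part": label,
                        "class": cls,
                        "nmax": int((member_mask & cls_sel).sum()),
                        "csnb": nx,
                        "csnb_weighted": weighted_csnb(nx, ng_csnb, gene.n),
                    }
                )
    return PartClassificationTable(table=pd.DataFrame(rows), gene_size=gene.n)
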