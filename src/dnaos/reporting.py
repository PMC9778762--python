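"""Derived summary statistics of the reference tables, and the pipeline driver.

Every printed comparison of the reference study is recomputed here from the
packaged tables: part-wise and class-wise count ratios, the new-approach
weighted CSNB sums, and the three Spearman correlations.  Values are kept
at full precision; ``printed`` rounds half away from zero to the quoted
number of decimals for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .classify import classify_scan, weighted_csnb
from .fixtures import ECRH_GRID, FixtureTables, load_tables, part_class_sum
from .parameters import ENERGY_UNIT, MechanicalParameterSet
from .scan import scan_substitutions
from .sequence import CompositionSpec, GeneSequence, read_sequence, synthesize_gene

__all__ = [
    "RatioReport",
    "weighted_part_sums",
    "ratio_report",
    "correlation_report",
    "run_pipeline",
]


def printed(value: float, decimals: int) -> float:
    """Round half away from zero at the given number of decimals."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(value) * q + 0.5) / q, value)


@dataclass
class RatioReport:
    """Named scalar results; division by zero yields the string 'undefined'."""

    values: dict[str, float | str] = field(default_factory=dict)

    def add(self, label: str, numerator: float, denominator: float, scale: float = 1.0):
        if label in self.values:
            raise ValueError(f"duplicate label {label}")
        if denominator == 0:
            self.values[label] = "undefined"
        else:
            self.values[label] = scale * numerator / denominator

    def set(self, label: str, value: float):
        if label in self.values:
            raise ValueError(f"duplicate label {label}")
        self.values[label] = float(value)

    def __getitem__(self, label: str):
        return self.values[label]


def weighted_part_sums(fix: FixtureTables, truncate: bool = True) -> pd.Series:
    """New-approach weighted CSNB sums per part over the whole energy grid.

    For each energy the part's total CSNB count (both classes) is weighted
    by (1 - ngCSNB/ng)^2 with the whole-gene count; truncation toward zero
    is applied per energy before summing (the reported convention).
    """
    ng = fix.gene_size()
    t1 = fix.table1
    sums = {p: 0.0 for p in ("I", "II", "III")}
    for e in ECRH_GRID:
        sel = t1[t1["ecrh"] == e]
        ngc = float(sel[["at", "gc"]].to_numpy().sum())
        for p in sums:
            nx = float(sel.loc[sel["part"] == p, ["at", "gc"]].to_numpy().sum())
            sums[p] += weighted_csnb(nx, ngc, ng, truncate=truncate)
    return pd.Series(sums)


def ratio_report(fix: FixtureTables) -> RatioReport:
    """Recompute every printed count ratio from the packaged tables."""
    r = RatioReport()
    t1, t3 = fix.table1, fix.table3

    # Maximum-range (nmax) comparisons
    r.add("nmax_II_over_I", part_class_sum(t3, parts=("II",)), part_class_sum(t3, parts=("I",)))
    r.add(
        "nmax_GC_over_AT_gene",
        part_class_sum(t3, classes=("gc",)),
        part_class_sum(t3, classes=("at",)),
    )
    r.add(
        "nmax_GC_over_AT_part_I",
        part_class_sum(t3, parts=("I",), classes=("gc",)),
        part_class_sum(t3, parts=("I",), classes=("at",)),
    )
    r.add(
        "nmax_GC_over_AT_part_II",
        part_class_sum(t3, parts=("II",), classes=("gc",)),
        part_class_sum(t3, parts=("II",), classes=("at",)),
    )
    r.add(
        "nmax_GC_over_AT_low_energies",  # EcrH 0.581-0.585
        part_class_sum(t3, classes=("gc",), energies=(0.581, 0.585)),
        part_class_sum(t3, classes=("at",), energies=(0.581, 0.585)),
    )
    r.add(
        "nmax_GC_over_AT_high_energies",  # EcrH 0.586-0.589
        part_class_sum(t3, classes=("gc",), energies=(0.586, 0.589)),
        part_class_sum(t3, classes=("at",), energies=(0.586, 0.589)),
    )

    # CSNB comparisons at single energies
    r.add(
        "csnb_I_over_II_at_0584",
        part_class_sum(t1, parts=("I",), energies=(0.584, 0.584)),
        part_class_sum(t1, parts=("II",), energies=(0.584, 0.584)),
    )
    r.add(
        "csnb_II_over_III_at_0585",
        part_class_sum(t1, parts=("II",), energies=(0.585, 0.585)),
        part_class_sum(t1, parts=("III",), energies=(0.585, 0.585)),
    )
    r.add(
        "csnb_III_over_I_at_0586",
        part_class_sum(t1, parts=("III",), energies=(0.586, 0.586)),
        part_class_sum(t1, parts=("I",), energies=(0.586, 0.586)),
    )
    r.add(
        "csnb_III_over_II_at_0586",
        part_class_sum(t1, parts=("III",), energies=(0.586, 0.586)),
        part_class_sum(t1, parts=("II",), energies=(0.586, 0.586)),
    )

    # Whole-gene composition from the saturation row (every pair closed)
    r.add(
        "gene_AT_over_GC_pairs",
        part_class_sum(t1, classes=("at",), energies=(0.589, 0.589)),
        part_class_sum(t1, classes=("gc",), energies=(0.589, 0.589)),
    )

    # New-approach weighted CSNB: part II vs part III, percent
    w = weighted_part_sums(fix, truncate=True)
    r.set("weighted_csnb_sum_II", w["II"])
    r.set("weighted_csnb_sum_III", w["III"])
    r.add("weighted_csnb_II_over_III_pct", w["II"], w["III"], scale=100.0)
    return r


def correlation_report(fix: FixtureTables) -> RatioReport:
    """Recompute the three printed Spearman correlations from the tables."""
    r = RatioReport()
    t1, t3 = fix.table1, fix.table3
    ratio = fix.at_gc_ratio()

    # 15 points: (part A-T/G-C ratio, part CSNB count), EcrH 0.581-0.585
    x, y = [], []
    for e in ECRH_GRID:
        if e > 0.585 + 1e-9:
            continue
        sel = t1[t1["ecrh"] == e]
        for p in ("I", "II", "III"):
            x.append(float(ratio[p]))
            y.append(float(sel.loc[sel["part"] == p, ["at", "gc"]].to_numpy().sum()))
    r.set("spearman_ratio_vs_csnb", st.spearman_pearson_ranks(x, y))
    r.set("spearman_ratio_vs_csnb_p", st.spearman_pvalue(float(r["spearman_ratio_vs_csnb"]), len(x)))

    # 8 points: continuous weighted whole-gene CSNB, total vs G-C only,
    # EcrH 0.581-0.588; both weighted by the whole-gene damping factor.
    ng = fix.gene_size()
    xw, yw = [], []
    for e in ECRH_GRID:
        if e > 0.588 + 1e-9:
            continue
        sel = t1[t1["ecrh"] == e]
        ngc = float(sel[["at", "gc"]].to_numpy().sum())
        gc = float(sel["gc"].sum())
        xw.append(weighted_csnb(ngc, ngc, ng))
        yw.append(weighted_csnb(gc, ngc, ng))
    r.set("spearman_weighted_csnb_total_vs_gc", st.spearman_pearson_ranks(xw, yw))
    r.set(
        "spearman_weighted_csnb_total_vs_gc_p",
        st.spearman_pvalue(float(r["spearman_weighted_csnb_total_vs_gc"]), len(xw)),
    )

    # 16 points: (total nmax, G-C nmax) for parts I and II, EcrH 0.581-0.588,
    # evaluated with the d^2 formula.
    xt, yt = [], []
    for e in ECRH_GRID:
        if e > 0.588 + 1e-9:
            continue
        sel = t3[t3["ecrh"] == e]
        for p in ("I", "II"):
            row = sel[sel["part"] == p].iloc[0]
            xt.append(float(row["at"] + row["gc"]))
            yt.append(float(row["gc"]))
    r.set("spearman_nmax_total_vs_gc", st.spearman_d2(xt, yt))
    r.set("spearman_nmax_total_vs_gc_p", st.spearman_pvalue(float(r["spearman_nmax_total_vs_gc"]), len(xt)))
    return r


def _plot_scan(scan_frame: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    base = scan_frame[scan_frame["site"] == 0]
    subs = scan_frame[scan_frame["site"] > 0]
    ax.scatter(subs["ecrh"], subs["P"], s=6, alpha=0.4, label="substituted $P_i$")
    ax.plot(base["ecrh"], base["P"], "r-o", label="baseline $P_0$")
    ax.set_xlabel(r"$E_{cr}^{H}$ ($10^{-22}$ N$\cdot$m)")
    ax.set_ylabel("open-state probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_csnb_fractions(class_table: pd.DataFrame, part_lengths: pd.Series, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    piv = class_table.pivot_table(index="ecrh", columns="part", values="csnb", aggfunc="sum")
    for p in piv.columns:
        ax.plot(piv.index, piv[p] / float(part_lengths[p]), marker="o", label=f"part {p}")
    ax.set_xlabel(r"$E_{cr}^{H}$ ($10^{-22}$ N$\cdot$m)")
    ax.set_ylabel("CSNB fraction of part")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: dict, outdir: "str | Path") -> dict:
    """End-to-end run: gene -> scan -> classification -> statistics -> files.

    ``config`` is a validated configuration mapping (see ``dnaos.config``).
    Writes ``gene.fasta``, ``scan.csv``, ``classification.csv``,
    ``stats.json`` and (when ``plots`` is true) two overview figures into
    ``outdir``.  Returns the in-memory artifacts.
    """
    from .config import build_composition, build_mechanics, build_simulation_config

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "sequence"
    try:
        seq_cfg = config.get("sequence", {})
        if "path" in seq_cfg:
            gene = read_sequence(seq_cfg["path"], seq_cfg.get("format", "fasta"))
        else:
            gene = synthesize_gene(build_composition(config))
        gene.to_fasta(outdir / "gene.fasta")

        stage = "scan"
        mech = build_mechanics(config)
        sim, energies = build_simulation_config(config)
        scan = scan_substitutions(gene, mech, sim, energies)
        scan_frame = scan.to_frame()
        scan_frame.to_csv(outdir / "scan.csv", index=False)

        stage = "classification"
        classification = classify_scan(scan, gene)
        classification.table.to_csv(outdir / "classification.csv", index=False)

        stage = "statistics"
        piv = classification.part_totals("csnb")
        results = {}
        parts = list(piv.columns)
        lengths = gene.pair_counts()["length"]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                a = int(piv[parts[i]].sum())
                c = int(piv[parts[j]].sum())
                NA = int(lengths[parts[i]]) * len(piv.index)
                NB = int(lengths[parts[j]]) * len(piv.index)
                if min(a, c) >= 0 and a < NA and c < NB and a + c > 0:
                    t = st.ContingencyTable2x2(a, NA - a, c, NB - c)
                    results[f"yates_csnb_{parts[i]}_vs_{parts[j]}"] = st.yates_chi2(t).as_dict()
        import json

        (outdir / "stats.json").write_text(json.dumps(results, indent=2))

        if config.get("plots", False):
            stage = "plots"
            _plot_scan(scan_frame, outdir / "scan.png")
            _plot_csnb_fractions(classification.table, lengths, outdir / "csnb_fractions.png")
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    return {"gene": gene, "scan": scan, "classification": classification, "stats": results}
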