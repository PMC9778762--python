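"""Contingency-table and rank statistics used in the site-classification study.

Implements the Yates-corrected chi-square for 2x2 tables, the Pearson
chi-square for r x 2 tables with Bonferroni adjustment, the Kruskal-Wallis
H test, and two Spearman rank-correlation variants: the classic d^2 formula
(mean ranks substituted for ties) and the Pearson-correlation-of-ranks form,
which is exact under heavy ties.  The two agree exactly on tie-free data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "yates_chi2",
    "chi2_rx2_bonferroni",
    "kruskal_wallis",
    "spearman_d2",
    "spearman_pearson_ranks",
    "spearman_pvalue",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table with the conventional a/b/c/d cell naming.

    Rows are the two compared groups (e.g. gene parts), the first column
    the classified sites (CSNB or nmax), the second the remaining pairs.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(NA, NB, NS, NF) = row and column sums."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    pvalue: float
    adjusted_pvalue: float | None = None

    def as_dict(self) -> dict:
        out = {"statistic": self.statistic, "df": self.df, "p": self.pvalue}
        if self.adjusted_pvalue is not None:
            out["adjusted_p"] = self.adjusted_pvalue
        return out


def yates_chi2(t: ContingencyTable2x2) -> TestResult:
    """Chi-square with Yates continuity correction, 1 df.

    statistic = N * (max(0, |ad - bc| - N/2))^2 / (NA * NB * NS * NF);
    the correction is clamped at zero so near-balanced tables score 0.
    """
    if min(t.a, t.b, t.c, t.d) < 0:
        raise ValueError("cell counts must be non-negative")
    NA, NB, NS, NF = t.margins()
    if min(NA, NB, NS, NF) == 0:
        raise ValueError("degenerate table: a zero margin")
    N = t.N
    num = max(0.0, abs(t.a * t.d - t.b * t.c) - N / 2.0)
    stat = N * num * num / (NA * NB * NS * NF)
    return TestResult(statistic=float(stat), df=1, pvalue=float(sps.chi2.sf(stat, 1)))


def chi2_rx2_bonferroni(grid: "np.ndarray | list", comparisons: int = 1) -> TestResult:
    """Pearson chi-square on an r x 2 grid, p-value Bonferroni-multiplied.

    Expected counts from the margins; df = (r-1).  The adjusted p is
    p * comparisons, capped at 1.  The number of comparisons is the
    caller's choice (it depends on the family of tests being run).
    """
    O = np.asarray(grid, dtype=float)
    if O.ndim != 2 or O.shape[1] != 2 or O.shape[0] < 2:
        raise ValueError(f"expected an r x 2 grid with r >= 2, got shape {O.shape}")
    if (O < 0).any():
        raise ValueError("cell counts must be non-negative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: a zero margin")
    if comparisons < 1:
        raise ValueError("comparisons must be >= 1")
    E = np.outer(row, col) / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, pvalue=p, adjusted_pvalue=min(1.0, p * comparisons))


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across two or more groups.

    Ranks are assigned over the pooled sample with mean ranks for ties.
    When every observation is equal the tie-correction denominator
    vanishes; H is then defined as 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = len(pooled)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = sps.rankdata(pooled)
    H = 0.0
    start = 0
    for s in sizes:
        r = ranks[start : start + s]
        H += r.sum() ** 2 / s
        start += s
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    H = 0.0 if correction == 0.0 else H / correction
    df = len(groups) - 1
    return TestResult(statistic=float(H), df=df, pvalue=float(sps.chi2.sf(H, df)))


def _ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.asarray(x, dtype=float))


def _check_input(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-d sequences of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def spearman_d2(x, y) -> float:
    """Spearman correlation via the classic d^2 formula with mean ranks.

    r = 1 - 6 sum d^2 / (n (n^2 - 1)), d = rank(x) - rank(y).  Under ties
    this differs slightly from the Pearson-of-ranks form.
    """
    x, y = _check_input(x, y)
    n = len(x)
    d = _ranks(x) - _ranks(y)
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1)))


def spearman_pearson_ranks(x, y) -> float:
    """Spearman correlation as the Pearson correlation of mean ranks."""
    x, y = _check_input(x, y)
    rx, ry = _ranks(x), _ranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant input: zero rank variance")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient via the t approximation, n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))
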