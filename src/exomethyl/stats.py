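"""Rank-sum testing and expression-breadth statistics.

All group comparisons in the pipeline (exon lengths by methylation status,
methylation levels by exon class) use the Wilcoxon rank-sum / Mann-Whitney U
test.  For small untied samples the p-value is exact, from the full null
distribution of U; otherwise a tie-corrected normal approximation is used.

Expression breadth is the number of samples (tissues or developmental
stages) in which a gene's FPKM exceeds a threshold, strictly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankSumResult",
    "BreadthResult",
    "rank_sum_test",
    "expression_breadth",
    "breadth_comparison",
]

EXACT_MAX_N = 20  # combined size at or below which the exact test is used


@dataclass
class RankSumResult:
    n_x: int
    n_y: int
    statistic: float  # Mann-Whitney U for the x sample
    p_value: float
    method: str  # exact | normal_approx | degenerate


def _exact_u_counts(m: int, n: int) -> np.ndarray:
    """Null distribution of U for sample sizes (m, n), as counts over
    u = 0..m*n.

    Uses the standard recursion c(u; m, n) = c(u-n; m-1, n) + c(u; m, n-1):
    the largest of the m ranks either is the overall maximum (contributing n
    to U) or is not.
    """
    size = m * n + 1
    # table[j] = counts for (i, j) as i advances
    table = [np.zeros(size, dtype=np.int64) for _ in range(n + 1)]
    for j in range(n + 1):
        table[j][0] = 1  # i = 0: only u = 0
    for _ in range(1, m + 1):
        new = [np.zeros(size, dtype=np.int64) for _ in range(n + 1)]
        new[0][0] = 1
        for j in range(1, n + 1):
            shifted = np.zeros(size, dtype=np.int64)
            shifted[j:] = table[j][: size - j]
            new[j] = shifted + new[j - 1]
        table = new
    return table[n]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of two independent samples.

    ``alternative='greater'`` tests whether x tends to exceed y.  Exact
    p-values (full enumeration of the U null distribution) are used when the
    combined sample size is at most 20 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m, n = x.size, y.size

    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_x = ranks[:m].sum()
    u_x = r_x - m * (m + 1) / 2.0

    if np.ptp(combined) == 0:
        return RankSumResult(m, n, u_x, 1.0, "degenerate")

    has_ties = np.unique(combined).size < combined.size
    if m + n <= EXACT_MAX_N and not has_ties:
        counts = _exact_u_counts(m, n)
        total = counts.sum()
        u = int(round(u_x))
        p_le = counts[: u + 1].sum() / total
        p_ge = counts[u:].sum() / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(m, n, u_x, float(p), "exact")

    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankSumResult(m, n, float(res.statistic), float(res.pvalue), "normal_approx")


@dataclass
class BreadthResult:
    """Expression-breadth histogram for one gene group."""

    group: str
    n_genes: int
    counts: np.ndarray  # counts[b] = genes expressed in exactly b samples

    @property
    def fraction_all(self) -> float | None:
        """Share of genes expressed in every sample; None for an empty group."""
        if self.n_genes == 0:
            return None
        return float(self.counts[-1] / self.n_genes)


def expression_breadth(values: Sequence[float], threshold: float = 1.0) -> int:
    """Number of samples where expression is strictly larger than threshold."""
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing expression value")
    return int((arr > threshold).sum())


def breadth_comparison(
    methylated: Iterable[str],
    unmethylated: Iterable[str],
    expression: pd.DataFrame,
    threshold: float = 1.0,
) -> tuple[BreadthResult, BreadthResult]:
    """Expression-breadth histograms for methylated vs unmethylated genes.

    ``expression``: features x samples FPKM table covering both gene sets.
    Returns one :class:`BreadthResult` per group (histogram over breadth
    0..n_samples plus the fraction expressed in every sample).
    """
    methylated = sorted(set(methylated))
    unmethylated = sorted(set(unmethylated))
    if set(methylated) & set(unmethylated):
        raise ValueError("gene groups must be disjoint")
    n_samples = expression.shape[1]

    def one(group_name: str, ids: list[str]) -> BreadthResult:
        counts = np.zeros(n_samples + 1, dtype=np.int64)
        missing = [g for g in ids if g not in expression.index]
        if missing:
            raise KeyError(f"genes missing from expression table: {missing[:5]}")
        if ids:
            sub = expression.loc[ids]
            breadth = (sub.values > threshold).sum(axis=1)
            for b in breadth:
                counts[b] += 1
        return BreadthResult(group_name, len(ids), counts)

    return one("methylated", methylated), one("unmethylated", unmethylated)
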