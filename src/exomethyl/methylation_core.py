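"""mCpG calling, weighted methylation levels, and genome summaries.

The central statistic is the weighted methylation level of a region,

    level = sum_i C_i / sum_i (C_i + T_i)

over CpG sites i with coverage >= ``min_cov`` in the region, where C_i and
T_i are read counts supporting the methylated and unmethylated state.  This
is coverage-weighted, not a mean of per-site fractions: splitting a region
and re-pooling the raw sums leaves it unchanged, averaging sub-region levels
does not.

A CpG site is called methylated (an mCpG) when it is covered by at least
``min_cov`` reads, at least ``min_frac`` of them support methylation, and at
least ``min_meth_reads`` do so in absolute terms — the last rule guards
against a single sequencing error creating a spurious methylated site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CytosineCall, GeneModel

__all__ = [
    "DEFAULT_MIN_COV",
    "DEFAULT_MIN_FRAC",
    "DEFAULT_MIN_METH_READS",
    "MethylationSummary",
    "GenomeSummaryRow",
    "Methylome",
    "call_mcpg",
    "mcpg_status_arrays",
    "weighted_methylation",
    "gene_methylation",
    "genome_summary",
    "gene_set_overlap",
]

DEFAULT_MIN_COV = 5
DEFAULT_MIN_FRAC = 0.10
DEFAULT_MIN_METH_READS = 2

UNCOVERED = "uncovered"
UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"

# tolerance for the >=10% fraction rule so integer ratios that equal the
# threshold exactly (2/20) are not lost to floating-point rounding
_FRAC_EPS = 1e-9


def call_mcpg(
    call: CytosineCall,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_meth_reads: int = DEFAULT_MIN_METH_READS,
) -> str:
    """Classify one CpG site as uncovered / unmethylated / methylated."""
    cov = call.n_meth + call.n_unmeth
    if cov < min_cov:
        return UNCOVERED
    if call.n_meth >= min_meth_reads and call.n_meth >= min_frac * cov - _FRAC_EPS:
        return METHYLATED
    return UNMETHYLATED


def mcpg_status_arrays(
    n_meth: np.ndarray,
    n_unmeth: np.ndarray,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_meth_reads: int = DEFAULT_MIN_METH_READS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised mCpG call: returns (covered mask, methylated mask)."""
    n_meth = np.asarray(n_meth)
    cov = n_meth + np.asarray(n_unmeth)
    covered = cov >= min_cov
    methylated = (
        covered
        & (n_meth >= min_meth_reads)
        & (n_meth >= min_frac * cov - _FRAC_EPS)
    )
    return covered, methylated


@dataclass
class MethylationSummary:
    """Covered-CpG counts and the weighted methylation level of a region."""

    n_covered: int
    n_mcpg: int
    sum_c: int
    sum_cov: int

    @property
    def level(self) -> float | None:
        """Weighted level, or None when the region has no covered CpGs."""
        if self.sum_cov == 0:
            return None
        return self.sum_c / self.sum_cov

    @property
    def has_data(self) -> bool:
        return self.sum_cov > 0


def weighted_methylation(
    n_meth: np.ndarray,
    n_unmeth: np.ndarray,
    min_cov: int = DEFAULT_MIN_COV,
    zero_uncalled: bool = False,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_meth_reads: int = DEFAULT_MIN_METH_READS,
) -> MethylationSummary:
    """Weighted methylation level over the sites of one region.

    Only sites with coverage >= ``min_cov`` enter the sums.  With
    ``zero_uncalled`` set, sites not called methylated contribute 0 to the
    numerator while their full coverage stays in the denominator (so the
    statistic reflects only read support at called mCpGs).
    """
    n_meth = np.asarray(n_meth, dtype=np.int64)
    n_unmeth = np.asarray(n_unmeth, dtype=np.int64)
    covered, methylated = mcpg_status_arrays(
        n_meth, n_unmeth, min_cov, min_frac, min_meth_reads
    )
    numer = n_meth[covered]
    if zero_uncalled:
        numer = np.where(methylated[covered], numer, 0)
    return MethylationSummary(
        n_covered=int(covered.sum()),
        n_mcpg=int(methylated.sum()),
        sum_c=int(numer.sum()),
        sum_cov=int((n_meth[covered] + n_unmeth[covered]).sum()),
    )


class Methylome:
    """Position-indexed CpG calls for one sample, queryable by region.

    Holds per-chromosome sorted position arrays (0-based) with methylated
    and unmethylated read counts; region queries are binary searches.
    """

    def __init__(self, calls: pd.DataFrame):
        """``calls``: DataFrame with chrom, pos (1-based), n_meth, n_unmeth."""
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.n_sites = len(calls)
        if self.n_sites == 0:
            return
        calls = calls.sort_values(["chrom", "pos"], kind="mergesort")
        for chrom, cdf in calls.groupby("chrom", sort=False, observed=True):
            self._chrom[str(chrom)] = (
                cdf["pos"].to_numpy(np.int64) - 1,  # to 0-based
                cdf["n_meth"].to_numpy(np.int64),
                cdf["n_unmeth"].to_numpy(np.int64),
            )

    @classmethod
    def from_report(cls, path, cg_only: bool = True) -> "Methylome":
        from .io_formats import read_cytosine_report_df

        return cls(read_cytosine_report_df(path, cg_only=cg_only))

    def region(self, chrom: str, start: int, end: int):
        """Counts for CpGs in [start, end), 0-based half-open.

        Returns (positions, n_meth, n_unmeth) arrays.
        """
        if chrom not in self._chrom:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        pos, m, u = self._chrom[chrom]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return pos[i:j], m[i:j], u[i:j]

    def region_summary(self, chrom, start, end, **kwargs) -> MethylationSummary:
        _, m, u = self.region(chrom, start, end)
        return weighted_methylation(m, u, **kwargs)

    def all_counts(self) -> tuple[np.ndarray, np.ndarray]:
        if not self._chrom:
            z = np.empty(0, dtype=np.int64)
            return z, z
        ms, us = [], []
        for _, m, u in self._chrom.values():
            ms.append(m)
            us.append(u)
        return np.concatenate(ms), np.concatenate(us)


def gene_methylation(
    gene: GeneModel,
    methylome: Methylome,
    min_mcpg: int = 2,
    min_cov: int = DEFAULT_MIN_COV,
    **kwargs,
) -> tuple[int, float | None, bool]:
    """Gene-body methylation: (n_mcpg, weighted level, is_methylated).

    The gene body is the span from the first to the last exon across all
    transcripts.  A gene is called methylated when it harbours at least
    ``min_mcpg`` mCpGs (default 2, i.e. "more than one").
    """
    start, end = gene.span
    summary = methylome.region_summary(
        gene.chrom, start, end, min_cov=min_cov, **kwargs
    )
    return summary.n_mcpg, summary.level, summary.n_mcpg >= min_mcpg


@dataclass
class GenomeSummaryRow:
    """One sample's genome-wide coverage and mCpG tallies.

    Both ratios share the total genomic CpG count as denominator, so
    ``mcpg_ratio`` is the fraction of *all* genomic CpGs called methylated,
    not of the covered ones.
    """

    sample: str
    n_total_cpg: int
    n_covered: int
    n_mcpg: int

    @property
    def coverage_ratio(self) -> float:
        return self.n_covered / self.n_total_cpg

    @property
    def mcpg_ratio(self) -> float:
        return self.n_mcpg / self.n_total_cpg


def genome_summary(
    sample: str,
    n_total_cpg: int,
    methylome: Methylome | None = None,
    n_covered: int | None = None,
    n_mcpg: int | None = None,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_meth_reads: int = DEFAULT_MIN_METH_READS,
) -> GenomeSummaryRow:
    """Genome-wide summary row for one sample.

    Counts are either taken from a :class:`Methylome` or supplied directly
    (e.g. when re-deriving ratios from published tallies).
    """
    if n_total_cpg <= 0:
        raise ValueError("n_total_cpg must be positive")
    if methylome is not None:
        m, u = methylome.all_counts()
        covered, methylated = mcpg_status_arrays(
            m, u, min_cov, min_frac, min_meth_reads
        )
        n_covered = int(covered.sum())
        n_mcpg = int(methylated.sum())
    if n_covered is None or n_mcpg is None:
        raise ValueError("supply a methylome or explicit counts")
    if n_covered > n_total_cpg:
        raise ValueError(
            f"covered CpGs ({n_covered}) exceed total genomic CpGs ({n_total_cpg})"
        )
    if n_mcpg > n_covered:
        raise ValueError("methylated CpGs exceed covered CpGs")
    return GenomeSummaryRow(sample, n_total_cpg, n_covered, n_mcpg)


def gene_set_overlap(
    methylated_by_sample: Mapping[str, Iterable[str]],
) -> tuple[int, int, float | None]:
    """Union/intersection of per-sample methylated gene sets.

    Returns (n_union, n_intersection, fraction_both) where fraction_both is
    the share of genes methylated in at least one sample that are methylated
    in every sample; None when the union is empty.
    """
    sets = [set(v) for v in methylated_by_sample.values()]
    if len(sets) < 2:
        raise ValueError("need at least two samples")
    union = set.union(*sets)
    inter = set.intersection(*sets)
    frac = len(inter) / len(union) if union else None
    return len(union), len(inter), frac
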