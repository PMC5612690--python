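"""Exon-level analyses: positional classification, methylation status,
length contrasts, inclusion calls, and boundary-anchored profiles.

Coding exons of multi-exon genes are grouped as first / internal / last in
transcription (5'->3') order; genes with fewer than three exons are
excluded.  An exon is methylated when it contains at least one mCpG.
Inclusion vs skipping is operationalised through exon-level FPKM within
genes that are both methylated (gene level >= 0.1) and expressed
(FPKM >= 1): an exon of such a gene is included when its own FPKM clears
the expression threshold, skipped otherwise.

Boundary profiles pool raw methylated/total read counts in equal-width bins
across exons, anchored at the exon start and end sites in transcription
orientation (+-200 bp in 20 bins for internal exons, +-150 bp in 15 bins
for first and last exons; 20 bp per bin either way).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel
from .methylation_core import (
    DEFAULT_MIN_COV,
    MethylationSummary,
    Methylome,
    weighted_methylation,
)
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "ExonRecord",
    "ClassificationResult",
    "ComparisonResult",
    "ProfileMatrix",
    "PROFILE_PARAMS",
    "classify_exon_positions",
    "exon_methylation_status",
    "compare_lengths_by_status",
    "compare_methylation_by_class",
    "classify_inclusion",
    "boundary_profile",
]

FIRST, INTERNAL, LAST = "first", "internal", "last"
POSITION_CLASSES = (FIRST, INTERNAL, LAST)

INCLUDED, SKIPPED, NOT_EVALUABLE = "included", "skipped", "not_evaluable"

# (flank bp, number of bins) per exon class; bin width is 20 bp in both
PROFILE_PARAMS = {FIRST: (150, 15), INTERNAL: (200, 20), LAST: (150, 15)}
BIN_WIDTH = 20


@dataclass
class ExonRecord:
    """One coding exon of a multi-exon gene with its analysis annotations."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    rank: int  # 1-based position in transcription order
    position_class: str
    meth: MethylationSummary | None = None
    is_methylated: bool | None = None
    inclusion: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_id(self) -> str:
        return f"{self.transcript_id}:exon{self.rank}"


@dataclass
class ClassificationResult:
    records: list[ExonRecord]
    n_genes_included: int
    n_genes_excluded: int  # genes with fewer than 3 exons


def classify_exon_positions(
    genes: Iterable[GeneModel], min_exons: int = 3
) -> ClassificationResult:
    """Assign first/internal/last classes from each gene's representative
    transcript; genes with fewer than ``min_exons`` exons yield no records.
    """
    records: list[ExonRecord] = []
    n_inc = n_exc = 0
    for gene in genes:
        t = gene.representative
        if t.n_exons < min_exons:
            n_exc += 1
            continue
        n_inc += 1
        exons = gene.exons_in_transcription_order()
        for i, (s, e) in enumerate(exons):
            cls = FIRST if i == 0 else LAST if i == len(exons) - 1 else INTERNAL
            records.append(
                ExonRecord(
                    gene_id=gene.gene_id,
                    transcript_id=t.transcript_id,
                    chrom=gene.chrom,
                    start=s,
                    end=e,
                    strand=gene.strand,
                    rank=i + 1,
                    position_class=cls,
                )
            )
    return ClassificationResult(records, n_inc, n_exc)


def exon_methylation_status(
    record: ExonRecord, methylome: Methylome, min_mcpg: int = 1, **kwargs
) -> ExonRecord:
    """Attach the exon's methylation summary; methylated iff >= min_mcpg
    mCpGs fall inside the exon (default: at least one)."""
    summary = methylome.region_summary(record.chrom, record.start, record.end, **kwargs)
    record.meth = summary
    record.is_methylated = summary.n_mcpg >= min_mcpg
    return record


@dataclass
class ComparisonResult:
    """Two-group rank-sum comparison with group medians."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float | None
    median_b: float | None
    test: RankSumResult | None
    computable: bool

    @property
    def p_value(self) -> float | None:
        return self.test.p_value if self.test else None

    @property
    def direction(self) -> str | None:
        if not self.computable:
            return None
        if self.median_a == self.median_b:
            return "equal"
        return f"{self.group_a}>{self.group_b}" if self.median_a > self.median_b else f"{self.group_b}>{self.group_a}"


def _compare(name_a, vals_a, name_b, vals_b, alternative="two-sided") -> ComparisonResult:
    n_a, n_b = len(vals_a), len(vals_b)
    if n_a == 0 or n_b == 0 or n_a + n_b < 4:
        return ComparisonResult(name_a, name_b, n_a, n_b, None, None, None, False)
    return ComparisonResult(
        name_a,
        name_b,
        n_a,
        n_b,
        float(np.median(vals_a)),
        float(np.median(vals_b)),
        rank_sum_test(vals_a, vals_b, alternative),
        True,
    )


def compare_lengths_by_status(
    records: Sequence[ExonRecord], position_class: str
) -> ComparisonResult:
    """Rank-sum comparison of exon lengths, methylated vs unmethylated,
    within one positional class.  Callers restrict ``records`` to exons of
    methylated genes beforehand."""
    sub = [r for r in records if r.position_class == position_class]
    meth = [r.length for r in sub if r.is_methylated]
    unmeth = [r.length for r in sub if r.is_methylated is False]
    return _compare("methylated", meth, "unmethylated", unmeth)


def compare_methylation_by_class(
    records: Sequence[ExonRecord],
) -> dict[tuple[str, str], ComparisonResult]:
    """Pairwise rank-sum comparisons of per-exon weighted levels among the
    first/internal/last classes.  Exons without covered CpGs are excluded."""
    levels = {
        cls: [
            r.meth.level
            for r in records
            if r.position_class == cls and r.meth is not None and r.meth.has_data
        ]
        for cls in POSITION_CLASSES
    }
    out = {}
    pairs = [(FIRST, INTERNAL), (FIRST, LAST), (INTERNAL, LAST)]
    for a, b in pairs:
        out[(a, b)] = _compare(a, levels[a], b, levels[b])
    return out


def classify_inclusion(
    record: ExonRecord,
    exon_fpkm: float | None,
    gene_fpkm: float | None,
    gene_level: float | None,
    expr_thresh: float = 1.0,
    meth_thresh: float = 0.1,
) -> str:
    """Inclusion status of one exon in one sample.

    Evaluable only within genes that are both methylated (gene-body weighted
    level >= ``meth_thresh``) and expressed (gene FPKM >= ``expr_thresh``);
    then included iff the exon's own FPKM >= ``expr_thresh``.
    """
    if exon_fpkm is None or gene_fpkm is None or gene_level is None:
        return NOT_EVALUABLE
    if gene_level < meth_thresh or gene_fpkm < expr_thresh:
        return NOT_EVALUABLE
    return INCLUDED if exon_fpkm >= expr_thresh else SKIPPED


@dataclass
class ProfileMatrix:
    """Binned pooled methylation around exon boundaries for one group.

    For each anchor ("start" = 5' boundary, "end" = 3' boundary, both in
    transcription orientation) the +-flank window is cut into equal bins
    ordered 5'->3'; every covered CpG contributes its raw C and C+T counts
    to exactly one bin per anchor window containing it.
    """

    exon_class: str
    inclusion_group: str
    flank_bp: int
    n_bins: int
    sum_c: dict[str, np.ndarray]  # anchor -> per-bin pooled methylated counts
    sum_cov: dict[str, np.ndarray]  # anchor -> per-bin pooled coverage
    n_exons: int

    def level(self, anchor: str) -> np.ndarray:
        """Per-bin pooled weighted level; NaN where a bin has no coverage."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.sum_cov[anchor] > 0,
                self.sum_c[anchor] / np.maximum(self.sum_cov[anchor], 1),
                np.nan,
            )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        width = 2 * self.flank_bp // self.n_bins
        for anchor in ("start", "end"):
            lv = self.level(anchor)
            for b in range(self.n_bins):
                rows.append(
                    {
                        "exon_class": self.exon_class,
                        "inclusion_group": self.inclusion_group,
                        "anchor": anchor,
                        "bin": b,
                        "offset_bp": b * width - self.flank_bp,
                        "sum_c": int(self.sum_c[anchor][b]),
                        "sum_cov": int(self.sum_cov[anchor][b]),
                        "level": lv[b],
                    }
                )
        return pd.DataFrame(rows)


def _anchor_bins(
    record: ExonRecord, anchor: str, flank: int, n_bins: int
) -> tuple[int, int, bool]:
    """Genomic window [lo, hi) for one anchor plus whether the transcription
    axis runs in decreasing genomic coordinates.

    Anchors are the half-open interval boundaries of the exon: "start" is
    the 5' boundary, "end" the 3' boundary, in transcription orientation.  A
    CpG exactly on the anchor coordinate falls in the first bin on the
    inside of that boundary (half-open bins).
    """
    plus = record.strand == "+"
    if anchor == "start":
        a = record.start if plus else record.end
    else:
        a = record.end if plus else record.start
    return a - flank, a + flank, not plus


def boundary_profile(
    records: Sequence[ExonRecord],
    exon_class: str,
    inclusion_group: str,
    methylome: Methylome,
    sample: str | None = None,
    min_cov: int = DEFAULT_MIN_COV,
) -> ProfileMatrix:
    """Pooled binned methylation around the boundaries of one exon group.

    ``records`` are filtered to ``exon_class`` and, when ``sample`` is
    given, to exons whose per-sample inclusion status equals
    ``inclusion_group``.  Only covered CpGs (coverage >= min_cov) enter the
    pooled per-bin sums.
    """
    flank, n_bins = PROFILE_PARAMS[exon_class]
    sum_c = {a: np.zeros(n_bins, dtype=np.int64) for a in ("start", "end")}
    sum_cov = {a: np.zeros(n_bins, dtype=np.int64) for a in ("start", "end")}
    n_exons = 0
    for r in records:
        if r.position_class != exon_class:
            continue
        if sample is not None and r.inclusion.get(sample) != inclusion_group:
            continue
        n_exons += 1
        for anchor in ("start", "end"):
            lo, hi, reverse = _anchor_bins(r, anchor, flank, n_bins)
            pos, m, u = methylome.region(r.chrom, max(lo, 0), hi)
            if pos.size == 0:
                continue
            cov = m + u
            keep = cov >= min_cov
            if not keep.any():
                continue
            pos, m, cov = pos[keep], m[keep], cov[keep]
            if reverse:
                u_axis = (hi - 1) - pos  # transcription-axis offset
            else:
                u_axis = pos - lo
            bins = u_axis // BIN_WIDTH
            np.add.at(sum_c[anchor], bins, m)
            np.add.at(sum_cov[anchor], bins, cov)
    return ProfileMatrix(
        exon_class, inclusion_group, flank, n_bins, sum_c, sum_cov, n_exons
    )
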