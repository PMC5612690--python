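"""Readers and writers for the formats the pipeline touches.

Methylation calls arrive as Bismark-style per-cytosine reports (one line per
cytosine: chrom, 1-based position, strand, methylated read count,
unmethylated read count, context, optional trinucleotide).  Gene models come
from GTF/GFF3, expression matrices from TSV.  Internally every interval is
0-based half-open; the 1-based conventions of GTF and cytosine reports are
converted at this boundary and nowhere else.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CytosineCall",
    "Transcript",
    "GeneModel",
    "read_cytosine_report",
    "read_cytosine_report_df",
    "write_cytosine_report",
    "read_gene_models",
    "write_gtf",
    "read_expression_table",
    "write_result_tables",
]

CYTOSINE_REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
VALID_CONTEXTS = {"CG", "CHG", "CHH"}
VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's strand-resolved read counts at a genomic position.

    ``pos`` is 1-based, as printed in the report.  ``n_meth`` counts reads
    supporting a methylated cytosine (unconverted C), ``n_unmeth`` reads
    supporting an unmethylated one (converted to T).
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str = "CG"

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


def read_cytosine_report(path, cg_only: bool = True) -> Iterator[CytosineCall]:
    """Stream :class:`CytosineCall` records from a cytosine report.

    Parameters
    ----------
    path
        Tab-separated file with at least six columns per line:
        chrom, 1-based position, strand, methylated count, unmethylated
        count, context (and optionally the trinucleotide).
    cg_only
        Drop non-CG contexts (the CpG-dinucleotide restriction used
        throughout the analysis).

    Raises
    ------
    ValueError
        On a malformed line (naming the line number) or a negative count.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=6 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos = int(pos_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative read count"
                )
            if pos < 1:
                raise ValueError(f"{path}: line {lineno}: position must be >=1")
            if strand not in VALID_STRANDS:
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            if cg_only and context != "CG":
                continue
            yield CytosineCall(chrom, pos, strand, n_meth, n_unmeth, context)


def read_cytosine_report_df(path, cg_only: bool = True) -> pd.DataFrame:
    """Load a cytosine report into a DataFrame (columns as in the stream)."""
    records = read_cytosine_report(path, cg_only=cg_only)
    df = pd.DataFrame.from_records(
        [(c.chrom, c.pos, c.strand, c.n_meth, c.n_unmeth, c.context) for c in records],
        columns=CYTOSINE_REPORT_COLUMNS,
    )
    if df.empty:
        df = df.astype(
            {"pos": np.int64, "n_meth": np.int64, "n_unmeth": np.int64}
        )
    return df


def write_cytosine_report(calls: Iterable[CytosineCall] | pd.DataFrame, path) -> None:
    """Write calls back out in cytosine-report layout (tab-separated)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(calls, pd.DataFrame):
        rows = calls.itertuples(index=False)
        with open(path, "w") as out:
            for r in rows:
                out.write(
                    f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.n_meth}\t{r.n_unmeth}\t{r.context}\n"
                )
    else:
        with open(path, "w") as out:
            for c in calls:
                out.write(
                    f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.n_meth}\t{c.n_unmeth}\t{c.context}\n"
                )


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by coordinate

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """gene -> transcript -> exon hierarchy for one gene.

    Exons are stored sorted by genomic coordinate; transcription order is
    derived from the strand (on '-' the highest-coordinate exon is exon 1).
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    representative_transcript: str | None = None

    @property
    def representative(self) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == self.representative_transcript:
                return t
        raise KeyError(self.representative_transcript)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)

    def exons_in_transcription_order(
        self, transcript_id: str | None = None
    ) -> list[tuple[int, int]]:
        t = (
            self.representative
            if transcript_id is None
            else next(x for x in self.transcripts if x.transcript_id == transcript_id)
        )
        exons = list(t.exons)
        return exons[::-1] if self.strand == "-" else exons


def _choose_representative(transcripts: list[Transcript]) -> str:
    """Most exons; ties broken by longest genomic span, then smallest id."""
    def key(t: Transcript):
        s, e = t.span
        return (-t.n_exons, -(e - s), t.transcript_id)

    return min(transcripts, key=key).transcript_id


def read_gene_models(path, feature: str | None = None) -> dict[str, GeneModel]:
    """Assemble :class:`GeneModel` objects from a GTF or GFF3 file.

    Coding exons (CDS features) are preferred when present; otherwise exon
    features are used.  ``feature`` forces one or the other.

    Returns a dict keyed by gene id.
    """
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff", ".gff3")):
        df = pr.read_gff3(path).df
    else:
        df = pr.read_gtf(path).df

    if feature is None:
        feature = "CDS" if (df["Feature"] == "CDS").any() else "exon"
    ex = df[df["Feature"] == feature].copy()
    if ex.empty:
        raise ValueError(f"{path}: no {feature!r} features found")

    # GFF3 parents may live in Parent rather than transcript_id
    if "transcript_id" not in ex.columns or ex["transcript_id"].isna().all():
        if "Parent" in ex.columns:
            ex["transcript_id"] = ex["Parent"]
        else:
            raise ValueError(f"{path}: {feature} features lack transcript parents")
    if ex["transcript_id"].isna().any():
        bad = ex[ex["transcript_id"].isna()].iloc[0]
        raise ValueError(
            f"{path}: {feature} at {bad.Chromosome}:{bad.Start}-{bad.End} "
            "has no parent transcript"
        )
    if "gene_id" not in ex.columns or ex["gene_id"].isna().any():
        raise ValueError(f"{path}: {feature} features lack gene_id")
    bad_strand = ~ex["Strand"].isin(list(VALID_STRANDS))
    if bad_strand.any():
        raise ValueError(
            f"{path}: unknown strand symbol {ex.loc[bad_strand, 'Strand'].iloc[0]!r}"
        )

    genes: dict[str, GeneModel] = {}
    for (gene_id, chrom, strand), gdf in ex.groupby(
        ["gene_id", "Chromosome", "Strand"], sort=True, observed=True
    ):
        model = GeneModel(gene_id=str(gene_id), chrom=str(chrom), strand=str(strand))
        for tid, tdf in gdf.groupby("transcript_id", sort=True):
            ivals = sorted(zip(tdf["Start"].astype(int), tdf["End"].astype(int)))
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{path}: overlapping exons in transcript {tid}"
                    )
            model.transcripts.append(Transcript(str(tid), ivals))
        model.representative_transcript = _choose_representative(model.transcripts)
        genes[model.gene_id] = model
    return genes


def write_gtf(genes: Iterable[GeneModel], path, source: str = "exomethyl") -> None:
    """Write gene models as GTF (1-based inclusive), deterministically sorted."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
        gs, ge = g.span
        attrs = f'gene_id "{g.gene_id}";'
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}"
        )
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            ts, te = t.span
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            lines.append(
                f"{g.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}"
                )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path) -> pd.DataFrame:
    """Read a TSV of FPKM values (rows: feature ids, columns: sample ids).

    The table must be complete (no missing cells), strictly numeric and
    non-negative, with unique feature ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: non-numeric value at ({bad!r}, {col!r})")
    if df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {feat!r}")
    if (df.values < 0).any():
        feat = df.index[(df < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative FPKM in row {feat!r}")
    return df


# ---------------------------------------------------------------------------
# Result tables


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_result_tables(results: dict, out_dir) -> list[str]:
    """Write a result bundle: BED6+ for per-exon methylation, TSVs for
    summary tables, JSON for the report.

    ``results`` maps names to payloads: a DataFrame with interval columns
    (chrom/start/end/name/score/strand, 0-based half-open) is written as
    ``<name>.bed``; any other DataFrame as ``<name>.tsv``; a dict as
    ``<name>.json``.  Output order and row order are deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        payload = results[name]
        if isinstance(payload, pd.DataFrame):
            bed_cols = ["chrom", "start", "end", "name", "score", "strand"]
            if list(payload.columns[:6]) == bed_cols:
                target = out_dir / f"{name}.bed"
                payload = payload.sort_values(
                    ["chrom", "start", "end", "name"], kind="mergesort"
                )
                payload.to_csv(target, sep="\t", index=False)
            else:
                target = out_dir / f"{name}.tsv"
                payload.to_csv(target, sep="\t", index=False)
        elif isinstance(payload, dict):
            target = out_dir / f"{name}.json"
            target.write_text(
                json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
                + "\n"
            )
        else:
            raise TypeError(f"unsupported result payload for {name!r}")
        written.append(str(target))
    return written
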