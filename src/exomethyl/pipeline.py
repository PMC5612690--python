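"""End-to-end orchestration: from input files to the report bundle.

The pipeline runs the analyses in their natural order: genome-wide
coverage/mCpG summary, per-gene methylation calls and two-sample overlap,
expression breadth of methylated vs unmethylated genes, exon length by
methylation status, methylation by exon class, and included-vs-skipped
boundary profiles.  Every filtering step's input/output counts are recorded
in a funnel so threshold-sensitive results stay auditable.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import exon_analysis as ea
from . import methylation_core as mc
from . import stats as st
from .io_formats import (
    GeneModel,
    read_expression_table,
    read_gene_models,
    write_result_tables,
)

__all__ = ["RunConfig", "InputBundle", "load_dataset", "run_pipeline"]

REPORT_SCHEMA_VERSION = "1.0"

log = logging.getLogger("exomethyl")


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run (echoed into the report)."""

    data_dir: str
    out_dir: str
    min_cov: int = mc.DEFAULT_MIN_COV
    min_frac: float = mc.DEFAULT_MIN_FRAC
    min_meth_reads: int = mc.DEFAULT_MIN_METH_READS
    gene_min_mcpg: int = 2
    exon_min_mcpg: int = 1
    gene_level_filter: float = 0.1
    expr_thresh: float = 1.0
    breadth_thresh: float = 1.0  # strict: expressed iff FPKM > this
    # methylation sample -> expression column used for inclusion calls;
    # defaults to tissue_1, tissue_2, ... in sample sort order
    sample_to_tissue: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class InputBundle:
    genes: dict[str, GeneModel]
    methylomes: dict[str, mc.Methylome]
    gene_fpkm_tissues: pd.DataFrame
    gene_fpkm_stages: pd.DataFrame
    exon_fpkm: pd.DataFrame
    n_total_cpg: int


def load_dataset(data_dir) -> InputBundle:
    """Load a dataset directory written by the simulator (or arranged to
    match its manifest layout)."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"{manifest_path} not found: run the simulate step first or "
            "provide a manifest describing the inputs"
        )
    manifest = json.loads(manifest_path.read_text())
    files = manifest["files"]
    genes = read_gene_models(data_dir / files["annotation"])
    methylomes = {
        sample: mc.Methylome.from_report(data_dir / rel)
        for sample, rel in sorted(files["methylation"].items())
    }
    return InputBundle(
        genes=genes,
        methylomes=methylomes,
        gene_fpkm_tissues=read_expression_table(data_dir / files["gene_fpkm_tissues"]),
        gene_fpkm_stages=read_expression_table(data_dir / files["gene_fpkm_stages"]),
        exon_fpkm=read_expression_table(data_dir / files["exon_fpkm_tissues"]),
        n_total_cpg=int(manifest["n_total_cpg"]),
    )


def _comparison_dict(c: ea.ComparisonResult) -> dict:
    return {
        "group_a": c.group_a,
        "group_b": c.group_b,
        "n_a": c.n_a,
        "n_b": c.n_b,
        "median_a": c.median_a,
        "median_b": c.median_b,
        "p_value": c.p_value,
        "direction": c.direction,
        "computable": c.computable,
    }


def quantify_stage(bundle: InputBundle, config: RunConfig) -> dict:
    """Genome summaries and per-gene methylation for every sample."""
    thresholds = dict(
        min_cov=config.min_cov,
        min_frac=config.min_frac,
        min_meth_reads=config.min_meth_reads,
    )
    summaries = {}
    gene_tables = {}
    for sample, methylome in bundle.methylomes.items():
        row = mc.genome_summary(
            sample, bundle.n_total_cpg, methylome=methylome, **thresholds
        )
        summaries[sample] = {
            "n_total_cpg": row.n_total_cpg,
            "n_covered": row.n_covered,
            "coverage_ratio": row.coverage_ratio,
            "n_mcpg": row.n_mcpg,
            "mcpg_ratio": row.mcpg_ratio,
        }
        rows = []
        for gene_id in sorted(bundle.genes):
            n_mcpg, level, is_meth = mc.gene_methylation(
                bundle.genes[gene_id],
                methylome,
                min_mcpg=config.gene_min_mcpg,
                **thresholds,
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_mcpg": n_mcpg,
                    "level": np.nan if level is None else level,
                    "is_methylated": is_meth,
                }
            )
        gene_tables[sample] = pd.DataFrame(rows)
    return {"genome_summary": summaries, "gene_methylation": gene_tables}


def _methylated_gene_sets(gene_tables: dict[str, pd.DataFrame], config: RunConfig):
    """Per-sample methylated gene id sets, their overlap, and the pooled
    methylated set after the gene-level >= ``gene_level_filter`` rule."""
    per_sample = {
        s: set(t.loc[t["is_methylated"], "gene_id"]) for s, t in gene_tables.items()
    }
    n_union, n_inter, frac = mc.gene_set_overlap(per_sample)

    # pooled methylated set: methylated in >=1 sample AND clearing the
    # gene-level filter in >=1 sample
    level_ok = set()
    for t in gene_tables.values():
        ok = t.loc[t["level"].notna() & (t["level"] >= config.gene_level_filter), "gene_id"]
        level_ok.update(ok)
    union = set.union(*per_sample.values())
    pooled = union & level_ok
    return per_sample, (n_union, n_inter, frac), pooled, len(union - level_ok)


def run_pipeline(config: RunConfig, bundle: InputBundle | None = None) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the report dict; files (JSON report, TSV/BED tables) are
    written under ``config.out_dir`` deterministically.
    """
    if bundle is None:
        bundle = load_dataset(config.data_dir)
    meth_samples = sorted(bundle.methylomes)
    tissues = list(bundle.gene_fpkm_tissues.columns)
    sample_to_tissue = config.sample_to_tissue or {
        s: tissues[i % len(tissues)] for i, s in enumerate(meth_samples)
    }
    missing = [s for s in meth_samples if s not in sample_to_tissue]
    if missing:
        raise ValueError(
            f"no expression sample mapped for methylation sample(s) {missing}"
        )
    bad = [t for t in sample_to_tissue.values() if t not in tissues]
    if bad:
        raise ValueError(f"expression samples not in table: {bad}")

    funnel: dict[str, int] = {"n_genes_annotated": len(bundle.genes)}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
    }
    tables: dict = {}

    # -- stage 1: genome summary + gene methylation -------------------------
    q = quantify_stage(bundle, config)
    report["genome_summary"] = q["genome_summary"]
    gene_tables = q["gene_methylation"]
    for sample, t in gene_tables.items():
        tables[f"gene_methylation_{sample}"] = t

    # -- stage 2: gene sets and overlap -------------------------------------
    per_sample_sets, (n_union, n_inter, frac), pooled_meth, n_below_filter = (
        _methylated_gene_sets(gene_tables, config)
    )
    funnel["n_genes_methylated_union"] = n_union
    funnel["n_genes_methylated_intersection"] = n_inter
    funnel["n_methylated_genes_below_level_filter"] = n_below_filter
    report["gene_sets"] = {
        "per_sample_methylated": {s: len(v) for s, v in per_sample_sets.items()},
        "n_union": n_union,
        "n_intersection": n_inter,
        "fraction_both": frac,
    }

    # -- stage 3: expression breadth ----------------------------------------
    all_genes = set(bundle.genes)
    unmeth_set = sorted(all_genes - set.union(*per_sample_sets.values()))
    meth_set = sorted(pooled_meth)
    breadth = {}
    for label, table in (
        ("tissues", bundle.gene_fpkm_tissues),
        ("stages", bundle.gene_fpkm_stages),
    ):
        bm, bu = st.breadth_comparison(
            meth_set, unmeth_set, table, threshold=config.breadth_thresh
        )
        breadth[label] = {
            "n_samples": table.shape[1],
            "methylated": {
                "n_genes": bm.n_genes,
                "counts": bm.counts.tolist(),
                "fraction_all": bm.fraction_all,
            },
            "unmethylated": {
                "n_genes": bu.n_genes,
                "counts": bu.counts.tolist(),
                "fraction_all": bu.fraction_all,
            },
        }
    report["expression_breadth"] = breadth

    # -- stage 4: exon classification + per-sample exon methylation ---------
    classification = ea.classify_exon_positions(bundle.genes.values())
    funnel["n_genes_lt3_exons_excluded"] = classification.n_genes_excluded
    funnel["n_genes_exon_analysis"] = classification.n_genes_included
    funnel["n_exon_records"] = len(classification.records)

    thresholds = dict(
        min_cov=config.min_cov,
        min_frac=config.min_frac,
        min_meth_reads=config.min_meth_reads,
    )
    exon_sections = {}
    profile_frames = []
    for sample in meth_samples:
        methylome = bundle.methylomes[sample]
        records = [copy.copy(r) for r in classification.records]
        for r in records:
            ea.exon_methylation_status(
                r, methylome, min_mcpg=config.exon_min_mcpg, **thresholds
            )

        # per-exon BED table
        tables[f"exon_methylation_{sample}"] = pd.DataFrame(
            {
                "chrom": [r.chrom for r in records],
                "start": [r.start for r in records],
                "end": [r.end for r in records],
                "name": [r.exon_id for r in records],
                "score": [
                    0 if r.meth.level is None else round(1000 * r.meth.level)
                    for r in records
                ],
                "strand": [r.strand for r in records],
                "position_class": [r.position_class for r in records],
                "level": [np.nan if r.meth.level is None else r.meth.level for r in records],
                "n_mcpg": [r.meth.n_mcpg for r in records],
            }
        )

        # exon analyses are restricted to the methylated gene set (called
        # methylated and clearing the gene-level filter in >=1 sample)
        meth_gene_records = [r for r in records if r.gene_id in pooled_meth]
        length_section = {
            cls: _comparison_dict(ea.compare_lengths_by_status(meth_gene_records, cls))
            for cls in ea.POSITION_CLASSES
        }

        # methylation level by positional class
        class_cmp = ea.compare_methylation_by_class(meth_gene_records)
        class_section = {
            f"{a}_vs_{b}": _comparison_dict(c) for (a, b), c in class_cmp.items()
        }
        medians = {}
        for cls in ea.POSITION_CLASSES:
            vals = [
                r.meth.level
                for r in meth_gene_records
                if r.position_class == cls and r.meth.has_data
            ]
            medians[cls] = float(np.median(vals)) if vals else None

        # inclusion + boundary profiles
        tissue = sample_to_tissue[sample]
        gene_t = gene_tables[sample].set_index("gene_id")
        n_not_eval = 0
        for r in records:
            exon_fpkm = (
                float(bundle.exon_fpkm.loc[r.exon_id, tissue])
                if r.exon_id in bundle.exon_fpkm.index
                else None
            )
            gene_fpkm = (
                float(bundle.gene_fpkm_tissues.loc[r.gene_id, tissue])
                if r.gene_id in bundle.gene_fpkm_tissues.index
                else None
            )
            glevel = gene_t.loc[r.gene_id, "level"] if r.gene_id in gene_t.index else None
            if glevel is not None and np.isnan(glevel):
                glevel = None
            status = ea.classify_inclusion(
                r,
                exon_fpkm,
                gene_fpkm,
                glevel,
                expr_thresh=config.expr_thresh,
                meth_thresh=config.gene_level_filter,
            )
            r.inclusion[sample] = status
            n_not_eval += status == ea.NOT_EVALUABLE
        funnel[f"n_exons_not_evaluable_{sample}"] = n_not_eval

        profiles = {}
        for cls in ea.POSITION_CLASSES:
            for group in (ea.INCLUDED, ea.SKIPPED):
                pm = ea.boundary_profile(
                    records, cls, group, methylome, sample=sample,
                    min_cov=config.min_cov,
                )
                frame = pm.to_frame()
                frame.insert(0, "sample", sample)
                profile_frames.append(frame)
                profiles[f"{cls}_{group}"] = {
                    "n_exons": pm.n_exons,
                    "start_level": [None if np.isnan(v) else v for v in pm.level("start")],
                    "end_level": [None if np.isnan(v) else v for v in pm.level("end")],
                }

        exon_sections[sample] = {
            "length_by_status": length_section,
            "class_medians": medians,
            "class_comparisons": class_section,
            "profiles": profiles,
        }

    report["exon_analysis"] = exon_sections
    report["funnel"] = funnel

    tables["boundary_profiles"] = pd.concat(profile_frames, ignore_index=True)
    tables["report"] = report
    written = write_result_tables(tables, config.out_dir)
    log.info("wrote %d result files to %s", len(written), config.out_dir)
    return report
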