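"""Seeded generator of cytosine reports, gene annotations and expression
tables with the statistical structure the downstream analyses assume.

The generator lays non-overlapping multi-exon genes on a linear genome,
scatters CpG sites at a fixed density, draws per-site coverage from a
floored Poisson and methylated read counts from a beta-binomial around
region-specific true levels, and draws per-sample FPKM values conditioned
on gene methylation status.  Ground truth (true levels, position classes,
inclusion labels) is recorded so parameter-recovery tests can compare the
pipeline's output against it.

Defaults encode the study conditions the analyses target: gene-body
methylation is bimodal (methylated genes at levels 0.1-0.3, an
unmethylated background at the bisulfite non-conversion scale), methylated
exons are longer, first exons are least methylated and internal exons most,
skipped internal exons are less methylated than included ones, and
methylated genes are expressed in more of the 8 tissues / 11 developmental
stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Transcript, write_cytosine_report, write_gtf

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "simulate_to_dir"]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated dataset.

    Levels are true methylation fractions in [0, 1]; lengths are in bp.
    """

    seed: int = 0
    n_genes: int = 2000
    # exon-count distribution over 1..len(weights); mode at 5 exons, with
    # explicit single- and two-exon classes the pipeline must exclude
    exons_per_gene_weights: tuple[float, ...] = (
        0.08, 0.07, 0.12, 0.18, 0.20, 0.15, 0.10, 0.06, 0.03, 0.01,
    )
    # exon length: N(mu_class + meth shift, sd), floored
    exon_len_mu: dict = field(
        default_factory=lambda: {"first": 250.0, "internal": 200.0, "last": 250.0}
    )
    exon_len_meth_shift: float = 100.0
    exon_len_sd: float = 50.0
    exon_len_min: int = 60
    intron_len_mu: float = 500.0
    intron_len_sd: float = 100.0
    intron_len_min: int = 150
    intergenic_len: int = 2000
    cpg_density: float = 0.04  # CpG sites per bp
    # true levels per (position class, inclusion group) for methylated genes
    levels_included: dict = field(
        default_factory=lambda: {"first": 0.10, "internal": 0.30, "last": 0.20}
    )
    levels_skipped: dict = field(
        default_factory=lambda: {"first": 0.05, "internal": 0.10, "last": 0.07}
    )
    intron_level_methylated: float = 0.25
    background_level: float = 0.002  # unmethylated genes + intergenic
    # flanking sequence within this distance of an exon boundary tracks the
    # exon's own level (local methylation domains extend past splice sites)
    flank_extent: int = 200
    boundary_delta: float = 0.05  # level elevation near exon boundaries
    boundary_width: int = 50  # bp on each side of a boundary
    coverage_mean: float = 20.0
    coverage_floor: int = 5
    bb_dispersion: float = 0.05  # beta-binomial rho; 0 = binomial
    p_gene_methylated: float = 0.5
    # within a methylated gene, each exon is itself methylated with a
    # class-dependent probability (first exons are hypomethylated near the
    # transcription start, internal exons most often methylated);
    # unmethylated exons sit at the background level and lack the
    # methylation-linked length shift.  A plain float applies to all classes.
    p_exon_methylated: dict | float = field(
        default_factory=lambda: {"first": 0.55, "internal": 0.80, "last": 0.65}
    )
    n_tissues: int = 8
    n_stages: int = 11
    n_meth_samples: int = 2  # methylation samples (e.g. two tissues)
    p_expr_methylated: float = 0.95
    p_expr_unmethylated: float = 0.5
    p_skip: float = 0.25  # per internal exon of a methylated expressed gene
    fpkm_log_mu: float = 1.5
    fpkm_log_sd: float = 0.7
    chrom: str = "sim1"

    def validate(self) -> None:
        probs = [
            self.p_gene_methylated,
            self.p_expr_methylated,
            self.p_expr_unmethylated,
            self.p_skip,
            self.background_level,
            self.intron_level_methylated,
            *self.levels_included.values(),
            *self.levels_skipped.values(),
        ]
        if isinstance(self.p_exon_methylated, dict):
            probs.extend(self.p_exon_methylated.values())
        else:
            probs.append(self.p_exon_methylated)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities and levels must lie in [0, 1]")
        if abs(sum(self.exons_per_gene_weights) - 1) > 1e-9:
            raise ValueError("exon-count weights must sum to 1")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: dict[str, GeneModel]
    calls: dict[str, pd.DataFrame]  # methylation sample -> cytosine report rows
    gene_expression: dict[str, pd.DataFrame]  # "tissues"/"stages" -> FPKM table
    exon_expression: pd.DataFrame  # exon FPKM over tissue samples
    truth_exons: pd.DataFrame
    truth_genes: pd.DataFrame
    n_total_cpg: int

    @property
    def tissue_samples(self) -> list[str]:
        return list(self.gene_expression["tissues"].columns)


def _beta_binomial(rng, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Counts ~ BetaBinomial(n, p, rho); rho -> 0 degenerates to binomial.

    Overdispersion models cell-to-cell variability of the methylated state,
    so it only applies where the true level is appreciably non-zero;
    background sites (non-conversion error scale) stay binomial — error
    reads are independent events.
    """
    p = np.clip(p, 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(n, p)
    s = (1.0 - rho) / rho  # a + b
    a = np.maximum(p * s, 1e-9)
    b = np.maximum((1.0 - p) * s, 1e-9)
    p_site = rng.beta(a, b)
    background = p < 0.01
    p_site = np.where(background, p, p_site)
    return rng.binomial(n, p_site)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset; identical config + seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes, truth_exon_rows, truth_gene_rows, genome_len = _layout_genes(config, rng)
    truth_exons = pd.DataFrame(truth_exon_rows)
    truth_genes = pd.DataFrame(truth_gene_rows)

    cpg_pos = np.flatnonzero(rng.random(genome_len) < config.cpg_density)
    true_level = _site_levels(config, cpg_pos, truth_exons, truth_genes)

    calls = {}
    for k in range(config.n_meth_samples):
        cov = np.maximum(
            rng.poisson(config.coverage_mean, cpg_pos.size), config.coverage_floor
        )
        n_meth = _beta_binomial(rng, cov, true_level, config.bb_dispersion)
        calls[f"meth_sample_{k + 1}"] = pd.DataFrame(
            {
                "chrom": config.chrom,
                "pos": cpg_pos + 1,  # report positions are 1-based
                "strand": "+",
                "n_meth": n_meth,
                "n_unmeth": cov - n_meth,
                "context": "CG",
            }
        )

    gene_expr, exon_expr = _expression(config, rng, truth_exons, truth_genes)

    return SimulatedDataset(
        config=config,
        genes=genes,
        calls=calls,
        gene_expression=gene_expr,
        exon_expression=exon_expr,
        truth_exons=pd.DataFrame(truth_exon_rows),
        truth_genes=pd.DataFrame(truth_gene_rows),
        n_total_cpg=int(cpg_pos.size),
    )


def _layout_genes(config: SimulationConfig, rng):
    """Place non-overlapping genes along the chromosome; record ground truth."""
    n_exon_choices = np.arange(1, len(config.exons_per_gene_weights) + 1)
    genes: dict[str, GeneModel] = {}
    truth_exon_rows: list[dict] = []
    truth_gene_rows: list[dict] = []
    cursor = config.intergenic_len
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        tid = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.choice(n_exon_choices, p=config.exons_per_gene_weights))
        gene_methylated = bool(rng.random() < config.p_gene_methylated)

        # classes in transcription order
        if n_exons == 1:
            classes = ["single"]
        elif n_exons == 2:
            classes = ["first2", "last2"]
        else:
            classes = ["first"] + ["internal"] * (n_exons - 2) + ["last"]

        # inclusion ground truth: internal exons of methylated genes may be
        # skipped; everything else constitutive
        inclusion = [
            "skipped"
            if (c == "internal" and gene_methylated and rng.random() < config.p_skip)
            else "included"
            for c in classes
        ]

        # exon methylation indicators; a methylated gene carries at least
        # one methylated exon (a gene with none would be unmethylated in
        # every operational sense)
        pem = config.p_exon_methylated
        if isinstance(pem, dict):
            p_per_exon = np.array(
                [
                    pem.get(c if c in pem else "internal", 0.0)
                    for c in classes
                ]
            )
        else:
            p_per_exon = np.full(n_exons, float(pem))
        if gene_methylated:
            while True:
                exon_meth_draws = rng.random(n_exons) < p_per_exon
                if exon_meth_draws.any():
                    break
        else:
            exon_meth_draws = np.zeros(n_exons, dtype=bool)

        lengths = []
        levels = []
        exon_meth = []
        for c, inc, em in zip(classes, inclusion, exon_meth_draws):
            key = c if c in config.exon_len_mu else "internal"
            em = bool(em)
            if em:
                table = (
                    config.levels_included if inc == "included" else config.levels_skipped
                )
                level = table.get(key, table["internal"])
                mu = config.exon_len_mu[key] + config.exon_len_meth_shift
            else:
                level = config.background_level
                mu = config.exon_len_mu[key]
            lengths.append(
                max(config.exon_len_min, int(round(rng.normal(mu, config.exon_len_sd))))
            )
            levels.append(level)
            exon_meth.append(em)

        introns = [
            max(
                config.intron_len_min,
                int(round(rng.normal(config.intron_len_mu, config.intron_len_sd))),
            )
            for _ in range(n_exons - 1)
        ]

        # build intervals 5'->3' then convert to genomic order
        ivals_tx = []
        pos = 0
        for i, L in enumerate(lengths):
            ivals_tx.append((pos, pos + L))
            pos += L + (introns[i] if i < len(introns) else 0)
        span = pos
        gstart = cursor
        if strand == "+":
            ivals = [(gstart + s, gstart + e) for s, e in ivals_tx]
        else:
            ivals = [(gstart + span - e, gstart + span - s) for s, e in ivals_tx]
        order = np.argsort([s for s, _ in ivals])
        genomic = [ivals[i] for i in order]

        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=config.chrom,
            strand=strand,
            transcripts=[Transcript(tid, genomic)],
            representative_transcript=tid,
        )
        for r, (s, e) in enumerate(ivals):
            truth_exon_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tid,
                    "rank": r + 1,
                    "position_class": classes[r],
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "gene_methylated": gene_methylated,
                    "exon_methylated": exon_meth[r],
                    "inclusion": inclusion[r],
                    "true_level": levels[r],
                }
            )
        truth_gene_rows.append(
            {
                "gene_id": gene_id,
                "strand": strand,
                "n_exons": n_exons,
                "start": gstart,
                "end": gstart + span,
                "methylated": gene_methylated,
            }
        )
        cursor = gstart + span + config.intergenic_len
    return genes, truth_exon_rows, truth_gene_rows, cursor


def _site_levels(
    config: SimulationConfig, cpg_pos: np.ndarray, truth_exons, truth_genes
) -> np.ndarray:
    """True methylation level per CpG site (exon / intron / intergenic),
    with boundary elevation near exon edges."""
    level = np.full(cpg_pos.size, config.background_level)

    # methylated-gene introns: within gene span, default intron level
    meth_genes = truth_genes[truth_genes["methylated"]]
    for row in meth_genes.itertuples(index=False):
        i = np.searchsorted(cpg_pos, row.start, side="left")
        j = np.searchsorted(cpg_pos, row.end, side="left")
        level[i:j] = config.intron_level_methylated

    # flanking sequence near each exon of a methylated gene tracks the
    # exon's level (methylation domains extend past the splice sites), then
    # exon bodies override everything
    ext = config.flank_extent
    meth_ids = set(truth_genes.loc[truth_genes["methylated"], "gene_id"])
    if ext > 0:
        for row in truth_exons.itertuples(index=False):
            if row.gene_id not in meth_ids:
                continue
            for lo, hi in ((row.start - ext, row.start), (row.end, row.end + ext)):
                i = np.searchsorted(cpg_pos, max(lo, 0), side="left")
                j = np.searchsorted(cpg_pos, hi, side="left")
                level[i:j] = row.true_level
    for row in truth_exons.itertuples(index=False):
        i = np.searchsorted(cpg_pos, row.start, side="left")
        j = np.searchsorted(cpg_pos, row.end, side="left")
        level[i:j] = row.true_level

    # boundary elevation around exon edges of methylated genes (an edge
    # effect of the methylated domain, absent from unmethylated genes)
    if config.boundary_delta > 0 and config.boundary_width > 0:
        w = config.boundary_width
        elevated = np.zeros(cpg_pos.size, dtype=bool)
        meth_exons = truth_exons[truth_exons["true_level"] > 0.05]
        bounds = np.concatenate(
            [meth_exons["start"].to_numpy(), meth_exons["end"].to_numpy()]
        )
        for b in bounds:
            i = np.searchsorted(cpg_pos, b - w, side="left")
            j = np.searchsorted(cpg_pos, b + w, side="left")
            elevated[i:j] = True
        level[elevated] = np.clip(level[elevated] + config.boundary_delta, 0, 1)
    return level


def _expression(config: SimulationConfig, rng, truth_exons, truth_genes):
    """Per-sample FPKM tables for genes (tissues + stages) and exons
    (tissues), plus inclusion structure.

    Expressed draws are 1 + LogNormal so they always clear the FPKM >= 1
    threshold; unexpressed draws are Uniform(0, 0.9).  Skipped exons get
    near-zero FPKM in every sample where the gene is expressed.
    """
    gene_ids = truth_genes["gene_id"].tolist()
    methylated = truth_genes["methylated"].to_numpy()
    p_expr = np.where(methylated, config.p_expr_methylated, config.p_expr_unmethylated)

    def gene_table(samples: list[str]) -> pd.DataFrame:
        vals = np.empty((len(gene_ids), len(samples)))
        expressed = rng.random(vals.shape) < p_expr[:, None]
        hi = 1.0 + rng.lognormal(config.fpkm_log_mu, config.fpkm_log_sd, vals.shape)
        lo = rng.uniform(0.0, 0.9, vals.shape)
        vals = np.where(expressed, hi, lo)
        return pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"), columns=samples)

    tissues = [f"tissue_{i + 1}" for i in range(config.n_tissues)]
    stages = [f"stage_{i + 1}" for i in range(config.n_stages)]
    gene_expr = {"tissues": gene_table(tissues), "stages": gene_table(stages)}

    # exon FPKM over tissue samples: included exons inherit the gene value,
    # skipped exons stay near zero
    gexpr = gene_expr["tissues"]
    exon_ids, rows = [], []
    for row in truth_exons.itertuples(index=False):
        exon_ids.append(f"{row.transcript_id}:exon{row.rank}")
        gv = gexpr.loc[row.gene_id].to_numpy()
        if row.inclusion == "included":
            vals = np.where(gv >= 1.0, gv * rng.uniform(0.8, 1.2, gv.size), gv)
        else:
            vals = rng.uniform(0.0, 0.2, gv.size)
        rows.append(vals)
    exon_expr = pd.DataFrame(
        np.vstack(rows), index=pd.Index(exon_ids, name="exon_id"), columns=tissues
    )
    return gene_expr, exon_expr


def simulate_to_dir(config: SimulationConfig, out_dir) -> dict:
    """Run the generator and write its outputs in the pipeline's input
    formats (cytosine reports, GTF, expression TSVs, ground-truth TSVs)
    plus a manifest.  Returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = simulate(config)

    write_gtf(ds.genes.values(), out_dir / "annotation.gtf")
    for sample, df in ds.calls.items():
        write_cytosine_report(df, out_dir / f"{sample}.cov.txt")
    ds.gene_expression["tissues"].to_csv(out_dir / "gene_fpkm_tissues.tsv", sep="\t")
    ds.gene_expression["stages"].to_csv(out_dir / "gene_fpkm_stages.tsv", sep="\t")
    ds.exon_expression.to_csv(out_dir / "exon_fpkm_tissues.tsv", sep="\t")
    ds.truth_exons.to_csv(out_dir / "truth_exons.tsv", sep="\t", index=False)
    ds.truth_genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "n_total_cpg": ds.n_total_cpg,
        "files": {
            "annotation": "annotation.gtf",
            "methylation": {s: f"{s}.cov.txt" for s in sorted(ds.calls)},
            "gene_fpkm_tissues": "gene_fpkm_tissues.tsv",
            "gene_fpkm_stages": "gene_fpkm_stages.tsv",
            "exon_fpkm_tissues": "exon_fpkm_tissues.tsv",
            "truth_exons": "truth_exons.tsv",
            "truth_genes": "truth_genes.tsv",
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
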