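#!/usr/bin/env python
"""Genome-wide summary and methylated-gene sets.

Reads results/analysis/report.json, prints the coverage/mCpG summary per
sample (the genome-summary table layout) and the two-sample methylated
gene-set overlap, and writes results/tables/genome_summary.tsv."""

import argparse
import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--report", type=Path, default=ROOT / "results" / "analysis" / "report.json")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    rep = json.loads(args.report.read_text())
    rows = []
    for sample, s in rep["genome_summary"].items():
        rows.append(
            {
                "sample": sample,
                "n_total_cpg": s["n_total_cpg"],
                "n_covered": s["n_covered"],
                "coverage_pct": round(100 * s["coverage_ratio"], 1),
                "n_mcpg": s["n_mcpg"],
                "mcpg_pct": round(100 * s["mcpg_ratio"], 1),
            }
        )
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "genome_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    gs = rep["gene_sets"]
    print(
        f"\nmethylated (>=2 mCpGs) in >=1 sample: {gs['n_union']} genes; "
        f"in both samples: {gs['n_intersection']} "
        f"({100 * gs['fraction_both']:.1f}% of the union)"
    )


if __name__ == "__main__":
    main()
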