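#!/usr/bin/env python
"""Exon length by methylation status and methylation level by exon class.

Reads the report and prints, per methylation sample: median lengths of
methylated vs unmethylated exons per positional class with rank-sum
p-values, and the pairwise class-level comparisons (first/internal/last).
Writes results/tables/exon_comparisons.tsv."""

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
    for sample, s in rep["exon_analysis"].items():
        print(f"== {sample}")
        for cls, c in s["length_by_status"].items():
            if not c["computable"]:
                print(f"  length ({cls}): not computable")
                continue
            rows.append({"sample": sample, "analysis": "length", "contrast": cls, **c})
            print(
                f"  length ({cls}): methylated median {c['median_a']:.0f} bp vs "
                f"unmethylated {c['median_b']:.0f} bp, p = {c['p_value']:.3g}"
            )
        med = s["class_medians"]
        order = sorted(med, key=lambda k: med[k])
        print(
            "  class levels: "
            + " < ".join(f"{k} ({med[k]:.3f})" for k in order)
        )
        for pair, c in s["class_comparisons"].items():
            rows.append({"sample": sample, "analysis": "class", "contrast": pair, **c})
            print(f"  {pair}: p = {c['p_value']:.3g} ({c['direction']})")
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "exon_comparisons.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
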