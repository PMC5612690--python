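#!/usr/bin/env python
"""Expression breadth of methylated vs unmethylated genes.

Reads the report, prints the share of each group expressed (FPKM > 1) in
every tissue / developmental stage, and writes the stacked-bar histogram
table plus a figure."""

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
    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, b in rep["expression_breadth"].items():
        for group in ("methylated", "unmethylated"):
            g = b[group]
            for breadth, count in enumerate(g["counts"]):
                rows.append(
                    {
                        "panel": label,
                        "group": group,
                        "breadth": breadth,
                        "n_genes": count,
                    }
                )
            print(
                f"{label}: {100 * g['fraction_all']:.1f}% of {group} genes "
                f"(n={g['n_genes']}) expressed in all {b['n_samples']} samples"
            )
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "expression_breadth.tsv", sep="\t", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, (label, sub) in zip(axes, df.groupby("panel")):
            pivot = sub.pivot(index="breadth", columns="group", values="n_genes")
            frac = pivot / pivot.sum()
            frac.plot.bar(ax=ax, width=0.8)
            ax.set_title(f"expression breadth ({label})")
            ax.set_ylabel("fraction of genes")
        fig.tight_layout()
        fig.savefig(args.out / "expression_breadth.png", dpi=120)
        print(f"figure -> {args.out / 'expression_breadth.png'}")
    except Exception as exc:  # plotting is best-effort
        print(f"(skipped figure: {exc})")


if __name__ == "__main__":
    main()
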