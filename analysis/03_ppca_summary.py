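#!/usr/bin/env python
"""Summarise the phylogenetic PCA: variance explained and PC-score models.

Reads the PPCA outputs of 02 and prints, per trait subset, the percent
variance of the leading components and the best-fitting factorial model
for every retained PC (components explaining >= 20% of total variance).
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results" / "analysis")
    args = ap.parse_args()
    for tag in ("all", "structural", "physiological", "niche"):
        var = pd.read_csv(args.results / f"ppca_{tag}_variance.tsv", sep="\t", index_col=0)
        lead = ", ".join(
            f"{pc} {v:.0f}%" for pc, v in var["percent_variance"].head(3).items()
        )
        print(f"{tag:>13s} traits: {lead}")
    for name in ("table_trait_pcs.tsv", "table_niche_pcs.tsv"):
        path = args.results / name
        if path.exists():
            table = pd.read_csv(path, sep="\t")
            print(f"\nretained PC models ({name}):")
            print(table[["response", "evidence_ratio", "best_model", "lambda_best"]]
                  .to_string(index=False))


if __name__ == "__main__":
    main()
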