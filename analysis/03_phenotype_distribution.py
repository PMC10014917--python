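#!/usr/bin/env python
"""Phenotype distribution and actionability of the cohort's called
diplotypes under the CPIC rules.

Prints the modal diplotype frequency, the metabolizer category breakdown
and the non-actionable fraction; writes results/phenotypes.tsv.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/run"))
parser.add_argument("--out", type=Path, default=Path("results/phenotypes.tsv"))
args = parser.parse_args()

calls = pd.read_csv(args.run / "calls.tsv", sep="\t").set_index("sample")
n = len(calls)

majors = calls["diplotype_major"].value_counts()
print(f"modal diplotype: {majors.index[0]} ({100 * majors.iloc[0] / n:.0f}%)")

dist = Counter(calls["phenotype"])
for cat in ("PM", "IM", "NM", "RM", "UM"):
    print(f"  {cat}: {dist.get(cat, 0):2d} ({100 * dist.get(cat, 0) / n:.0f}%)")

non_actionable = (~calls["actionable"]).sum()
print(f"samples without actionable findings: {non_actionable}/{n} "
      f"({100 * non_actionable / n:.1f}%)")

calls[["diplotype_minor", "diplotype_major", "phenotype", "actionable"]].to_csv(
    args.out, sep="\t"
)
print(f"wrote {args.out}")
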