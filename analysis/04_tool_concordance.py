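#!/usr/bin/env python
"""Concordance between the manually curated calls and the three star-allele
tools, on the bundled verbatim 37-sample call table.

Scores minor-exact and major-level agreement (and, for the caller that
emits ranked output, first-listed vs any-listed), plus phenotype-level
agreement; also reports the fraction of samples on which all three tools
and the manual call agree at major level (first-listed).  Writes
results/concordance.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from phasestar.concordance import (
    agreement,
    load_table2_calls,
    normalize_diplotype,
    parse_cell,
    phenotype_concordance,
)

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/concordance.tsv"))
args = parser.parse_args()

calls = load_table2_calls()
m = calls["manual"]
rows = []
for tool in ("aldy", "pharmaku", "pharmcat"):
    for level in ("minor_exact", "major"):
        r = agreement(m, calls[tool], level=level, label=tool)
        rows.append((tool, r.level, r.n_agree, r.n_total, round(r.percent, 1)))
    if tool == "pharmcat":
        r = agreement(m, calls[tool], level="major", any_listed=True, label=tool)
        rows.append((tool, r.level, r.n_agree, r.n_total, round(r.percent, 1)))
    if tool != "pharmcat":  # no phenotypes printed for PharmCat
        r = phenotype_concordance(m, calls[tool], label=tool)
        rows.append((tool, r.level, r.n_agree, r.n_total, round(r.percent, 1)))

df = pd.DataFrame(rows, columns=["tool", "level", "n_agree", "n_total", "percent"])
print(df.to_string(index=False))

# all-tools agreement at major level, first-listed calls only
all_agree = 0
for sid in calls.index:
    ref = normalize_diplotype(parse_cell(calls.loc[sid, "manual"]).ranked[0], "major")
    toks = [
        normalize_diplotype(parse_cell(calls.loc[sid, t]).ranked[0], "major")
        for t in ("aldy", "pharmaku", "pharmcat")
    ]
    all_agree += all(t == ref for t in toks)
print(f"\nall tools + manual agree (major, first-listed): "
      f"{all_agree}/{len(calls)} ({100 * all_agree / len(calls):.1f}%)")

args.out.parent.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out, sep="\t", index=False)
print(f"wrote {args.out}")
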