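#!/usr/bin/env python
"""Run the full calling pipeline on the simulated cohort and verify that
every truth diplotype is recovered at the suballele (minor) level.

Writes per-sample calls, phasing statistics and the novel-suballele
candidate list under results/run/; prints the recovery rate and the
candidate novel suballeles (the *38.003 + g.94781616A>G carriers).
"""

import argparse
from pathlib import Path

import pandas as pd

from phasestar.interfaces import RunConfig, run_full_analysis

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

bundle = run_full_analysis(
    RunConfig(
        vcf=args.cohort / "cohort.vcf",
        coverage=args.cohort / "coverage.tsv",
        out_dir=args.out,
    )
)
truth = pd.read_csv(args.cohort / "truth.tsv", sep="\t", dtype=str).set_index("sample")
calls = pd.read_csv(args.out / "calls.tsv", sep="\t", dtype=str).set_index("sample")
recovered = (calls["diplotype_minor"] == truth["diplotype"]).sum()
print(f"minor-level recovery: {recovered}/{len(truth)}")
confident = [n for n in bundle["novel_suballeles"] if n["confident"]]
print(f"confident novel-suballele candidates: {len(confident)}")
for n in confident:
    print(f"  sample {n['sample']}: {n['candidate']}")
print(f"mean phased fraction: {bundle['phasing']['mean_pct']}%")
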