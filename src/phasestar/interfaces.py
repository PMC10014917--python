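"""End-to-end analysis driver: QC -> ingest -> restrict -> phasing stats ->
variant catalog -> diplotype calling -> phenotypes -> (optional)
concordance, with per-stage TSV/JSON outputs and a rendered text report.

Machine-readable outputs go to files; log text goes to stderr via
``logging`` so the two never interleave.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allele_definitions import AlleleDefinitionTable, bundled_cyp2c19_table, load_allele_table
from .concordance import agreement, phenotype_concordance
from .phasing_metrics import cohort_phasing_summary, phasing_stats
from .phenotype_translation import (
    FunctionMap,
    assign_phenotype,
    cohort_phenotype_distribution,
    load_phenotype_rules,
)
from .star_caller import (
    CallingPolicy,
    call_diplotype,
    detect_novel_suballeles,
    render_diplotype,
)
from .variant_catalog import AnnotationConfig, catalog_report, read_annotation_tsv
from .vcf_ingest import (
    CYP2C19_REGION,
    GeneRegion,
    QcPolicy,
    read_coverage_tsv,
    read_phased_vcf,
    restrict_to_region,
    sample_qc_filter,
)

logger = logging.getLogger("phasestar")

__all__ = ["RunConfig", "run_full_analysis", "render_report"]


@dataclass
class RunConfig:
    vcf: Path
    out_dir: Path
    definitions: Path | None = None  # bundled CYP2C19 table when None
    annotations: Path | None = None
    coverage: Path | None = None
    region: GeneRegion = CYP2C19_REGION
    include_flanks: bool = True
    qc: QcPolicy = field(default_factory=QcPolicy)
    calling: CallingPolicy = field(default_factory=CallingPolicy)
    annotation_config: AnnotationConfig = field(default_factory=AnnotationConfig)
    guideline: str = "CPIC"
    compare_tables: dict[str, Path] = field(default_factory=dict)  # label -> calls TSV

    def validate(self) -> None:
        for label, p in [("vcf", self.vcf), ("definitions", self.definitions),
                         ("annotations", self.annotations), ("coverage", self.coverage)]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"[config] {label} file not found: {p}")


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the pipeline; write per-stage outputs under ``config.out_dir``
    and return the report bundle as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"version": __version__, "guideline": config.guideline,
                    "policy": {"missing_mode": config.calling.missing_mode}}

    table = (
        load_allele_table(config.definitions)
        if config.definitions is not None
        else bundled_cyp2c19_table()
    )

    # stage: sample QC
    if config.coverage is not None:
        coverage = read_coverage_tsv(config.coverage)
        retained, excluded = sample_qc_filter(coverage, config.qc)
        bundle["qc"] = {"retained": sorted(retained), "excluded": sorted(excluded)}
        logger.info("QC: %d retained, %d excluded", len(retained), len(excluded))
    else:
        retained = None
        bundle["qc"] = {"retained": None, "excluded": []}

    # stage: ingest + region restriction
    try:
        callsets = read_phased_vcf(config.vcf, samples=retained)
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc
    callsets = [restrict_to_region(cs, config.region, config.include_flanks) for cs in callsets]
    if not callsets:
        logger.warning("no samples after QC/ingest")
    bundle["n_samples"] = len(callsets)

    # stage: phasing statistics
    stats = [phasing_stats(cs) for cs in callsets]
    phasing_df = pd.DataFrame(
        {
            "sample": s.sample_id,
            "n_het": s.n_het,
            "phased_fraction": round(s.phased_fraction, 1) if s.defined else "NA",
            "n_blocks": s.n_blocks,
            "mean_span": (sum(sp for _, sp in s.block_spans) / s.n_blocks) if s.n_blocks else "NA",
        }
        for s in stats
    )
    phasing_df.to_csv(out / "phasing.tsv", sep="\t", index=False)
    defined = [s for s in stats if s.defined]
    bundle["phasing"] = (
        {
            "mean_pct": round(cohort_phasing_summary(stats).mean_pct, 1),
            "min_pct": round(cohort_phasing_summary(stats).min_pct, 1),
            "max_pct": round(cohort_phasing_summary(stats).max_pct, 1),
            "n_undefined": len(stats) - len(defined),
        }
        if defined
        else {"mean_pct": None, "n_undefined": len(stats)}
    )

    # stage: variant catalog
    if callsets:
        annotations = read_annotation_tsv(config.annotations) if config.annotations else None
        bundle["catalog"] = catalog_report(callsets, table, annotations, config.annotation_config)
    else:
        bundle["catalog"] = {}

    # stage: diplotype calling + phenotype translation
    fmap = FunctionMap.from_table(table, guideline=config.guideline)
    rules = load_phenotype_rules()
    calls_rows = []
    assignments = []
    novel_rows = []
    for cs in callsets:
        call = call_diplotype(cs, table, config.calling)
        novel = detect_novel_suballeles(call, table)
        majors = (call.primary.a.major, call.primary.b.major)
        pheno = assign_phenotype(
            majors, fmap, rules, sample_id=cs.sample_id,
            carries_extras=bool(call.primary.a.extras or call.primary.b.extras),
        )
        assignments.append(pheno)
        calls_rows.append(
            {
                "sample": cs.sample_id,
                "diplotype_minor": render_diplotype(call.primary),
                "diplotype_major": "/".join(sorted(majors)),
                "phenotype": pheno.phenotype,
                "actionable": pheno.actionable,
                "alternatives": ";".join(c.token() for c in call.alternatives),
                "novel_suballele_candidates": ";".join(
                    n.descriptor for n in novel if n.confident
                ),
                "unconfirmed_candidates": ";".join(
                    n.descriptor for n in novel if not n.confident
                ),
                "phase_supported": call.primary.a.phase_supported and call.primary.b.phase_supported,
                "truncated": call.truncated,
            }
        )
        for n in novel:
            novel_rows.append({"sample": cs.sample_id, "candidate": n.descriptor, "confident": n.confident})
    calls_df = pd.DataFrame(calls_rows)
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    bundle["calls"] = calls_rows
    bundle["novel_suballeles"] = novel_rows
    bundle["phenotype_distribution"] = (
        cohort_phenotype_distribution(assignments) if assignments else {}
    )

    # stage: optional concordance against external call tables
    concordance_rows = []
    if config.compare_tables and calls_rows:
        reference = {r["sample"]: r["diplotype_minor"] for r in calls_rows}
        for label, path in config.compare_tables.items():
            col = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("sample").iloc[:, 0]
            for level in ("minor_exact", "major"):
                res = agreement(reference, col, level=level, label=label)
                concordance_rows.append(
                    {"tool": label, "level": level, "n_agree": res.n_agree,
                     "n_total": res.n_total, "percent": round(res.percent, 1)}
                )
    bundle["concordance"] = concordance_rows
    if concordance_rows:
        pd.DataFrame(concordance_rows).to_csv(out / "concordance.tsv", sep="\t", index=False)

    (out / "report.json").write_text(json.dumps(bundle, indent=1, default=str) + "\n", encoding="utf-8")
    (out / "report.md").write_text(render_report(bundle), encoding="utf-8")
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable markdown summary, numbers identical to the TSVs."""
    lines = [f"# phasestar report (v{bundle['version']})", ""]
    qc = bundle.get("qc", {})
    lines += ["## Sample QC",
              f"- retained: {len(qc['retained']) if qc.get('retained') is not None else 'all (no coverage table)'}",
              f"- excluded: {len(qc.get('excluded', []))}", ""]
    ph = bundle.get("phasing", {})
    lines += ["## Phasing",
              f"- mean phased fraction: {ph.get('mean_pct')}%"
              f" (range {ph.get('min_pct')}-{ph.get('max_pct')}%)"
              if ph.get("mean_pct") is not None else "- no sample with >=1 het call",
              f"- samples with undefined fraction: {ph.get('n_undefined', 0)}", ""]
    cat = bundle.get("catalog", {})
    if cat:
        lines += ["## Variant catalog"] + [f"- {k}: {v}" for k, v in cat.items()] + [""]
    dist = bundle.get("phenotype_distribution", {})
    if dist:
        lines += ["## Phenotype distribution"]
        for cat_name, rec in dist.items():
            lines.append(f"- {cat_name}: {rec['count']} ({rec['percent']}%)")
        lines.append("")
    novel = [n for n in bundle.get("novel_suballeles", []) if n["confident"]]
    if novel:
        lines += ["## Candidate novel suballeles"]
        for n in novel:
            lines.append(f"- {n['sample']}: {n['candidate']}")
        lines.append("")
    if bundle.get("concordance"):
        lines += ["## Concordance"]
        for row in bundle["concordance"]:
            lines.append(
                f"- {row['tool']} @ {row['level']}: {row['n_agree']}/{row['n_total']} ({row['percent']}%)"
            )
        lines.append("")
    return "\n".join(lines)
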