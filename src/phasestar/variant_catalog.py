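"""Cohort-level variant characterization.

Known/novel flagging against the star-allele nomenclature (plus an optional
extra clinical panel), singleton counting over carrier samples, and
impact classing from CADD scores supplied as an annotation table.  "Novel"
here means "not part of current pharmacogenomic nomenclature", not "absent
from population databases".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .allele_definitions import AlleleDefinitionTable, VariantKey
from .vcf_ingest import SampleCallSet

__all__ = [
    "VariantAnnotation",
    "AnnotationConfig",
    "flag_known",
    "count_singletons",
    "classify_impact",
    "consequence_breakdown",
    "read_annotation_tsv",
    "catalog_report",
]

CONSEQUENCE_CLASSES = (
    "upstream", "downstream", "intronic", "synonymous", "missense", "splice-site",
)


@dataclass(frozen=True)
class VariantAnnotation:
    variant: VariantKey
    cadd: float | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"negative CADD score for {self.variant}")


@dataclass(frozen=True)
class AnnotationConfig:
    """CADD cut-off for flagging high-impact candidates (default >10)."""

    cadd_threshold: float = 10.0
    threshold_mode: str = "strict_greater"  # or "greater_or_equal"

    def __post_init__(self) -> None:
        if self.cadd_threshold <= 0:
            raise ValueError("cadd_threshold must be positive")
        if self.threshold_mode not in ("strict_greater", "greater_or_equal"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def flag_known(
    variants: Iterable[VariantKey],
    nomenclature: AlleleDefinitionTable,
    extra_panel: Iterable[VariantKey] | None = None,
) -> dict[VariantKey, bool]:
    """known iff the variant appears in the nomenclature or the extra panel."""
    panel = set(nomenclature.variant_universe) | set(extra_panel or ())
    return {v: v in panel for v in variants}


def count_singletons(
    cohort_calls: list[SampleCallSet],
) -> tuple[int, int, dict[VariantKey, int]]:
    """(n_unique, n_singletons, per-variant carrier counts).

    A carrier is a sample with any non-hom-ref genotype for the variant;
    a singleton is carried by exactly one sample (regardless of zygosity).
    """
    if not cohort_calls:
        raise ValueError("empty cohort")
    carriers: dict[VariantKey, int] = {}
    for cs in cohort_calls:
        for c in cs.calls:
            if c.zygosity != "hom_ref":
                carriers[c.variant] = carriers.get(c.variant, 0) + 1
    n_singletons = sum(1 for n in carriers.values() if n == 1)
    return len(carriers), n_singletons, carriers


def classify_impact(ann: VariantAnnotation, config: AnnotationConfig = AnnotationConfig()) -> str:
    """-> 'high_impact_candidate' | 'below_threshold' | 'unscored'."""
    if ann.cadd is None:
        return "unscored"
    if config.threshold_mode == "strict_greater":
        high = ann.cadd > config.cadd_threshold
    else:
        high = ann.cadd >= config.cadd_threshold
    return "high_impact_candidate" if high else "below_threshold"


def consequence_breakdown(
    annotations: list[VariantAnnotation],
    known_flags: Mapping[VariantKey, bool],
) -> pd.DataFrame:
    """Cross-tabulate consequence class x known/novel (counts)."""
    if not annotations:
        return pd.DataFrame(columns=["known", "novel"])
    rows = [
        {
            "consequence": a.consequence or "unannotated",
            "status": "known" if known_flags.get(a.variant, False) else "novel",
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows)
    tab = df.groupby(["consequence", "status"]).size().unstack(fill_value=0)
    for col in ("known", "novel"):
        if col not in tab.columns:
            tab[col] = 0
    return tab[["known", "novel"]]


def read_annotation_tsv(path: str | Path) -> list[VariantAnnotation]:
    """Read ``chrom pos ref alt cadd consequence`` (tab-separated, header)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for rec in df.itertuples(index=False):
        cadd = None if pd.isna(rec.cadd) else float(rec.cadd)
        cons = None if pd.isna(rec.consequence) else str(rec.consequence)
        out.append(
            VariantAnnotation(
                variant=VariantKey(str(rec.chrom), int(rec.pos), rec.ref, rec.alt),
                cadd=cadd,
                consequence=cons,
            )
        )
    return out


def catalog_report(
    cohort_calls: list[SampleCallSet],
    nomenclature: AlleleDefinitionTable,
    annotations: list[VariantAnnotation] | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> dict[str, int]:
    """Per-gene summary counts for the catalog stage."""
    n_unique, n_singletons, carriers = count_singletons(cohort_calls)
    flags = flag_known(carriers.keys(), nomenclature)
    n_known = sum(flags.values())
    n_high = 0
    if annotations:
        by_var = {a.variant: a for a in annotations}
        n_high = sum(
            1
            for v in carriers
            if v in by_var and classify_impact(by_var[v], config) == "high_impact_candidate"
        )
    return {
        "n_unique": n_unique,
        "n_known": n_known,
        "n_novel": n_unique - n_known,
        "n_singletons": n_singletons,
        "n_high_impact": n_high,
    }
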