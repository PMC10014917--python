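"""Diplotype-to-phenotype translation under CPIC or DPWG rules.

Each major star allele carries a function class (normal, decreased,
no_function, increased, unknown); an unordered pair of function classes is
looked up in a guideline-specific combination table bundled as editable
YAML (``data/phenotype_rules.yaml``).  CPIC uses five metabolizer
categories (PM/IM/NM/RM/UM); DPWG lacks RM, and the increased+normal
combination is reported NM with a carrier annotation.  Combinations absent
from the table map to an explicit "indeterminate", never a silent default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .allele_definitions import AlleleDefinitionTable

__all__ = [
    "FunctionMap",
    "PhenotypeAssignment",
    "load_phenotype_rules",
    "assign_phenotype",
    "cohort_phenotype_distribution",
]

CPIC_CATEGORIES = ("PM", "IM", "NM", "RM", "UM")


@dataclass(frozen=True)
class FunctionMap:
    """major allele -> function class, for one gene under one guideline."""

    gene: str
    functions: tuple[tuple[str, str], ...]
    guideline: str = "CPIC"

    @classmethod
    def from_table(cls, table: AlleleDefinitionTable, guideline: str = "CPIC") -> "FunctionMap":
        return cls(
            gene=table.gene,
            functions=tuple((m, table.function_of(m)) for m in table.majors()),
            guideline=guideline,
        )

    def function_of(self, major: str) -> str:
        for m, f in self.functions:
            if m == major:
                return f
        raise KeyError(f"no function entry for major allele {major}")


@dataclass(frozen=True)
class PhenotypeAssignment:
    sample_id: str
    diplotype: tuple[str, str]  # major-level, sorted
    phenotype: str
    guideline: str
    actionable: bool
    annotation: str | None = None


def load_phenotype_rules(path: str | Path | None = None) -> dict:
    """Load the guideline rule tables (bundled YAML by default)."""
    if path is None:
        ref = resources.files("phasestar.data").joinpath("phenotype_rules.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def assign_phenotype(
    diplotype: tuple[str, str],
    fmap: FunctionMap,
    rules: dict | None = None,
    sample_id: str = "",
    carries_extras: bool = False,
) -> PhenotypeAssignment:
    """Translate a major-level diplotype into a metabolizer category.

    Order-invariant in the two alleles.  ``carries_extras`` marks samples
    whose call included variants beyond the catalogued definitions (e.g. a
    candidate novel suballele); such findings count as actionable even when
    the category itself is NM.
    """
    rules = rules if rules is not None else load_phenotype_rules()
    guideline = rules[fmap.guideline]
    f1, f2 = fmap.function_of(diplotype[0]), fmap.function_of(diplotype[1])
    key = "|".join(sorted((f1, f2)))
    phenotype = guideline["combinations"].get(key, "indeterminate")
    annotation = guideline.get("annotations", {}).get(key)
    actionable = (
        phenotype not in ("NM",)
        or f1 != "normal"
        or f2 != "normal"
        or carries_extras
    )
    return PhenotypeAssignment(
        sample_id=sample_id,
        diplotype=tuple(sorted(diplotype)),  # type: ignore[arg-type]
        phenotype=phenotype,
        guideline=fmap.guideline,
        actionable=actionable,
        annotation=annotation,
    )


def cohort_phenotype_distribution(
    assignments: list[PhenotypeAssignment],
) -> dict[str, dict[str, float]]:
    """Counts, exact percentages (0.1 precision) and display-rounded integers
    per category, over all categories of the assignments' guideline(s)."""
    if not assignments:
        raise ValueError("no assignments")
    n = len(assignments)
    counts = Counter(a.phenotype for a in assignments)
    categories = list(CPIC_CATEGORIES)
    for cat in counts:
        if cat not in categories:
            categories.append(cat)
    return {
        cat: {
            "count": counts.get(cat, 0),
            "percent": round(100.0 * counts.get(cat, 0) / n, 1),
            "percent_display": round(100.0 * counts.get(cat, 0) / n),
        }
        for cat in categories
    }
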