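"""Per-sample and cohort read-backed phasing statistics.

A heterozygous variant counts as "phased to its allele of origin" when it
sits in a phase block (shared PS tag) together with at least one other
heterozygous variant — a solitary phased call carries no relative phase
information.  Homozygous calls need no phasing and are excluded from the
default denominator; an all-variants denominator (hom calls counted as
trivially phased) is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .vcf_ingest import GeneRegion, SampleCallSet, restrict_to_region

__all__ = ["PhasingStats", "phasing_stats", "cohort_phasing_summary", "CohortPhasingSummary"]


@dataclass(frozen=True)
class PhasingStats:
    sample_id: str
    n_het: int
    n_phased_with_partner: int
    phased_fraction: float  # percent; NaN when undefined
    block_spans: tuple[tuple[int, int], ...]  # (phase_set, span in bp)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.phased_fraction)

    @property
    def n_blocks(self) -> int:
        return len(self.block_spans)


def phasing_stats(
    callset: SampleCallSet,
    region: GeneRegion | None = None,
    include_flanks: bool = True,
    denominator: str = "het",
) -> PhasingStats:
    """Compute phasing statistics for one sample.

    denominator="het" divides by heterozygous calls only (default);
    "all" divides by all non-hom-ref calls, counting homozygous calls as
    trivially phased.
    """
    if region is not None:
        callset = restrict_to_region(callset, region, include_flanks)
    hets = callset.het_calls
    blocks = callset.phase_blocks
    partnered_blocks = {ps: cs for ps, cs in blocks.items() if len(cs) >= 2}
    n_partnered = sum(len(cs) for cs in partnered_blocks.values())
    spans = tuple(
        (ps, max(c.variant.pos + len(c.variant.ref) - 1 for c in cs) - min(c.variant.pos for c in cs))
        for ps, cs in sorted(partnered_blocks.items())
    )
    if denominator == "het":
        num, den = n_partnered, len(hets)
    elif denominator == "all":
        n_hom_alt = sum(1 for c in callset.calls if c.zygosity == "hom_alt")
        num, den = n_partnered + n_hom_alt, len(hets) + n_hom_alt
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    fraction = 100.0 * num / den if den > 0 else float("nan")
    return PhasingStats(
        sample_id=callset.sample_id,
        n_het=len(hets),
        n_phased_with_partner=n_partnered,
        phased_fraction=fraction,
        block_spans=spans,
    )


@dataclass(frozen=True)
class CohortPhasingSummary:
    n_samples: int
    n_undefined: int
    mean_pct: float
    min_pct: float
    max_pct: float
    mean_block_span: float
    span_range: tuple[float, float]


def cohort_phasing_summary(stats: list[PhasingStats]) -> CohortPhasingSummary:
    """Cohort averages over samples with a defined phased fraction."""
    if not stats:
        raise ValueError("empty cohort")
    defined = [s for s in stats if s.defined]
    if not defined:
        raise ValueError("no sample has a defined phased fraction")
    fractions = [s.phased_fraction for s in defined]
    spans = [span for s in stats for (_, span) in s.block_spans]
    return CohortPhasingSummary(
        n_samples=len(stats),
        n_undefined=len(stats) - len(defined),
        mean_pct=sum(fractions) / len(fractions),
        min_pct=min(fractions),
        max_pct=max(fractions),
        mean_block_span=(sum(spans) / len(spans)) if spans else float("nan"),
        span_range=(min(spans), max(spans)) if spans else (float("nan"), float("nan")),
    )
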