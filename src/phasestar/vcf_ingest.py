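"""Phased-VCF ingestion, gene-region restriction and sample-level QC.

Reads WhatsHap-style phased VCFs (GT with ``|`` separators plus PS
phase-set FORMAT tags) into per-sample call sets.  Homozygous-reference
records are dropped from the call list but their positions are retained as
"observed reference", so downstream haplotype matching can distinguish a
position assayed as wildtype from one that is simply missing — the
distinction at the heart of the PharmCat-style missing-position ambiguity.

Coordinates are 1-based VCF positions throughout the package; BED input
(0-based half-open) is converted at the boundary by :func:`read_bed_regions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .allele_definitions import VariantKey

__all__ = [
    "GenotypeCall",
    "SampleCallSet",
    "QcPolicy",
    "GeneRegion",
    "CYP2C19_REGION",
    "read_phased_vcf",
    "restrict_to_region",
    "sample_qc_filter",
    "read_coverage_tsv",
    "read_bed_regions",
    "VcfIngestError",
]


class VcfIngestError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeCall:
    """One decomposed genotype call for one sample.

    ``alleles`` is the ordered pair of allele indices relative to this
    biallelic decomposition (0 = reference, 1 = this alt).  The order is
    meaningful only when ``phased`` is true, where it encodes the strand
    orientation within the phase set.
    """

    variant: VariantKey
    alleles: tuple[int, int]
    phased: bool
    phase_set: int | None = None

    def __post_init__(self) -> None:
        if self.phased and self.zygosity == "het" and self.phase_set is None:
            raise VcfIngestError(
                f"phased het call at {self.variant} lacks a phase set"
            )

    @property
    def zygosity(self) -> str:
        a, b = self.alleles
        if a == 0 and b == 0:
            return "hom_ref"
        if a == b:
            return "hom_alt"
        return "het"


@dataclass
class SampleCallSet:
    sample_id: str
    calls: list[GenotypeCall]
    observed_ref_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: (c.variant.pos, c.variant.ref, c.variant.alt))
        seen = set()
        for c in self.calls:
            if c.variant in seen:
                raise VcfIngestError(
                    f"{self.sample_id}: duplicate call for {c.variant}"
                )
            seen.add(c.variant)

    @property
    def het_calls(self) -> list[GenotypeCall]:
        return [c for c in self.calls if c.zygosity == "het"]

    @property
    def phase_blocks(self) -> dict[int, list[GenotypeCall]]:
        """Phase-set id -> phased het calls in that block, by position."""
        blocks: dict[int, list[GenotypeCall]] = {}
        for c in self.het_calls:
            if c.phased and c.phase_set is not None:
                blocks.setdefault(c.phase_set, []).append(c)
        return blocks


@dataclass(frozen=True)
class QcPolicy:
    """Sample exclusion rule: drop samples with *less than* ``min_fraction``
    of target bases covered to at least ``depth_threshold``."""

    min_fraction: float = 0.10
    depth_threshold: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.depth_threshold <= 0:
            raise ValueError("depth_threshold must be positive")


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    flank: int = 10_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    def span(self, include_flanks: bool = True) -> tuple[int, int]:
        if include_flanks:
            return (max(1, self.start - self.flank), self.end + self.flank)
        return (self.start, self.end)

    def contains(self, pos: int, include_flanks: bool = True) -> bool:
        lo, hi = self.span(include_flanks)
        return lo <= pos <= hi


#: CYP2C19 gene body on GRCh38 chromosome 10 (NC_000010.11), with the
#: capture panel's ~10 kb up/downstream flanks as the default.
CYP2C19_REGION = GeneRegion(gene="CYP2C19", chrom="10", start=94_762_681, end=94_855_547)


def read_phased_vcf(
    path: str | Path, samples: Sequence[str] | None = None
) -> list[SampleCallSet]:
    """Read a (multi-sample) VCF into one :class:`SampleCallSet` per sample.

    Multiallelic records are decomposed into one biallelic call per alt
    allele.  ``./.`` genotypes are treated as missing (neither called nor
    observed reference); ``0|0``/``0/0`` genotypes contribute the position
    to ``observed_ref_positions`` only.
    """
    vcf = pysam.VariantFile(str(path))
    available = list(vcf.header.samples)
    if not available:
        raise VcfIngestError(f"{path}: VCF has no samples")
    if samples is None:
        samples = available
    else:
        missing = [s for s in samples if s not in available]
        if missing:
            raise VcfIngestError(f"{path}: samples not found: {missing}")
    calls: dict[str, list[GenotypeCall]] = {s: [] for s in samples}
    obs_ref: dict[str, set[int]] = {s: set() for s in samples}
    for rec in vcf:
        alts = rec.alts or ()
        for sample in samples:
            sdata = rec.samples[sample]
            gt = sdata.get("GT")
            if gt is None:
                raise VcfIngestError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks GT for {sample}"
                )
            if len(gt) != 2 or any(a is None for a in gt):
                continue  # missing / non-diploid: treated as unobserved
            phased = bool(sdata.phased)
            ps = sdata.get("PS")
            if gt == (0, 0):
                obs_ref[sample].add(rec.pos)
                continue
            for alt_index, alt in enumerate(alts, start=1):
                pair = tuple(1 if a == alt_index else 0 for a in gt)
                if pair == (0, 0):
                    continue
                if alt is None or not set(alt) <= set("ACGT"):
                    continue  # symbolic alts out of scope
                var = VariantKey(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                                 rsid=rec.id if rec.id not in (None, ".") else None)
                is_het = pair[0] != pair[1]
                calls[sample].append(
                    GenotypeCall(
                        variant=var,
                        alleles=pair,  # type: ignore[arg-type]
                        phased=phased and (not is_het or ps is not None),
                        phase_set=int(ps) if (phased and is_het and ps is not None) else None,
                    )
                )
    return [
        SampleCallSet(sample_id=s, calls=calls[s], observed_ref_positions=frozenset(obs_ref[s]))
        for s in samples
    ]


def restrict_to_region(
    callset: SampleCallSet, region: GeneRegion, include_flanks: bool = True
) -> SampleCallSet:
    """Keep only calls (and observed-reference positions) inside the region."""
    kept = [
        c
        for c in callset.calls
        if c.variant.chrom == region.chrom and region.contains(c.variant.pos, include_flanks)
    ]
    obs = frozenset(
        p for p in callset.observed_ref_positions if region.contains(p, include_flanks)
    )
    return SampleCallSet(sample_id=callset.sample_id, calls=kept, observed_ref_positions=obs)


def sample_qc_filter(
    coverage: Mapping[str, float], policy: QcPolicy = QcPolicy()
) -> tuple[list[str], list[str]]:
    """Partition samples into (retained, excluded) by the coverage rule.

    A sample is excluded iff its fraction of target bases at or above the
    depth threshold is strictly below ``policy.min_fraction``.
    """
    retained, excluded = [], []
    for sample, fraction in coverage.items():
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"{sample}: coverage fraction {fraction} outside [0, 1]")
        (excluded if fraction < policy.min_fraction else retained).append(sample)
    return retained, excluded


def read_coverage_tsv(path: str | Path) -> dict[str, float]:
    """Read ``sample_id<TAB>fraction_ge_depth`` (comment lines allowed)."""
    out: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("sample"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise VcfIngestError(f"{path}:{lineno}: expected two tab-separated fields")
        out[parts[0]] = float(parts[1])
    return out


def read_bed_regions(path: str | Path, flank: int = 10_000) -> dict[str, GeneRegion]:
    """Read gene regions from BED (0-based half-open -> 1-based inclusive)."""
    out: dict[str, GeneRegion] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise VcfIngestError(f"{path}:{lineno}: need chrom,start,end,name")
        chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        out[name] = GeneRegion(gene=name, chrom=chrom, start=start0 + 1, end=end0, flank=flank)
    return out
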