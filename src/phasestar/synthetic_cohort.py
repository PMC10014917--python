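"""Synthetic phased-VCF cohorts with known truth diplotypes.

The generator emulates the phased variant calls a long-read pipeline
(mapping -> variant calling -> read-backed phasing) would emit for samples
with specified diplotypes: strand A carries the first allele's defining
variants (plus any declared extras), strand B the second's; variants shared
by both strands are emitted homozygous-alt; heterozygous variants are
phased into PS-tagged blocks with GT orientation consistent with the
strands.  A noise model then degrades the calls the way real data does:
loss of phase on individual genotypes, phase-block fragmentation between
consecutive het sites, per-position dropout (missing, not hom-ref), and
injected novel variants drawn from a reserved position range guaranteed to
lie outside every definition.

With the default (zero) noise the VCF is a faithful rendering of the truth
table, which is what the recovery tests assert; noisy settings exercise the
caller's ambiguity reporting.  Generation is deterministic: each sample has
its own RNG stream keyed by (seed, sample_id), so cohorts are stable under
sample-list reordering.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_definitions import AlleleDefinitionTable, VariantKey, _star_sort_key, bundled_cyp2c19_table
from .concordance import load_table2_calls, parse_cell
from .phenotype_translation import FunctionMap, assign_phenotype, load_phenotype_rules

__all__ = [
    "NoiseModel",
    "SampleSpec",
    "CohortSpec",
    "GeneratedCohort",
    "generate_cohort",
    "resolve_diplotype_spec",
    "intended_call_string",
    "table2_fixture",
    "NOVEL_POSITION_RANGE",
]

#: Positions reserved for injected novel variants; disjoint by construction
#: from every position used in the bundled definition table.
NOVEL_POSITION_RANGE = (94_820_000, 94_830_000)

_CHROM_LENGTH = 133_797_422  # GRCh38 chromosome 10


@dataclass(frozen=True)
class NoiseModel:
    p_unphase: float = 0.0
    p_block_split: float = 0.0
    p_drop: float = 0.0
    novel_rate: float = 0.0
    qc_fraction_range: tuple[float, float] = (0.33, 0.96)

    def __post_init__(self) -> None:
        for name in ("p_unphase", "p_block_split", "p_drop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.novel_rate < 0:
            raise ValueError("novel_rate must be >= 0")
        lo, hi = self.qc_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("qc_fraction_range must be ordered within [0, 1]")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    allele_a: str  # suballele names resolvable in the table
    allele_b: str
    extras_a: frozenset[VariantKey] = frozenset()
    extras_b: frozenset[VariantKey] = frozenset()


@dataclass(frozen=True)
class CohortSpec:
    gene: str
    table: AlleleDefinitionTable
    samples: tuple[SampleSpec, ...]
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids are not unique")
        for s in self.samples:
            for name in (s.allele_a, s.allele_b):
                if name not in self.table:
                    raise ValueError(f"{s.sample_id}: unknown suballele {name}")
            for strand_extras, allele in ((s.extras_a, s.allele_a), (s.extras_b, s.allele_b)):
                strand = self.table[allele].defining_variants | strand_extras
                by_pos: dict[int, VariantKey] = {}
                for v in strand:
                    if v.pos in by_pos and by_pos[v.pos] != v:
                        raise ValueError(
                            f"{s.sample_id}: contradictory variants at position {v.pos}"
                        )
                    by_pos[v.pos] = v


@dataclass(frozen=True)
class GeneratedCohort:
    vcf_path: Path
    truth_path: Path
    coverage_path: Path
    truth: pd.DataFrame
    coverage: dict[str, float]


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode("utf-8"))])


def _strands_for(spec: CohortSpec, s: SampleSpec) -> tuple[set[VariantKey], set[VariantKey]]:
    a = set(spec.table[s.allele_a].defining_variants) | set(s.extras_a)
    b = set(spec.table[s.allele_b].defining_variants) | set(s.extras_b)
    return a, b


def _render_intended_allele(suballele: str, extras: frozenset[VariantKey]) -> str:
    parts = [suballele]
    for v in sorted(extras):
        parts.append(f"+ {v.gdot}")
    return " ".join(parts)


def intended_call_string(spec_sample: SampleSpec) -> str:
    """The diplotype string the caller is expected to produce (canonical
    allele order, extras rendered as ``+ g.<pos><ref>><alt>``)."""
    halves = sorted(
        [
            (spec_sample.allele_a, spec_sample.extras_a),
            (spec_sample.allele_b, spec_sample.extras_b),
        ],
        key=lambda t: (_star_sort_key(t[0]), sorted(t[1])),
    )
    return "/".join(_render_intended_allele(name, extras) for name, extras in halves)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> GeneratedCohort:
    """Write cohort.vcf, truth.tsv and coverage.tsv; return the bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_sample: dict[str, dict] = {}
    novel_sites: set[VariantKey] = set()
    for s in spec.samples:
        rng = _sample_rng(spec.seed, s.sample_id)
        a, b = _strands_for(spec, s)
        # injected novel variants, reserved position range
        n_novel = int(rng.poisson(spec.noise.novel_rate))
        lo, hi = NOVEL_POSITION_RANGE
        for _ in range(n_novel):
            pos = int(rng.integers(lo, hi))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            v = VariantKey(chrom="10", pos=pos, ref=str(ref), alt=str(alt))
            (a if rng.random() < 0.5 else b).add(v)
            novel_sites.add(v)
        hom = a & b
        hets = sorted(a ^ b)
        # phase-set assignment with optional fragmentation
        phase_sets: dict[VariantKey, int] = {}
        current_ps: int | None = None
        for i, v in enumerate(hets):
            if current_ps is None or (i > 0 and rng.random() < spec.noise.p_block_split):
                current_ps = v.pos
            phase_sets[v] = current_ps
        unphased = {v for v in hets if rng.random() < spec.noise.p_unphase}
        dropped: set[VariantKey] = set()  # filled per site below
        per_sample[s.sample_id] = {
            "a": a, "b": b, "hom": hom, "phase_sets": phase_sets,
            "unphased": unphased, "rng": rng, "dropped": dropped,
        }

    # site list: every definition position plus every carried variant
    sites = sorted(set(spec.table.variant_universe) | novel_sites
                   | {v for d in per_sample.values() for v in d["a"] | d["b"]})

    sample_ids = [s.sample_id for s in spec.samples]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=10,length={_CHROM_LENGTH}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT" + "".join(f"\t{s}" for s in sample_ids),
    ]
    for v in sites:
        row = [v.chrom, str(v.pos), v.rsid or ".", v.ref, v.alt, ".", "PASS", ".", "GT:PS"]
        for sid in sample_ids:
            d = per_sample[sid]
            if d["rng"].random() < spec.noise.p_drop:
                row.append("./.:.")
                continue
            in_a, in_b = v in d["a"], v in d["b"]
            if not in_a and not in_b:
                row.append("0|0:.")
            elif in_a and in_b:
                row.append("1|1:.")
            else:
                if v in d["unphased"]:
                    gt = "0/1"
                    ps = "."
                else:
                    gt = "1|0" if in_a else "0|1"
                    ps = str(d["phase_sets"][v])
                row.append(f"{gt}:{ps}")
        lines.append("\t".join(row))
    vcf_path = out_dir / "cohort.vcf"
    vcf_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # truth table with intended calls and phenotypes
    fmap = FunctionMap.from_table(spec.table)
    rules = load_phenotype_rules()
    records = []
    for s in spec.samples:
        majors = (spec.table[s.allele_a].major, spec.table[s.allele_b].major)
        pheno = assign_phenotype(
            majors, fmap, rules, sample_id=s.sample_id,
            carries_extras=bool(s.extras_a or s.extras_b),
        )
        records.append(
            {
                "sample": s.sample_id,
                "diplotype": intended_call_string(s),
                "diplotype_major": "/".join(sorted(majors, key=_star_sort_key)),
                "phenotype": pheno.phenotype,
                "actionable": pheno.actionable,
            }
        )
    truth = pd.DataFrame.from_records(records).set_index("sample")
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t")

    coverage = {
        sid: float(
            np.round(
                _sample_rng(spec.seed + 1, sid).uniform(*spec.noise.qc_fraction_range), 4
            )
        )
        for sid in sample_ids
    }
    coverage_path = out_dir / "coverage.tsv"
    coverage_path.write_text(
        "sample_id\tfraction_ge_depth\n"
        + "".join(f"{sid}\t{coverage[sid]:.4f}\n" for sid in sample_ids),
        encoding="utf-8",
    )
    return GeneratedCohort(vcf_path, truth_path, coverage_path, truth, coverage)


# ----------------------------------------------------------------------
# building cohort specs from printed diplotype strings
# ----------------------------------------------------------------------

def resolve_diplotype_spec(
    sample_id: str, cell: str, table: AlleleDefinitionTable
) -> SampleSpec:
    """Turn a printed diplotype cell (e.g. ``*1.002/*38.003 + 94781616A>G
    (NM)``) into a :class:`SampleSpec`.

    Extra-variant identifiers are resolved either as ``<pos><ref>><alt>``
    genomic shorthands or as rsids present in the definition table.  A
    ``-variant`` annotation (variant explicitly absent from the strand) is
    honoured by leaving the variant out.
    """
    parsed = parse_cell(cell)
    if not parsed.well_formed or not parsed.ranked:
        raise ValueError(f"{sample_id}: cannot parse diplotype cell {cell!r}")
    dip = parsed.ranked[0]
    names: list[str] = []
    extra_sets: list[frozenset[VariantKey]] = []
    by_rsid = {v.rsid: v for v in table.variant_universe if v.rsid}
    for tok in dip.alleles:
        name = tok.suballele or tok.major
        if name not in table:
            raise ValueError(f"{sample_id}: suballele {name} not in table")
        extras = set()
        for sign, ident in tok.extras:
            if sign != "+":
                continue
            extras.add(_resolve_extra(ident, by_rsid))
        names.append(name)
        extra_sets.append(frozenset(extras))
    return SampleSpec(
        sample_id=sample_id,
        allele_a=names[0], allele_b=names[1],
        extras_a=extra_sets[0], extras_b=extra_sets[1],
    )


_GDOT = re.compile(r"^(?:g\.)?(\d+)([ACGT]+)>([ACGT]+)$")


def _resolve_extra(ident: str, by_rsid: dict[str, VariantKey]) -> VariantKey:
    m = _GDOT.match(ident)
    if m:
        return VariantKey(chrom="10", pos=int(m.group(1)), ref=m.group(2), alt=m.group(3))
    if ident in by_rsid:
        return by_rsid[ident]
    raise ValueError(f"cannot resolve extra variant identifier {ident!r}")


def table2_fixture(
    noise: NoiseModel = NoiseModel(), seed: int = 0
) -> tuple[CohortSpec, pd.DataFrame]:
    """The published 37-sample cohort: a :class:`CohortSpec` built from the
    manually curated call column, plus the verbatim four-column call table
    for concordance analysis."""
    table = bundled_cyp2c19_table()
    calls = load_table2_calls()
    samples = tuple(
        resolve_diplotype_spec(str(sid), calls.loc[sid, "manual"], table)
        for sid in calls.index
    )
    return CohortSpec(gene=table.gene, table=table, samples=samples, noise=noise, seed=seed), calls
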