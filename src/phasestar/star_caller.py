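"""Phasing-aware diplotype assignment against a star-allele table.

The caller formalizes manual star-allele curation from a phased VCF:

1. reconstruct the two parental haplotypes from the genotype calls — within
   a phase block the GT orientation fixes the strand assignment; across
   blocks and for unphased heterozygous calls both orientations are
   enumerated (up to a strand-swap symmetry);
2. match each candidate strand against every suballele definition, ranking
   by most core variants matched, then most defining variants matched, then
   fewest extra known variants, then fewest extra novel variants, then
   name — the "most variants accounted for" principle;
3. pick the haplotype pair whose summed strand scores are maximal; when
   phasing leaves several pairs indistinguishable, the runners-up are kept
   as ranked alternatives rather than silently dropped.

Strands carrying phase-supported extra variants that no catalogued
suballele of the same major explains are reported as candidate novel
suballeles (e.g. ``*38.003 + g.94781616A>G``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .allele_definitions import AlleleDefinitionTable, VariantKey, _star_sort_key
from .vcf_ingest import GenotypeCall, SampleCallSet

__all__ = [
    "CallingPolicy",
    "HaplotypePair",
    "StarAlleleMatch",
    "DiplotypeCall",
    "NovelSuballeleCandidate",
    "build_haplotype_pairs",
    "match_strand",
    "call_diplotype",
    "detect_novel_suballeles",
    "render_allele",
    "render_diplotype",
]


@dataclass(frozen=True)
class CallingPolicy:
    """missing_mode "assume_reference" treats uncalled positions as wildtype
    (appropriate when hom-ref positions are tracked); "strict_missing"
    keeps candidates whose defining variants fall on unassayed positions,
    flagged, reproducing the ambiguity of callers that refuse the wildtype
    assumption."""

    missing_mode: str = "assume_reference"
    max_unphased_enumeration: int = 12
    report_alternatives: int = 8

    def __post_init__(self) -> None:
        if self.missing_mode not in ("assume_reference", "strict_missing"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if self.max_unphased_enumeration < 0:
            raise ValueError("enumeration cap must be >= 0")


@dataclass(frozen=True)
class HaplotypePair:
    strand_a: frozenset[VariantKey]
    strand_b: frozenset[VariantKey]
    unassigned: frozenset[VariantKey] = frozenset()
    observed_ref_positions: frozenset[int] = frozenset()


@dataclass(frozen=True)
class StarAlleleMatch:
    suballele: str
    major: str
    matched_defining: frozenset[VariantKey]
    missing_defining: frozenset[VariantKey]
    extra_known: frozenset[VariantKey]
    extra_novel: frozenset[VariantKey]
    n_core_matched: int
    phase_supported: bool = True

    @property
    def extras(self) -> frozenset[VariantKey]:
        return self.extra_known | self.extra_novel

    def rank_key(self) -> tuple:
        """Higher is better in the first components; used descending."""
        return (
            self.n_core_matched,
            len(self.matched_defining),
            -len(self.extra_known),
            -len(self.extra_novel),
            -len(self.missing_defining),
        )


@dataclass(frozen=True)
class DiplotypeCandidate:
    a: StarAlleleMatch
    b: StarAlleleMatch

    def score(self) -> tuple:
        ka, kb = self.a.rank_key(), self.b.rank_key()
        return tuple(x + y for x, y in zip(ka, kb))

    def token(self) -> str:
        return render_diplotype(self)

    def order_key(self) -> tuple:
        """Deterministic tie-break: natural star order, then extras."""
        return (
            _star_sort_key(self.a.suballele), sorted(self.a.extras),
            _star_sort_key(self.b.suballele), sorted(self.b.extras),
        )


@dataclass(frozen=True)
class DiplotypeCall:
    sample_id: str
    primary: DiplotypeCandidate
    alternatives: tuple[DiplotypeCandidate, ...]
    policy: CallingPolicy
    truncated: bool = False
    unconfirmed_extras: frozenset[VariantKey] = frozenset()

    @property
    def score_components(self) -> tuple:
        return self.primary.score()


@dataclass(frozen=True)
class NovelSuballeleCandidate:
    descriptor: str
    suballele: str
    extras: frozenset[VariantKey]
    confident: bool


# ----------------------------------------------------------------------
# haplotype reconstruction
# ----------------------------------------------------------------------

def build_haplotype_pairs(
    callset: SampleCallSet,
    policy: CallingPolicy = CallingPolicy(),
    known_variants: frozenset[VariantKey] | None = None,
) -> list[HaplotypePair]:
    """Enumerate consistent strand assignments for one sample.

    Each phase block and each unphased het call is an independently
    orientable unit; the first unit's orientation is pinned, so the result
    has at most ``2**(units-1)`` pairs with no strand-swap duplicates.
    When the orientation count would exceed the policy cap, unphased het
    variants are dropped from enumeration (novel variants first, then
    highest position first) and returned in ``unassigned``.
    """
    hom_alt = frozenset(c.variant for c in callset.calls if c.zygosity == "hom_alt")
    blocks = callset.phase_blocks
    unphased = [c for c in callset.het_calls if not (c.phased and c.phase_set is not None)]

    dropped: set[VariantKey] = set()
    n_units = len(blocks) + len(unphased)
    max_units = policy.max_unphased_enumeration + 1  # bits = units - 1
    if n_units > max_units:
        def impact(c: GenotypeCall) -> tuple:
            known = known_variants is not None and c.variant in known_variants
            return (known, -c.variant.pos)  # novel first, then rightmost

        for c in sorted(unphased, key=impact):
            if n_units <= max_units:
                break
            dropped.add(c.variant)
            n_units -= 1
        unphased = [c for c in unphased if c.variant not in dropped]

    # Per-unit "haplotype 0" / "haplotype 1" variant sets.
    units: list[tuple[frozenset[VariantKey], frozenset[VariantKey]]] = []
    for ps in sorted(blocks):
        h0 = frozenset(c.variant for c in blocks[ps] if c.alleles[0] == 1)
        h1 = frozenset(c.variant for c in blocks[ps] if c.alleles[1] == 1)
        units.append((h0, h1))
    for c in unphased:
        units.append((frozenset([c.variant]), frozenset()))

    obs = callset.observed_ref_positions
    if not units:
        return [HaplotypePair(hom_alt, hom_alt, frozenset(dropped), obs)]

    pairs = []
    for bits in itertools.product((0, 1), repeat=len(units) - 1):
        orient = (0,) + bits
        a, b = set(hom_alt), set(hom_alt)
        for (h0, h1), o in zip(units, orient):
            if o == 0:
                a |= h0
                b |= h1
            else:
                a |= h1
                b |= h0
        pairs.append(HaplotypePair(frozenset(a), frozenset(b), frozenset(dropped), obs))
    return pairs


# ----------------------------------------------------------------------
# strand matching
# ----------------------------------------------------------------------

def match_strand(
    strand: frozenset[VariantKey],
    observed_ref: frozenset[int],
    table: AlleleDefinitionTable,
    policy: CallingPolicy = CallingPolicy(),
) -> list[StarAlleleMatch]:
    """Rank all compatible suballeles for one strand (best first).

    The reference allele (empty defining set) is always compatible, so the
    list is never empty; an empty strand matches the reference exactly.
    """
    universe = table.variant_universe
    strand_positions = {v.pos for v in strand}
    out: list[StarAlleleMatch] = []
    for name in sorted(table.alleles, key=_star_sort_key):
        a = table[name]
        matched = a.defining_variants & strand
        absent = a.defining_variants - strand
        if policy.missing_mode == "assume_reference":
            if absent:
                continue
            missing: frozenset[VariantKey] = frozenset()
        else:
            # strict_missing: an absent defining variant at an assayed
            # position (observed ref, or called with another allele) rules
            # the candidate out; at an unassayed position it is "missing".
            if any(v.pos in observed_ref or v.pos in strand_positions for v in absent):
                continue
            missing = frozenset(absent)
        extras = strand - a.defining_variants
        out.append(
            StarAlleleMatch(
                suballele=a.suballele,
                major=a.major,
                matched_defining=frozenset(matched),
                missing_defining=missing,
                extra_known=frozenset(v for v in extras if v in universe),
                extra_novel=frozenset(v for v in extras if v not in universe),
                n_core_matched=len(a.core_variants & strand),
            )
        )
    out.sort(key=lambda m: (tuple(-x for x in m.rank_key()), _star_sort_key(m.suballele)))
    return out


# ----------------------------------------------------------------------
# diplotype calling
# ----------------------------------------------------------------------

def render_allele(m: StarAlleleMatch) -> str:
    parts = [m.suballele]
    for v in sorted(m.extras):
        parts.append(f"+ {v.gdot}")
    return " ".join(parts)


def render_diplotype(cand: DiplotypeCandidate) -> str:
    return f"{render_allele(cand.a)}/{render_allele(cand.b)}"


def _canonical_pair(a: StarAlleleMatch, b: StarAlleleMatch) -> DiplotypeCandidate:
    key = lambda m: (_star_sort_key(m.suballele), sorted(m.extras))
    return DiplotypeCandidate(*sorted((a, b), key=key))


def _phase_support(
    strand: frozenset[VariantKey], callset: SampleCallSet
) -> bool:
    """True when every het variant on the strand shares one phase block."""
    het_by_var = {c.variant: c for c in callset.het_calls}
    hets = [het_by_var[v] for v in strand if v in het_by_var]
    if len(hets) <= 1:
        return True
    sets = {c.phase_set if (c.phased and c.phase_set is not None) else None for c in hets}
    return None not in sets and len(sets) == 1


def call_diplotype(
    callset: SampleCallSet,
    table: AlleleDefinitionTable,
    policy: CallingPolicy = CallingPolicy(),
) -> DiplotypeCall:
    """Assign the ranked diplotype for one sample (region-restricted calls)."""
    pairs = build_haplotype_pairs(callset, policy, known_variants=table.variant_universe)
    candidates: dict[str, DiplotypeCandidate] = {}
    for pair in pairs:
        best_a = _best_for_strand(pair.strand_a, pair.observed_ref_positions, table, policy, callset)
        best_b = _best_for_strand(pair.strand_b, pair.observed_ref_positions, table, policy, callset)
        cand = _canonical_pair(best_a, best_b)
        tok = cand.token()
        if tok not in candidates or cand.score() > candidates[tok].score():
            candidates[tok] = cand
    ranked = sorted(
        candidates.values(), key=lambda c: (tuple(-x for x in c.score()), c.order_key())
    )
    primary, *rest = ranked
    unassigned = pairs[0].unassigned if pairs else frozenset()
    return DiplotypeCall(
        sample_id=callset.sample_id,
        primary=primary,
        alternatives=tuple(rest[: policy.report_alternatives]),
        policy=policy,
        truncated=bool(unassigned),
        unconfirmed_extras=unassigned,
    )


def _best_for_strand(
    strand: frozenset[VariantKey],
    observed_ref: frozenset[int],
    table: AlleleDefinitionTable,
    policy: CallingPolicy,
    callset: SampleCallSet,
) -> StarAlleleMatch:
    best = match_strand(strand, observed_ref, table, policy)[0]
    supported = _phase_support(strand, callset)
    if supported == best.phase_supported:
        return best
    return StarAlleleMatch(
        suballele=best.suballele,
        major=best.major,
        matched_defining=best.matched_defining,
        missing_defining=best.missing_defining,
        extra_known=best.extra_known,
        extra_novel=best.extra_novel,
        n_core_matched=best.n_core_matched,
        phase_supported=supported,
    )


# ----------------------------------------------------------------------
# novel suballele detection
# ----------------------------------------------------------------------

def detect_novel_suballeles(
    call: DiplotypeCall, table: AlleleDefinitionTable
) -> list[NovelSuballeleCandidate]:
    """Candidate "<suballele> + <variants>" descriptors from the primary call.

    A candidate is *confident* only when the carrying strand is fully
    phase-supported; extras without phase support are still reported so a
    curator can follow them up, but flagged unconfirmed.
    """
    out: list[NovelSuballeleCandidate] = []
    for m in (call.primary.a, call.primary.b):
        extras = m.extras
        if not extras:
            continue
        siblings = [a for a in table if a.major == m.major]
        if any(extras <= a.defining_variants for a in siblings):
            continue  # an existing sibling suballele already carries these
        descriptor = f"{m.suballele} + " + " + ".join(v.gdot for v in sorted(extras))
        out.append(
            NovelSuballeleCandidate(
                descriptor=descriptor,
                suballele=m.suballele,
                extras=extras,
                confident=m.phase_supported and not call.truncated,
            )
        )
    return out
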