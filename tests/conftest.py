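"""Shared fixtures: the bundled CYP2C19 table, the published 37-sample call
table, and a zero-noise synthetic cohort generated from its manual column."""

from __future__ import annotations

import itertools

import pytest

from phasestar import (
    CYP2C19_REGION,
    bundled_cyp2c19_table,
    call_diplotype,
    read_phased_vcf,
    restrict_to_region,
)
from phasestar.allele_definitions import _star_sort_key
from phasestar.synthetic_cohort import generate_cohort, table2_fixture


@pytest.fixture(scope="session")
def table():
    return bundled_cyp2c19_table()


@pytest.fixture(scope="session")
def table2():
    """(CohortSpec from the manual column, verbatim four-column call table)."""
    return table2_fixture()


@pytest.fixture(scope="session")
def cohort(table2, tmp_path_factory):
    """Zero-noise 37-sample cohort written once per session."""
    spec, _ = table2
    return generate_cohort(spec, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def callsets(cohort):
    return [
        restrict_to_region(cs, CYP2C19_REGION)
        for cs in read_phased_vcf(cohort.vcf_path)
    ]


# ----------------------------------------------------------------------
# independent brute-force oracle for the star caller
# ----------------------------------------------------------------------

def oracle_best_diplotype(callset, table):
    """Best diplotype by exhaustive enumeration, independent of the caller.

    Enumerates all 2^h assignments of het variants to strands, discards
    assignments inconsistent with the recorded phase blocks (within a
    block, the alt-carrying haplotype index of every variant must map to
    the same strand), scores every compatible suballele pair directly from
    the definition sets, and returns (score, canonical token).
    """
    hets = callset.het_calls
    homs = frozenset(c.variant for c in callset.calls if c.zygosity == "hom_alt")
    universe = table.variant_universe

    def consistent(mask: int) -> bool:
        seen: dict[int, dict[bool, int]] = {}
        for i, c in enumerate(hets):
            if not (c.phased and c.phase_set is not None):
                continue
            hap0_has_alt = c.alleles[0] == 1
            strand = (mask >> i) & 1
            block = seen.setdefault(c.phase_set, {})
            if hap0_has_alt in block and block[hap0_has_alt] != strand:
                return False
            if (not hap0_has_alt) in block and block[not hap0_has_alt] == strand:
                return False
            block[hap0_has_alt] = strand
        return True

    def strand_score(strand, allele):
        if not allele.defining_variants <= strand:
            return None
        extras = strand - allele.defining_variants
        return (
            len(allele.core_variants & strand),
            len(allele.defining_variants),
            -sum(1 for v in extras if v in universe),
            -sum(1 for v in extras if v not in universe),
        )

    def token(allele, strand):
        extras = sorted(strand - allele.defining_variants)
        return " ".join([allele.suballele] + [f"+ {v.gdot}" for v in extras])

    best = None  # (score, tie_key, token)
    for mask in range(2 ** len(hets)):
        if not consistent(mask):
            continue
        a, b = set(homs), set(homs)
        for i, c in enumerate(hets):
            (a if (mask >> i) & 1 else b).add(c.variant)
        a, b = frozenset(a), frozenset(b)
        for al1, al2 in itertools.product(table, repeat=2):
            s1, s2 = strand_score(a, al1), strand_score(b, al2)
            if s1 is None or s2 is None:
                continue
            score = tuple(x + y for x, y in zip(s1, s2))
            halves = sorted(
                [
                    (_star_sort_key(al1.suballele), sorted(a - al1.defining_variants), token(al1, a)),
                    (_star_sort_key(al2.suballele), sorted(b - al2.defining_variants), token(al2, b)),
                ]
            )
            tie = (halves[0][0], halves[0][1], halves[1][0], halves[1][1])
            cand = (score, tie, "/".join(h[2] for h in halves))
            if best is None or (cand[0], _desc(cand[1])) > (best[0], _desc(best[1])):
                best = cand
    return (best[0], best[2])


class _desc:
    """Wrap a key so smaller keys win inside a max()."""

    def __init__(self, key):
        self.key = key

    def __lt__(self, other):
        return self.key > other.key

    def __gt__(self, other):
        return self.key < other.key

    def __eq__(self, other):
        return self.key == other.key
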