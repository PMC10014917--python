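# Methods

## Data model

An **allele definition table** holds, per gene, a set of suballeles each
defined by a set of variants (`chrom`, 1-based GRCh38 `pos`, `ref`, `alt`;
rsids are decorative).  Variants flagged `is_core` are shared by every
suballele of a major allele and are validated as such.  One allele — here
`*38.001`, with an empty defining set — is the *reference allele*,
assigned to a strand on which no variants are observed.  Strict-mode
validation additionally rejects two suballeles with identical defining
sets, since no caller could ever distinguish them.

The bundled CYP2C19 table is deliberately small (14 suballeles, 15
variants).  It encodes the documented variant-allele relationships at
their published positions: the `*2` core `g.94781859G>A`;
`*2.011 = *2.001 + g.94762608T>C` (rs4986894); `g.94775165G>C` carried by
`*2.002/*2.010/*2.012`; `g.94781616A>G` (rs7088784) inside `*3.002`; the
`*11` core `g.94775507G>A`; and the `*1` core `g.94842866A>G`.  Positions
that exist only to make suballeles distinguishable (e.g. what separates
`*1.005` from `*1.006`, or the upstream `*17` variant) are synthetic
placeholders, marked with an `SYN_`-prefixed rsid.  Modelling the `*38`
family with `*38.001` as an empty-set reference and `*38.003` with an
explicit (synthetic) defining variant diverges from real nomenclature
semantics, where the `*38` family is defined largely by *absence* of other
cores; the explicit set keeps matching uniform and is adequate for every
analysis here.

## VCF ingestion

`pysam` reads VCF 4.2 with `GT` and `PS` FORMAT fields.  Multiallelic
records are decomposed into per-alt biallelic calls.  Three states are
distinguished per sample and position: *called* (non-hom-ref genotype),
*observed reference* (`0|0`, position retained in
`observed_ref_positions`), and *missing* (`./.` or no record).  This
three-way distinction is what lets the caller implement both
missing-position policies (below).  Coordinates are 1-based VCF positions
throughout; BED input (0-based half-open) is converted once at the
boundary.  Indels are assumed left-normalized upstream; no re-normalization
is performed (documented limitation — the synthetic generator only emits
normalized records).

Sample-level QC consumes a per-sample coverage summary (fraction of target
bases at ≥ depth threshold, default 30×) and excludes samples strictly
below the minimum fraction (default 0.10).  The boundary is exclusive:
exactly 0.10 is retained.

## Phasing statistics

A heterozygous call is *phased with a partner* when its phase block
contains ≥ 2 het calls; a solitary phased call carries no relative phase
information and does not count.  The default denominator is het calls only
(homozygous calls need no phasing); an all-variants mode (homs counted as
trivially phased) is provided for sensitivity analysis since published
phasing percentages do not always state their denominator.  Samples with
no het calls report the fraction as NaN (flagged), never 0.  Block span is
max(pos) − min(pos) + (ref length of the rightmost variant − 1).

## Haplotype reconstruction and matching

Within one phase block the two GT orderings define the strand assignment
up to a global flip.  Each block, and each unphased het call, is therefore
one orientable *unit*; pinning the first unit's orientation removes the
strand-swap symmetry, leaving ≤ 2^(units−1) candidate haplotype pairs.
Hom-alt variants sit on both strands.  The enumeration is capped
(`max_unphased_enumeration`, default 12 free orientation bits ≈ 4096
pairs); beyond the cap, unphased het variants are deterministically dropped
from enumeration — variants absent from the definition table first, then
by descending position — and carried through as unconfirmed extras, with
the call flagged truncated.

A strand is matched against every suballele.  Under the default
`assume_reference` policy a suballele is compatible iff its defining set is
a subset of the strand: positions not called are treated as wildtype,
which is appropriate for targeted capture where hom-ref positions are
assayed and tracked.  Under `strict_missing`, a defining variant absent
from the strand rules the candidate out only if its position was assayed
(observed reference, or called with a different allele); at unassayed
positions the candidate survives with a flagged `missing_defining` set.
This reproduces the ranked-ambiguity behaviour of callers that refuse the
wildtype assumption.

Compatible candidates are ranked by: most core variants matched, most
defining variants matched, fewest extra known variants (extras present
elsewhere in the nomenclature), fewest extra novel variants, fewest
missing, then natural star order (`*2.001` before `*11.001`).  The
diplotype score of a haplotype pair is the component-wise sum of its two
strand keys; the pair maximizing it is the primary call and distinct
runner-up diplotypes are kept as ranked alternatives (up to
`report_alternatives`, default 8).  All tie-breaks are lexicographic in
natural star order, so repeated runs are bit-identical; the caller has no
randomness.

A strand match is *phase-supported* when all het variants on that strand
lie in a single phase block (or there are ≤ 1).  Novel-suballele detection
emits, for each primary strand with a non-empty extra set that no
same-major suballele's defining set contains, a descriptor
`<suballele> + g.<pos><ref>><alt>`; the candidate is *confident* only when
the strand is phase-supported and the call was not truncated, otherwise it
is reported unconfirmed.

## Phenotype translation

Each major allele carries a function class (`normal`, `decreased`,
`no_function`, `increased`, `unknown`).  An unordered pair of classes maps
to a metabolizer category through a guideline table shipped as YAML:
CPIC uses PM/IM/NM/RM/UM (two no-function → PM; any no-function or
decreased with a non-increased partner → IM; two normal → NM;
increased + normal → RM; two increased → UM).  DPWG lacks RM;
increased + normal is reported NM with an "increased-function carrier"
annotation, a bundled-config choice since the guideline divergence is
stated only as the absence of the RM category.  The decreased × increased
combination has no defined categorical mapping and returns
`indeterminate`, as does any pair missing from the table — never a silent
default.  The CPIC table is verified in the test suite against an
independent rule oracle rather than against any printed source, which
publishes only the category names and per-sample outcomes.

A sample is **actionable** when its phenotype is not NM, or either allele
has non-normal function, or the call carries extra (beyond-nomenclature)
variants.  Under this rule exactly the 8 all-`*1` samples of the bundled
cohort are non-actionable (21.6%): the `*1/*38` NM samples carry the
phased `g.94781616A>G` finding and count as carrying findings.

## Concordance

Call cells are parsed into ranked diplotype lists: a trailing
parenthesized group is a phenotype if it is a two-letter category, or an
alternate diplotype if it contains `/` (the ranked-output convention of
callers that list a second call when the first is ambiguous).  Agreement
levels: `minor_exact` compares full allele tokens (suballele plus sorted
`+extra` annotations, order-insensitive across the pair); `major` strips
suballeles and extras; `any_listed` accepts a match with any diplotype in
the tool's ranked list; `phenotype` compares printed categories.  A
`-variant` annotation (one bundled manual cell uses this unexplained
notation) parses as a distinct token at minor level — a data-faithfulness
choice that the bundled cohort's minor-level agreement count depends on —
while the cohort generator interprets it as "variant absent from that
strand".  Malformed cells are flagged and scored as disagreements, never
dropped.  Coarsening monotonicity (major ≥ minor; any-listed ≥
first-listed) is property-tested.

## Synthetic cohorts

`generate_cohort` renders each specified diplotype as phased VCF records:
strand A gets allele 1's defining variants plus declared extras, strand B
allele 2's; shared variants are hom-alt; het variants form a single phase
block before noise.  Every definition-table position is emitted as a site,
so non-carriers are genotyped `0|0` (observed reference) — this is what
makes the `assume_reference` policy sound on synthetic data.  The noise
model then applies, per sample: phase loss per het genotype
(`p_unphase`), a phase-set break between consecutive het sites
(`p_block_split`), per-site dropout to `./.` (`p_drop`, removing the
position from observed-reference too), and Poisson-injected novel variants
(`novel_rate`) at reserved positions (94,820,000–94,830,000) disjoint from
every definition position, so injected variants are novel by construction.
Per-sample QC fractions are drawn uniformly from `qc_fraction_range`
(default 0.33–0.96, the retained-sample coverage range the study design
anticipates; widen it below 0.10 to exercise the QC filter).

Defaults are zero noise: the generator's baseline condition is a faithful
phased rendering of the specified diplotypes, and that is the condition
under which exact recovery is asserted.  Each sample draws from its own
RNG stream keyed by (seed, CRC32(sample id)), so cohorts are byte-stable
under sample reordering and fully reproducible from the seed.

What the generator does **not** emulate: read-level errors, genotyping
error (wrong calls rather than missing calls), coverage profiles along the
gene, allelic imbalance, structural variants, or linkage structure between
samples.  Passing recovery tests therefore demonstrate the correctness of
the calling logic given correct (possibly incomplete/unphased) genotypes,
not robustness to miscalled genotypes.

## Problem sizes and numerical choices

The bundled analyses run on the 37-sample cohort (11 het sites maximum per
sample), where calling is effectively instantaneous; the noise sweep uses
37 samples × 5 levels × 3 seeds per knob, and the exhaustive recovery test
covers all 105 diplotypes constructible from the fixture table.  The
brute-force oracle used in tests enumerates all 2^h strand assignments and
all suballele pairs for samples of ≤ 8 variants; caller and oracle share
only the documented tie-break convention, not code.  There are no floating
point tolerances anywhere in the calling path — scores are integer tuples —
and percentages are reported at 0.1% precision with integer display
rounding.

## Known limitations

- SNV and simple-indel definitions only; no structural variants, hybrid
  genes or copy-number calling (`*36`/`*37`-type events are out of scope).
- Read-backed phase is consumed, never inferred; no statistical (LD)
  phasing, and no switch-error modelling.
- Indel normalization is assumed upstream.
- The bundled definition table is a self-contained teaching-scale model of
  the CYP2C19 nomenclature, not a PharmVar release; synthetic placeholder
  variants are clearly marked and must not be interpreted as real
  positions.
- Coverage summaries are consumed as a table; depth is never recomputed
  from alignments.
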