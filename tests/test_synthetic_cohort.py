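"""Synthetic cohort generator: determinism, truth recovery and noise
degradation of the full generate -> read -> call loop."""

import itertools

import pytest

from phasestar import (
    CYP2C19_REGION,
    call_diplotype,
    read_phased_vcf,
    render_diplotype,
    restrict_to_region,
)
from phasestar.phasing_metrics import phasing_stats
from phasestar.synthetic_cohort import (
    CohortSpec,
    NoiseModel,
    SampleSpec,
    generate_cohort,
    intended_call_string,
    resolve_diplotype_spec,
    table2_fixture,
)
from phasestar.allele_definitions import VariantKey


def _recovery_rate(spec, out_dir):
    gen = generate_cohort(spec, out_dir)
    ok = 0
    for cs in read_phased_vcf(gen.vcf_path):
        call = call_diplotype(restrict_to_region(cs, CYP2C19_REGION), spec.table)
        if render_diplotype(call.primary) == gen.truth.loc[cs.sample_id, "diplotype"]:
            ok += 1
    return ok / len(spec.samples)


def test_generation_is_deterministic(table, tmp_path):
    spec, _ = table2_fixture(noise=NoiseModel(p_unphase=0.3, p_drop=0.1, novel_rate=0.5), seed=11)
    g1 = generate_cohort(spec, tmp_path / "a")
    g2 = generate_cohort(spec, tmp_path / "b")
    assert g1.vcf_path.read_bytes() == g2.vcf_path.read_bytes()
    assert g1.coverage == g2.coverage


def test_per_sample_streams_stable_under_reordering(table, tmp_path):
    noise = NoiseModel(p_unphase=0.3, novel_rate=0.5)
    spec, _ = table2_fixture(noise=noise, seed=5)
    reversed_spec = CohortSpec(
        gene=spec.gene, table=spec.table, samples=tuple(reversed(spec.samples)),
        noise=spec.noise, seed=spec.seed,
    )
    a = {cs.sample_id: cs for cs in read_phased_vcf(generate_cohort(spec, tmp_path / "a").vcf_path)}
    b = {cs.sample_id: cs for cs in read_phased_vcf(generate_cohort(reversed_spec, tmp_path / "b").vcf_path)}
    for sid in a:
        assert [(c.variant, c.alleles, c.phased) for c in a[sid].calls] == [
            (c.variant, c.alleles, c.phased) for c in b[sid].calls
        ]


def test_reference_reference_sample_has_no_alt_records(table, tmp_path):
    ref = table.reference_allele
    spec = CohortSpec(
        gene=table.gene, table=table,
        samples=(SampleSpec("S", ref, ref),),
    )
    gen = generate_cohort(spec, tmp_path)
    (cs,) = read_phased_vcf(gen.vcf_path)
    assert cs.calls == []
    assert len(cs.observed_ref_positions) == len({v.pos for v in table.variant_universe})
    call = call_diplotype(cs, table)
    assert render_diplotype(call.primary) == f"{ref}/{ref}"


def test_zero_noise_recovery_exhaustive_over_fixture_diplotypes(table, tmp_path):
    """Every diplotype constructible from the fixture table is recovered
    exactly from its zero-noise synthetic sample."""
    names = sorted(table.alleles)
    samples = tuple(
        SampleSpec(f"s{i}", a, b)
        for i, (a, b) in enumerate(itertools.combinations_with_replacement(names, 2))
    )
    spec = CohortSpec(gene=table.gene, table=table, samples=samples)
    assert len(samples) == 105
    assert _recovery_rate(spec, tmp_path) == 1.0


def test_table2_cohort_recovery_and_phenotypes(table2, cohort, callsets):
    spec, _ = table2
    truth = cohort.truth
    for cs in callsets:
        call = call_diplotype(cs, spec.table)
        assert render_diplotype(call.primary) == truth.loc[cs.sample_id, "diplotype"]


def test_full_phasing_yields_100_percent_metric(callsets):
    for cs in callsets:
        s = phasing_stats(cs)
        if s.n_het >= 2:
            assert s.phased_fraction == 100.0


def test_fully_unphased_2011_sample_reports_ambiguity(table, tmp_path):
    spec = CohortSpec(
        gene=table.gene, table=table,
        samples=(SampleSpec("S", "*1.002", "*2.011"),),
        noise=NoiseModel(p_unphase=1.0),
    )
    gen = generate_cohort(spec, tmp_path)
    (cs,) = read_phased_vcf(gen.vcf_path)
    call = call_diplotype(restrict_to_region(cs, CYP2C19_REGION), table)
    tokens = [call.primary.token()] + [c.token() for c in call.alternatives]
    assert "*1.002/*2.011" in tokens
    assert "*1.002 + g.94762608T>C/*2.001" in tokens


@pytest.mark.parametrize("knob", ["p_unphase", "p_drop"])
def test_recovery_degrades_with_noise(knob, tmp_path):
    """Minor-level recovery is non-increasing in the noise level (mean over
    a small seed grid, with slack for sampling error)."""
    levels = [0.0, 0.5, 1.0]
    means = []
    for level in levels:
        rates = []
        for seed in (1, 2, 3):
            noise = NoiseModel(**{knob: level})
            spec, _ = table2_fixture(noise=noise, seed=seed)
            rates.append(_recovery_rate(spec, tmp_path / f"{knob}{level}s{seed}"))
        means.append(sum(rates) / len(rates))
    assert means[0] == 1.0
    for lo, hi in zip(means[1:], means[:-1]):
        assert lo <= hi + 0.05
    assert means[-1] < means[0]


def test_contradictory_extras_rejected(table):
    clash = VariantKey("10", 94781859, "G", "C")  # same position, different alt
    with pytest.raises(ValueError, match="contradictory"):
        CohortSpec(
            gene=table.gene, table=table,
            samples=(SampleSpec("S", "*2.001", "*1.002", extras_a=frozenset({clash})),),
        )


def test_unresolvable_diplotype_rejected(table):
    with pytest.raises(ValueError, match="unknown suballele"):
        CohortSpec(gene=table.gene, table=table,
                   samples=(SampleSpec("S", "*9.009", "*1.002"),))


def test_resolve_diplotype_spec_handles_extras_and_minus(table):
    s = resolve_diplotype_spec("5", "*1.002 +94842865C>T/*2.002-94842865C>T (IM)", table)
    assert s.allele_a == "*1.002" and s.allele_b == "*2.002"
    assert s.extras_a == {VariantKey("10", 94842865, "C", "T")}
    assert s.extras_b == frozenset()  # "-variant" means absent
    assert intended_call_string(s) == "*1.002 + g.94842865C>T/*2.002"


def test_injected_novel_variants_are_outside_definitions(table, tmp_path):
    spec = CohortSpec(
        gene=table.gene, table=table,
        samples=(SampleSpec("S", "*1.002", "*1.002"),),
        noise=NoiseModel(novel_rate=3.0), seed=42,
    )
    gen = generate_cohort(spec, tmp_path)
    (cs,) = read_phased_vcf(gen.vcf_path)
    def_positions = {v.pos for v in table.variant_universe}
    novel = [c.variant for c in cs.calls if c.variant not in table.variant_universe]
    assert novel, "expected injected novel variants at rate 3.0"
    assert all(v.pos not in def_positions for v in novel)
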