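"""Sequence-variant cascade: QC, inheritance, pairing, gene filter, retention."""

import pytest

from asdtriage.config import PipelineConfig
from asdtriage.model import (
    AcmgClass,
    Consequence,
    Inheritance,
    Sex,
    Zygosity,
)
from asdtriage.snv import (
    assign_inheritance,
    detect_compound_het,
    gene_filter,
    qc_filter,
    triage_snvs,
)

from conftest import make_gene, make_variant

CFG = PipelineConfig()


class TestQcFilter:
    @pytest.mark.parametrize(
        "coverage,gq,maf,kept,reason",
        [
            (9, 50, None, False, "low_coverage"),   # below 10x is excluded
            (10, 15, 0.049, True, None),            # equality at both thresholds kept
            (50, 14, None, False, "low_gq"),
            (50, 50, 0.06, False, "common_maf"),    # MAF >= 5% excluded
            (50, 50, 0.05, False, "common_maf"),
            (50, 50, None, True, None),             # unannotated MAF passes
        ],
    )
    def test_thresholds(self, coverage, gq, maf, kept, reason):
        v = make_variant(coverage=coverage, gq=gq, gnomad_maf=maf)
        retained, dropped = qc_filter([v], CFG)
        assert bool(retained) == kept
        if not kept:
            assert dropped[0].reason == reason


class TestAssignInheritance:
    @pytest.mark.parametrize(
        "pro,fat,mot,sex,chrom,expect,consistent",
        [
            ("0/1", "0/0", "0/0", Sex.MALE, "1", Inheritance.DE_NOVO, True),
            ("0/1", "0/1", "0/0", Sex.MALE, "1", Inheritance.PATERNAL, True),
            ("0/1", "0/0", "0/1", Sex.MALE, "1", Inheritance.MATERNAL, True),
            ("0/1", "0/1", "0/1", Sex.MALE, "1", Inheritance.BIPARENTAL, True),
            # hemizygous X in a male resolves against the mother
            ("1", "0", "0/1", Sex.MALE, "X", Inheritance.MATERNAL, True),
            ("1", "0", "0/0", Sex.MALE, "X", Inheritance.DE_NOVO, True),
            # homozygous proband needs both parents as carriers
            ("1/1", "0/1", "0/1", Sex.FEMALE, "1", Inheritance.BIPARENTAL, True),
            ("1/1", "0/0", "0/1", Sex.MALE, "1", Inheritance.UNKNOWN, False),
            # incomplete trio data
            ("0/1", None, "0/1", Sex.MALE, "1", Inheritance.UNKNOWN, True),
        ],
    )
    def test_trio_rules(self, pro, fat, mot, sex, chrom, expect, consistent):
        inheritance, ok = assign_inheritance(pro, fat, mot, sex, chrom)
        assert inheritance is expect
        assert ok is consistent


class TestCompoundHetDetection:
    def test_distinct_parental_origins_pair(self):
        a = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL)
        b = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.PATERNAL)
        (pair,) = detect_compound_het([a, b])
        assert {pair.variant_a, pair.variant_b} == {a.key, b.key}

    def test_same_parent_does_not_pair(self):
        a = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL)
        b = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.MATERNAL)
        assert detect_compound_het([a, b]) == []

    def test_de_novo_counts_as_distinct_origin(self):
        a = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL)
        b = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.DE_NOVO)
        assert len(detect_compound_het([a, b])) == 1

    def test_synonymous_and_non_het_never_pair(self):
        a = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL,
                         consequence=Consequence.SYNONYMOUS)
        b = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.PATERNAL)
        c = make_variant(hgvs_c="c.3A>G", inheritance=Inheritance.MATERNAL,
                         zygosity=Zygosity.HOMOZYGOUS)
        assert detect_compound_het([a, b, c]) == []

    def test_variant_may_join_multiple_pairs(self):
        m = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL)
        p1 = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.PATERNAL)
        p2 = make_variant(hgvs_c="c.3A>G", inheritance=Inheritance.PATERNAL)
        assert len(detect_compound_het([m, p1, p2])) == 2


class TestGeneFilter:
    def test_sfari_gene_passes_any_variant(self):
        v = make_variant(inheritance=Inheritance.MATERNAL)
        assert gene_filter(v, make_gene(sfari=True), in_pair=False, config=CFG)

    def test_non_sfari_rare_frameshift_passes(self):
        v = make_variant(inheritance=Inheritance.MATERNAL,
                         consequence=Consequence.FRAMESHIFT, gnomad_maf=0.005)
        assert gene_filter(v, make_gene(sfari=False, tags=()), False, CFG)

    def test_non_sfari_common_frameshift_fails(self):
        v = make_variant(inheritance=Inheritance.MATERNAL,
                         consequence=Consequence.FRAMESHIFT, gnomad_maf=0.02)
        assert not gene_filter(v, make_gene(sfari=False, tags=()), False, CFG)

    def test_non_sfari_inherited_missense_singleton_fails(self):
        v = make_variant(inheritance=Inheritance.MATERNAL, gnomad_maf=0.005)
        assert not gene_filter(v, make_gene(sfari=False, tags=()), False, CFG)

    def test_non_sfari_de_novo_or_paired_passes(self):
        v = make_variant(inheritance=Inheritance.DE_NOVO)
        gene = make_gene(sfari=False, tags=())
        assert gene_filter(v, gene, False, CFG)
        w = make_variant(inheritance=Inheritance.MATERNAL)
        assert gene_filter(w, gene, True, CFG)


GENES = {"GENE1": make_gene("GENE1"), "GENE2": make_gene("GENE2")}


class TestRetentionCascade:
    def test_synonymous_de_novo_dropped(self):
        v = make_variant(consequence=Consequence.SYNONYMOUS)
        result = triage_snvs([v], GENES, CFG)
        assert not result.retained
        assert result.dropped[0].reason == "synonymous"

    def test_inherited_het_singleton_dropped(self):
        v = make_variant(inheritance=Inheritance.MATERNAL)
        result = triage_snvs([v], GENES, CFG)
        assert result.dropped[0].reason == "inherited_het"

    def test_homozygote_count_boundary(self):
        keep = make_variant(hgvs_c="c.1A>G", gnomad_hom_count=10)
        drop = make_variant(hgvs_c="c.2A>G", gene="GENE2", gnomad_hom_count=11)
        result = triage_snvs([keep, drop], GENES, CFG)
        assert result.retained_keys == {keep.key}
        assert any(d.reason == "hom_count" for d in result.dropped)

    def test_unannotated_hom_count_retained(self):
        v = make_variant(gnomad_hom_count=None)
        assert triage_snvs([v], GENES, CFG).retained_keys == {v.key}

    def test_lp_pair_rescued_regardless_of_hom_count(self):
        # (LP, VOUS) pair: the VOUS member has 50 homozygotes yet is kept
        lp = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL,
                          cadd=30.0, acmg=AcmgClass.VOUS, gnomad_hom_count=5)
        vous = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.PATERNAL,
                            cadd=18.0, acmg=AcmgClass.VOUS, gnomad_hom_count=50)
        result = triage_snvs([lp, vous], GENES, CFG)
        assert result.retained_keys == {lp.key, vous.key}
        by_key = {c.key: c for c in result.retained}
        assert by_key[lp.key].assigned_class is AcmgClass.LP
        assert by_key[vous.key].assigned_class is AcmgClass.VOUS
        assert by_key[lp.key].combined_class is AcmgClass.LP
        assert by_key[lp.key].compound_partner == vous.key
        assert by_key[vous.key].compound_partner == lp.key

    def test_orphaned_partner_falls_to_inherited_het(self):
        # (VOUS, VOUS) pair without the LP rescue: the 50-homozygote member
        # drops on count, which orphans its partner on the next sweep
        a = make_variant(hgvs_c="c.1A>G", inheritance=Inheritance.MATERNAL,
                         cadd=18.0, gnomad_hom_count=50)
        b = make_variant(hgvs_c="c.2A>G", inheritance=Inheritance.PATERNAL,
                         cadd=18.0, gnomad_hom_count=0)
        result = triage_snvs([a, b], GENES, CFG)
        assert result.retained == []
        reasons = {d.key: d.reason for d in result.dropped}
        assert reasons == {a.key: "hom_count", b.key: "inherited_het"}

    def test_each_drop_has_exactly_one_reason(self, default_cohort):
        from asdtriage.snv import triage_snvs as run

        result = run(default_cohort.variants, default_cohort.genes, CFG)
        keys = [d.key for d in result.dropped]
        assert len(keys) == len(set(keys))
        assert not (set(keys) & result.retained_keys)

    def test_idempotent_and_order_invariant(self, default_cohort):
        variants = list(default_cohort.variants)
        first = triage_snvs(variants, default_cohort.genes, CFG)
        again = triage_snvs([c.variant for c in first.retained],
                            default_cohort.genes, CFG)
        assert again.retained_keys == first.retained_keys
        assert not again.dropped
        shuffled = variants[::-1]
        assert (triage_snvs(shuffled, default_cohort.genes, CFG).retained_keys
                == first.retained_keys)
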