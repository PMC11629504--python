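"""Domain-type invariants and tabular round trips."""

import pytest

from asdtriage import io
from asdtriage.io import TableError
from asdtriage.model import (
    AcmgClass,
    Affected,
    ClassifiedVariant,
    CnvCall,
    Consequence,
    CopyState,
    Inheritance,
    ModelError,
    PedigreeMember,
    Sex,
    SfariScore,
    Zygosity,
)

from conftest import make_variant

PED_TRIO = "F001 A001 A001-F A001-M 1 2\nF001 A001-F 0 0 1 1\nF001 A001-M 0 0 2 1\n"

VARIANT_HEADER = "\t".join(io.VARIANT_COLUMNS)


def _variant_line(**overrides):
    row = {
        "patient_id": "A001", "family_id": "F001", "gene": "GENE1",
        "hgvs_c": "c.100A>G", "chrom": "1", "pos": "1500", "ref": "A", "alt": "G",
        "consequence": "missense", "zygosity": "heterozygous",
        "inheritance": "de_novo", "cadd": "25.0", "acmg": "LP",
        "gnomad_maf": "", "gnomad_hom": "", "coverage": "50", "gq": "90",
    }
    row.update(overrides)
    return "\t".join(row[c] for c in io.VARIANT_COLUMNS)


class TestPedigree:
    def test_standard_trio(self, tmp_path):
        p = tmp_path / "trio.ped"
        p.write_text(PED_TRIO)
        members = io.read_pedigree(p)
        assert len(members) == 3
        proband = members[0]
        assert proband.sex is Sex.MALE and proband.affected is Affected.AFFECTED
        assert io.trio_complete(proband, members)
        assert io.probands(members) == [proband]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.ped"
        p.write_text("")
        assert io.read_pedigree(p) == []

    def test_absent_mother_flags_incomplete_trio(self, tmp_path, caplog):
        p = tmp_path / "t.ped"
        p.write_text("F001 A001 A001-F A001-M 1 2\nF001 A001-F 0 0 1 1\n")
        with caplog.at_level("WARNING", logger="asdtriage"):
            members = io.read_pedigree(p)
        assert not io.trio_complete(members[0], members)
        assert io.probands(members) == []
        assert any("absent parent" in r.message for r in caplog.records)

    def test_duplicate_individual_is_error(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 A1 0 0 1 2\nF1 A1 0 0 1 2\n")
        with pytest.raises(TableError, match="duplicate"):
            io.read_pedigree(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 A1 0 0 1 2\nF1 A2 0 0\n")
        with pytest.raises(TableError, match="row 2"):
            io.read_pedigree(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "trio.ped"
        p.write_text(PED_TRIO)
        members = io.read_pedigree(p)
        q = tmp_path / "out.ped"
        io.write_pedigree(members, q)
        assert io.read_pedigree(q) == members


class TestVariantTable:
    def test_missing_gnomad_is_absent_not_zero(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER + "\n" + _variant_line() + "\n")
        (v,) = io.read_variant_table(p)
        assert v.gnomad_hom_count is None
        assert v.gnomad_maf is None
        assert v.acmg is AcmgClass.LP

    def test_unknown_enum_token_names_row_and_column(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER + "\n" + _variant_line(zygosity="weird") + "\n")
        with pytest.raises(TableError, match=r"row 2.*zygosity"):
            io.read_variant_table(p)

    def test_non_numeric_cadd_is_error(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER + "\n" + _variant_line(cadd="high") + "\n")
        with pytest.raises(TableError, match="cadd"):
            io.read_variant_table(p)

    def test_hemizygous_female_warns(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            VARIANT_HEADER + "\n"
            + _variant_line(chrom="X", zygosity="hemizygous") + "\n"
        )
        variants = io.read_variant_table(p)
        members = [PedigreeMember("F001", "A001", None, None, Sex.FEMALE,
                                  Affected.AFFECTED)]
        warnings = io.validate_variants_against_pedigree(variants, members)
        assert any("hemizygous" in w for w in warnings)

    def test_hemizygous_autosome_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER + "\n" + _variant_line(zygosity="hemizygous") + "\n")
        with pytest.raises(TableError, match="hemizygous"):
            io.read_variant_table(p)


CNV_HEADER = "\t".join(io.CNV_COLUMNS)


def _cnv_line(**overrides):
    row = {
        "patient_id": "A001", "chrom": "14", "start": "79388339",
        "end": "79657573", "copy_state": "loss", "copy_number": "1",
        "inheritance": "de_novo", "prior_class": "P", "dgv_frequency": "",
        "band_start": "14q31.1", "band_end": "14q31.1",
    }
    row.update(overrides)
    return "\t".join(row[c] for c in io.CNV_COLUMNS)


class TestCnvTable:
    def test_size_recomputed_from_coordinates(self, tmp_path):
        # 269.24 kb intragenic deletion: 79657573 - 79388339 + 1
        p = tmp_path / "c.tsv"
        p.write_text(CNV_HEADER + "\n" + _cnv_line() + "\n")
        (c,) = io.read_cnv_table(p)
        assert c.size_bp == 269_235
        assert c.dgv_frequency is None

    def test_start_after_end_is_error(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(CNV_HEADER + "\n" + _cnv_line(start="80000000") + "\n")
        with pytest.raises(TableError, match="start > end"):
            io.read_cnv_table(p)

    def test_declared_size_mismatch_is_error(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(CNV_HEADER + "\tsize_bp\n" + _cnv_line() + "\t100\n")
        with pytest.raises(TableError, match="size"):
            io.read_cnv_table(p)

    def test_autosomal_state_number_consistency(self):
        with pytest.raises(ModelError, match="copy_number"):
            CnvCall("A1", "1", 100, 200, CopyState.LOSS, 2,
                    Inheritance.MATERNAL, AcmgClass.VOUS)


GENE_HEADER = "\t".join(io.GENE_COLUMNS)


def _gene_line(**overrides):
    row = {
        "symbol": "KCND1", "chrom": "X", "start": "1000", "end": "90000",
        "strand": "+", "sfari_member": "true", "sfari_score": "2B",
        "function_tags": "synaptic_transmission;neurodevelopment",
        "family_name": "", "brain_expression_pct": "85.0",
        "haploinsufficient": "", "triplosensitive": "",
    }
    row.update(overrides)
    return "\t".join(row[c] for c in io.GENE_COLUMNS)


class TestGeneMetadata:
    def test_score_2b_normalises_to_tier_2(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(GENE_HEADER + "\n" + _gene_line() + "\n")
        genes = io.read_gene_metadata(p)
        g = genes["KCND1"]
        assert g.sfari_member and g.sfari_score is SfariScore.S2
        assert g.has_criterion4_tag()

    def test_duplicate_symbol_is_error(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(GENE_HEADER + "\n" + _gene_line() + "\n" + _gene_line() + "\n")
        with pytest.raises(TableError, match="duplicate"):
            io.read_gene_metadata(p)

    def test_absent_gene_gets_non_sfari_default(self):
        g = io.default_gene_record("NOVEL1")
        assert not g.sfari_member and not g.function_tags

    def test_round_trip(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(GENE_HEADER + "\n" + _gene_line() + "\n")
        genes = io.read_gene_metadata(p)
        q = tmp_path / "out.tsv"
        io.write_gene_metadata(genes, q)
        assert io.read_gene_metadata(q) == genes


class TestResults:
    def _classified(self):
        return [
            ClassifiedVariant(
                variant=make_variant(gene="B1", hgvs_c="c.2T>C"),
                assigned_class=AcmgClass.LP,
                rule_trace=["sfari_branch", "class_LP"],
            ),
            ClassifiedVariant(
                variant=make_variant(gene="A1", gnomad_maf=0.001,
                                     gnomad_hom_count=None),
                assigned_class=AcmgClass.VOUS,
                rule_trace=["class_VOUS_default"],
            ),
        ]

    def test_round_trip_exact(self, tmp_path, default_result):
        import pandas as pd

        paths = io.write_results(tmp_path, self._classified(), [],
                                 pd.DataFrame(columns=["section", "key", "value"]))
        back = io.read_classified_table(paths["classified"])
        original = sorted(self._classified(), key=lambda c: c.key)
        assert back == original

    def test_round_trip_full_cohort(self, tmp_path, default_result):
        from asdtriage.summary import summary_frame

        paths = io.write_results(
            tmp_path, default_result.classified, default_result.findings,
            summary_frame(default_result.summary), default_result.snv.dropped,
        )
        back = io.read_classified_table(paths["classified"])
        assert back == sorted(default_result.classified,
                              key=lambda c: (c.variant.patient_id, c.variant.gene,
                                             c.variant.hgvs_c))
        findings = io.read_findings_table(paths["findings"])
        assert {f.patient_id: f.best_class for f in findings} == {
            f.patient_id: f.best_class for f in default_result.findings
        }

    def test_same_inputs_give_identical_bytes(self, tmp_path):
        import pandas as pd

        frame = pd.DataFrame(columns=["section", "key", "value"])
        p1 = io.write_results(tmp_path / "a", self._classified(), [], frame)
        p2 = io.write_results(tmp_path / "b", self._classified()[::-1], [], frame)
        assert p1["classified"].read_bytes() == p2["classified"].read_bytes()

    def test_empty_cohort_writes_headers_only(self, tmp_path):
        import pandas as pd

        paths = io.write_results(tmp_path, [], [],
                                 pd.DataFrame(columns=["section", "key", "value"]))
        lines = paths["classified"].read_text().splitlines()
        assert lines == ["\t".join(io.CLASSIFIED_COLUMNS)]
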