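"""Cohort statistics: findings, rates, recurrence, families, rounding."""

import pytest

from asdtriage.config import PipelineConfig
from asdtriage.model import (
    AcmgClass,
    Affected,
    BestClass,
    ClassifiedVariant,
    CnvCall,
    CopyState,
    FindingSource,
    Inheritance,
    PatientFinding,
    PedigreeMember,
    Sex,
)
from asdtriage.summary import (
    best_finding,
    detection_rates,
    gene_family_summary,
    percent,
    recurrence_and_private,
    round_half_away,
    sex_stratified_positivity,
)

from conftest import make_gene, make_variant

CFG = PipelineConfig()


def classified(pid="A001", gene="G1", hgvs="c.1A>G", cls=AcmgClass.VOUS,
               combined=None, partner=None):
    return ClassifiedVariant(
        variant=make_variant(patient_id=pid, gene=gene, hgvs_c=hgvs),
        assigned_class=cls, rule_trace=["t"],
        compound_partner=partner, combined_class=combined,
    )


def cnv(pid="A001", prior=AcmgClass.VOUS):
    return CnvCall(pid, "1", 100, 200, CopyState.LOSS, 1,
                   Inheritance.MATERNAL, prior)


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [
            (2.5, 0, 3.0),        # half away from zero, not banker's
            (0.125, 2, 0.13),
            (11.4754, 1, 11.5),
            (23.913, 0, 24.0),
            (-2.5, 0, -3.0),
        ],
    )
    def test_half_away(self, value, decimals, expected):
        assert round_half_away(value, decimals) == expected

    def test_percent_against_printed_cohort_values(self):
        assert percent(30, 104, 1) == 28.8  # consistent rounding of 28.846
        assert percent(1, 122, 2) == 0.82
        assert percent(5, 18, 1) == 27.8

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0, 1)


class TestBestFinding:
    def test_sequence_beats_weaker_cnv(self):
        f = best_finding("A001", [classified(cls=AcmgClass.LP)],
                         [cnv(prior=AcmgClass.VOUS)])
        assert (f.best_class, f.source) == (BestClass.LP, FindingSource.SEQUENCE)

    def test_cnv_only_pathogenic(self):
        f = best_finding("A001", [], [cnv(prior=AcmgClass.P)])
        assert (f.best_class, f.source) == (BestClass.P, FindingSource.CNV)

    def test_both_when_platforms_tie(self):
        f = best_finding("A001", [classified(cls=AcmgClass.LP)],
                         [cnv(prior=AcmgClass.LP)])
        assert f.source is FindingSource.BOTH

    def test_no_findings(self):
        f = best_finding("A001", [], [])
        assert (f.best_class, f.source) == (BestClass.NONE, FindingSource.NONE)

    def test_lb_only_patient_has_no_finding(self):
        f = best_finding("A001", [classified(cls=AcmgClass.LB)], [])
        assert f.best_class is BestClass.NONE

    def test_pair_level_class_used_for_members(self):
        a = classified(hgvs="c.1A>G", cls=AcmgClass.VOUS,
                       combined=AcmgClass.LP, partner="x")
        f = best_finding("A001", [a], [])
        assert f.best_class is BestClass.LP


def _members(n_m, n_f):
    members = []
    for i in range(n_m + n_f):
        pid = f"A{i:03d}"
        sex = Sex.MALE if i < n_m else Sex.FEMALE
        members.append(PedigreeMember(f"F{i:03d}", pid, f"{pid}-F", f"{pid}-M",
                                      sex, Affected.AFFECTED))
        members.append(PedigreeMember(f"F{i:03d}", f"{pid}-F", None, None,
                                      Sex.MALE, Affected.UNAFFECTED))
        members.append(PedigreeMember(f"F{i:03d}", f"{pid}-M", None, None,
                                      Sex.FEMALE, Affected.UNAFFECTED))
    return members


def _findings(spec):
    """spec: list of (count, tier, source)."""
    findings, i = [], 0
    for count, tier, source in spec:
        for _ in range(count):
            findings.append(PatientFinding(f"A{i:03d}", tier, source,
                                           ["k"] if tier is not BestClass.NONE
                                           else []))
            i += 1
    return findings


class TestDetectionRates:
    def test_small_cohort_arithmetic(self):
        findings = _findings([
            (1, BestClass.P, FindingSource.SEQUENCE),
            (2, BestClass.LP, FindingSource.CNV),
            (1, BestClass.NONE, FindingSource.NONE),
        ])
        s = detection_rates(findings, _members(3, 1), CFG)
        assert s.category_counts[BestClass.P] == 1
        assert s.category_rates[BestClass.P] == 25.0
        assert s.overall_detection_rate == 75.0
        assert s.male_female_ratio == 3.0

    def test_duplicate_patient_rejected(self):
        f = PatientFinding("A000", BestClass.NONE, FindingSource.NONE, [])
        with pytest.raises(ValueError, match="one finding per proband"):
            detection_rates([f, f], _members(1, 0), CFG)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ZeroDivisionError):
            detection_rates([], [], CFG)


class TestRecurrenceAndPrivate:
    def test_sibling_carriers_are_recurrent(self):
        # one key carried by three siblings: recurrent, not private
        shared = [classified(pid=p, gene="MAG", hgvs="c.181G>A")
                  for p in ("A057", "A058", "A059")]
        private = [classified(pid="A001", gene="G2", hgvs="c.9A>T")]
        recurrence, private_tbl, dist = recurrence_and_private(
            shared + private, CFG)
        assert recurrence.iloc[0]["n_patients"] == 3
        assert list(private_tbl["gene"]) == ["G2"]
        assert "MAG" in recurrence.attrs["recurrent_genes"]

    def test_partition_of_key_set(self, default_result):
        recurrence, private_tbl, _ = recurrence_and_private(
            default_result.classified, CFG)
        keys = {(c.variant.gene, c.variant.hgvs_c)
                for c in default_result.classified}
        split = (set(map(tuple, recurrence[["gene", "hgvs_c"]].values))
                 | set(map(tuple, private_tbl[["gene", "hgvs_c"]].values)))
        assert split == keys
        assert not (set(map(tuple, recurrence[["gene", "hgvs_c"]].values))
                    & set(map(tuple, private_tbl[["gene", "hgvs_c"]].values)))

    def test_printed_private_distribution(self):
        # 95 private variants split 2 P / 24 LP / 61 VOUS / 8 LB
        rows = []
        i = 0
        for cls, n in [(AcmgClass.P, 2), (AcmgClass.LP, 24),
                       (AcmgClass.VOUS, 61), (AcmgClass.LB, 8)]:
            for _ in range(n):
                rows.append(classified(pid=f"A{i:03d}", gene=f"G{i}",
                                       hgvs=f"c.{i}A>G", cls=cls))
                i += 1
        _, private_tbl, dist = recurrence_and_private(rows, CFG)
        assert len(private_tbl) == 95
        assert dist == {AcmgClass.P: 2.1, AcmgClass.LP: 25.3,
                        AcmgClass.VOUS: 64.2, AcmgClass.LB: 8.4}


class TestSexPositivity:
    def test_rates_by_sex(self):
        members = _members(104, 18)
        ids = {m.individual_id for m in members if m.affected is Affected.AFFECTED}
        males = sorted(i for i in ids if int(i[1:]) < 104)
        females = sorted(i for i in ids if int(i[1:]) >= 104)
        positives = set(males[:30]) | set(females[:5])
        rates = sex_stratified_positivity(positives, members, ids, CFG)
        assert rates[Sex.FEMALE] == 27.8
        assert rates[Sex.MALE] == 28.8

    def test_zero_positive(self):
        members = _members(2, 2)
        ids = {m.individual_id for m in members if m.affected is Affected.AFFECTED}
        rates = sex_stratified_positivity(set(), members, ids, CFG)
        assert rates == {Sex.MALE: 0.0, Sex.FEMALE: 0.0}


class TestGeneFamilies:
    GENES = {
        "ANK2": make_gene("ANK2", family_name="Ankyrin"),
        "ANK3": make_gene("ANK3", family_name="Ankyrin"),
        "SOLO": make_gene("SOLO", family_name="Singleton"),
        "NOFAM": make_gene("NOFAM"),
    }

    def _classified(self):
        return [classified(pid="A052", gene="ANK2"),
                classified(pid="A116", gene="ANK3"),
                classified(pid="A001", gene="SOLO"),
                classified(pid="A002", gene="NOFAM")]

    def test_family_grouping(self):
        table = gene_family_summary(self._classified(), self.GENES, CFG)
        assert list(table["family"]) == ["Ankyrin"]
        row = table.iloc[0]
        assert row["n_genes"] == 2 and row["genes"] == "ANK2;ANK3"

    def test_genome_wide_sizes_override_observed(self):
        table = gene_family_summary(self._classified(), self.GENES, CFG,
                                    genome_family_sizes={"Singleton": 7})
        assert set(table["family"]) == {"Ankyrin", "Singleton"}

    def test_min_size_larger_than_any_family(self):
        cfg = CFG.with_overrides(min_family_size=10)
        assert gene_family_summary(self._classified(), self.GENES, cfg).empty
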