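"""End-to-end orchestration: triage both platforms, resolve findings,
summarise the cohort, and (for synthetic cohorts) score label recovery."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classify import annotate_incomplete_penetrance, upgrade_unique_candidate
from .cnv import CnvTriageResult, triage_cnvs
from .config import PipelineConfig
from . import io
from .model import (
    AnnotatedVariant,
    ArrayQc,
    CnvCall,
    GeneRecord,
    PatientFinding,
    PedigreeMember,
)
from .snv import SnvTriageResult, triage_snvs
from .summary import (
    CohortSummary,
    best_finding,
    cnv_composition,
    cnv_detection_counts,
    detection_rates,
    gene_family_summary,
    recurrence_and_private,
    sex_stratified_positivity,
    summary_frame,
)


@dataclass
class PipelineResult:
    snv: SnvTriageResult
    cnv: CnvTriageResult
    findings: list[PatientFinding]
    summary: CohortSummary
    summary_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def classified(self):
        return self.snv.retained


def run_pipeline(
    variants: Sequence[AnnotatedVariant],
    cnvs: Sequence[CnvCall],
    genes: dict[str, GeneRecord],
    array_qc: Sequence[ArrayQc],
    members: Sequence[PedigreeMember],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    io.validate_variants_against_pedigree(variants, members)
    proband_ids = sorted(m.individual_id for m in io.probands(members))

    snv_result = triage_snvs(variants, genes, config)
    annotate_incomplete_penetrance(snv_result.retained)
    cnv_result = triage_cnvs(cnvs, genes, array_qc, config)

    findings = [
        best_finding(pid, snv_result.retained, cnv_result.retained)
        for pid in proband_ids
    ]
    findings = upgrade_unique_candidate(
        findings, snv_result.retained, cnv_result.retained, genes, config
    )

    summary = detection_rates(findings, members, config)
    comp_counts, comp_rates = cnv_composition(cnv_result, config)
    det_counts, det_rates = cnv_detection_counts(
        cnv_result.retained, len(proband_ids), config
    )
    summary.cnv_counts = {**comp_counts, **det_counts}
    summary.cnv_rates = {**comp_rates, **det_rates}
    summary.sex_positivity = sex_stratified_positivity(
        {c.patient_id for c in cnv_result.retained}, members,
        set(proband_ids), config,
    )
    (summary.recurrence_table, summary.private_table,
     summary.private_class_rates) = recurrence_and_private(
        snv_result.retained, config
    )
    summary.family_table = gene_family_summary(snv_result.retained, genes, config)

    result = PipelineResult(snv_result, cnv_result, findings, summary)
    result.summary_table = summary_frame(summary)
    return result


def run_from_paths(
    variants_path: str | Path,
    cnvs_path: str | Path,
    genes_path: str | Path,
    array_qc_path: str | Path,
    pedigree_path: str | Path,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    return run_pipeline(
        io.read_variant_table(variants_path),
        io.read_cnv_table(cnvs_path),
        io.read_gene_metadata(genes_path),
        io.read_array_qc(array_qc_path),
        io.read_pedigree(pedigree_path),
        config,
    )


# ---------------------------------------------------------------------------
# truth-label recovery (synthetic cohorts)

def evaluate_against_truth(
    result: PipelineResult, truth: pd.DataFrame
) -> dict:
    """Compare pipeline output with a synthetic cohort's planted labels.

    Scores retention flags, assigned/pair classes and drop reasons for
    variants, retention for CNVs, and tier/source for patients. Returns
    the agreement fraction and the list of mismatches (empty when the
    pipeline reproduces the plan exactly).
    """
    classified = {c.key: c for c in result.snv.retained}
    dropped = {d.key: d for d in result.snv.dropped}
    cnv_retained = {c.key for c in result.cnv.retained}
    cnv_dropped = {d.key: d for d in result.cnv.dropped}
    findings = {f.patient_id: f for f in result.findings}

    mismatches: list[str] = []
    n = 0
    for row in truth.itertuples(index=False):
        n += 1
        if row.record_type == "variant":
            expect_keep = row.expected_retained == "true"
            got = classified.get(row.key)
            if expect_keep:
                if got is None:
                    mismatches.append(f"{row.key}: expected retained, was dropped "
                                      f"({dropped.get(row.key)})")
                    continue
                if got.assigned_class.value != row.expected_class:
                    mismatches.append(
                        f"{row.key}: class {got.assigned_class.value} != "
                        f"{row.expected_class}"
                    )
                combined = got.combined_class.value if got.combined_class else ""
                if combined != row.expected_combined_class:
                    mismatches.append(
                        f"{row.key}: combined {combined!r} != "
                        f"{row.expected_combined_class!r}"
                    )
            else:
                if got is not None:
                    mismatches.append(f"{row.key}: expected dropped, was retained")
                    continue
                drop = dropped.get(row.key)
                if drop is None or drop.reason != row.expected_drop_reason:
                    mismatches.append(
                        f"{row.key}: drop reason "
                        f"{drop.reason if drop else None!r} != "
                        f"{row.expected_drop_reason!r}"
                    )
        elif row.record_type == "cnv":
            expect_keep = row.expected_retained == "true"
            if expect_keep != (row.key in cnv_retained):
                mismatches.append(f"{row.key}: CNV retention mismatch")
            elif not expect_keep:
                drop = cnv_dropped.get(row.key)
                if drop is None or drop.reason != row.expected_drop_reason:
                    mismatches.append(f"{row.key}: CNV drop reason mismatch")
        elif row.record_type == "patient":
            f = findings.get(row.key)
            if f is None:
                mismatches.append(f"{row.key}: no finding")
                continue
            if f.best_class.value != row.expected_tier:
                mismatches.append(
                    f"{row.key}: tier {f.best_class.value} != {row.expected_tier}"
                )
            if f.source.value != row.expected_source:
                mismatches.append(
                    f"{row.key}: source {f.source.value} != {row.expected_source}"
                )
    # a record may raise several messages; score records, not messages
    bad_records = len({m.split(": ", 1)[0] for m in mismatches})
    agreement = 100.0 * (n - bad_records) / n if n else 100.0
    return {"n_records": n, "n_mismatches": bad_records,
            "agreement_pct": agreement, "mismatches": mismatches}
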