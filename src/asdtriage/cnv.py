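"""Array-CGH CNV triage: QC gate, retention, gene overlap and labeling.

CNV pathogenicity itself is consumed as the ``prior_class`` annotation
(assigned upstream under the ACMG/ClinGen CNV guidelines); this module
filters calls, types the rearrangement of each overlapped gene, ranks
genes of interest and renders compact ISCN-style labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .config import PipelineConfig
from .model import (
    AcmgClass,
    ArrayQc,
    CnvCall,
    CopyState,
    DropRecord,
    GeneRecord,
    Inheritance,
    Rearrangement,
    SFARI_RANK,
)

log = logging.getLogger("asdtriage")


@dataclass(frozen=True)
class GeneOverlap:
    cnv_key: str
    gene: str
    rearrangement: Rearrangement


# ---------------------------------------------------------------------------
# QC and retention

def array_qc_check(qc: ArrayQc, config: PipelineConfig) -> bool:
    """Array-level QC gate: SD < 1.0 and DLR spread < 0.3 (both strict)."""
    return qc.sd < config.array_qc_max_sd and qc.dlr_spread < config.array_qc_max_dlr_spread


def cnv_retention_filter(cnv: CnvCall, config: PipelineConfig) -> bool:
    """Retain calls that are neither benign-tier nor common.

    Benign and likely-benign calls are excluded, as are calls seen in
    more than 1% of healthy subjects in DGV (strictly greater; exactly
    1% is retained, and an absent frequency passes).
    """
    if cnv.prior_class in (AcmgClass.B, AcmgClass.LB):
        return False
    if cnv.dgv_frequency is not None and cnv.dgv_frequency > config.max_dgv_frequency:
        return False
    return True


# ---------------------------------------------------------------------------
# rearrangement typing

class OverlapError(ValueError):
    pass


def rearrangement_type(cnv: CnvCall, gene: GeneRecord) -> Rearrangement:
    """Label how a CNV rearranges one overlapping gene.

    Full gene inside the CNV -> DELETED/DUPLICATED by copy state; CNV
    inside the gene -> INTRAGENIC; partial overlaps are labelled by
    which transcriptional terminus of the gene lies inside the CNV,
    strand-aware (unknown strand treated as +). Intervals are closed and
    1-based; a single shared base counts as overlap. When the two
    intervals coincide exactly, whole-gene containment wins.
    """
    if cnv.chrom != gene.chrom or cnv.end < gene.start or gene.end < cnv.start:
        raise OverlapError(
            f"{cnv.key} does not overlap {gene.symbol} "
            f"({gene.chrom}:{gene.start}-{gene.end})"
        )
    if cnv.start <= gene.start and gene.end <= cnv.end:
        return (
            Rearrangement.DELETED
            if cnv.copy_state is CopyState.LOSS
            else Rearrangement.DUPLICATED
        )
    if gene.start <= cnv.start and cnv.end <= gene.end:
        return Rearrangement.INTRAGENIC
    if cnv.start <= gene.tss() <= cnv.end:
        return Rearrangement.INT_START
    return Rearrangement.INT_END


def overlapping_genes(
    cnv: CnvCall, gene_index: dict[str, IntervalTree], genes: dict[str, GeneRecord]
) -> list[GeneRecord]:
    tree = gene_index.get(cnv.chrom)
    if tree is None:
        return []
    # interval tree is half-open; +1 converts the closed 1-based end
    hits = tree.overlap(cnv.start, cnv.end + 1)
    return sorted((genes[h.data] for h in hits), key=lambda g: (g.start, g.symbol))


def build_gene_index(genes: dict[str, GeneRecord]) -> dict[str, IntervalTree]:
    index: dict[str, IntervalTree] = {}
    for g in genes.values():
        index.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.symbol)
    return index


# ---------------------------------------------------------------------------
# genes of interest

def genes_of_interest(
    cnv: CnvCall, overlapped: Sequence[GeneRecord], config: PipelineConfig
) -> list[str]:
    """Rank the genes of a CNV by candidacy for the phenotype.

    A monogenic CNV nominates its single gene. Multi-gene CNVs are
    ranked lexicographically by SFARI score tier (1 < 2 < 3 < S < none),
    presence of a neurodevelopmental function tag, dosage-sensitivity
    flag matching the copy state (haploinsufficiency for losses,
    triplosensitivity for gains), brain expression percentile
    (descending, unannotated last), then symbol. The order is total and
    deterministic.
    """
    if not overlapped:
        log.warning("%s: no overlapped genes", cnv.key)
        return []

    def rank(g: GeneRecord):
        dosage = (
            g.haploinsufficient if cnv.copy_state is CopyState.LOSS else g.triplosensitive
        )
        return (
            SFARI_RANK[g.sfari_score],
            0 if g.has_criterion4_tag(config.criterion4_tags) else 1,
            0 if dosage else 1,
            g.brain_expression_pct is None,
            -(g.brain_expression_pct or 0.0),
            g.symbol,
        )

    return [g.symbol for g in sorted(overlapped, key=rank)]


# ---------------------------------------------------------------------------
# ISCN-style labels

_INHERITANCE_SUFFIX = {
    Inheritance.PATERNAL: "pat",
    Inheritance.MATERNAL: "mat",
    Inheritance.DE_NOVO: "de novo",
}


def format_iscn(cnv: CnvCall) -> str:
    """Compact band/coordinate/copy-number label, e.g.
    ``14q31.1(79388339_79657573)x1 de novo``."""
    if cnv.band_start:
        band = cnv.band_start
        if cnv.band_end and cnv.band_end != cnv.band_start:
            # two-band span: the chromosome number is not repeated
            # (13q14.13 + 13q14.2 -> "13q14.13q14.2")
            end = cnv.band_end
            if end.startswith(cnv.chrom):
                end = end[len(cnv.chrom):]
            band += end
    else:
        log.warning("%s: cytoband labels missing; label has no band prefix", cnv.key)
        band = ""
    label = f"{band}({cnv.start}_{cnv.end})x{cnv.copy_number}"
    suffix = _INHERITANCE_SUFFIX.get(cnv.inheritance)
    return f"{label} {suffix}" if suffix else label


# ---------------------------------------------------------------------------
# full CNV triage

@dataclass
class CnvTriageResult:
    retained: list[CnvCall] = field(default_factory=list)
    dropped: list[DropRecord] = field(default_factory=list)
    overlaps: dict[str, list[GeneOverlap]] = field(default_factory=dict)
    genes_of_interest: dict[str, list[str]] = field(default_factory=dict)
    iscn_labels: dict[str, str] = field(default_factory=dict)
    qc_failed_patients: set[str] = field(default_factory=set)

    def is_intragenic(self, cnv: CnvCall) -> bool:
        """A CNV whose breakpoints both fall within overlapped gene(s)."""
        ovl = self.overlaps.get(cnv.key, [])
        return bool(ovl) and all(
            o.rearrangement is Rearrangement.INTRAGENIC for o in ovl
        )


def triage_cnvs(
    cnvs: Sequence[CnvCall],
    genes: dict[str, GeneRecord],
    array_qc: Sequence[ArrayQc],
    config: PipelineConfig,
) -> CnvTriageResult:
    result = CnvTriageResult()
    qc_by_patient = {q.patient_id: q for q in array_qc}
    for q in array_qc:
        if not array_qc_check(q, config):
            result.qc_failed_patients.add(q.patient_id)
            log.warning(
                "patient %s failed array QC (sd=%.3g, dlr=%.3g); CNVs excluded",
                q.patient_id, q.sd, q.dlr_spread,
            )

    index = build_gene_index(genes)
    for cnv in cnvs:
        if cnv.patient_id in result.qc_failed_patients:
            result.dropped.append(
                DropRecord(cnv.key, cnv.patient_id, "array_qc", "array_qc_fail")
            )
            continue
        if cnv.patient_id not in qc_by_patient:
            log.warning("patient %s has no array QC record; assuming pass",
                        cnv.patient_id)
        if not cnv_retention_filter(cnv, config):
            reason = (
                "benign_class"
                if cnv.prior_class in (AcmgClass.B, AcmgClass.LB)
                else "dgv_frequency"
            )
            result.dropped.append(
                DropRecord(cnv.key, cnv.patient_id, "cnv_retention", reason)
            )
            continue
        result.retained.append(cnv)
        hits = overlapping_genes(cnv, index, genes)
        result.overlaps[cnv.key] = [
            GeneOverlap(cnv.key, g.symbol, rearrangement_type(cnv, g)) for g in hits
        ]
        result.genes_of_interest[cnv.key] = genes_of_interest(cnv, hits, config)
        result.iscn_labels[cnv.key] = format_iscn(cnv)
    return result
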