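"""Rule-based pathogenicity classifier for retained sequence variants.

Variants are scored on four criteria:

1. in-silico deleteriousness: CADD PHRED >= 20;
2. clinical prior: ACMG class P or LP (the ACMG class is an input
   annotation, not computed here);
3. population constraint: absent from gnomAD or at most one homozygote;
4. gene function: the gene carries at least one neurodevelopmental
   involvement tag (neurodevelopment, nervous-system function, synaptic
   transmission, epigenetic transcription regulation).

Genes on the SFARI autism panel can reach P; variants in non-SFARI genes
are capped at LP because their contribution to the ASD phenotype is
unestablished. Compound-heterozygous pairs receive a pair-level class
from a fixed combination matrix, and a proband whose single retained
candidate is an LP variant in a SFARI gene can be upgraded to P
(unique-candidate rule).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .config import PipelineConfig, normalize_pair
from .model import (
    AcmgClass,
    BestClass,
    ClassifiedVariant,
    CnvCall,
    FindingSource,
    GeneRecord,
    PatientFinding,
)


class ClassificationError(ValueError):
    """Raised when a variant cannot be classified (missing CADD/ACMG)."""


def classify_variant(
    variant, gene: GeneRecord, config: PipelineConfig
) -> tuple[AcmgClass, list[str]]:
    """Assign a five-tier class; returns ``(class, fired-rule trace)``.

    Total on its inputs: every (SFARI membership, CADD, ACMG, homozygote
    count, function tags) combination yields exactly one class.
    """
    cadd = variant.cadd
    acmg = variant.acmg
    if cadd is None or not math.isfinite(cadd):
        raise ClassificationError(f"{variant.key}: CADD score missing or non-finite")
    if acmg is None:
        raise ClassificationError(f"{variant.key}: ACMG evaluation missing")
    hom = variant.gnomad_hom_count

    c1 = cadd >= config.cadd_path_min
    c2 = acmg in (AcmgClass.P, AcmgClass.LP)
    c3 = hom is None or hom <= config.hom_path_max
    c4 = gene.has_criterion4_tag(config.criterion4_tags)
    hom_lp_band = hom is not None and config.hom_lp_min <= hom <= config.hom_lp_max
    if config.lp_allow_low_hom:
        hom_lp_band = hom_lp_band or c3

    trace: list[str] = []
    if gene.sfari_member:
        trace.append("sfari_branch")
        if c1 and c2 and c3:
            trace += ["criterion1_cadd", "criterion2_acmg", "criterion3_hom", "class_P"]
            return AcmgClass.P, trace
        if (
            hom_lp_band
            and c1
            and acmg in (AcmgClass.P, AcmgClass.LP, AcmgClass.VOUS)
            and c4
        ):
            trace += ["criterion1_cadd", "hom_2_10_band", "criterion4_function",
                      "class_LP"]
            return AcmgClass.LP, trace
        if cadd < config.cadd_benign_max and acmg is AcmgClass.LB:
            trace += ["cadd_below_benign", "acmg_lb", "class_LB"]
            return AcmgClass.LB, trace
        trace.append("class_VOUS_default")
        return AcmgClass.VOUS, trace

    trace.append("non_sfari_branch")
    if c1 and c2 and c4:
        if config.allow_non_sfari_pathogenic and c3:
            trace += ["criterion1_cadd", "criterion2_acmg", "criterion3_hom",
                      "class_P_non_sfari"]
            return AcmgClass.P, trace
        trace += ["criterion1_cadd", "criterion2_acmg", "criterion4_function",
                  "class_LP_capped"]
        return AcmgClass.LP, trace
    if cadd < config.cadd_benign_max and acmg in (
        AcmgClass.B, AcmgClass.LB, AcmgClass.VOUS
    ):
        # "LB or B" outputs collapse to LB; the tiers are never distinguished
        # downstream.
        trace += ["cadd_below_benign", "acmg_b_lb_vous", "class_LB"]
        return AcmgClass.LB, trace
    trace.append("class_VOUS_default")
    return AcmgClass.VOUS, trace


class CombinationError(ValueError):
    """A compound-het pair contained a class the matrix does not accept."""


def combine_compound_het(
    class_a: AcmgClass, class_b: AcmgClass, config: PipelineConfig
) -> AcmgClass:
    """Pair-level class for a compound-heterozygous couple.

    Commutative by construction: the pair is severity-normalised before
    the matrix lookup. Benign (B) members are pre-excluded upstream and
    are an error here.
    """
    if AcmgClass.B in (class_a, class_b):
        raise CombinationError("class B variants are excluded before pairing")
    pair = normalize_pair(class_a, class_b)
    try:
        return config.combination_matrix[pair]
    except KeyError:
        raise CombinationError(
            f"no combination rule for pair ({pair[0].value}, {pair[1].value})"
        ) from None


def upgrade_unique_candidate(
    findings: Sequence[PatientFinding],
    classified: Sequence[ClassifiedVariant],
    retained_cnvs: Sequence[CnvCall],
    gene_map: dict[str, GeneRecord],
    config: PipelineConfig,
) -> list[PatientFinding]:
    """Upgrade sole-candidate LP variants in SFARI genes to P.

    A proband whose *only* retained finding across both platforms is a
    single (unpaired) LP sequence variant in a SFARI gene has that
    variant promoted to pathogenic. The upgrade is recorded in the
    variant's rule trace; with the flag disabled this is the identity.
    """
    if not config.unique_candidate_upgrade:
        return list(findings)

    by_patient: dict[str, list[ClassifiedVariant]] = {}
    for c in classified:
        by_patient.setdefault(c.variant.patient_id, []).append(c)
    cnv_patients = {c.patient_id for c in retained_cnvs}

    updated = []
    for finding in findings:
        candidates = by_patient.get(finding.patient_id, [])
        if (
            len(candidates) == 1
            and candidates[0].compound_partner is None
            and candidates[0].assigned_class is AcmgClass.LP
            and finding.patient_id not in cnv_patients
        ):
            sole = candidates[0]
            gene = gene_map.get(sole.variant.gene)
            if gene is not None and gene.sfari_member:
                sole.assigned_class = AcmgClass.P
                sole.rule_trace.append("unique_candidate_upgrade")
                finding = PatientFinding(
                    patient_id=finding.patient_id,
                    best_class=BestClass.P,
                    source=FindingSource.SEQUENCE,
                    contributing_keys=[sole.key],
                )
        updated.append(finding)
    return updated


def annotate_incomplete_penetrance(classified: Sequence[ClassifiedVariant]) -> None:
    """Flag variants inherited from an unaffected parent.

    Incomplete penetrance is a descriptive annotation only — it affects
    no classification or summary arithmetic.
    """
    from .model import Inheritance, Zygosity

    for c in classified:
        inherited = c.variant.inheritance in (
            Inheritance.MATERNAL, Inheritance.PATERNAL, Inheritance.BIPARENTAL
        ) or (
            c.variant.zygosity is Zygosity.HEMIZYGOUS
            and c.variant.inheritance is Inheritance.MATERNAL
        )
        c.incomplete_penetrance = inherited
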