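"""Sequence-variant triage cascade for trio exomes.

Pipeline order: QC -> inheritance -> compound-het pairing -> gene filter
-> provisional classification -> retention -> final classification.
Pairing runs before the inherited-heterozygous exclusion because each
member of a compound-het pair is, individually, an inherited
heterozygous variant; the pair is what rescues them. Synonymous variants
are unconditionally excluded and therefore never enter pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classify import classify_variant, combine_compound_het
from .config import PipelineConfig
from .io import default_gene_record
from .model import (
    AcmgClass,
    AnnotatedVariant,
    ClassifiedVariant,
    CompoundHetPair,
    Consequence,
    DropRecord,
    GeneRecord,
    Inheritance,
    Sex,
    Zygosity,
    is_allosome,
)

log = logging.getLogger("asdtriage")

#: Origins that can phase a compound-het pair in a trio. De novo counts as
#: its own origin: a de novo het opposite an inherited het is in trans
#: unless the mutation hit the already-variant haplotype.
PHASING_ORIGINS = (Inheritance.MATERNAL, Inheritance.PATERNAL, Inheritance.DE_NOVO)


# ---------------------------------------------------------------------------
# QC filter

def qc_filter(
    variants: Sequence[AnnotatedVariant],
    config: PipelineConfig,
) -> tuple[list[AnnotatedVariant], list[DropRecord]]:
    """Coverage / genotype-quality / common-variant filter.

    Exclusions are strict: coverage < 10x or GQ < 15 drop the variant
    (equality is retained), and variants at gnomAD MAF >= 5% are removed
    as too common to be causal; an absent MAF annotation passes.
    """
    kept, dropped = [], []
    for v in variants:
        if v.coverage < config.min_coverage:
            dropped.append(DropRecord(v.key, v.patient_id, "qc", "low_coverage"))
        elif v.gq < config.min_gq:
            dropped.append(DropRecord(v.key, v.patient_id, "qc", "low_gq"))
        elif v.gnomad_maf is not None and v.gnomad_maf >= config.max_maf:
            dropped.append(DropRecord(v.key, v.patient_id, "qc", "common_maf"))
        else:
            kept.append(v)
    return kept, dropped


# ---------------------------------------------------------------------------
# inheritance from trio genotypes

def _alleles(gt: Optional[str]) -> Optional[list[str]]:
    if gt is None or gt in ("", ".", "./.", ".|."):
        return None
    return gt.replace("|", "/").split("/")


def assign_inheritance(
    proband_gt: Optional[str],
    father_gt: Optional[str],
    mother_gt: Optional[str],
    sex: Sex = Sex.UNKNOWN,
    chrom: str = "",
) -> tuple[Inheritance, bool]:
    """Derive inheritance from trio genotypes.

    Returns ``(inheritance, mendelian_consistent)``. Genotypes are
    VCF-style strings ("0/1", "1", ...). Hemizygous X variants in males
    are resolved against the mother's genotype. Mendelian-impossible
    configurations return ``unknown`` with the consistency flag cleared.
    """
    pro = _alleles(proband_gt)
    fat = _alleles(father_gt)
    mot = _alleles(mother_gt)
    if pro is None or "1" not in pro:
        return Inheritance.UNKNOWN, True
    if fat is None or mot is None:
        return Inheritance.UNKNOWN, True

    father_carries = "1" in fat
    mother_carries = "1" in mot

    hemizygous = len(pro) == 1 and sex is Sex.MALE and is_allosome(chrom)
    if hemizygous:
        return (Inheritance.MATERNAL if mother_carries else Inheritance.DE_NOVO), True

    if pro == ["1", "1"]:  # homozygous alternate
        if father_carries and mother_carries:
            return Inheritance.BIPARENTAL, True
        return Inheritance.UNKNOWN, False

    # heterozygous proband
    if father_carries and mother_carries:
        return Inheritance.BIPARENTAL, True
    if father_carries:
        return Inheritance.PATERNAL, True
    if mother_carries:
        return Inheritance.MATERNAL, True
    return Inheritance.DE_NOVO, True


# ---------------------------------------------------------------------------
# compound-het pairing

def detect_compound_het(
    variants: Sequence[AnnotatedVariant],
) -> list[CompoundHetPair]:
    """Pair heterozygous variants in the same gene with distinct origins.

    All couples with distinct origins among {maternal, paternal, de novo}
    are emitted; a variant may belong to several pairs, and pairing is
    symmetric. Unphased same-parent couples are rejected (trio phasing is
    the only phase evidence available). Synonymous variants never pair.
    """
    by_patient_gene: dict[tuple[str, str], list[AnnotatedVariant]] = {}
    for v in variants:
        if v.zygosity is not Zygosity.HETEROZYGOUS:
            continue
        if v.consequence is Consequence.SYNONYMOUS:
            continue
        if v.inheritance not in PHASING_ORIGINS:
            continue
        by_patient_gene.setdefault((v.patient_id, v.gene), []).append(v)

    pairs = []
    for (patient_id, gene), group in sorted(by_patient_gene.items()):
        group = sorted(group, key=lambda v: v.key)
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if a.inheritance != b.inheritance:
                    pairs.append(
                        CompoundHetPair(
                            patient_id=patient_id,
                            gene=gene,
                            variant_a=a.key,
                            variant_b=b.key,
                            origin_a=a.inheritance,
                            origin_b=b.inheritance,
                        )
                    )
    return pairs


def _partner_map(pairs: Sequence[CompoundHetPair]) -> dict[str, set[str]]:
    partners: dict[str, set[str]] = {}
    for p in pairs:
        partners.setdefault(p.variant_a, set()).add(p.variant_b)
        partners.setdefault(p.variant_b, set()).add(p.variant_a)
    return partners


# ---------------------------------------------------------------------------
# gene filter

def gene_filter(
    variant: AnnotatedVariant,
    gene: GeneRecord,
    in_pair: bool,
    config: PipelineConfig,
) -> bool:
    """Gene-level eligibility.

    SFARI-panel genes are investigated for every variant. Other genes
    are considered only for de novo variants, compound-het members, or
    rare truncating/frameshift/splicing variants (MAF < 1% or
    unannotated).
    """
    if gene.sfari_member:
        return True
    if variant.inheritance is Inheritance.DE_NOVO:
        return True
    if in_pair:
        return True
    if variant.consequence in config.truncating_consequences:
        return variant.gnomad_maf is None or variant.gnomad_maf < config.non_sfari_max_maf
    return False


# ---------------------------------------------------------------------------
# retention

def _pair_exception(
    cls_a: AcmgClass, cls_b: AcmgClass
) -> bool:
    """The compound-het rescue: one member LP, the other VOUS/LP/P."""
    rescue = (AcmgClass.VOUS, AcmgClass.LP, AcmgClass.P)
    return (cls_a is AcmgClass.LP and cls_b in rescue) or (
        cls_b is AcmgClass.LP and cls_a in rescue
    )


def retention_filter(
    variant: AnnotatedVariant,
    active_partners: Sequence[str],
    classes: dict[str, AcmgClass],
    config: PipelineConfig,
) -> Optional[str]:
    """Apply the retention cascade to one variant.

    Returns ``None`` when the variant is retained, else the drop reason.
    Synonymous variants are always excluded; inherited heterozygous
    variants survive only inside a compound-het pair; everything else
    (hemizygous, homozygous, de novo, paired) must have at most 10
    gnomAD homozygotes or no annotation — except pairs combining an LP
    member with a VOUS/LP/P member, which are kept regardless of
    homozygote count.
    """
    if variant.consequence is Consequence.SYNONYMOUS:
        return "synonymous"
    if variant.is_inherited_het and not active_partners:
        return "inherited_het"
    hom = variant.gnomad_hom_count
    if hom is None or hom <= config.max_hom_count:
        return None
    own = classes[variant.key]
    for partner in active_partners:
        if _pair_exception(own, classes[partner]):
            return None
    return "hom_count"


# ---------------------------------------------------------------------------
# full cascade

@dataclass
class SnvTriageResult:
    retained: list[ClassifiedVariant] = field(default_factory=list)
    dropped: list[DropRecord] = field(default_factory=list)
    pairs: list[CompoundHetPair] = field(default_factory=list)

    @property
    def retained_keys(self) -> set[str]:
        return {c.key for c in self.retained}


def triage_snvs(
    variants: Sequence[AnnotatedVariant],
    genes: dict[str, GeneRecord],
    config: PipelineConfig,
) -> SnvTriageResult:
    """Run the full sequence-variant cascade and classify survivors."""
    result = SnvTriageResult()

    qc_passed, result.dropped = qc_filter(variants, config)

    pairs = detect_compound_het(qc_passed)
    partners = _partner_map(pairs)

    def record(symbol: str) -> GeneRecord:
        return genes.get(symbol) or default_gene_record(symbol)

    candidates = []
    for v in qc_passed:
        if gene_filter(v, record(v.gene), v.key in partners, config):
            candidates.append(v)
        else:
            result.dropped.append(
                DropRecord(v.key, v.patient_id, "gene_filter", "gene_filter")
            )

    # provisional classification of every candidate (the compound-het
    # retention exception reads both members' classes, so this must
    # precede retention)
    classes: dict[str, AcmgClass] = {}
    traces: dict[str, list[str]] = {}
    for v in candidates:
        cls, trace = classify_variant(v, record(v.gene), config)
        classes[v.key] = cls
        traces[v.key] = trace

    # retention as a fixed point: dropping one pair member can orphan its
    # partner, which then falls to the inherited-het exclusion
    surviving: dict[str, AnnotatedVariant] = {v.key: v for v in candidates}
    while True:
        to_drop: list[tuple[AnnotatedVariant, str]] = []
        for key, v in surviving.items():
            active = sorted(p for p in partners.get(key, ()) if p in surviving)
            reason = retention_filter(v, active, classes, config)
            if reason is not None:
                to_drop.append((v, reason))
        if not to_drop:
            break
        for v, reason in to_drop:
            del surviving[v.key]
            result.dropped.append(DropRecord(v.key, v.patient_id, "retention", reason))

    result.pairs = [
        p for p in pairs if p.variant_a in surviving and p.variant_b in surviving
    ]

    matched = _match_partners(result.pairs, classes, config)
    for key in sorted(surviving):
        v = surviving[key]
        partner = matched.get(key)
        combined = (
            combine_compound_het(classes[key], classes[partner], config)
            if partner
            else None
        )
        result.retained.append(
            ClassifiedVariant(
                variant=v,
                assigned_class=classes[key],
                rule_trace=list(traces[key]),
                compound_partner=partner,
                combined_class=combined,
            )
        )
    return result


def _match_partners(
    pairs: Sequence[CompoundHetPair],
    classes: dict[str, AcmgClass],
    config: PipelineConfig,
) -> dict[str, str]:
    """Greedy mutual matching so partner links are symmetric.

    Pairs are taken in order of decreasing pair-level severity, ties
    broken lexicographically. With more than two pair-eligible variants
    in a gene some variant may stay unmatched; it remains retained (the
    cascade uses pair eligibility, not the matching), just without a
    recorded partner.
    """
    from .model import SEVERITY

    def pair_rank(p: CompoundHetPair):
        combined = combine_compound_het(
            classes[p.variant_a], classes[p.variant_b], config
        )
        return (-SEVERITY[combined], p.variant_a, p.variant_b)

    matched: dict[str, str] = {}
    for p in sorted(pairs, key=pair_rank):
        if p.variant_a not in matched and p.variant_b not in matched:
            matched[p.variant_a] = p.variant_b
            matched[p.variant_b] = p.variant_a
    return matched
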