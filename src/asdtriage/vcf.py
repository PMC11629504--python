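"""Optional VCF ingestion adapter (requires pysam).

Maps trio VCF records onto :class:`~asdtriage.model.AnnotatedVariant`
using INFO keys ``GENE``, ``HGVSC``, ``CSQ_CLASS``, ``CADD``, ``ACMG``,
``GNOMAD_AF`` and ``GNOMAD_NHOMALT``, deriving zygosity and inheritance
from the trio genotypes. A convenience for VCF-based workflows; the TSV
tables remain the reference interchange format.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .model import (
    AcmgClass,
    AnnotatedVariant,
    Consequence,
    Inheritance,
    PedigreeMember,
    Sex,
    Zygosity,
    is_allosome,
)
from .snv import assign_inheritance


def _gt_string(sample) -> Optional[str]:
    alleles = sample.get("GT")
    if alleles is None or all(a is None for a in alleles):
        return None
    return "/".join("." if a is None else str(a) for a in alleles)


def read_trio_vcf(
    path: str | Path,
    proband: PedigreeMember,
) -> list[AnnotatedVariant]:
    """Read one proband's annotated variants from a trio VCF."""
    import pysam  # deferred: pysam is an optional dependency

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples.get(proband.individual_id)
            if sample is None:
                continue
            gt = _gt_string(sample)
            if gt is None or "1" not in gt:
                continue
            father = rec.samples.get(proband.father_id or "")
            mother = rec.samples.get(proband.mother_id or "")
            inheritance, _consistent = assign_inheritance(
                gt,
                _gt_string(father) if father else None,
                _gt_string(mother) if mother else None,
                proband.sex,
                rec.chrom,
            )
            alleles = gt.split("/")
            if len(alleles) == 1 and proband.sex is Sex.MALE and is_allosome(rec.chrom):
                zygosity = Zygosity.HEMIZYGOUS
            elif set(alleles) == {"1"}:
                zygosity = Zygosity.HOMOZYGOUS
            else:
                zygosity = Zygosity.HETEROZYGOUS

            info = rec.info
            variants.append(
                AnnotatedVariant(
                    patient_id=proband.individual_id,
                    family_id=proband.family_id,
                    gene=str(info.get("GENE", "")),
                    hgvs_c=str(info.get("HGVSC", f"c.{rec.pos}")),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else None,
                    consequence=Consequence(str(info.get("CSQ_CLASS", "other"))),
                    zygosity=zygosity,
                    inheritance=inheritance,
                    cadd=float(info["CADD"]),
                    acmg=AcmgClass(str(info["ACMG"])),
                    gnomad_maf=float(info["GNOMAD_AF"])
                    if "GNOMAD_AF" in info else None,
                    gnomad_hom_count=int(info["GNOMAD_NHOMALT"])
                    if "GNOMAD_NHOMALT" in info else None,
                    coverage=int(sample.get("DP", 0) or 0),
                    gq=int(sample.get("GQ", 0) or 0),
                )
            )
    return variants
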