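import logging

import pytest

from asdtriage.config import PipelineConfig
from asdtriage.model import (
    AcmgClass,
    AnnotatedVariant,
    Consequence,
    GeneRecord,
    Inheritance,
    SfariScore,
    Strand,
    Zygosity,
)
from asdtriage.pipeline import run_pipeline
from asdtriage.simulate import SimConfig, generate_cohort

logging.getLogger("asdtriage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """Default 122-trio synthetic cohort (study composition), fixed seed."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    c = default_cohort
    return run_pipeline(c.variants, c.cnvs, c.genes, c.array_qc, c.members)


def make_gene(
    symbol="GENE1",
    sfari=True,
    tags=("neurodevelopment",),
    chrom="1",
    start=1000,
    end=100_000,
    strand=Strand.PLUS,
    score=None,
    **kwargs,
) -> GeneRecord:
    return GeneRecord(
        symbol=symbol,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        sfari_member=sfari,
        sfari_score=score or (SfariScore.S2 if sfari else SfariScore.NONE),
        function_tags=frozenset(tags),
        **kwargs,
    )


def make_variant(
    patient_id="A001",
    gene="GENE1",
    hgvs_c="c.100A>G",
    chrom="1",
    pos=1500,
    consequence=Consequence.MISSENSE,
    zygosity=Zygosity.HETEROZYGOUS,
    inheritance=Inheritance.DE_NOVO,
    cadd=25.0,
    acmg=AcmgClass.VOUS,
    gnomad_maf=None,
    gnomad_hom_count=0,
    coverage=50,
    gq=90,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        patient_id=patient_id,
        family_id="F" + patient_id[1:],
        gene=gene,
        hgvs_c=hgvs_c,
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        consequence=consequence,
        zygosity=zygosity,
        inheritance=inheritance,
        cadd=cadd,
        acmg=acmg,
        gnomad_maf=gnomad_maf,
        gnomad_hom_count=gnomad_hom_count,
        coverage=coverage,
        gq=gq,
    )
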