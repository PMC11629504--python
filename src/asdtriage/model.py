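"""Domain types for trio-based variant triage in essential ASD cohorts.

The pipeline consumes annotated sequence variants (one row per proband
variant, with CADD, ACMG class, gnomAD frequency/homozygote annotations
already attached), array-CGH CNV calls with a prior five-tier class, a
gene-metadata table (SFARI membership, functional tags, dosage
sensitivity), and standard 6-column pedigrees. All genomic coordinates
are 1-based inclusive (array-CGH / ISCN convention).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional


class ModelError(ValueError):
    """An invariant of a domain type was violated."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affected(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICING = "splicing"
    START_LOST = "start_lost"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    OTHER = "other"


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"


class Inheritance(str, enum.Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL = "biparental"
    UNKNOWN = "unknown"


class AcmgClass(str, enum.Enum):
    """Five-tier clinical classification (consumed as an input annotation)."""

    P = "P"
    LP = "LP"
    VOUS = "VOUS"
    LB = "LB"
    B = "B"


#: Severity order used for best-finding selection, compound-het pair
#: normalisation and the classifier monotonicity property: P > LP > VOUS > LB > B.
SEVERITY: dict[AcmgClass, int] = {
    AcmgClass.B: 0,
    AcmgClass.LB: 1,
    AcmgClass.VOUS: 2,
    AcmgClass.LP: 3,
    AcmgClass.P: 4,
}


def severity(cls: AcmgClass) -> int:
    return SEVERITY[cls]


def more_severe(a: AcmgClass, b: AcmgClass) -> AcmgClass:
    return a if SEVERITY[a] >= SEVERITY[b] else b


class CopyState(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "unknown"


class SfariScore(str, enum.Enum):
    """SFARI gene score tier; ``2B`` is normalised to tier 2 on input."""

    S1 = "1"
    S2 = "2"
    S3 = "3"
    SYNDROMIC = "S"
    NONE = "none"


#: Ranking order for genes-of-interest selection (1 strongest).
SFARI_RANK: dict[SfariScore, int] = {
    SfariScore.S1: 0,
    SfariScore.S2: 1,
    SfariScore.S3: 2,
    SfariScore.SYNDROMIC: 3,
    SfariScore.NONE: 4,
}


class Rearrangement(str, enum.Enum):
    """How a CNV rearranges an overlapped gene."""

    DELETED = "DELETED"
    DUPLICATED = "DUPLICATED"
    INTRAGENIC = "INTRAGENIC"
    INT_START = "INT START"
    INT_END = "INT END"


#: Gene-function tags that satisfy the neurodevelopmental-involvement
#: criterion (criterion 4) of the classifier.
CRITERION4_TAGS = frozenset(
    {
        "neurodevelopment",
        "nervous_system_function",
        "synaptic_transmission",
        "epigenetic_transcription_regulation",
    }
)

ALLOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


def is_allosome(chrom: str) -> bool:
    return chrom in ALLOSOMES


@dataclass(frozen=True)
class PedigreeMember:
    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affected: Affected

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class AnnotatedVariant:
    """One proband sequence variant with every annotation the rules consume.

    ``gnomad_hom_count`` of ``None`` means "not annotated in gnomAD", a
    distinct state from zero: the retention rule treats it as a pass.
    """

    patient_id: str
    family_id: str
    gene: str
    hgvs_c: str
    chrom: str
    pos: int
    ref: Optional[str]
    alt: Optional[str]
    consequence: Consequence
    zygosity: Zygosity
    inheritance: Inheritance
    cadd: float
    acmg: AcmgClass
    gnomad_maf: Optional[float]
    gnomad_hom_count: Optional[int]
    coverage: int
    gq: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError(f"{self.key}: pos must be >= 1, got {self.pos}")
        if not math.isfinite(self.cadd) or self.cadd < 0:
            raise ModelError(f"{self.key}: CADD must be finite and >= 0")
        if self.gnomad_maf is not None and not 0.0 <= self.gnomad_maf <= 1.0:
            raise ModelError(f"{self.key}: gnomad_maf outside [0, 1]")
        if self.gnomad_hom_count is not None and self.gnomad_hom_count < 0:
            raise ModelError(f"{self.key}: gnomad_hom_count must be >= 0")
        if self.coverage < 0 or self.gq < 0:
            raise ModelError(f"{self.key}: coverage/GQ must be >= 0")
        if self.zygosity is Zygosity.HEMIZYGOUS and not is_allosome(self.chrom):
            raise ModelError(
                f"{self.key}: hemizygous zygosity on autosome {self.chrom}"
            )

    @property
    def key(self) -> str:
        return f"{self.patient_id}:{self.gene}:{self.hgvs_c}"

    @property
    def is_inherited_het(self) -> bool:
        return self.zygosity is Zygosity.HETEROZYGOUS and self.inheritance in (
            Inheritance.MATERNAL,
            Inheritance.PATERNAL,
            Inheritance.BIPARENTAL,
        )


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN
    sfari_member: bool = False
    sfari_score: SfariScore = SfariScore.NONE
    function_tags: frozenset[str] = frozenset()
    family_name: Optional[str] = None
    brain_expression_pct: Optional[float] = None
    haploinsufficient: Optional[bool] = None
    triplosensitive: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"{self.symbol}: start > end")
        if self.sfari_score is not SfariScore.NONE and not self.sfari_member:
            raise ModelError(f"{self.symbol}: sfari_score set but sfari_member false")
        if self.brain_expression_pct is not None and not (
            0.0 <= self.brain_expression_pct <= 100.0
        ):
            raise ModelError(f"{self.symbol}: brain_expression_pct outside [0, 100]")

    def has_criterion4_tag(self, tags: frozenset[str] = CRITERION4_TAGS) -> bool:
        return bool(self.function_tags & tags)

    def tss(self) -> int:
        """Transcription start position (strand-aware; unknown strand as +)."""
        return self.start if self.strand is not Strand.MINUS else self.end

    def tes(self) -> int:
        """Transcription end position (strand-aware; unknown strand as +)."""
        return self.end if self.strand is not Strand.MINUS else self.start


@dataclass(frozen=True)
class CnvCall:
    patient_id: str
    chrom: str
    start: int
    end: int
    copy_state: CopyState
    copy_number: int
    inheritance: Inheritance
    prior_class: AcmgClass
    dgv_frequency: Optional[float] = None
    band_start: Optional[str] = None
    band_end: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"{self.key}: start > end")
        if self.copy_number < 0:
            raise ModelError(f"{self.key}: copy_number must be >= 0")
        if self.dgv_frequency is not None and not 0.0 <= self.dgv_frequency <= 1.0:
            raise ModelError(f"{self.key}: dgv_frequency outside [0, 1]")
        # Expected ploidy is sex-dependent on X/Y, so the strict consistency
        # check applies to autosomes only.
        if not is_allosome(self.chrom):
            if self.copy_state is CopyState.LOSS and self.copy_number >= 2:
                raise ModelError(f"{self.key}: autosomal loss with copy_number >= 2")
            if self.copy_state is CopyState.GAIN and self.copy_number <= 2:
                raise ModelError(f"{self.key}: autosomal gain with copy_number <= 2")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return (
            f"{self.patient_id}:{self.chrom}:{self.start}-{self.end}"
            f":{self.copy_state.value}"
        )


@dataclass(frozen=True)
class ArrayQc:
    patient_id: str
    sd: float
    dlr_spread: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd) and math.isfinite(self.dlr_spread)):
            raise ModelError(f"{self.patient_id}: array QC metrics must be finite")
        if self.sd < 0 or self.dlr_spread < 0:
            raise ModelError(f"{self.patient_id}: array QC metrics must be >= 0")


@dataclass
class ClassifiedVariant:
    """A retained variant with its assigned class and audit trail."""

    variant: AnnotatedVariant
    assigned_class: AcmgClass
    rule_trace: list[str] = field(default_factory=list)
    compound_partner: Optional[str] = None
    combined_class: Optional[AcmgClass] = None
    incomplete_penetrance: bool = False

    def __post_init__(self) -> None:
        if (self.compound_partner is None) != (self.combined_class is None):
            raise ModelError(
                f"{self.variant.key}: compound_partner and combined_class "
                "must be set together"
            )

    @property
    def key(self) -> str:
        return self.variant.key

    @property
    def effective_class(self) -> AcmgClass:
        """Pair-level class for compound-het members, else the variant class."""
        return self.combined_class or self.assigned_class


@dataclass(frozen=True)
class CompoundHetPair:
    patient_id: str
    gene: str
    variant_a: str
    variant_b: str
    origin_a: Inheritance
    origin_b: Inheritance

    def __post_init__(self) -> None:
        if self.origin_a == self.origin_b:
            raise ModelError(
                f"{self.patient_id}/{self.gene}: compound-het pair needs two "
                f"distinct parental origins, got {self.origin_a.value} twice"
            )


class FindingSource(str, enum.Enum):
    SEQUENCE = "sequence"
    CNV = "cnv"
    BOTH = "both"
    NONE = "none"


class BestClass(str, enum.Enum):
    P = "P"
    LP = "LP"
    VOUS = "VOUS"
    NONE = "none"


@dataclass
class PatientFinding:
    patient_id: str
    best_class: BestClass
    source: FindingSource
    contributing_keys: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.best_class is BestClass.NONE) != (self.source is FindingSource.NONE):
            raise ModelError(
                f"{self.patient_id}: best_class none iff source none"
            )


@dataclass
class DropRecord:
    """Why a variant or CNV left the cascade (exactly one primary reason)."""

    key: str
    patient_id: str
    stage: str
    reason: str
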