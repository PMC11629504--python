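"""Seeded synthetic trio-cohort generator with planted ground truth.

Emits a pedigree, annotated variant table, CNV table, gene-metadata
table, array-QC table and a truth table whose labels the triage
pipeline must recover exactly (the rules are deterministic, so any
mismatch is a pipeline bug). Every record is planted by a *branch
recipe* that satisfies exactly one classification/filtering outcome:
annotation values are drawn from ranges that force the intended rule to
fire (e.g. a "sequence P" variant draws CADD from [20.5, 44.5], ACMG
from {P, LP} and 0-1 gnomAD homozygotes), and noise records violate
exactly one retention predicate.

The default plan reproduces the structure of the study cohort this
package models: 122 trios (104 male, 18 female probands), per-patient
tiers {P: 4, LP: 34 (24 sequence / 8 CNV / 2 both), VOUS: 70 (54/3/13),
none: 14}, and 46 retained CNVs (16 losses, 30 duplications, 11
intragenic; one de novo pathogenic; 12 patients with P/LP CNVs; 35
CNV-positive patients, 30 male / 5 female). Same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, normalize_pair
from .io import write_gene_metadata, write_pedigree
from .model import (
    AcmgClass,
    Affected,
    AnnotatedVariant,
    ArrayQc,
    CnvCall,
    Consequence,
    CopyState,
    GeneRecord,
    Inheritance,
    ModelError,
    PedigreeMember,
    Sex,
    SfariScore,
    Strand,
    Zygosity,
)


class SimulationError(ValueError):
    """The simulation plan is infeasible or inconsistent."""


# ---------------------------------------------------------------------------
# plan

#: Default per-patient branch plan: the study-cohort composition.
DEFAULT_BRANCH_PLAN: dict[str, int] = {
    "seq_P_denovo_lpcnv": 1,   # de novo P variant; also carries an LP CNV
    "seq_P_hom": 1,            # homozygous P variant
    "seq_P_upgrade": 1,        # sole LP candidate upgraded to P
    "cnv_P": 1,                # de novo pathogenic intragenic deletion
    "seq_LP_hom2to10": 3,      # LP via the 2-10 homozygote rule
    "seq_LP_hom2to10_vouscnv": 7,  # same, plus an incidental VOUS CNV
    "seq_LP_chet": 4,          # compound het (LP, VOUS) -> pair LP
    "seq_LP_chet_homexc": 2,   # same, VOUS member >10 homozygotes (rescued)
    "seq_LP_nonsfari": 4,      # LP in a non-SFARI gene (capped, never P)
    "seq_LP_hemi": 4,          # hemizygous LP on X
    "cnv_LP": 4,               # LP CNV only
    "cnv_LP_vouscnv": 4,       # LP CNV plus a VOUS CNV
    "both_LP": 2,              # LP variant and LP CNV
    "seq_VOUS": 54,
    "cnv_VOUS": 2,
    "cnv_VOUS_2cnv": 1,
    "both_VOUS": 7,
    "both_VOUS_2cnv": 6,
    "none_LB": 8,              # retained but likely-benign only
    "none_empty": 6,           # nothing retained
}

#: Which branches carry hemizygous variants (male probands only).
_MALE_ONLY_BRANCHES = {"seq_P_upgrade", "seq_LP_hemi"}

#: Default placement of the 18 female probands across branches.
DEFAULT_FEMALE_PLAN: dict[str, int] = {
    "cnv_LP": 1,
    "cnv_VOUS": 1,
    "both_VOUS": 3,
    "seq_VOUS": 11,
    "none_LB": 1,
    "none_empty": 1,
}

_TIER_BY_BRANCH = {
    "seq_P_denovo_lpcnv": ("P", "sequence"),
    "seq_P_hom": ("P", "sequence"),
    "seq_P_upgrade": ("P", "sequence"),
    "cnv_P": ("P", "cnv"),
    "seq_LP_hom2to10": ("LP", "sequence"),
    "seq_LP_hom2to10_vouscnv": ("LP", "sequence"),
    "seq_LP_chet": ("LP", "sequence"),
    "seq_LP_chet_homexc": ("LP", "sequence"),
    "seq_LP_nonsfari": ("LP", "sequence"),
    "seq_LP_hemi": ("LP", "sequence"),
    "cnv_LP": ("LP", "cnv"),
    "cnv_LP_vouscnv": ("LP", "cnv"),
    "both_LP": ("LP", "both"),
    "seq_VOUS": ("VOUS", "sequence"),
    "cnv_VOUS": ("VOUS", "cnv"),
    "cnv_VOUS_2cnv": ("VOUS", "cnv"),
    "both_VOUS": ("VOUS", "both"),
    "both_VOUS_2cnv": ("VOUS", "both"),
    "none_LB": ("none", "none"),
    "none_empty": ("none", "none"),
}

_NOISE_TYPES = [
    "noise_synonymous", "noise_inherited_het", "noise_qc_coverage",
    "noise_qc_gq", "noise_qc_maf", "noise_hom_gt10", "noise_gene_filter",
]


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 122
    male_fraction: float = 104 / 122
    seed: int = 0
    branch_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_PLAN)
    )
    female_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_PLAN)
    )
    noise_every: int = 8  # plant one noise record on every k-th patient
    cnv_noise: int = 6    # benign-class / common-DGV CNVs that must be dropped

    def __post_init__(self) -> None:
        unknown = set(self.branch_plan) - set(_TIER_BY_BRANCH)
        if unknown:
            raise SimulationError(f"unknown branch labels: {sorted(unknown)}")
        total = sum(self.branch_plan.values())
        if total != self.n_families:
            raise SimulationError(
                f"branch plan covers {total} patients, n_families is {self.n_families}"
            )
        n_females = round(self.n_families * (1.0 - self.male_fraction))
        planned = sum(self.female_plan.values())
        if planned != n_females:
            raise SimulationError(
                f"female plan places {planned} females, expected {n_females}"
            )
        for branch, count in self.female_plan.items():
            if branch in _MALE_ONLY_BRANCHES:
                raise SimulationError(
                    f"branch {branch} carries hemizygous variants; cannot be female"
                )
            if count > self.branch_plan.get(branch, 0):
                raise SimulationError(
                    f"female plan exceeds branch {branch} capacity"
                )


# ---------------------------------------------------------------------------
# cohort container

@dataclass
class Cohort:
    config: SimConfig
    members: list[PedigreeMember]
    variants: list[AnnotatedVariant]
    cnvs: list[CnvCall]
    genes: dict[str, GeneRecord]
    array_qc: list[ArrayQc]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# gene panel synthesis

_TAG_CYCLE = [
    "neurodevelopment", "nervous_system_function",
    "synaptic_transmission", "epigenetic_transcription_regulation",
]
_SCORE_CYCLE = [SfariScore.S1, SfariScore.S2, SfariScore.S3, SfariScore.SYNDROMIC]
_FAMILY_BLOCKS = {
    "ankyrin-like": (0, 3),
    "cadherin-like": (3, 6),
    "helicase-like": (6, 9),
}


def synthesize_gene_panel(rng: np.random.Generator) -> dict[str, GeneRecord]:
    """Synthetic gene metadata (no real SFARI content is shipped).

    ``read_gene_metadata`` accepts a real SFARI-derived table with the
    same columns when one is available.
    """
    genes: dict[str, GeneRecord] = {}

    def add(symbol, chrom, start, *, sfari, score, tags, family=None,
            strand=Strand.PLUS, hap=None, trip=None):
        genes[symbol] = GeneRecord(
            symbol=symbol, chrom=chrom, start=start, end=start + 99_999,
            strand=strand, sfari_member=sfari, sfari_score=score,
            function_tags=frozenset(tags), family_name=family,
            brain_expression_pct=float(round(rng.uniform(10, 99), 1)),
            haploinsufficient=hap, triplosensitive=trip,
        )

    for i in range(30):  # SFARI autosomal candidates
        family = next(
            (name for name, (lo, hi) in _FAMILY_BLOCKS.items() if lo <= i < hi), None
        )
        add(f"SFG{i + 1:03d}", str(i % 22 + 1), 1_000_000 + i * 300_000,
            sfari=True, score=_SCORE_CYCLE[i % 4],
            tags=[_TAG_CYCLE[i % 4]], family=family)
    for i in range(6):  # SFARI X-linked (hemizygous branches)
        add(f"SFGX{i + 1:02d}", "X", 1_000_000 + i * 300_000,
            sfari=True, score=_SCORE_CYCLE[i % 4], tags=[_TAG_CYCLE[i % 4]])
    for i in range(10):  # non-SFARI with neurodevelopmental tags
        add(f"NSG{i + 1:03d}", str(i % 22 + 1), 20_000_000 + i * 300_000,
            sfari=False, score=SfariScore.NONE, tags=[_TAG_CYCLE[i % 4]])
    for i in range(5):  # non-SFARI, untagged (gene-filter noise)
        add(f"NSU{i + 1:03d}", str(i % 22 + 1), 30_000_000 + i * 300_000,
            sfari=False, score=SfariScore.NONE, tags=[])
    for i in range(8):  # SFARI pool reserved for planted noise variants
        add(f"SFN{i + 1:03d}", str(i % 22 + 1), 40_000_000 + i * 300_000,
            sfari=True, score=SfariScore.S3, tags=[])
    return genes


def _add_cnv_gene(
    genes: dict[str, GeneRecord], idx: int, copy_state: CopyState,
    rng: np.random.Generator, sfari: bool,
) -> GeneRecord:
    chrom = str(idx % 22 + 1)
    start = 50_000_000 + idx * 2_000_000
    record = GeneRecord(
        symbol=f"CVG{idx + 1:03d}", chrom=chrom, start=start, end=start + 49_999,
        strand=Strand.PLUS,
        sfari_member=sfari,
        sfari_score=SfariScore.S1 if sfari else SfariScore.NONE,
        function_tags=frozenset([_TAG_CYCLE[idx % 4]]) if sfari else frozenset(),
        brain_expression_pct=float(round(rng.uniform(10, 99), 1)),
        haploinsufficient=True if copy_state is CopyState.LOSS else None,
        triplosensitive=True if copy_state is CopyState.GAIN else None,
    )
    genes[record.symbol] = record
    return record


# ---------------------------------------------------------------------------
# variant recipes

def _draw_common(rng) -> dict:
    return {
        "coverage": int(rng.integers(20, 100)),
        "gq": int(rng.integers(30, 99)),
        "gnomad_maf": float(round(rng.uniform(0.0001, 0.004), 6))
        if rng.random() < 0.5 else None,
    }


def _hgvs(rng, gene: GeneRecord) -> tuple[str, int, str, str]:
    offset = int(rng.integers(1, 5000))
    bases = "ACGT"
    ref = bases[int(rng.integers(0, 4))]
    alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
    pos = gene.start + int(rng.integers(0, gene.end - gene.start))
    return f"c.{offset}{ref}>{alt}", pos, ref, alt


def _make_variant(
    rng, patient_id: str, family_id: str, gene: GeneRecord, *,
    consequence: Consequence, zygosity: Zygosity, inheritance: Inheritance,
    cadd: float, acmg: AcmgClass, hom: Optional[int],
    maf: Optional[float] = "draw", coverage: Optional[int] = None,
    gq: Optional[int] = None, hgvs: Optional[str] = None,
) -> AnnotatedVariant:
    common = _draw_common(rng)
    auto_hgvs, pos, ref, alt = _hgvs(rng, gene)
    return AnnotatedVariant(
        patient_id=patient_id, family_id=family_id, gene=gene.symbol,
        hgvs_c=hgvs or auto_hgvs, chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
        consequence=consequence, zygosity=zygosity, inheritance=inheritance,
        cadd=cadd, acmg=acmg,
        gnomad_maf=common["gnomad_maf"] if maf == "draw" else maf,
        gnomad_hom_count=hom,
        coverage=coverage if coverage is not None else common["coverage"],
        gq=gq if gq is not None else common["gq"],
    )


def _cadd(rng, lo: float, hi: float) -> float:
    return float(round(rng.uniform(lo, hi), 1))


# class-forcing recipes for compound-het members (SFARI, criterion-4 gene)
def _chet_member_recipe(rng, member_class: AcmgClass) -> dict:
    if member_class is AcmgClass.P:
        return {"cadd": _cadd(rng, 20.5, 44.5),
                "acmg": AcmgClass.P, "hom": int(rng.integers(0, 2))}
    if member_class is AcmgClass.LP:
        return {"cadd": _cadd(rng, 20.5, 44.5),
                "acmg": AcmgClass.VOUS, "hom": int(rng.integers(2, 11))}
    if member_class is AcmgClass.VOUS:
        return {"cadd": _cadd(rng, 15.1, 19.4),
                "acmg": AcmgClass.VOUS, "hom": int(rng.integers(0, 2))}
    if member_class is AcmgClass.LB:
        return {"cadd": _cadd(rng, 5.0, 14.4),
                "acmg": AcmgClass.LB, "hom": int(rng.integers(0, 2))}
    raise SimulationError(f"unreachable member class {member_class.value}")


def plant_compound_het(
    rng: np.random.Generator,
    patient_id: str,
    family_id: str,
    gene: GeneRecord,
    class_pair: tuple[AcmgClass, AcmgClass],
    config: PipelineConfig,
    origins: tuple[Inheritance, Inheritance] = (
        Inheritance.MATERNAL, Inheritance.PATERNAL,
    ),
    hom_override_b: Optional[int] = None,
) -> tuple[list[AnnotatedVariant], AcmgClass]:
    """Two heterozygous rows forcing the requested member classes.

    Returns the rows and the pair-level class from the combination
    matrix. Refuses same-origin couples (no phase evidence) and pairs
    the matrix does not cover.
    """
    if origins[0] == origins[1]:
        raise ModelError("compound-het pair requires two distinct parental origins")
    pair = normalize_pair(*class_pair)
    if pair not in config.combination_matrix:
        raise SimulationError(
            f"no combination rule for pair ({pair[0].value}, {pair[1].value})"
        )
    rows = []
    for member_class, origin, hom_override in zip(
        class_pair, origins, (None, hom_override_b)
    ):
        recipe = _chet_member_recipe(rng, member_class)
        if hom_override is not None:
            recipe["hom"] = hom_override
        rows.append(
            _make_variant(
                rng, patient_id, family_id, gene,
                consequence=Consequence.MISSENSE,
                zygosity=Zygosity.HETEROZYGOUS, inheritance=origin, **recipe,
            )
        )
    return rows, config.combination_matrix[pair]


# ---------------------------------------------------------------------------
# CNV geometry allocation

# (copy_state, rearrangement) queues per prior class; together they plant
# 16 losses / 30 gains with 11 intragenic calls (8 del + 3 dup)
_LP_GEOMETRY = (
    [("loss", "INTRAGENIC")] * 4 + [("loss", "DELETED")] * 4
    + [("gain", "DUPLICATED")] * 3
)
_VOUS_GEOMETRY = (
    [("loss", "INTRAGENIC")] * 3 + [("loss", "DELETED")] * 2
    + [("loss", "INT_START"), ("loss", "INT_END")]
    + [("gain", "INTRAGENIC")] * 3
    + [("gain", "DUPLICATED"), ("gain", "INT_START"), ("gain", "INT_END")] * 8
)


class _CnvAllocator:
    def __init__(self, genes: dict[str, GeneRecord], rng: np.random.Generator):
        self.genes = genes
        self.rng = rng
        self.idx = 0
        self.queues = {
            AcmgClass.P: [("loss", "INTRAGENIC")],
            AcmgClass.LP: list(_LP_GEOMETRY),
            AcmgClass.VOUS: list(_VOUS_GEOMETRY),
            "noise": [("gain", "DUPLICATED"), ("loss", "DELETED")] * 10,
        }
        self.inherit_cycle = 0
        self.vous_count = 0

    def make(
        self, patient_id: str, prior: AcmgClass, *,
        de_novo: bool = False, dgv: Optional[float] = "auto", noise: bool = False,
    ) -> CnvCall:
        queue = self.queues["noise" if noise else prior]
        if not queue:
            raise SimulationError(f"CNV geometry queue for {prior.value} exhausted")
        state_s, rearrangement = queue.pop(0)
        state = CopyState(state_s)
        gene = _add_cnv_gene(self.genes, self.idx, state, self.rng,
                             sfari=prior in (AcmgClass.P, AcmgClass.LP))
        gs, ge = gene.start, gene.end
        if rearrangement == "INTRAGENIC":
            start, end = gs + 5_000, gs + 15_000
        elif rearrangement in ("DELETED", "DUPLICATED"):
            start, end = gs - 10_000, ge + 10_000
        elif rearrangement == "INT_START":
            start, end = gs - 20_000, gs + 20_000
        else:  # INT_END
            start, end = gs + 20_000, ge + 30_000

        if de_novo:
            inheritance = Inheritance.DE_NOVO
        else:
            inheritance = (
                Inheritance.MATERNAL if self.inherit_cycle % 2 == 0
                else Inheritance.PATERNAL
            )
            self.inherit_cycle += 1

        if dgv == "auto":
            if prior is AcmgClass.VOUS:
                # first VOUS call sits exactly on the 1% DGV boundary
                dgv = 0.01 if self.vous_count == 0 else (
                    0.005 if self.vous_count == 1 else None
                )
                self.vous_count += 1
            else:
                dgv = None

        band = f"{gene.chrom}q{21 + self.idx % 5}.{1 + self.idx % 3}"
        band_end = (
            f"{gene.chrom}q{21 + self.idx % 5}.{2 + self.idx % 3}"
            if rearrangement in ("DELETED", "DUPLICATED") else band
        )
        self.idx += 1
        return CnvCall(
            patient_id=patient_id, chrom=gene.chrom, start=start, end=end,
            copy_state=state, copy_number=1 if state is CopyState.LOSS else 3,
            inheritance=inheritance, prior_class=prior, dgv_frequency=dgv,
            band_start=band, band_end=band_end,
        )


# ---------------------------------------------------------------------------
# generator

def _expand_plan(config: SimConfig) -> list[tuple[str, Sex]]:
    """Fixed-order (branch, sex) assignment for every proband."""
    females_left = dict(config.female_plan)
    plan = []
    for branch in DEFAULT_BRANCH_PLAN:  # canonical branch order
        count = config.branch_plan.get(branch, 0)
        n_female = min(females_left.get(branch, 0), count)
        for j in range(count):
            sex = Sex.FEMALE if j < n_female else Sex.MALE
            plan.append((branch, sex))
    # branches outside the canonical order (custom plans)
    for branch, count in config.branch_plan.items():
        if branch not in DEFAULT_BRANCH_PLAN:
            plan.extend((branch, Sex.MALE) for _ in range(count))
    return plan


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    pipeline_cfg = PipelineConfig()

    genes = synthesize_gene_panel(rng)
    sfg = [genes[f"SFG{i + 1:03d}"] for i in range(30)]
    sfgx = [genes[f"SFGX{i + 1:02d}"] for i in range(6)]
    nsg = [genes[f"NSG{i + 1:03d}"] for i in range(10)]
    nsu = [genes[f"NSU{i + 1:03d}"] for i in range(5)]
    sfn = [genes[f"SFN{i + 1:03d}"] for i in range(8)]

    members: list[PedigreeMember] = []
    variants: list[AnnotatedVariant] = []
    cnvs: list[CnvCall] = []
    array_qc: list[ArrayQc] = []
    truth_rows: list[dict] = []
    allocator = _CnvAllocator(genes, rng)

    def truth_variant(v: AnnotatedVariant, branch: str, retained: bool,
                      cls: Optional[AcmgClass] = None,
                      combined: Optional[AcmgClass] = None,
                      partner: Optional[str] = None,
                      drop_reason: str = "") -> None:
        truth_rows.append({
            "record_type": "variant", "key": v.key, "patient_id": v.patient_id,
            "branch": branch, "expected_retained": str(retained).lower(),
            "expected_class": cls.value if cls else "",
            "expected_combined_class": combined.value if combined else "",
            "expected_partner": partner or "",
            "expected_tier": "", "expected_source": "",
            "expected_drop_reason": drop_reason,
        })

    def truth_cnv(c: CnvCall, branch: str, retained: bool,
                  drop_reason: str = "") -> None:
        truth_rows.append({
            "record_type": "cnv", "key": c.key, "patient_id": c.patient_id,
            "branch": branch, "expected_retained": str(retained).lower(),
            "expected_class": c.prior_class.value if retained else "",
            "expected_combined_class": "", "expected_partner": "",
            "expected_tier": "", "expected_source": "",
            "expected_drop_reason": drop_reason,
        })

    def truth_patient(pid: str, branch: str) -> None:
        tier, source = _TIER_BY_BRANCH.get(branch, ("none", "none"))
        truth_rows.append({
            "record_type": "patient", "key": pid, "patient_id": pid,
            "branch": branch, "expected_retained": "",
            "expected_class": "", "expected_combined_class": "",
            "expected_partner": "",
            "expected_tier": tier, "expected_source": source,
            "expected_drop_reason": "",
        })

    plan = _expand_plan(config)
    seq_vous_subindex = 0
    shared_planted = 0
    shared_vous: Optional[tuple[GeneRecord, str]] = None

    for i, (branch, sex) in enumerate(plan):
        pid = f"A{i + 1:03d}"
        fid = f"F{i + 1:03d}"
        members.extend([
            PedigreeMember(fid, pid, f"{pid}-F", f"{pid}-M", sex, Affected.AFFECTED),
            PedigreeMember(fid, f"{pid}-F", None, None, Sex.MALE, Affected.UNAFFECTED),
            PedigreeMember(fid, f"{pid}-M", None, None, Sex.FEMALE, Affected.UNAFFECTED),
        ])
        array_qc.append(ArrayQc(pid, float(round(rng.uniform(0.1, 0.6), 3)),
                                float(round(rng.uniform(0.05, 0.25), 3))))
        truth_patient(pid, branch)

        gene_a = sfg[i % 30]
        gene_b = sfg[(i + 13) % 30]
        if gene_b.symbol == gene_a.symbol:
            gene_b = sfg[(i + 14) % 30]

        def plant_primary_lp(gene: GeneRecord) -> AnnotatedVariant:
            v = _make_variant(
                rng, pid, fid, gene, consequence=Consequence.MISSENSE,
                zygosity=Zygosity.HETEROZYGOUS, inheritance=Inheritance.DE_NOVO,
                cadd=_cadd(rng, 20.5, 44.5),
                acmg=[AcmgClass.P, AcmgClass.LP, AcmgClass.VOUS][int(rng.integers(0, 3))],
                hom=int(rng.integers(2, 11)),
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.LP)
            return v

        def plant_companion_vous(gene: GeneRecord) -> AnnotatedVariant:
            v = _make_variant(
                rng, pid, fid, gene, consequence=Consequence.MISSENSE,
                zygosity=Zygosity.HETEROZYGOUS, inheritance=Inheritance.DE_NOVO,
                cadd=_cadd(rng, 15.1, 19.4), acmg=AcmgClass.VOUS,
                hom=[None, 0, 1][int(rng.integers(0, 3))],
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.VOUS)
            return v

        if branch in ("seq_P_denovo_lpcnv", "seq_P_hom"):
            zyg = (Zygosity.HETEROZYGOUS if branch == "seq_P_denovo_lpcnv"
                   else Zygosity.HOMOZYGOUS)
            inh = (Inheritance.DE_NOVO if branch == "seq_P_denovo_lpcnv"
                   else Inheritance.BIPARENTAL)
            v = _make_variant(
                rng, pid, fid, gene_a, consequence=Consequence.MISSENSE,
                zygosity=zyg, inheritance=inh, cadd=_cadd(rng, 20.5, 44.5),
                acmg=[AcmgClass.P, AcmgClass.LP][int(rng.integers(0, 2))],
                hom=[None, 0, 1][int(rng.integers(0, 3))],
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.P)
            if branch == "seq_P_denovo_lpcnv":
                c = allocator.make(pid, AcmgClass.LP)
                cnvs.append(c)
                truth_cnv(c, branch, True)

        elif branch == "seq_P_upgrade":
            gene = sfgx[i % 6]
            v = _make_variant(
                rng, pid, fid, gene, consequence=Consequence.SPLICING,
                zygosity=Zygosity.HEMIZYGOUS, inheritance=Inheritance.MATERNAL,
                cadd=_cadd(rng, 20.5, 44.5), acmg=AcmgClass.VOUS,
                hom=int(rng.integers(2, 11)),
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.P)  # LP upgraded to P

        elif branch == "cnv_P":
            c = allocator.make(pid, AcmgClass.P, de_novo=True)
            cnvs.append(c)
            truth_cnv(c, branch, True)

        elif branch in ("seq_LP_hom2to10", "seq_LP_hom2to10_vouscnv", "both_LP"):
            plant_primary_lp(gene_a)
            if branch == "both_LP":
                c = allocator.make(pid, AcmgClass.LP)
                cnvs.append(c)
                truth_cnv(c, branch, True)
            else:
                plant_companion_vous(gene_b)
                if branch.endswith("_vouscnv"):
                    c = allocator.make(pid, AcmgClass.VOUS)
                    cnvs.append(c)
                    truth_cnv(c, branch, True)

        elif branch in ("seq_LP_chet", "seq_LP_chet_homexc"):
            rows, pair_class = plant_compound_het(
                rng, pid, fid, gene_a, (AcmgClass.LP, AcmgClass.VOUS),
                pipeline_cfg,
                hom_override_b=50 if branch.endswith("homexc") else None,
            )
            variants.extend(rows)
            truth_variant(rows[0], branch, True, AcmgClass.LP, pair_class,
                          partner=rows[1].key)
            truth_variant(rows[1], branch, True, AcmgClass.VOUS, pair_class,
                          partner=rows[0].key)

        elif branch == "seq_LP_nonsfari":
            gene = nsg[i % 10]
            v = _make_variant(
                rng, pid, fid, gene, consequence=Consequence.STOP_GAINED,
                zygosity=Zygosity.HETEROZYGOUS, inheritance=Inheritance.DE_NOVO,
                cadd=_cadd(rng, 20.5, 44.5),
                acmg=[AcmgClass.P, AcmgClass.LP][int(rng.integers(0, 2))],
                hom=[None, 0][int(rng.integers(0, 2))],
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.LP)

        elif branch == "seq_LP_hemi":
            gene = sfgx[i % 6]
            v = _make_variant(
                rng, pid, fid, gene, consequence=Consequence.MISSENSE,
                zygosity=Zygosity.HEMIZYGOUS, inheritance=Inheritance.MATERNAL,
                cadd=_cadd(rng, 20.5, 44.5), acmg=AcmgClass.VOUS,
                hom=int(rng.integers(2, 11)),
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.LP)
            plant_companion_vous(gene_b)

        elif branch in ("cnv_LP", "cnv_LP_vouscnv"):
            c = allocator.make(pid, AcmgClass.LP)
            cnvs.append(c)
            truth_cnv(c, branch, True)
            if branch.endswith("_vouscnv"):
                c2 = allocator.make(pid, AcmgClass.VOUS)
                cnvs.append(c2)
                truth_cnv(c2, branch, True)

        elif branch in ("seq_VOUS", "both_VOUS", "both_VOUS_2cnv"):
            if branch == "seq_VOUS" and shared_planted < 2 and sex is Sex.MALE:
                # two unrelated probands share one variant key (recurrence)
                if shared_vous is None:
                    shared_vous = (sfg[19], "c.100A>G")
                gene, hgvs = shared_vous
                v = _make_variant(
                    rng, pid, fid, gene, consequence=Consequence.MISSENSE,
                    zygosity=Zygosity.HETEROZYGOUS, inheritance=Inheritance.DE_NOVO,
                    cadd=17.0, acmg=AcmgClass.VOUS, hom=0, hgvs=hgvs,
                )
                shared_planted += 1
            else:
                kind = seq_vous_subindex % 3 if sex is Sex.MALE else 0
                seq_vous_subindex += 1
                if kind == 1:
                    gene = sfgx[i % 6]
                    zyg, inh = Zygosity.HEMIZYGOUS, Inheritance.MATERNAL
                elif kind == 2:
                    gene, zyg, inh = gene_a, Zygosity.HOMOZYGOUS, Inheritance.BIPARENTAL
                else:
                    gene, zyg, inh = gene_a, Zygosity.HETEROZYGOUS, Inheritance.DE_NOVO
                v = _make_variant(
                    rng, pid, fid, gene, consequence=Consequence.MISSENSE,
                    zygosity=zyg, inheritance=inh,
                    cadd=_cadd(rng, 15.1, 19.4), acmg=AcmgClass.VOUS,
                    hom=[None, 0, 1][int(rng.integers(0, 3))],
                )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.VOUS)
            if branch.startswith("both_VOUS"):
                n_cnv = 2 if branch.endswith("_2cnv") else 1
                for _ in range(n_cnv):
                    c = allocator.make(pid, AcmgClass.VOUS)
                    cnvs.append(c)
                    truth_cnv(c, branch, True)

        elif branch in ("cnv_VOUS", "cnv_VOUS_2cnv"):
            n_cnv = 2 if branch.endswith("_2cnv") else 1
            for _ in range(n_cnv):
                c = allocator.make(pid, AcmgClass.VOUS)
                cnvs.append(c)
                truth_cnv(c, branch, True)

        elif branch == "none_LB":
            v = _make_variant(
                rng, pid, fid, gene_a, consequence=Consequence.MISSENSE,
                zygosity=Zygosity.HOMOZYGOUS, inheritance=Inheritance.BIPARENTAL,
                cadd=_cadd(rng, 5.0, 14.4), acmg=AcmgClass.LB,
                hom=int(rng.integers(0, 6)),
            )
            variants.append(v)
            truth_variant(v, branch, True, AcmgClass.LB)

        elif branch == "none_empty":
            pass

        else:
            raise SimulationError(f"no recipe for branch {branch}")

        # planted noise: violates exactly one retention predicate
        if config.noise_every and i % config.noise_every == 0:
            noise_type = _NOISE_TYPES[(i // config.noise_every) % len(_NOISE_TYPES)]
            nv = _plant_noise(rng, pid, fid, noise_type, sfn, nsu)
            variants.append(nv)
            truth_variant(nv, noise_type, False,
                          drop_reason=_NOISE_REASON[noise_type])

    # CNV noise: benign-tier and common-DGV calls that must be excluded
    none_patients = [f"A{i + 1:03d}" for i, (b, _) in enumerate(plan)
                     if b == "none_empty"]
    for k in range(config.cnv_noise):
        pid = none_patients[k % len(none_patients)] if none_patients else "A001"
        if k % 2 == 0:
            c = allocator.make(pid, AcmgClass.LB, dgv=0.001, noise=True)
            cnvs.append(c)
            truth_cnv(c, "cnv_LB_drop", False, drop_reason="benign_class")
        else:
            c = allocator.make(pid, AcmgClass.VOUS, dgv=0.05, noise=True)
            cnvs.append(c)
            truth_cnv(c, "cnv_dgv_drop", False, drop_reason="dgv_frequency")

    truth = pd.DataFrame(truth_rows)
    return Cohort(config=config, members=members, variants=variants, cnvs=cnvs,
                  genes=genes, array_qc=array_qc, truth=truth)


_NOISE_REASON = {
    "noise_synonymous": "synonymous",
    "noise_inherited_het": "inherited_het",
    "noise_qc_coverage": "low_coverage",
    "noise_qc_gq": "low_gq",
    "noise_qc_maf": "common_maf",
    "noise_hom_gt10": "hom_count",
    "noise_gene_filter": "gene_filter",
}


def _plant_noise(rng, pid: str, fid: str, noise_type: str,
                 sfn: list[GeneRecord], nsu: list[GeneRecord]) -> AnnotatedVariant:
    gene = sfn[int(rng.integers(0, len(sfn)))]
    base = dict(consequence=Consequence.MISSENSE,
                zygosity=Zygosity.HETEROZYGOUS, inheritance=Inheritance.DE_NOVO,
                cadd=_cadd(rng, 20.5, 30.0), acmg=AcmgClass.VOUS, hom=0)
    if noise_type == "noise_synonymous":
        base["consequence"] = Consequence.SYNONYMOUS
    elif noise_type == "noise_inherited_het":
        base["inheritance"] = Inheritance.MATERNAL
    elif noise_type == "noise_qc_coverage":
        return _make_variant(rng, pid, fid, gene, coverage=5, **base)
    elif noise_type == "noise_qc_gq":
        return _make_variant(rng, pid, fid, gene, gq=8, **base)
    elif noise_type == "noise_qc_maf":
        return _make_variant(rng, pid, fid, gene, maf=0.2, **base)
    elif noise_type == "noise_hom_gt10":
        base["hom"] = int(rng.integers(11, 100))
    elif noise_type == "noise_gene_filter":
        gene = nsu[int(rng.integers(0, len(nsu)))]
        base["inheritance"] = Inheritance.MATERNAL
        base["maf"] = 0.005
    else:
        raise SimulationError(f"unknown noise type {noise_type}")
    return _make_variant(rng, pid, fid, gene, **base)


# ---------------------------------------------------------------------------
# file output

def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write all input tables plus the truth table; byte-deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# asdtriage synthetic cohort\n# seed: {cohort.config.seed}\n"
        f"# n_families: {cohort.config.n_families}\n"
    )
    paths = {
        "pedigree": out / "trios.ped",
        "variants": out / "variants.tsv",
        "cnvs": out / "cnvs.tsv",
        "genes": out / "genes.tsv",
        "array_qc": out / "arrayqc.tsv",
        "truth": out / "truth.tsv",
    }

    write_pedigree(cohort.members, paths["pedigree"])
    paths["pedigree"].write_text(header + paths["pedigree"].read_text())

    from .io import _fmt, _fmt_float  # shared formatting

    variant_rows = [
        {
            "patient_id": v.patient_id, "family_id": v.family_id, "gene": v.gene,
            "hgvs_c": v.hgvs_c, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref or "", "alt": v.alt or "",
            "consequence": v.consequence.value, "zygosity": v.zygosity.value,
            "inheritance": v.inheritance.value, "cadd": _fmt_float(v.cadd),
            "acmg": v.acmg.value, "gnomad_maf": _fmt_float(v.gnomad_maf),
            "gnomad_hom": _fmt(v.gnomad_hom_count),
            "coverage": v.coverage, "gq": v.gq,
        }
        for v in cohort.variants
    ]
    from .io import VARIANT_COLUMNS, CNV_COLUMNS
    _write_tsv(pd.DataFrame(variant_rows, columns=VARIANT_COLUMNS),
               paths["variants"], header)

    cnv_rows = [
        {
            "patient_id": c.patient_id, "chrom": c.chrom, "start": c.start,
            "end": c.end, "copy_state": c.copy_state.value,
            "copy_number": c.copy_number, "inheritance": c.inheritance.value,
            "prior_class": c.prior_class.value,
            "dgv_frequency": _fmt_float(c.dgv_frequency),
            "band_start": c.band_start or "", "band_end": c.band_end or "",
            "size_bp": c.size_bp,
        }
        for c in cohort.cnvs
    ]
    _write_tsv(pd.DataFrame(cnv_rows, columns=CNV_COLUMNS + ["size_bp"]),
               paths["cnvs"], header)

    write_gene_metadata(cohort.genes, paths["genes"])
    paths["genes"].write_text(header + paths["genes"].read_text())

    qc_rows = [
        {"patient_id": q.patient_id, "sd": _fmt_float(q.sd),
         "dlr_spread": _fmt_float(q.dlr_spread)}
        for q in cohort.array_qc
    ]
    _write_tsv(pd.DataFrame(qc_rows, columns=["patient_id", "sd", "dlr_spread"]),
               paths["array_qc"], header)

    _write_tsv(cohort.truth, paths["truth"], header)
    return paths


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    path.write_text(header + df.to_csv(sep="\t", index=False))
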