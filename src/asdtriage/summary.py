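"""Per-patient best-finding resolution and cohort-level statistics.

Percentages are rounded half-away-from-zero at a configurable number of
decimals (default 1). The detection rate of the combined tests is the
fraction of probands with at least one pathogenic or likely pathogenic
finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .cnv import CnvTriageResult
from .config import PipelineConfig
from .model import (
    AcmgClass,
    BestClass,
    ClassifiedVariant,
    CnvCall,
    CopyState,
    FindingSource,
    GeneRecord,
    PatientFinding,
    PedigreeMember,
    SEVERITY,
    Sex,
)

import logging

log = logging.getLogger("asdtriage")


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (10.25 -> 10.3 at 1 decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, decimals: int) -> float:
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in rate computation")
    return round_half_away(count / denominator * 100.0, decimals)


# ---------------------------------------------------------------------------
# best finding per proband

_REPORTABLE = (AcmgClass.P, AcmgClass.LP, AcmgClass.VOUS)

_TIER = {AcmgClass.P: BestClass.P, AcmgClass.LP: BestClass.LP,
         AcmgClass.VOUS: BestClass.VOUS}


def best_finding(
    patient_id: str,
    classified: Sequence[ClassifiedVariant],
    retained_cnvs: Sequence[CnvCall],
) -> PatientFinding:
    """Resolve a proband's best classification across both platforms.

    Compound-het members contribute their pair-level class. Findings are
    capped at the {P, LP, VOUS} tiers: a patient with only likely-benign
    results has no reportable finding. The source is ``both`` when the
    sequencing and array platforms independently reach the best tier.
    """
    seq = [c for c in classified if c.variant.patient_id == patient_id
           and c.effective_class in _REPORTABLE]
    cnv = [c for c in retained_cnvs if c.patient_id == patient_id
           and c.prior_class in _REPORTABLE]
    seq_best = max((c.effective_class for c in seq), key=SEVERITY.get, default=None)
    cnv_best = max((c.prior_class for c in cnv), key=SEVERITY.get, default=None)

    if seq_best is None and cnv_best is None:
        return PatientFinding(patient_id, BestClass.NONE, FindingSource.NONE, [])

    candidates = [c for c in (seq_best, cnv_best) if c is not None]
    best = max(candidates, key=SEVERITY.get)
    seq_hit = seq_best is best
    cnv_hit = cnv_best is best
    source = (
        FindingSource.BOTH if seq_hit and cnv_hit
        else FindingSource.SEQUENCE if seq_hit
        else FindingSource.CNV
    )
    keys = sorted(
        [c.key for c in seq if c.effective_class is best] if seq_hit else []
    ) + sorted(
        [c.key for c in cnv if c.prior_class is best] if cnv_hit else []
    )
    return PatientFinding(patient_id, _TIER[best], source, keys)


# ---------------------------------------------------------------------------
# cohort summary container

@dataclass
class CohortSummary:
    n_patients: int
    n_males: int
    n_females: int
    category_counts: dict[BestClass, int]
    category_rates: dict[BestClass, float]
    strata_counts: dict[BestClass, dict[FindingSource, int]]
    strata_rates: dict[BestClass, dict[FindingSource, float]]
    overall_detection_rate: float
    male_female_ratio: float
    cnv_counts: dict[str, int] = field(default_factory=dict)
    cnv_rates: dict[str, float] = field(default_factory=dict)
    sex_positivity: dict[Sex, float] = field(default_factory=dict)
    recurrence_table: Optional[pd.DataFrame] = None
    private_table: Optional[pd.DataFrame] = None
    private_class_rates: dict[AcmgClass, float] = field(default_factory=dict)
    family_table: Optional[pd.DataFrame] = None


def detection_rates(
    findings: Sequence[PatientFinding],
    members: Sequence[PedigreeMember],
    config: PipelineConfig,
) -> CohortSummary:
    """Tier counts/rates, platform strata, sex ratio and overall yield."""
    n = len(findings)
    if n == 0:
        raise ZeroDivisionError("empty cohort")
    ids = {f.patient_id for f in findings}
    if len(ids) != n:
        raise ValueError("one finding per proband required")
    sex_by_id = {m.individual_id: m.sex for m in members}
    n_males = sum(1 for i in ids if sex_by_id.get(i) is Sex.MALE)
    n_females = sum(1 for i in ids if sex_by_id.get(i) is Sex.FEMALE)

    counts = {tier: 0 for tier in BestClass}
    strata: dict[BestClass, dict[FindingSource, int]] = {
        tier: {s: 0 for s in (FindingSource.SEQUENCE, FindingSource.CNV,
                              FindingSource.BOTH)}
        for tier in (BestClass.P, BestClass.LP, BestClass.VOUS)
    }
    for f in findings:
        counts[f.best_class] += 1
        if f.best_class in strata:
            strata[f.best_class][f.source] += 1

    d = config.rate_decimals
    rates = {tier: percent(c, n, d) for tier, c in counts.items()}
    strata_rates = {
        tier: {s: percent(c, n, d) for s, c in by_source.items()}
        for tier, by_source in strata.items()
    }
    dr = percent(counts[BestClass.P] + counts[BestClass.LP], n, d)
    ratio = (
        round_half_away(n_males / n_females, config.ratio_decimals)
        if n_females else float("inf")
    )
    return CohortSummary(
        n_patients=n,
        n_males=n_males,
        n_females=n_females,
        category_counts=counts,
        category_rates=rates,
        strata_counts=strata,
        strata_rates=strata_rates,
        overall_detection_rate=dr,
        male_female_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# CNV composition

def cnv_composition(
    cnv_result: CnvTriageResult, config: PipelineConfig
) -> tuple[dict[str, int], dict[str, float]]:
    """Deletion/duplication/intragenic shares of the retained CNV set."""
    retained = cnv_result.retained
    n = len(retained)
    counts = {
        "total": n,
        "deletions": sum(1 for c in retained if c.copy_state is CopyState.LOSS),
        "duplications": sum(1 for c in retained if c.copy_state is CopyState.GAIN),
        "intragenic": sum(1 for c in retained if cnv_result.is_intragenic(c)),
    }
    if n == 0:
        return counts, {}
    rates = {
        "deletions": percent(counts["deletions"], n, config.rate_decimals),
        "duplications": percent(counts["duplications"], n, config.rate_decimals),
        "intragenic": percent(counts["intragenic"], n, config.intragenic_decimals),
    }
    return counts, rates


def cnv_detection_counts(
    retained_cnvs: Sequence[CnvCall], n_patients: int, config: PipelineConfig
) -> tuple[dict[str, int], dict[str, float]]:
    """Patient-level CNV yields: P carriers, P+LP carriers, any-CNV carriers."""
    p_patients = {c.patient_id for c in retained_cnvs if c.prior_class is AcmgClass.P}
    plp_patients = {
        c.patient_id
        for c in retained_cnvs
        if c.prior_class in (AcmgClass.P, AcmgClass.LP)
    }
    positive = {c.patient_id for c in retained_cnvs}
    counts = {
        "cnv_p_patients": len(p_patients),
        "cnv_p_lp_patients": len(plp_patients),
        "cnv_positive_patients": len(positive),
    }
    rates = {
        "cnv_p_patients": percent(len(p_patients), n_patients,
                                  config.cnv_rate_decimals),
        "cnv_p_lp_patients": percent(len(plp_patients), n_patients,
                                     config.rate_decimals),
        "cnv_positive_patients": percent(len(positive), n_patients,
                                         config.rate_decimals),
    }
    return counts, rates


# ---------------------------------------------------------------------------
# recurrence / private variants

def recurrence_and_private(
    classified: Sequence[ClassifiedVariant], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[AcmgClass, float]]:
    """Split retained variant keys into private and recurrent sets.

    A variant key (gene, HGVS c.) is private when carried by exactly one
    proband, recurrent when carried by two or more (siblings count as
    separate carriers). Returns the recurrence table (keys and genes with
    >= 2 carriers), the private-variant table, and the class distribution
    over the private set.
    """
    carriers: dict[tuple[str, str], list[ClassifiedVariant]] = {}
    for c in classified:
        carriers.setdefault((c.variant.gene, c.variant.hgvs_c), []).append(c)

    recurrent_rows, private_rows = [], []
    for (gene, hgvs), group in sorted(carriers.items()):
        patients = sorted({c.variant.patient_id for c in group})
        cls = max((c.effective_class for c in group), key=SEVERITY.get)
        row = {
            "gene": gene, "hgvs_c": hgvs, "n_patients": len(patients),
            "patients": ";".join(patients), "class": cls.value,
        }
        (private_rows if len(patients) == 1 else recurrent_rows).append(row)

    gene_carriers: dict[str, set[str]] = {}
    for c in classified:
        gene_carriers.setdefault(c.variant.gene, set()).add(c.variant.patient_id)
    recurrent_genes = sorted(g for g, pats in gene_carriers.items() if len(pats) >= 2)

    recurrence = pd.DataFrame(
        recurrent_rows, columns=["gene", "hgvs_c", "n_patients", "patients", "class"]
    )
    recurrence.attrs["recurrent_genes"] = recurrent_genes
    private = pd.DataFrame(
        private_rows, columns=["gene", "hgvs_c", "n_patients", "patients", "class"]
    )

    dist: dict[AcmgClass, float] = {}
    if private_rows:
        n_private = len(private_rows)
        for cls in (AcmgClass.P, AcmgClass.LP, AcmgClass.VOUS, AcmgClass.LB):
            count = sum(1 for r in private_rows if r["class"] == cls.value)
            dist[cls] = percent(count, n_private, config.rate_decimals)
    return recurrence, private, dist


# ---------------------------------------------------------------------------
# sex-stratified positivity

def sex_stratified_positivity(
    positive_patients: set[str],
    members: Sequence[PedigreeMember],
    proband_ids: set[str],
    config: PipelineConfig,
) -> dict[Sex, float]:
    """Positivity rate by proband sex; unknown-sex probands are excluded."""
    sex_by_id = {m.individual_id: m.sex for m in members}
    out: dict[Sex, float] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        denom = [i for i in proband_ids if sex_by_id.get(i) is sex]
        if not denom:
            out[sex] = 0.0
            continue
        pos = sum(1 for i in denom if i in positive_patients)
        out[sex] = percent(pos, len(denom), config.rate_decimals)
    unknown = [i for i in proband_ids if sex_by_id.get(i) not in (Sex.MALE, Sex.FEMALE)]
    if unknown:
        log.warning("%d probands with unknown sex excluded from sex strata",
                    len(unknown))
    return out


# ---------------------------------------------------------------------------
# gene families

def gene_family_summary(
    classified: Sequence[ClassifiedVariant],
    genes: dict[str, GeneRecord],
    config: PipelineConfig,
    genome_family_sizes: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Group observed genes by gene family.

    The size filter applies to the genome-wide family size when
    provided, else to the number of distinct observed genes. Genes with
    no family annotation group under ``unassigned`` and are excluded
    from the filtered view.
    """
    rows: dict[str, dict] = {}
    for c in classified:
        g = genes.get(c.variant.gene)
        family = (g.family_name if g and g.family_name else "unassigned")
        entry = rows.setdefault(
            family, {"family": family, "genes": set(), "sfari_genes": set(),
                     "patients": set()}
        )
        entry["genes"].add(c.variant.gene)
        if g and g.sfari_member:
            entry["sfari_genes"].add(c.variant.gene)
        entry["patients"].add(c.variant.patient_id)

    out = []
    for family in sorted(rows):
        if family == "unassigned":
            continue
        entry = rows[family]
        size = (
            genome_family_sizes.get(family, len(entry["genes"]))
            if genome_family_sizes
            else len(entry["genes"])
        )
        if size < config.min_family_size:
            continue
        out.append(
            {
                "family": family,
                "n_genes": len(entry["genes"]),
                "genes": ";".join(sorted(entry["genes"])),
                "sfari_genes": ";".join(sorted(entry["sfari_genes"])),
                "n_patients": len(entry["patients"]),
                "patients": ";".join(sorted(entry["patients"])),
            }
        )
    return pd.DataFrame(
        out, columns=["family", "n_genes", "genes", "sfari_genes",
                      "n_patients", "patients"]
    )


# ---------------------------------------------------------------------------
# serialisation

def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Long-format (section, key, value) table of the cohort summary."""
    rows: list[tuple[str, str, str]] = []

    def add(section: str, key: str, value) -> None:
        rows.append((section, key, str(value)))

    add("cohort", "n_patients", summary.n_patients)
    add("cohort", "n_males", summary.n_males)
    add("cohort", "n_females", summary.n_females)
    add("cohort", "male_female_ratio", summary.male_female_ratio)
    for tier in (BestClass.P, BestClass.LP, BestClass.VOUS, BestClass.NONE):
        add("tier_counts", tier.value, summary.category_counts[tier])
        add("tier_rates_pct", tier.value, summary.category_rates[tier])
    for tier, by_source in summary.strata_counts.items():
        for source, count in by_source.items():
            add("strata_counts", f"{tier.value}/{source.value}", count)
    add("detection", "overall_p_lp_rate_pct", summary.overall_detection_rate)
    for key in sorted(summary.cnv_counts):
        add("cnv_counts", key, summary.cnv_counts[key])
    for key in sorted(summary.cnv_rates):
        add("cnv_rates_pct", key, summary.cnv_rates[key])
    for sex, rate in summary.sex_positivity.items():
        add("cnv_sex_positivity_pct", sex.value, rate)
    for cls, rate in summary.private_class_rates.items():
        add("private_class_rates_pct", cls.value, rate)
    return pd.DataFrame(rows, columns=["section", "key", "value"])
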