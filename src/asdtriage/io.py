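"""Readers and writers for the tabular interchange formats.

All tables are tab-separated text with a header row, ``.`` as the decimal
point, empty cells for missing values, and ``#``-prefixed comment lines.
Pedigrees use the standard 6-column PED format. Parsers are total on the
documented dialect: every malformed cell raises a :class:`TableError`
naming the file, row and column — there is no silent coercion.
"""

from __future__ import annotations

import enum
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    AcmgClass,
    Affected,
    AnnotatedVariant,
    ArrayQc,
    BestClass,
    ClassifiedVariant,
    CnvCall,
    Consequence,
    CopyState,
    DropRecord,
    FindingSource,
    GeneRecord,
    Inheritance,
    ModelError,
    PatientFinding,
    PedigreeMember,
    Sex,
    SfariScore,
    Strand,
    Zygosity,
)

log = logging.getLogger("asdtriage")


class TableError(ValueError):
    """A located parse/validation error in a tabular input."""

    def __init__(self, path, row: Optional[int], column: Optional[str], message: str):
        self.path = str(path)
        self.row = row
        self.column = column
        loc = self.path
        if row is not None:
            loc += f", row {row}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")


# ---------------------------------------------------------------------------
# cell-level parsers

def _parse_enum(cls, value: str, path, row: int, column: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise TableError(
            path, row, column, f"unknown token {value!r} (allowed: {allowed})"
        ) from None


def _parse_float(value: str, path, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise TableError(path, row, column, f"not a number: {value!r}") from None


def _parse_int(value: str, path, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise TableError(path, row, column, f"not an integer: {value!r}") from None


def _opt(value: str) -> Optional[str]:
    return value if value != "" else None


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(path, None, None, "file not found")
    df = pd.read_csv(
        path, sep="\t", dtype=str, comment="#", keep_default_na=False, skip_blank_lines=True
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(path, None, None, f"missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# PED pedigrees

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN,
            "male": Sex.MALE, "female": Sex.FEMALE, "unknown": Sex.UNKNOWN}
_PED_AFF = {"2": Affected.AFFECTED, "1": Affected.UNAFFECTED,
            "0": Affected.UNKNOWN, "-9": Affected.UNKNOWN,
            "affected": Affected.AFFECTED, "unaffected": Affected.UNAFFECTED,
            "unknown": Affected.UNKNOWN}


def read_pedigree(path: str | Path) -> list[PedigreeMember]:
    """Read a standard 6-column PED file (whitespace-delimited)."""
    path = Path(path)
    if not path.exists():
        raise TableError(path, None, None, "file not found")
    members: list[PedigreeMember] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 6:
            raise TableError(path, lineno, None, f"expected 6 columns, got {len(cols)}")
        fam, ind, father, mother, sex, aff = cols
        if (fam, ind) in seen:
            raise TableError(path, lineno, "individual_id",
                             f"duplicate individual {ind!r} in family {fam!r}")
        seen.add((fam, ind))
        if sex not in _PED_SEX:
            raise TableError(path, lineno, "sex", f"unknown sex code {sex!r}")
        if aff not in _PED_AFF:
            raise TableError(path, lineno, "affected", f"unknown status code {aff!r}")
        members.append(
            PedigreeMember(
                family_id=fam,
                individual_id=ind,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_PED_SEX[sex],
                affected=_PED_AFF[aff],
            )
        )
    # referential check within each family
    by_family: dict[str, set[str]] = {}
    for m in members:
        by_family.setdefault(m.family_id, set()).add(m.individual_id)
    for m in members:
        for parent in (m.father_id, m.mother_id):
            if parent is not None and parent not in by_family[m.family_id]:
                log.warning(
                    "pedigree %s: %s references absent parent %s (trio incomplete)",
                    path, m.individual_id, parent,
                )
    return members


def trio_complete(member: PedigreeMember, members: Iterable[PedigreeMember]) -> bool:
    """True when both parents of ``member`` are present in the same family."""
    ids = {m.individual_id for m in members if m.family_id == member.family_id}
    return (
        member.father_id is not None
        and member.mother_id is not None
        and member.father_id in ids
        and member.mother_id in ids
    )


def probands(members: Sequence[PedigreeMember]) -> list[PedigreeMember]:
    """Affected members with a complete trio (the study is trio-based)."""
    out = []
    for m in members:
        if m.affected is not Affected.AFFECTED:
            continue
        if trio_complete(m, members):
            out.append(m)
        else:
            log.warning("proband %s excluded: incomplete trio", m.individual_id)
    return out


def write_pedigree(members: Sequence[PedigreeMember], path: str | Path) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affected.AFFECTED: "2", Affected.UNAFFECTED: "1", Affected.UNKNOWN: "0"}
    lines = [
        "\t".join(
            [
                m.family_id,
                m.individual_id,
                m.father_id or "0",
                m.mother_id or "0",
                sex_code[m.sex],
                aff_code[m.affected],
            ]
        )
        for m in members
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# variant table

VARIANT_COLUMNS = [
    "patient_id", "family_id", "gene", "hgvs_c", "chrom", "pos", "ref", "alt",
    "consequence", "zygosity", "inheritance", "cadd", "acmg",
    "gnomad_maf", "gnomad_hom", "coverage", "gq",
]


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    df = _read_tsv(path, VARIANT_COLUMNS)
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        maf = _opt(row.gnomad_maf)
        hom = _opt(row.gnomad_hom)
        try:
            variants.append(
                AnnotatedVariant(
                    patient_id=row.patient_id,
                    family_id=row.family_id,
                    gene=row.gene,
                    hgvs_c=row.hgvs_c,
                    chrom=row.chrom,
                    pos=_parse_int(row.pos, path, i, "pos"),
                    ref=_opt(row.ref),
                    alt=_opt(row.alt),
                    consequence=_parse_enum(Consequence, row.consequence, path, i, "consequence"),
                    zygosity=_parse_enum(Zygosity, row.zygosity, path, i, "zygosity"),
                    inheritance=_parse_enum(Inheritance, row.inheritance, path, i, "inheritance"),
                    cadd=_parse_float(row.cadd, path, i, "cadd"),
                    acmg=_parse_enum(AcmgClass, row.acmg, path, i, "acmg"),
                    gnomad_maf=_parse_float(maf, path, i, "gnomad_maf") if maf else None,
                    gnomad_hom_count=_parse_int(hom, path, i, "gnomad_hom") if hom else None,
                    coverage=_parse_int(row.coverage, path, i, "coverage"),
                    gq=_parse_int(row.gq, path, i, "gq"),
                )
            )
        except ModelError as exc:
            raise TableError(path, i, None, str(exc)) from None
    return variants


def validate_variants_against_pedigree(
    variants: Sequence[AnnotatedVariant], members: Sequence[PedigreeMember]
) -> list[str]:
    """Cross-table checks that warn rather than fail (e.g. hemizygous female)."""
    sex_by_id = {m.individual_id: m.sex for m in members}
    warnings = []
    for v in variants:
        sex = sex_by_id.get(v.patient_id)
        if v.zygosity is Zygosity.HEMIZYGOUS and sex is Sex.FEMALE:
            warnings.append(f"{v.key}: hemizygous variant in female proband")
        if sex is None:
            warnings.append(f"{v.key}: patient {v.patient_id} absent from pedigree")
    for w in warnings:
        log.warning("%s", w)
    return warnings


# ---------------------------------------------------------------------------
# CNV table

CNV_COLUMNS = [
    "patient_id", "chrom", "start", "end", "copy_state", "copy_number",
    "inheritance", "prior_class", "dgv_frequency", "band_start", "band_end",
]


def read_cnv_table(path: str | Path) -> list[CnvCall]:
    df = _read_tsv(path, CNV_COLUMNS)
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        dgv = _opt(row.dgv_frequency)
        try:
            call = CnvCall(
                patient_id=row.patient_id,
                chrom=row.chrom,
                start=_parse_int(row.start, path, i, "start"),
                end=_parse_int(row.end, path, i, "end"),
                copy_state=_parse_enum(CopyState, row.copy_state, path, i, "copy_state"),
                copy_number=_parse_int(row.copy_number, path, i, "copy_number"),
                inheritance=_parse_enum(Inheritance, row.inheritance, path, i, "inheritance"),
                prior_class=_parse_enum(AcmgClass, row.prior_class, path, i, "prior_class"),
                dgv_frequency=_parse_float(dgv, path, i, "dgv_frequency") if dgv else None,
                band_start=_opt(row.band_start),
                band_end=_opt(row.band_end),
            )
        except ModelError as exc:
            raise TableError(path, i, None, str(exc)) from None
        if hasattr(row, "size_bp") and _opt(getattr(row, "size_bp")):
            declared = _parse_int(getattr(row, "size_bp"), path, i, "size_bp")
            if declared != call.size_bp:
                raise TableError(
                    path, i, "size_bp",
                    f"declared size {declared} != end-start+1 = {call.size_bp}",
                )
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# gene metadata

GENE_COLUMNS = [
    "symbol", "chrom", "start", "end", "strand", "sfari_member", "sfari_score",
    "function_tags", "family_name", "brain_expression_pct",
    "haploinsufficient", "triplosensitive",
]

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_bool(value: str, path, row: int, column: str) -> bool:
    try:
        return _BOOL[value.lower()]
    except KeyError:
        raise TableError(path, row, column, f"not a boolean: {value!r}") from None


def read_gene_metadata(path: str | Path) -> dict[str, GeneRecord]:
    df = _read_tsv(path, GENE_COLUMNS)
    genes: dict[str, GeneRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.symbol in genes:
            raise TableError(path, i, "symbol", f"duplicate gene {row.symbol!r}")
        score_raw = row.sfari_score if row.sfari_score else "none"
        if score_raw == "2B":  # SFARI 2B normalises to tier 2 for ranking
            score_raw = "2"
        brain = _opt(row.brain_expression_pct)
        hap = _opt(row.haploinsufficient)
        trip = _opt(row.triplosensitive)
        try:
            genes[row.symbol] = GeneRecord(
                symbol=row.symbol,
                chrom=row.chrom,
                start=_parse_int(row.start, path, i, "start"),
                end=_parse_int(row.end, path, i, "end"),
                strand=_parse_enum(Strand, row.strand or "unknown", path, i, "strand"),
                sfari_member=_parse_bool(row.sfari_member, path, i, "sfari_member"),
                sfari_score=_parse_enum(SfariScore, score_raw, path, i, "sfari_score"),
                function_tags=frozenset(
                    t for t in row.function_tags.split(";") if t
                ),
                family_name=_opt(row.family_name),
                brain_expression_pct=_parse_float(brain, path, i, "brain_expression_pct")
                if brain else None,
                haploinsufficient=_parse_bool(hap, path, i, "haploinsufficient")
                if hap else None,
                triplosensitive=_parse_bool(trip, path, i, "triplosensitive")
                if trip else None,
            )
        except ModelError as exc:
            raise TableError(path, i, None, str(exc)) from None
    return genes


def default_gene_record(symbol: str) -> GeneRecord:
    """Fallback for genes absent from the metadata table.

    Such genes follow the non-SFARI branch with no functional tags; the
    synthesis is logged so missing annotation is visible.
    """
    log.warning("gene %s absent from metadata table; using non-SFARI default", symbol)
    return GeneRecord(symbol=symbol, chrom="unknown", start=1, end=1)


def write_gene_metadata(genes: dict[str, GeneRecord], path: str | Path) -> None:
    rows = []
    for g in genes.values():
        rows.append(
            {
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand.value,
                "sfari_member": str(g.sfari_member).lower(),
                "sfari_score": "" if g.sfari_score is SfariScore.NONE else g.sfari_score.value,
                "function_tags": ";".join(sorted(g.function_tags)),
                "family_name": g.family_name or "",
                "brain_expression_pct": _fmt_float(g.brain_expression_pct),
                "haploinsufficient": "" if g.haploinsufficient is None
                else str(g.haploinsufficient).lower(),
                "triplosensitive": "" if g.triplosensitive is None
                else str(g.triplosensitive).lower(),
            }
        )
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# array QC

def read_array_qc(path: str | Path) -> list[ArrayQc]:
    df = _read_tsv(path, ["patient_id", "sd", "dlr_spread"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                ArrayQc(
                    patient_id=row.patient_id,
                    sd=_parse_float(row.sd, path, i, "sd"),
                    dlr_spread=_parse_float(row.dlr_spread, path, i, "dlr_spread"),
                )
            )
        except ModelError as exc:
            raise TableError(path, i, None, str(exc)) from None
    return out


# ---------------------------------------------------------------------------
# results

def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    return format(x, ".10g")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return _fmt_float(value)
    return str(value)


CLASSIFIED_COLUMNS = VARIANT_COLUMNS + [
    "assigned_class", "rule_trace", "compound_partner", "combined_class",
    "incomplete_penetrance",
]


def classified_frame(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    rows = []
    for c in sorted(classified, key=lambda c: (c.variant.patient_id, c.variant.gene,
                                               c.variant.hgvs_c)):
        v = c.variant
        rows.append(
            {
                "patient_id": v.patient_id, "family_id": v.family_id,
                "gene": v.gene, "hgvs_c": v.hgvs_c, "chrom": v.chrom,
                "pos": v.pos, "ref": _fmt(v.ref), "alt": _fmt(v.alt),
                "consequence": v.consequence.value, "zygosity": v.zygosity.value,
                "inheritance": v.inheritance.value, "cadd": _fmt_float(v.cadd),
                "acmg": v.acmg.value, "gnomad_maf": _fmt_float(v.gnomad_maf),
                "gnomad_hom": _fmt(v.gnomad_hom_count),
                "coverage": v.coverage, "gq": v.gq,
                "assigned_class": c.assigned_class.value,
                "rule_trace": ";".join(c.rule_trace),
                "compound_partner": _fmt(c.compound_partner),
                "combined_class": _fmt(c.combined_class),
                "incomplete_penetrance": _fmt(c.incomplete_penetrance),
            }
        )
    return pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS)


def read_classified_table(path: str | Path) -> list[ClassifiedVariant]:
    """Re-read a written classification table (round-trip contract)."""
    df = _read_tsv(path, CLASSIFIED_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        maf = _opt(row.gnomad_maf)
        hom = _opt(row.gnomad_hom)
        variant = AnnotatedVariant(
            patient_id=row.patient_id, family_id=row.family_id, gene=row.gene,
            hgvs_c=row.hgvs_c, chrom=row.chrom,
            pos=_parse_int(row.pos, path, i, "pos"),
            ref=_opt(row.ref), alt=_opt(row.alt),
            consequence=_parse_enum(Consequence, row.consequence, path, i, "consequence"),
            zygosity=_parse_enum(Zygosity, row.zygosity, path, i, "zygosity"),
            inheritance=_parse_enum(Inheritance, row.inheritance, path, i, "inheritance"),
            cadd=_parse_float(row.cadd, path, i, "cadd"),
            acmg=_parse_enum(AcmgClass, row.acmg, path, i, "acmg"),
            gnomad_maf=_parse_float(maf, path, i, "gnomad_maf") if maf else None,
            gnomad_hom_count=_parse_int(hom, path, i, "gnomad_hom") if hom else None,
            coverage=_parse_int(row.coverage, path, i, "coverage"),
            gq=_parse_int(row.gq, path, i, "gq"),
        )
        combined = _opt(row.combined_class)
        out.append(
            ClassifiedVariant(
                variant=variant,
                assigned_class=_parse_enum(AcmgClass, row.assigned_class, path, i,
                                           "assigned_class"),
                rule_trace=[t for t in row.rule_trace.split(";") if t],
                compound_partner=_opt(row.compound_partner),
                combined_class=_parse_enum(AcmgClass, combined, path, i, "combined_class")
                if combined else None,
                incomplete_penetrance=_parse_bool(
                    row.incomplete_penetrance or "false", path, i, "incomplete_penetrance"
                ),
            )
        )
    return out


def findings_frame(findings: Sequence[PatientFinding]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": f.patient_id,
            "best_class": f.best_class.value,
            "source": f.source.value,
            "contributing_keys": ";".join(f.contributing_keys),
        }
        for f in sorted(findings, key=lambda f: f.patient_id)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "best_class", "source",
                                       "contributing_keys"])


def read_findings_table(path: str | Path) -> list[PatientFinding]:
    df = _read_tsv(path, ["patient_id", "best_class", "source", "contributing_keys"])
    return [
        PatientFinding(
            patient_id=row.patient_id,
            best_class=_parse_enum(BestClass, row.best_class, path, i, "best_class"),
            source=_parse_enum(FindingSource, row.source, path, i, "source"),
            contributing_keys=[k for k in row.contributing_keys.split(";") if k],
        )
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]


def drop_log_frame(dropped: Sequence[DropRecord]) -> pd.DataFrame:
    rows = [
        {"key": d.key, "patient_id": d.patient_id, "stage": d.stage, "reason": d.reason}
        for d in sorted(dropped, key=lambda d: (d.patient_id, d.key))
    ]
    return pd.DataFrame(rows, columns=["key", "patient_id", "stage", "reason"])


def write_results(
    out_dir: str | Path,
    classified: Sequence[ClassifiedVariant],
    findings: Sequence[PatientFinding],
    summary_frame: pd.DataFrame,
    dropped: Sequence[DropRecord] = (),
) -> dict[str, Path]:
    """Write the result tables with deterministic column order and row sort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "classified": out_dir / "classified_variants.tsv",
        "findings": out_dir / "patient_findings.tsv",
        "summary": out_dir / "cohort_summary.tsv",
        "drop_log": out_dir / "drop_log.tsv",
    }
    classified_frame(classified).to_csv(paths["classified"], sep="\t", index=False)
    findings_frame(findings).to_csv(paths["findings"], sep="\t", index=False)
    summary_frame.to_csv(paths["summary"], sep="\t", index=False)
    drop_log_frame(dropped).to_csv(paths["drop_log"], sep="\t", index=False)
    return paths
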