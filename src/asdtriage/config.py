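"""Pipeline configuration: every threshold used by the triage cascade.

Defaults are the study conditions of the cohort analysis this package
implements: WES QC at 10x coverage / GQ 15, common variants (MAF >= 5%)
excluded, the non-SFARI gene filter at MAF < 1%, the homozygote-count
retention ceiling at 10, classifier CADD cut-offs at 20 (deleterious)
and 15 (benign), and the CNV filter at DGV frequency > 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .model import AcmgClass, Consequence, CRITERION4_TAGS, more_severe


class ConfigError(ValueError):
    pass


PairKey = tuple[AcmgClass, AcmgClass]


def normalize_pair(a: AcmgClass, b: AcmgClass) -> PairKey:
    """Order an unordered class pair as (more severe, less severe)."""
    hi = more_severe(a, b)
    lo = b if hi is a else a
    return (hi, lo)


#: Compound-heterozygosity combination matrix (pair class from the two
#: member classes, severity-normalised). The (P, VOUS) pair is not covered
#: by the published table; it defaults to LP, between the neighbouring
#: (P, LP) -> P and (LP, VOUS) -> LP rows, and is config-overridable.
DEFAULT_COMBINATION_MATRIX: dict[PairKey, AcmgClass] = {
    (AcmgClass.P, AcmgClass.P): AcmgClass.P,
    (AcmgClass.P, AcmgClass.LP): AcmgClass.P,
    (AcmgClass.P, AcmgClass.VOUS): AcmgClass.LP,
    (AcmgClass.P, AcmgClass.LB): AcmgClass.VOUS,
    (AcmgClass.LP, AcmgClass.LP): AcmgClass.LP,
    (AcmgClass.LP, AcmgClass.VOUS): AcmgClass.LP,
    (AcmgClass.LP, AcmgClass.LB): AcmgClass.VOUS,
    (AcmgClass.VOUS, AcmgClass.VOUS): AcmgClass.VOUS,
    (AcmgClass.VOUS, AcmgClass.LB): AcmgClass.VOUS,
    (AcmgClass.LB, AcmgClass.LB): AcmgClass.LB,
}

#: Consequences counted as "truncating" by the non-SFARI gene filter.
DEFAULT_TRUNCATING = frozenset(
    {
        Consequence.FRAMESHIFT,
        Consequence.STOP_GAINED,
        Consequence.START_LOST,
        Consequence.SPLICING,
    }
)


@dataclass(frozen=True)
class PipelineConfig:
    # --- sequence-variant QC (strict exclusions below threshold) ---
    min_coverage: int = 10
    min_gq: int = 15
    max_maf: float = 0.05  # variants with MAF >= this are excluded

    # --- gene filter (non-SFARI branch) ---
    non_sfari_max_maf: float = 0.01
    truncating_consequences: frozenset[Consequence] = DEFAULT_TRUNCATING

    # --- retention ---
    max_hom_count: int = 10

    # --- classifier ---
    cadd_path_min: float = 20.0  # criterion 1
    cadd_benign_max: float = 15.0
    hom_path_max: int = 1  # criterion 3
    hom_lp_min: int = 2
    hom_lp_max: int = 10
    criterion4_tags: frozenset[str] = CRITERION4_TAGS
    allow_non_sfari_pathogenic: bool = False
    lp_allow_low_hom: bool = False  # lenient reading of the 2-10 homozygote LP rule
    unique_candidate_upgrade: bool = True
    combination_matrix: dict[PairKey, AcmgClass] = field(
        default_factory=lambda: dict(DEFAULT_COMBINATION_MATRIX)
    )

    # --- CNV triage ---
    max_dgv_frequency: float = 0.01  # strictly-greater frequencies excluded
    array_qc_max_sd: float = 1.0  # strict: sd must be < this
    array_qc_max_dlr_spread: float = 0.3

    # --- summaries ---
    rate_decimals: int = 1
    ratio_decimals: int = 1
    intragenic_decimals: int = 0
    cnv_rate_decimals: int = 2
    min_family_size: int = 2

    def __post_init__(self) -> None:
        if self.cadd_benign_max > self.cadd_path_min:
            raise ConfigError("cadd_benign_max must be <= cadd_path_min")
        if self.hom_lp_min <= self.hom_path_max:
            raise ConfigError("hom_lp_min must be > hom_path_max")
        if not 0.0 < self.max_maf <= 1.0:
            raise ConfigError("max_maf must be in (0, 1]")
        if self.min_coverage < 0 or self.min_gq < 0:
            raise ConfigError("QC thresholds must be non-negative")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


_SET_FIELDS = {"truncating_consequences", "criterion4_tags"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"{path}: unknown config key {key!r}")
        if key == "combination_matrix":
            kwargs[key] = _parse_matrix(value)
        elif key == "truncating_consequences":
            kwargs[key] = frozenset(Consequence(v) for v in value)
        elif key == "criterion4_tags":
            kwargs[key] = frozenset(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    out: dict = {}
    for f in fields(PipelineConfig):
        value = getattr(config, f.name)
        if f.name == "combination_matrix":
            value = {
                f"{hi.value}+{lo.value}": cls.value for (hi, lo), cls in value.items()
            }
        elif f.name in _SET_FIELDS:
            value = sorted(v.value if hasattr(v, "value") else v for v in value)
        out[f.name] = value
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def _parse_matrix(raw: dict) -> dict[PairKey, AcmgClass]:
    matrix = {}
    for key, value in raw.items():
        try:
            a, b = key.split("+")
            pair = normalize_pair(AcmgClass(a), AcmgClass(b))
        except ValueError as exc:
            raise ConfigError(f"bad combination_matrix key {key!r}") from exc
        matrix[pair] = AcmgClass(value)
    return matrix
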