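"""Configuration objects for the synthetic-claims generator and the
analysis pipeline.

Every threshold that drives the pipeline (era gap, lookback, PDC
cut-offs, clinical-control counting rules, matching tolerances) is a
configuration default here rather than a literal in the algorithms, so
that sensitivity variants are plain config edits.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

from .exceptions import ConfigurationError

DRUG_CLASSES = ("BP", "LIPID", "GLUCOSE")

#: The five clinical controls recommended annually for people with diabetes.
CONTROL_TYPES = (
    "hba1c",
    "lipid_profile",
    "serum_creatinine",
    "urine_albumin",
    "eye_exam",
)

#: Service-code -> control-type map used by the synthetic tables.  Codes
#: mapping to ``None`` are recognised non-control services and are
#: skipped silently; codes absent from the map trigger a logged warning.
DEFAULT_CONTROL_CODE_MAP: dict[str, str | None] = {
    "HBA1C": "hba1c",
    "LIPID_PANEL": "lipid_profile",
    "CREATININE": "serum_creatinine",
    "URINE_ALB": "urine_albumin",
    "EYE_EXAM": "eye_exam",
    "GENERIC_VISIT": None,
}

SMI_DIAGNOSES = (
    "depression",
    "schizophrenia",
    "bipolar disorder",
    "personality disorder",
)

#: Tie-break for concurrent open care episodes: most to least severe.
SEVERITY_ORDER = (
    "schizophrenia",
    "bipolar disorder",
    "personality disorder",
    "depression",
)

#: Default comorbidity/cotreatment codelists over the 2-year lookback.
#: Codelists are inputs, not hard-coded vocabularies: each entry names
#: the table to scan, the column holding the code and the codes that
#: raise the flag.
DEFAULT_CODELISTS: dict[str, dict[str, Any]] = {
    "nsaid": {"table": "dispensations", "column": "drug_class", "codes": ["NSAID"]},
    "antithrombotic": {
        "table": "dispensations",
        "column": "drug_class",
        "codes": ["ANTITHROMBOTIC"],
    },
    "cardiovascular_disease": {
        "table": "hospital_stays",
        "column": "diagnosis_code",
        "codes": ["CVD"],
    },
}

#: Cut-points binning the supplied Multisource Comorbidity Score into
#: clinical-profile categories ("good" .. "very poor").  Closed on the
#: right: a score exactly at a cut-point falls in the lower category.
DEFAULT_MCS_CUTPOINTS = (1.0, 3.0, 5.0)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic-claims scenario.

    The planted ``true_log_or`` is the conditional (within matched set)
    log-odds ratio of high drug adherence for exposed versus unexposed
    patients; recovering its exponential is what the downstream pipeline
    is tested on.  ``confounder_effects`` contribute to both the
    exposure model and the adherence model, so the crude and conditional
    effects differ and matching is actually exercised.
    """

    n_patients: int = 20_000
    index_date: dt.date = dt.date(2017, 1, 1)
    smi_prevalence: float = 0.02
    true_log_or: float = 0.0
    #: planted conditional log-OR for the >=4-of-5 clinical-control
    #: outcome among GLUCOSE patients; falls back to ``true_log_or``.
    true_log_or_controls: float | None = None
    baseline_high_adherence_prob: float = 0.5
    baseline_high_controls_prob: float = 0.5
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: {
            "gender_female": -0.2,
            "age_per_decade": 0.15,
            "log_contacts": 0.30,
        }
    )
    drug_class_mix: dict[str, float] = field(
        default_factory=lambda: {"BP": 0.60, "LIPID": 0.22, "GLUCOSE": 0.18}
    )
    #: yearly intensity of extra (non-outcome-driving) control services
    control_rates: dict[str, float] = field(
        default_factory=lambda: {
            "hba1c": 0.5,
            "lipid_profile": 0.3,
            "serum_creatinine": 0.3,
            "urine_albumin": 0.2,
            "eye_exam": 0.2,
        }
    )
    hospital_rate: float = 0.10
    death_emigration_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        _check_prob("smi_prevalence", self.smi_prevalence)
        _check_prob("baseline_high_adherence_prob", self.baseline_high_adherence_prob)
        _check_prob("baseline_high_controls_prob", self.baseline_high_controls_prob)
        _check_prob("death_emigration_prob", self.death_emigration_prob)
        if self.hospital_rate < 0:
            raise ConfigurationError("hospital_rate must be non-negative")
        for cls, p in self.drug_class_mix.items():
            if cls not in DRUG_CLASSES:
                raise ConfigurationError(f"unknown drug class {cls!r} in drug_class_mix")
            _check_prob(f"drug_class_mix[{cls}]", p)
        total = sum(self.drug_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"drug_class_mix must sum to 1, got {total}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")

    @property
    def effective_control_log_or(self) -> float:
        if self.true_log_or_controls is None:
            return self.true_log_or
        return self.true_log_or_controls

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["index_date"] = self.index_date.isoformat()
        return d


@dataclass
class EraConfig:
    """Drug-era chaining and prevalent-user thresholds."""

    gap_days: int = 60
    lookback_days: int = 730
    min_dispensations: int = 3
    #: if True, the qualifying chain must also still be active at the
    #: index date (its coverage end within ``gap_days`` of the index).
    require_active_at_index: bool = False

    def validate(self) -> None:
        if self.gap_days < 0:
            raise ConfigurationError("gap_days must be >= 0")
        if self.min_dispensations < 1:
            raise ConfigurationError("min_dispensations must be >= 1")


@dataclass
class AdherenceConfig:
    """PDC measurement rules over the one-year follow-up."""

    followup_days: int = 365
    #: count pre-window supply that spills into the follow-up window
    include_spillover: bool = True
    #: 'any_prior_era' bridges a hospital stay whenever the patient had
    #: any era of the class before admission; 'overlapping_era' demands
    #: an era whose span contains the admission date.
    bridging: str = "any_prior_era"
    high_thresholds: tuple[float, ...] = (0.70, 0.75, 0.80)
    #: minimum annual counts per control for the recommendation to count
    control_min_counts: dict[str, int] = field(
        default_factory=lambda: {
            "hba1c": 2,
            "lipid_profile": 1,
            "serum_creatinine": 1,
            "urine_albumin": 1,
            "eye_exam": 1,
        }
    )
    control_code_map: dict[str, str | None] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_CODE_MAP)
    )

    def validate(self) -> None:
        if self.followup_days < 1:
            raise ConfigurationError("followup_days must be >= 1")
        if self.bridging not in ("any_prior_era", "overlapping_era"):
            raise ConfigurationError(f"unknown bridging rule {self.bridging!r}")


@dataclass
class MatchingConfig:
    """1:M comparator sampling constraints."""

    ratio: int = 3
    age_tolerance_years: int = 1
    #: 'decile' matches on equal decile of the pool contact-volume
    #: distribution; 'caliper' on |difference| <= contact_caliper;
    #: 'none' drops the contact constraint.
    contact_binning: str = "decile"
    contact_caliper: float | None = None

    def validate(self) -> None:
        if self.ratio < 1:
            raise ConfigurationError("matching ratio must be >= 1")
        if self.contact_binning not in ("decile", "caliper", "none"):
            raise ConfigurationError(f"unknown contact_binning {self.contact_binning!r}")
        if self.contact_binning == "caliper" and (
            self.contact_caliper is None or self.contact_caliper < 0
        ):
            raise ConfigurationError("contact_caliper must be a non-negative number")


@dataclass
class CovariateConfig:
    """Baseline covariate derivation: codelists and MCS binning."""

    codelists: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CODELISTS.items()}
    )
    mcs_cutpoints: tuple[float, ...] = DEFAULT_MCS_CUTPOINTS
    lookback_days: int = 730

    def validate(self) -> None:
        for name, spec in self.codelists.items():
            for key in ("table", "column", "codes"):
                if key not in spec:
                    raise ConfigurationError(f"codelist {name!r} is missing {key!r}")


@dataclass
class AnalysisConfig:
    """Which outcomes, adjustments and strata the estimation stage runs."""

    main_outcome: str = "pdc_high_75"
    sensitivity_outcomes: tuple[str, ...] = ("pdc_high_70", "pdc_high_75", "pdc_high_80")
    control_outcomes: tuple[str, ...] = ("controls_high_4", "controls_high_3")
    adjustment_covariates: tuple[str, ...] = ()
    strata_variables: tuple[str, ...] = ("diagnosis_category", "gender", "age_class", "mcs_category")
    #: strata tested for trend (with ordinal scores) rather than homogeneity
    trend_strata: tuple[str, ...] = ("age_class", "mcs_category")
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """Single configuration object driving an end-to-end run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    era: EraConfig = field(default_factory=EraConfig)
    adherence: AdherenceConfig = field(default_factory=AdherenceConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    drug_classes: tuple[str, ...] = DRUG_CLASSES

    def validate(self) -> None:
        self.scenario.validate()
        self.era.validate()
        self.adherence.validate()
        self.matching.validate()
        self.covariates.validate()
        for cls in self.drug_classes:
            if cls not in DRUG_CLASSES:
                raise ConfigurationError(f"unknown drug class {cls!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["scenario"]["index_date"] = self.scenario.index_date.isoformat()
        return d

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in manifests."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        def build(klass, key):
            section = dict(raw.get(key, {}))
            if key == "scenario" and "index_date" in section and isinstance(
                section["index_date"], str
            ):
                section["index_date"] = dt.date.fromisoformat(section["index_date"])
            # YAML has no tuple type; coerce list-valued fields back
            obj = klass(**section)
            return obj

        cfg = cls(
            scenario=build(ScenarioConfig, "scenario"),
            era=build(EraConfig, "era"),
            adherence=build(AdherenceConfig, "adherence"),
            matching=build(MatchingConfig, "matching"),
            covariates=build(CovariateConfig, "covariates"),
            analysis=build(AnalysisConfig, "analysis"),
            drug_classes=tuple(raw.get("drug_classes", DRUG_CLASSES)),
        )
        cfg.validate()
        return cfg
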