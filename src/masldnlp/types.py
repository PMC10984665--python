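"""Domain types for pathology-report annotation and cohort analysis.

All character spans are 0-based, half-open intervals into NFKC-normalized
text. Booleans follow the scoring rubric's omission rule: a feature never
mentioned is recorded as absent, not missing.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date


class Concept(str, enum.Enum):
    """Histology concepts recognized by the bundled lexicon."""

    STEATOSIS = "steatosis"
    LOBULAR_INFLAMMATION = "lobular_inflammation"
    PORTAL_INFLAMMATION = "portal_inflammation"
    BALLOONING = "ballooning"
    STEATOHEPATITIS = "steatohepatitis"
    CIRRHOSIS = "cirrhosis"
    FIBROSIS_GENERIC = "fibrosis_generic"
    PERISINUSOIDAL_FIBROSIS = "perisinusoidal_fibrosis"
    PERIPORTAL_FIBROSIS = "periportal_fibrosis"
    BRIDGING_FIBROSIS = "bridging_fibrosis"
    NODULARITY = "nodularity"
    COINCIDENT_DISEASE = "coincident_disease"


class Assertion(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    NON_LIVER_ORGAN = "non_liver_organ"
    FINE_NEEDLE_ASPIRATION = "fine_needle_aspiration"
    TUMOR_BIOPSY = "tumor_biopsy"
    NO_LIVER_MENTION = "no_liver_mention"


class Stage(str, enum.Enum):
    """MASH CRN fibrosis stage, or unstaged when no CRN-scale evidence exists."""

    F0 = "F0"
    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    F4 = "F4"
    UNSTAGED = "unstaged"

    @property
    def number(self) -> int | None:
        return None if self is Stage.UNSTAGED else int(self.value[1])

    @classmethod
    def from_number(cls, n: int) -> "Stage":
        return cls(f"F{n}")


class StageSource(str, enum.Enum):
    EXPLICIT = "explicit"
    COMPONENTS = "components"
    NEGATION = "negation"
    OMISSION = "omission"


class Category(str, enum.Enum):
    """Report-level MASLD category used for cohort strata."""

    NO_STEATOSIS = "no_steatosis"
    SIMPLE_STEATOSIS = "simple_steatosis"
    MASH_F0 = "mash_f0"
    MASH_F1 = "mash_f1"
    MASH_F2 = "mash_f2"
    MASH_F3 = "mash_f3"
    CIRRHOSIS_F4 = "cirrhosis_f4"


class Borderline(str, enum.Enum):
    NONE = "none"
    BALLOONING_ONLY = "ballooning_only"
    INFLAMMATION_ONLY = "inflammation_only"


@dataclass(frozen=True)
class RawPathologyReport:
    """One free-text pathology report as received from the record system."""

    report_id: str
    patient_id: str
    report_date: date | str
    hospital: str
    text: str

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.text:
            raise ValueError(f"report {self.report_id}: text must be non-empty")


@dataclass(frozen=True)
class RemovedSpan:
    label: str  # header | footer | gross
    start: int
    end: int


@dataclass
class DiagnosticSection:
    """The findings/impression text left after boilerplate stripping."""

    report_id: str
    diagnostic_text: str
    removed_spans: list[RemovedSpan] = field(default_factory=list)
    empty_diagnostic: bool = False


@dataclass(frozen=True)
class BiopsyScreenResult:
    report_id: str
    is_parenchymal_liver_biopsy: bool
    exclusion_reason: ExclusionReason

    def __post_init__(self) -> None:
        ok = self.is_parenchymal_liver_biopsy == (
            self.exclusion_reason is ExclusionReason.NONE
        )
        if not ok:
            raise ValueError("screen decision inconsistent with exclusion_reason")


@dataclass
class ConceptMention:
    """A lexicon match with its span and present/absent assertion."""

    concept_id: Concept
    surface_text: str
    start: int
    end: int
    sentence_index: int
    assertion: Assertion | None = None
    disease_name: str | None = None  # set only for coincident-disease mentions


@dataclass
class HistologyFeatureSet:
    """Report-level core MASLD features (omission coded as False)."""

    report_id: str
    steatosis: bool = False
    lobular_inflammation: bool = False
    ballooning: bool = False
    mash_asserted: bool = False
    cirrhosis_asserted: bool = False
    conflict_flags: set[Concept] = field(default_factory=set)
    coincident_diseases: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ExplicitStageMention:
    stage: int
    denominator: int | None  # 4, 6, or None when unstated
    start: int
    end: int


@dataclass
class FibrosisAssessment:
    report_id: str
    explicit_stages: list[ExplicitStageMention] = field(default_factory=list)
    perisinusoidal_zone3: bool = False
    zone1_periportal: bool = False
    bridging: bool = False
    nodularity: bool = False
    fibrosis_negated: bool = False
    resolved_stage: Stage = Stage.UNSTAGED
    stage_source: StageSource = StageSource.OMISSION
    scale_mismatch: bool = False
    malformed_stage: bool = False


@dataclass
class MASLDLabel:
    report_id: str
    category: Category
    borderline: Borderline = Borderline.NONE
    mash: bool = False
    fibrosis_stage: Stage = Stage.UNSTAGED
    audit_notes: list[str] = field(default_factory=list)
    excluded_borderline: bool = False


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for one concept against gold labels."""

    concept: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PerformanceRow:
    """Sensitivity/specificity/PPV/NPV/F1 (percent) plus gold-positive support.

    A metric with a zero denominator is ``None`` (not applicable), never 0.
    """

    concept: str
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    support: int
    n: int


@dataclass(frozen=True)
class FollowUpRecord:
    patient_id: str
    exposure_category: str
    time_years: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError("time_years must be non-negative")


@dataclass(frozen=True)
class IncidenceEstimate:
    events: int
    person_years: float
    rate_per_1000: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RateDifference:
    diff_per_1000: float
    ci_low: float
    ci_high: float
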