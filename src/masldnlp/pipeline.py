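"""End-to-end report annotation: strip, screen, extract, stage, classify."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import classify, extract, fibrosis, histology, ingest
from .config import (
    BoilerplateRules,
    ClassificationPolicy,
    DEFAULT_POLICY,
    LexiconEntry,
    NegationRules,
    ScreenLexicon,
)
from .types import (
    BiopsyScreenResult,
    ConceptMention,
    DiagnosticSection,
    FibrosisAssessment,
    HistologyFeatureSet,
    MASLDLabel,
    RawPathologyReport,
    Stage,
)

CONCEPT_COLUMNS = [
    "steatosis",
    "lobular_inflammation",
    "ballooning",
    "steatohepatitis",
    "cirrhosis",
    "F0",
    "F1",
    "F2",
    "F3",
    "F4",
]


@dataclass
class AnnotationResult:
    """Everything the pipeline derived for one report."""

    report_id: str
    section: DiagnosticSection
    screen: BiopsyScreenResult
    mentions: list[ConceptMention] = field(default_factory=list)
    features: HistologyFeatureSet | None = None
    fibrosis: FibrosisAssessment | None = None
    label: MASLDLabel | None = None

    @property
    def screened_in(self) -> bool:
        return self.screen.is_parenchymal_liver_biopsy


class Annotator:
    """Configurable annotation pipeline over the rule files.

    Any component's rules can be replaced at construction; ``recognizer``
    accepts an external concept-recognition callable (text -> asserted
    mentions) in place of the bundled lexicon matcher.
    """

    def __init__(
        self,
        lexicon: list[LexiconEntry] | None = None,
        negation_rules: NegationRules | None = None,
        boilerplate_rules: BoilerplateRules | None = None,
        screen_lexicon: ScreenLexicon | None = None,
        exclusion_lexicon: dict[str, tuple[str, ...]] | None = None,
        policy: ClassificationPolicy = DEFAULT_POLICY,
        recognizer: extract.Recognizer | None = None,
    ):
        self.lexicon = lexicon
        self.negation_rules = negation_rules
        self.boilerplate_rules = boilerplate_rules
        self.screen_lexicon = screen_lexicon
        self.exclusion_lexicon = exclusion_lexicon
        self.policy = policy
        self.recognizer = recognizer

    def annotate(self, report: RawPathologyReport) -> AnnotationResult:
        section = ingest.strip_report_boilerplate(report, self.boilerplate_rules)
        screen = ingest.screen_parenchymal_biopsy(section, self.screen_lexicon)
        result = AnnotationResult(report.report_id, section, screen)
        if not screen.is_parenchymal_liver_biopsy or section.empty_diagnostic:
            return result

        text = section.diagnostic_text
        sentences = extract.segment_sentences(text)
        if self.recognizer is not None:
            mentions = self.recognizer(text)
        else:
            mentions = extract.match_lexicon_mentions(text, sentences, self.lexicon)
            extract.assign_assertions(mentions, sentences, text, self.negation_rules)
        result.mentions = mentions

        features = histology.derive_feature_set(mentions, report.report_id)
        disease_mentions = extract.match_disease_mentions(
            text, self.exclusion_lexicon, self.negation_rules
        )
        features.coincident_diseases = histology.detect_coincident_disease(
            disease_mentions
        )
        result.features = features

        result.fibrosis = fibrosis.assess_fibrosis(
            text, mentions, sentences, report.report_id, features.cirrhosis_asserted
        )
        result.label = classify.classify_report(features, result.fibrosis, self.policy)
        return result

    def annotate_corpus(
        self, reports: list[RawPathologyReport]
    ) -> list[AnnotationResult]:
        return [self.annotate(r) for r in reports]


def results_to_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    """One row per report: screen decision, the validated concept booleans
    (fibrosis stages one-vs-rest), stage, category, and audit columns."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "report_id": r.report_id,
            "screened_in": r.screened_in,
            "exclusion_reason": r.screen.exclusion_reason.value,
        }
        if r.features is not None and r.fibrosis is not None and r.label is not None:
            stage = r.label.fibrosis_stage
            row.update(
                steatosis=r.features.steatosis,
                lobular_inflammation=r.features.lobular_inflammation,
                ballooning=r.features.ballooning,
                steatohepatitis=r.features.mash_asserted,
                cirrhosis=r.features.cirrhosis_asserted or stage is Stage.F4,
                **{
                    f"F{k}": stage is not Stage.UNSTAGED and stage.number == k
                    for k in range(5)
                },
            )
            row.update(
                fibrosis_stage=stage.value,
                stage_source=r.fibrosis.stage_source.value,
                scale_mismatch=r.fibrosis.scale_mismatch,
                category=r.label.category.value,
                borderline=r.label.borderline.value,
                mash=r.label.mash,
                coincident_diseases=";".join(sorted(r.features.coincident_diseases)),
                audit_notes="; ".join(r.label.audit_notes),
            )
        else:
            for c in CONCEPT_COLUMNS:
                row[c] = False
            row.update(
                fibrosis_stage="",
                stage_source="",
                scale_mismatch=False,
                category="",
                borderline="",
                mash=False,
                coincident_diseases="",
                audit_notes="",
            )
        rows.append(row)
    return pd.DataFrame(rows)
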