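"""Report-level histology features under the MASLD scoring rubric.

Four core features are collapsed from mention-level assertions: steatosis,
lobular inflammation, ballooning, and a summative steatohepatitis (MASH)
assertion; cirrhosis assertion is carried alongside. Rubric rules:

* any pathologist assertion of presence scores the feature present, and
  omissions are recorded as absent;
* when one report both affirms and negates the same concept the report
  scores present, with a conflict flag (pathologists often negate a
  feature in the findings then affirm it focally in the impression);
* portal inflammation and its synonyms never count as lobular
  inflammation, while zone-3/centrilobular inflammation does.
"""
from __future__ import annotations

from .types import Assertion, Concept, ConceptMention, HistologyFeatureSet

_CORE = {
    Concept.STEATOSIS: "steatosis",
    Concept.LOBULAR_INFLAMMATION: "lobular_inflammation",
    Concept.BALLOONING: "ballooning",
    Concept.STEATOHEPATITIS: "mash_asserted",
    Concept.CIRRHOSIS: "cirrhosis_asserted",
}


def derive_feature_set(
    mentions: list[ConceptMention], report_id: str
) -> HistologyFeatureSet:
    """Collapse asserted mentions into the report-level feature booleans.

    A feature is true iff at least one present-asserted mention of its
    concept exists; present-vs-absent conflicts resolve to present with a
    conflict flag. Portal-inflammation mentions never set lobular
    inflammation (zone-3 surface forms are lexicalized directly as lobular
    inflammation, so no remapping happens here).
    """
    features = HistologyFeatureSet(report_id=report_id)
    present: set[Concept] = set()
    absent: set[Concept] = set()
    for m in mentions:
        if m.assertion is None:
            raise ValueError("mentions must have assertions assigned")
        (present if m.assertion is Assertion.PRESENT else absent).add(m.concept_id)
    for concept, attr in _CORE.items():
        setattr(features, attr, concept in present)
        if concept in present and concept in absent:
            features.conflict_flags.add(concept)
    return features


def detect_coincident_disease(mentions: list[ConceptMention]) -> set[str]:
    """Present-asserted coincident diseases named in the report text.

    Operates on disease mentions from the exclusion lexicon (see
    :func:`masldnlp.extract.match_disease_mentions`); negated diseases are
    dropped.
    """
    return {
        m.disease_name
        for m in mentions
        if m.concept_id is Concept.COINCIDENT_DISEASE
        and m.assertion is Assertion.PRESENT
        and m.disease_name
    }
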