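"""Sentence segmentation, lexicon matching, and negation scoping."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masldnlp import (
    Assertion,
    Concept,
    extract_mentions,
    match_lexicon_mentions,
    segment_sentences,
)
from masldnlp.config import LexiconError, load_lexicon


class TestSegmentation:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Steatosis. No ballooning.", ["Steatosis.", "No ballooning."]),
            (
                "1. Steatohepatitis, stage 2.\n2. No malignancy.",
                ["1. Steatohepatitis, stage 2.", "2. No malignancy."],
            ),
            ("no terminal punctuation", ["no terminal punctuation"]),
            ("Fibrosis stage: 1/4; no bridging.", ["Fibrosis stage: 1/4;", "no bridging."]),
        ],
    )
    def test_examples(self, text, expected):
        spans = segment_sentences(text)
        assert [text[a:b] for a, b in spans] == expected

    def test_spans_are_ordered_nonoverlapping_and_cover_nonwhitespace(self):
        text = "1. Steatosis, 30%.\n2. Mild lobular inflammation.\nNo ballooning. "
        spans = segment_sentences(text)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 <= a2
        covered = set()
        for a, b in spans:
            covered.update(range(a, b))
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered


class TestLexiconMatching:
    def test_canonical_synonym_maps_to_concept(self):
        mentions = match_lexicon_mentions("macrovesicular steatosis")
        assert [m.concept_id for m in mentions] == [Concept.STEATOSIS]

    def test_longest_match_wins_one_concept_per_span(self):
        mentions = match_lexicon_mentions("steatohepatitis")
        assert [m.concept_id for m in mentions] == [Concept.STEATOHEPATITIS]

    def test_coordinated_heads_yield_both_concepts(self):
        mentions = match_lexicon_mentions("portal and lobular inflammation")
        concepts = {m.concept_id for m in mentions}
        assert concepts == {Concept.PORTAL_INFLAMMATION, Concept.LOBULAR_INFLAMMATION}

    def test_surface_text_equals_text_at_span(self):
        text = "Marked Macrovesicular Steatosis with zone 3 inflammation."
        for m in match_lexicon_mentions(text):
            assert text[m.start : m.end] == m.surface_text

    def test_word_boundaries_prevent_substring_hits(self):
        # "hepatitis" inside "steatohepatitis" must not surface separately
        mentions = match_lexicon_mentions("early steatohepatitis noted")
        assert len(mentions) == 1

    def test_duplicate_surface_form_rejected_at_load(self, tmp_path):
        bad = tmp_path / "lex.yaml"
        bad.write_text("steatosis:\n  - steatosis\nballooning:\n  - steatosis\n")
        with pytest.raises(LexiconError):
            load_lexicon(bad)


class TestNegation:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("No ballooning is seen.", [(Concept.BALLOONING, Assertion.ABSENT)]),
            ("Minimal steatosis.", [(Concept.STEATOSIS, Assertion.PRESENT)]),
            ("Patchy steatosis is noted.", [(Concept.STEATOSIS, Assertion.PRESENT)]),
            ("Borderline steatohepatitis.", [(Concept.STEATOHEPATITIS, Assertion.PRESENT)]),
            ("Ballooning is not identified.", [(Concept.BALLOONING, Assertion.ABSENT)]),
            ("Hepatocellular ballooning is absent.", [(Concept.BALLOONING, Assertion.ABSENT)]),
            ("Negative for steatosis.", [(Concept.STEATOSIS, Assertion.ABSENT)]),
        ],
    )
    def test_trigger_examples(self, text, expected):
        mentions = extract_mentions(text)
        assert [(m.concept_id, m.assertion) for m in mentions] == expected

    def test_scope_terminates_at_but(self):
        text = "Steatosis without ballooning, but lobular inflammation is present."
        got = {m.concept_id: m.assertion for m in extract_mentions(text)}
        assert got == {
            Concept.STEATOSIS: Assertion.PRESENT,
            Concept.BALLOONING: Assertion.ABSENT,
            Concept.LOBULAR_INFLAMMATION: Assertion.PRESENT,
        }

    def test_negation_chain_spans_commas(self):
        text = "No steatosis, ballooning, or lobular inflammation is identified."
        assertions = {m.assertion for m in extract_mentions(text)}
        assert assertions == {Assertion.ABSENT}

    def test_negation_does_not_cross_sentences(self):
        text = "No ballooning is seen. Steatosis is present."
        got = {m.concept_id: m.assertion for m in extract_mentions(text)}
        assert got[Concept.STEATOSIS] is Assertion.PRESENT
        assert got[Concept.BALLOONING] is Assertion.ABSENT


_POSITIVE_PHRASES = [
    ("macrovesicular steatosis", Concept.STEATOSIS),
    ("lobular inflammation", Concept.LOBULAR_INFLAMMATION),
    ("hepatocyte ballooning", Concept.BALLOONING),
    ("steatohepatitis", Concept.STEATOHEPATITIS),
    ("bridging fibrosis", Concept.BRIDGING_FIBROSIS),
    ("cirrhosis", Concept.CIRRHOSIS),
    ("perisinusoidal fibrosis", Concept.PERISINUSOIDAL_FIBROSIS),
]


@settings(derandomize=True, max_examples=60)
@given(
    idx=st.integers(min_value=0, max_value=len(_POSITIVE_PHRASES) - 1),
    other=st.integers(min_value=0, max_value=len(_POSITIVE_PHRASES) - 1),
)
def test_negation_wrap_flips_only_the_wrapped_mention(idx, other):
    """Wrapping a canonical phrase as "No <phrase>." flips that mention's
    assertion and leaves a co-occurring positive sentence untouched."""
    phrase, concept = _POSITIVE_PHRASES[idx]
    other_phrase, other_concept = _POSITIVE_PHRASES[other]
    if other_concept == concept:
        return
    text = f"No {phrase}. {other_phrase.capitalize()} is present."
    got = {m.concept_id: m.assertion for m in extract_mentions(text)}
    assert got[concept] is Assertion.ABSENT
    assert got[other_concept] is Assertion.PRESENT


def test_extraction_is_a_pure_function_of_text(canonical_corpus, annotator):
    reports, _ = canonical_corpus
    sample = [r for r in reports if "Liver," in r.text][:25]
    for r in sample:
        a = annotator.annotate(r)
        b = annotator.annotate(r)
        assert [(m.concept_id, m.start, m.end, m.assertion) for m in a.mentions] == [
            (m.concept_id, m.start, m.end, m.assertion) for m in b.mentions
        ]
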