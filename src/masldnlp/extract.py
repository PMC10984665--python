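"""Concept extraction: sentence segmentation, lexicon matching, negation.

The recognizer is a curated-lexicon matcher: surface forms are matched
case-insensitively with word boundaries on NFKC-normalized text, and the
longest match wins among overlapping candidates. Assertions are assigned by
trigger-based negation scoping in the NegEx style: a pre-trigger ("no",
"without", "negative for") negates forward to the nearest scope terminator
("but", "however", ";", "."), a post-trigger ("not identified", "is
absent") negates backward; scoping never crosses a sentence boundary.
Diminutive qualifiers ("minimal", "patchy", "borderline") never negate —
under the scoring rubric they count as presence.

An external concept-recognition engine can be plugged in by supplying any
callable with the :data:`Recognizer` signature to the pipeline; the
downstream rubric logic operates on (concept, assertion) pairs regardless
of recognizer.
"""
from __future__ import annotations

import re
import unicodedata
from typing import Callable, Sequence

from .config import (
    LexiconEntry,
    NegationRules,
    load_exclusion_lexicon,
    load_lexicon,
    load_negation_rules,
    normalize,
)
from .types import Assertion, Concept, ConceptMention

#: signature for a pluggable recognizer: diagnostic text -> asserted mentions
Recognizer = Callable[[str], "list[ConceptMention]"]

# heads whose coordinated modifiers are expanded ("portal and lobular
# inflammation" yields both a portal and a lobular mention)
_COORD_HEADS = ("inflammation", "fibrosis")


def segment_sentences(diagnostic_text: str) -> list[tuple[int, int]]:
    """Split diagnostic text into ordered, non-overlapping sentence spans.

    Sentences end at '.', ';', '!', '?' or a newline. A period after a
    bare list-item number at the start of a sentence ("1.", "2)") and a
    period inside a decimal number do not terminate. Spans are trimmed to
    non-whitespace and jointly cover all non-whitespace text.
    """
    spans: list[tuple[int, int]] = []
    text = diagnostic_text
    n = len(text)
    start = 0
    i = 0

    def emit(lo: int, hi: int) -> None:
        seg = text[lo:hi]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((lo + lead, hi - trail))

    while i < n:
        c = text[i]
        terminal = False
        if c in ";!?\n":
            terminal = True
        elif c == ".":
            prev = text[i - 1] if i > 0 else ""
            nxt = text[i + 1] if i + 1 < n else ""
            if prev.isdigit() and nxt.isdigit():
                pass  # decimal number
            elif prev.isdigit() and text[start:i].strip().isdigit():
                pass  # bare enumerator at item start
            else:
                terminal = True
        if terminal:
            emit(start, i + 1)
            start = i + 1
        i += 1
    emit(start, n)
    return spans


def _form_pattern(form: str) -> re.Pattern[str]:
    return re.compile(rf"(?<!\w){re.escape(form)}(?!\w)")


class _CompiledLexicon:
    def __init__(self, entries: Sequence[LexiconEntry]):
        self.patterns: list[tuple[re.Pattern[str], Concept, str]] = []
        self.form_to_concept: dict[str, Concept] = {}
        for entry in entries:
            for form in entry.surface_forms:
                self.patterns.append((_form_pattern(form), entry.concept_id, form))
                self.form_to_concept[form] = entry.concept_id


def _compile(entries: Sequence[LexiconEntry]) -> _CompiledLexicon:
    return _CompiledLexicon(entries)


def _resolve_overlaps(cands: list[ConceptMention]) -> list[ConceptMention]:
    """Longest-match-wins among overlapping candidates; ties to the earlier."""
    kept: list[ConceptMention] = []
    for m in sorted(cands, key=lambda m: (-(m.end - m.start), m.start)):
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def _coordination_candidates(
    lowered: str, lex: _CompiledLexicon
) -> list[tuple[int, int, Concept, str]]:
    """Expand "X and Y <head>" so each conjunct is matched against the
    lexicon as "<conjunct> <head>"; spans cover only the conjunct word."""
    out = []
    head_re = re.compile(
        r"((?:\w[\w-]*)(?:\s*(?:,|and|or|/)\s*\w[\w-]*)+)\s+(%s)\b"
        % "|".join(_COORD_HEADS)
    )
    word_re = re.compile(r"\w[\w-]*")
    for m in head_re.finditer(lowered):
        head = m.group(2)
        for w in word_re.finditer(m.group(1)):
            token = w.group(0)
            if token in ("and", "or"):
                continue
            concept = lex.form_to_concept.get(f"{token} {head}")
            if concept is not None:
                out.append((m.start(1) + w.start(), m.start(1) + w.end(), concept, token))
    return out


def match_lexicon_mentions(
    diagnostic_text: str,
    sentences: list[tuple[int, int]] | None = None,
    lexicon: Sequence[LexiconEntry] | None = None,
) -> list[ConceptMention]:
    """Find histology-concept mentions; assertions are left unset."""
    if sentences is None:
        sentences = segment_sentences(diagnostic_text)
    if lexicon is None:
        lexicon = load_lexicon()
    lex = _compile(lexicon)
    text = unicodedata.normalize("NFKC", diagnostic_text)
    mentions: list[ConceptMention] = []
    for s_idx, (s_lo, s_hi) in enumerate(sentences):
        sent = text[s_lo:s_hi]
        lowered = sent.casefold()
        cands: list[ConceptMention] = []
        for pat, concept, _form in lex.patterns:
            for m in pat.finditer(lowered):
                cands.append(
                    ConceptMention(
                        concept_id=concept,
                        surface_text=sent[m.start() : m.end()],
                        start=s_lo + m.start(),
                        end=s_lo + m.end(),
                        sentence_index=s_idx,
                    )
                )
        coord = _coordination_candidates(lowered, lex)
        existing = {(c.start, c.end) for c in cands}
        for lo, hi, concept, _tok in coord:
            if (s_lo + lo, s_lo + hi) not in existing:
                cands.append(
                    ConceptMention(
                        concept_id=concept,
                        surface_text=sent[lo:hi],
                        start=s_lo + lo,
                        end=s_lo + hi,
                        sentence_index=s_idx,
                    )
                )
        mentions.extend(_resolve_overlaps(cands))
    mentions.sort(key=lambda m: m.start)
    return mentions


# ---------------------------------------------------------------------------
# negation scoping


def _find_occurrences(lowered: str, phrases: Sequence[str]) -> list[tuple[int, int]]:
    occ = []
    for p in phrases:
        if p.isalnum() or " " in p or "-" in p:
            pat = _form_pattern(p)
        else:
            pat = re.compile(re.escape(p))
        occ.extend((m.start(), m.end()) for m in pat.finditer(lowered))
    return sorted(occ)


def _negated_ranges(lowered: str, rules: NegationRules) -> list[tuple[int, int]]:
    terms = _find_occurrences(lowered, rules.scope_terminators)
    ranges: list[tuple[int, int]] = []
    for ts, te in _find_occurrences(lowered, rules.pre_triggers):
        stop = len(lowered)
        for t_lo, _t_hi in terms:
            if t_lo >= te:
                stop = t_lo
                break
        ranges.append((te, stop))
    for ts, te in _find_occurrences(lowered, rules.post_triggers):
        begin = 0
        for _t_lo, t_hi in reversed(terms):
            if t_hi <= ts:
                begin = t_hi
                break
        ranges.append((begin, ts))
    return ranges


def assign_assertions(
    mentions: list[ConceptMention],
    sentences: list[tuple[int, int]],
    diagnostic_text: str,
    negation_rules: NegationRules | None = None,
) -> list[ConceptMention]:
    """Set each mention's assertion by trigger-based negation scoping.

    A mention is absent iff its span intersects the scope of a negation
    trigger within its own sentence; otherwise present. Mentions are
    mutated in place and returned.
    """
    if negation_rules is None:
        negation_rules = load_negation_rules()
    text = unicodedata.normalize("NFKC", diagnostic_text)
    scopes_by_sentence: dict[int, list[tuple[int, int]]] = {}
    for m in mentions:
        s_idx = m.sentence_index
        if s_idx not in scopes_by_sentence:
            s_lo, s_hi = sentences[s_idx]
            scopes_by_sentence[s_idx] = _negated_ranges(
                text[s_lo:s_hi].casefold(), negation_rules
            )
        s_lo, _ = sentences[s_idx]
        rel_lo, rel_hi = m.start - s_lo, m.end - s_lo
        negated = any(
            rel_lo < hi and rel_hi > lo for lo, hi in scopes_by_sentence[s_idx]
        )
        m.assertion = Assertion.ABSENT if negated else Assertion.PRESENT
    return mentions


def extract_mentions(
    diagnostic_text: str,
    lexicon: Sequence[LexiconEntry] | None = None,
    negation_rules: NegationRules | None = None,
) -> list[ConceptMention]:
    """Segment, match, and assert in one call (the default recognizer)."""
    sentences = segment_sentences(diagnostic_text)
    mentions = match_lexicon_mentions(diagnostic_text, sentences, lexicon)
    return assign_assertions(mentions, sentences, diagnostic_text, negation_rules)


def match_disease_mentions(
    diagnostic_text: str,
    exclusion_lexicon: dict[str, tuple[str, ...]] | None = None,
    negation_rules: NegationRules | None = None,
) -> list[ConceptMention]:
    """Find coincident-disease mentions with assertions assigned."""
    if exclusion_lexicon is None:
        exclusion_lexicon = load_exclusion_lexicon()
    entries = [
        LexiconEntry(Concept.COINCIDENT_DISEASE, forms)
        for forms in exclusion_lexicon.values()
    ]
    form_to_disease = {
        form: disease
        for disease, forms in exclusion_lexicon.items()
        for form in forms
    }
    sentences = segment_sentences(diagnostic_text)
    mentions = match_lexicon_mentions(diagnostic_text, sentences, entries)
    for m in mentions:
        m.disease_name = form_to_disease.get(normalize(m.surface_text))
    return assign_assertions(mentions, sentences, diagnostic_text, negation_rules)
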