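"""MASH CRN fibrosis staging from explicit statements and components.

Staging follows the CRN system: perisinusoidal/pericellular fibrosis in
zone 3 is stage 1, zone-3 plus zone-1 (periportal) fibrosis is stage 2,
bridging fibrosis is stage 3, and nodule formation (cirrhosis) is stage 4.
Explicit pathologist stage statements take priority as evidence, but the
resolved stage is always the highest over all contributing evidence — a
range like "F1-F2" resolves to F2, and "F2 with focal areas of bridging"
resolves to F3.

Ishak-style "of 6" stages are never silently remapped onto the CRN scale:
with no other evidence they yield ``unstaged`` with a scale-mismatch flag,
and staging falls back to components when those are present.
"""
from __future__ import annotations

import re

from .types import (
    Assertion,
    Concept,
    ConceptMention,
    ExplicitStageMention,
    FibrosisAssessment,
    Stage,
    StageSource,
)

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5, "vi": 6}

# "stage 3 of 4", "stage: F1-F2", "fibrosis stage iv", "stage 2/6" ...
_STAGE_RE = re.compile(
    r"""\bstage\s*[:=]?\s*
        (?:f\s*)?(?P<a>\d+|iv|i{1,3}|vi?)
        (?:\s*(?:-|–|—|to|through)\s*(?:f\s*)?(?P<b>\d+|iv|i{1,3}|vi?))?
        (?:\s*(?:of|/|out\s+of)\s*(?P<d>\d+))?""",
    re.IGNORECASE | re.VERBOSE,
)
# bare "F2", "F1-F2" (no "stage" keyword)
_F_RE = re.compile(
    r"\bf\s?(?P<a>[0-6])(?:\s*(?:-|–|—|to)\s*f?\s?(?P<b>[0-6]))?(?:\s*(?:of|/)\s*(?P<d>\d+))?\b",
    re.IGNORECASE,
)
# "fibrosis 3/4", "fibrosis: 2 of 6"
_FIB_FRAC_RE = re.compile(
    r"\bfibrosis\s*[,:]?\s*(?P<a>\d)\s*(?:/|of)\s*(?P<d>\d)\b", re.IGNORECASE
)

_COMPONENT_ATTR = {
    Concept.PERISINUSOIDAL_FIBROSIS: "perisinusoidal_zone3",
    Concept.PERIPORTAL_FIBROSIS: "zone1_periportal",
    Concept.BRIDGING_FIBROSIS: "bridging",
    Concept.NODULARITY: "nodularity",
}

_FIBROSIS_FAMILY = set(_COMPONENT_ATTR) | {Concept.FIBROSIS_GENERIC}


def _to_int(token: str) -> int | None:
    token = token.lower()
    if token.isdigit():
        return int(token)
    return _ROMAN.get(token)


def parse_explicit_stages(
    sentences_text: list[str], offsets: list[int] | None = None
) -> tuple[list[ExplicitStageMention], bool]:
    """Find explicit fibrosis-stage statements in sentence texts.

    Recognizes "stage N", "stage N of M", "N/M" after a fibrosis cue,
    bare "F N", and ranges "N-M"/"N to M" (both bounds recorded), with
    Arabic or Roman numerals; the denominator is recorded when stated.
    Returns the mentions plus a flag set when a malformed stage token
    (outside 0–6) was seen and ignored.
    """
    if offsets is None:
        offsets = [0] * len(sentences_text)
    out: list[ExplicitStageMention] = []
    malformed = False

    def add(a: int | None, denom: int | None, lo: int, hi: int) -> None:
        nonlocal malformed
        if a is None or not (0 <= a <= 6):
            malformed = True
            return
        out.append(ExplicitStageMention(a, denom, lo, hi))

    for text, base in zip(sentences_text, offsets):
        spans_taken: list[tuple[int, int]] = []
        for pat in (_STAGE_RE, _FIB_FRAC_RE, _F_RE):
            for m in pat.finditer(text):
                if any(m.start() < hi and m.end() > lo for lo, hi in spans_taken):
                    continue
                spans_taken.append((m.start(), m.end()))
                denom_s = m.groupdict().get("d")
                denom = int(denom_s) if denom_s else None
                if denom not in (None, 4, 6):
                    denom = None
                lo, hi = base + m.start(), base + m.end()
                add(_to_int(m.group("a")), denom, lo, hi)
                b = m.groupdict().get("b")
                if b:
                    add(_to_int(b), denom, lo, hi)
    return out, malformed


def detect_fibrosis_components(
    mentions: list[ConceptMention],
) -> tuple[dict[str, bool], bool]:
    """Component flags from present-asserted fibrosis-pattern mentions.

    Negated components never set flags. ``fibrosis_negated`` is true iff
    some fibrosis-family concept is absent-asserted while none is
    present-asserted.
    """
    flags = {attr: False for attr in _COMPONENT_ATTR.values()}
    any_absent = False
    any_present = False
    for m in mentions:
        if m.concept_id not in _FIBROSIS_FAMILY:
            continue
        if m.assertion is Assertion.PRESENT:
            any_present = True
            attr = _COMPONENT_ATTR.get(m.concept_id)
            if attr:
                flags[attr] = True
        elif m.assertion is Assertion.ABSENT:
            any_absent = True
    fibrosis_negated = any_absent and not any_present
    return flags, fibrosis_negated


def resolve_fibrosis_stage(
    report_id: str,
    explicit_stages: list[ExplicitStageMention],
    components: dict[str, bool],
    fibrosis_negated: bool,
    cirrhosis_asserted: bool = False,
    malformed_stage: bool = False,
) -> FibrosisAssessment:
    """Resolve the report's CRN stage as the maximum over all evidence.

    Candidates: in-scale explicit stages (denominator 4 or unstated, value
    ≤ 4); component-mapped stages (perisinusoidal→1, perisinusoidal+zone1→2,
    zone-1 alone→1 as a conservative F1-equivalent, bridging→3,
    nodularity→4); and 4 when cirrhosis is asserted. With no candidates the
    report is F0 when fibrosis was negated (source ``negation``) or never
    mentioned (source ``omission``); an out-of-scale explicit stage alone
    yields ``unstaged`` with a scale-mismatch flag.
    """
    a = FibrosisAssessment(
        report_id=report_id,
        explicit_stages=list(explicit_stages),
        fibrosis_negated=fibrosis_negated,
        malformed_stage=malformed_stage,
        **components,
    )

    explicit_candidates: list[int] = []
    off_scale = False
    for es in explicit_stages:
        if es.denominator == 6 or es.stage > 4:
            off_scale = True
        else:
            explicit_candidates.append(es.stage)
    a.scale_mismatch = off_scale

    component_candidates: list[int] = []
    if a.perisinusoidal_zone3 and a.zone1_periportal:
        component_candidates.append(2)
    elif a.perisinusoidal_zone3 or a.zone1_periportal:
        component_candidates.append(1)
    if a.bridging:
        component_candidates.append(3)
    if a.nodularity:
        component_candidates.append(4)
    if cirrhosis_asserted:
        component_candidates.append(4)

    candidates = explicit_candidates + component_candidates
    if candidates:
        best = max(candidates)
        a.resolved_stage = Stage.from_number(best)
        a.stage_source = (
            StageSource.EXPLICIT
            if explicit_candidates and max(explicit_candidates) == best
            else StageSource.COMPONENTS
        )
    elif off_scale:
        a.resolved_stage = Stage.UNSTAGED
        a.stage_source = StageSource.EXPLICIT
    elif fibrosis_negated:
        a.resolved_stage = Stage.F0
        a.stage_source = StageSource.NEGATION
    else:
        a.resolved_stage = Stage.F0
        a.stage_source = StageSource.OMISSION
    return a


def assess_fibrosis(
    diagnostic_text: str,
    mentions: list[ConceptMention],
    sentences: list[tuple[int, int]],
    report_id: str,
    cirrhosis_asserted: bool = False,
) -> FibrosisAssessment:
    """End-to-end fibrosis assessment for one report."""
    texts = [diagnostic_text[lo:hi] for lo, hi in sentences]
    offsets = [lo for lo, _ in sentences]
    explicit, malformed = parse_explicit_stages(texts, offsets)
    components, negated = detect_fibrosis_components(mentions)
    return resolve_fibrosis_stage(
        report_id, explicit, components, negated, cirrhosis_asserted, malformed
    )
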