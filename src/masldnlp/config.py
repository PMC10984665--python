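"""Loading and validation of the YAML rule files.

All rule content (lexicon surface forms, negation triggers, boilerplate
heading markers, screening term lists, coincident-disease synonyms) is data,
not code: every loader accepts an optional path so users can override the
bundled defaults with their own site-specific files.
"""
from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .types import Concept


class LexiconError(ValueError):
    """Raised when a lexicon or rule file violates its invariants."""


def normalize(text: str) -> str:
    """NFKC-normalize and casefold; the canonical form for all matching."""
    return unicodedata.normalize("NFKC", text).casefold()


def _load_yaml(name: str, path: str | Path | None):
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    ref = resources.files("masldnlp.resources").joinpath(name)
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: Concept
    surface_forms: tuple[str, ...]


def load_lexicon(path: str | Path | None = None) -> list[LexiconEntry]:
    """Load the concept lexicon and enforce its invariants.

    Raises :class:`LexiconError` if a concept has no surface forms or a
    surface form is claimed by two concepts.
    """
    raw = _load_yaml("lexicon.yaml", path)
    entries: list[LexiconEntry] = []
    seen: dict[str, str] = {}
    for concept_name, forms in raw.items():
        if not forms:
            raise LexiconError(f"concept {concept_name!r} has no surface forms")
        normed = tuple(normalize(f) for f in forms)
        for form in normed:
            if form in seen and seen[form] != concept_name:
                raise LexiconError(
                    f"surface form {form!r} maps to both "
                    f"{seen[form]!r} and {concept_name!r}"
                )
            seen[form] = concept_name
        entries.append(LexiconEntry(Concept(concept_name), normed))
    return entries


@dataclass(frozen=True)
class NegationRules:
    pre_triggers: tuple[str, ...]
    post_triggers: tuple[str, ...]
    scope_terminators: tuple[str, ...]
    diminutives: tuple[str, ...]


def load_negation_rules(path: str | Path | None = None) -> NegationRules:
    raw = _load_yaml("negation.yaml", path)
    return NegationRules(
        pre_triggers=tuple(normalize(t) for t in raw["pre_triggers"]),
        post_triggers=tuple(normalize(t) for t in raw["post_triggers"]),
        scope_terminators=tuple(normalize(t) for t in raw["scope_terminators"]),
        diminutives=tuple(normalize(t) for t in raw.get("diminutives", [])),
    )


@dataclass(frozen=True)
class BoilerplateRules:
    diagnosis_headings: tuple[str, ...]
    header_headings: tuple[str, ...]
    footer_headings: tuple[str, ...]
    gross_headings: tuple[str, ...]


def load_boilerplate_rules(path: str | Path | None = None) -> BoilerplateRules:
    raw = _load_yaml("boilerplate.yaml", path)
    return BoilerplateRules(
        diagnosis_headings=tuple(normalize(h) for h in raw["diagnosis_headings"]),
        header_headings=tuple(normalize(h) for h in raw["header_headings"]),
        footer_headings=tuple(normalize(h) for h in raw["footer_headings"]),
        gross_headings=tuple(normalize(h) for h in raw.get("gross_headings", [])),
    )


@dataclass(frozen=True)
class ScreenLexicon:
    liver_terms: tuple[str, ...]
    non_liver_specimens: tuple[str, ...]
    fna_phrases: tuple[str, ...]
    tumor_phrases: tuple[str, ...]


def load_screen_lexicon(path: str | Path | None = None) -> ScreenLexicon:
    raw = _load_yaml("screening.yaml", path)
    return ScreenLexicon(
        liver_terms=tuple(normalize(t) for t in raw["liver_terms"]),
        non_liver_specimens=tuple(normalize(t) for t in raw["non_liver_specimens"]),
        fna_phrases=tuple(normalize(t) for t in raw["fna_phrases"]),
        tumor_phrases=tuple(normalize(t) for t in raw["tumor_phrases"]),
    )


def load_exclusion_lexicon(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    """Coincident-disease lexicon: disease name -> normalized surface forms."""
    raw = _load_yaml("exclusions.yaml", path)
    out: dict[str, tuple[str, ...]] = {}
    seen: dict[str, str] = {}
    for disease, forms in raw.items():
        if not forms:
            raise LexiconError(f"disease {disease!r} has no surface forms")
        normed = tuple(normalize(f) for f in forms)
        for form in normed:
            if form in seen and seen[form] != disease:
                raise LexiconError(
                    f"surface form {form!r} maps to both "
                    f"{seen[form]!r} and {disease!r}"
                )
            seen[form] = disease
        out[disease] = normed
    return out


@dataclass(frozen=True)
class ClassificationPolicy:
    """Switches for the genuinely policy-level classification choices.

    supersede_requires_feature
        When True (default), fibrosis stage F1–F3 promotes a steatotic
        report to MASH only when at least one of lobular inflammation,
        ballooning, or a steatohepatitis assertion accompanies it; bland
        fibrotic steatosis stays simple steatosis with an audit note.
        When False, any F1–F3 stage promotes.
    unstaged_mash_stage
        Stage assigned to a MASH report whose fibrosis could not be staged
        (default F0, by the omission-scored-absent principle).
    borderline_assertion_sets_mash
        Whether "borderline steatohepatitis" sets the MASH assertion
        (default True: diminutives are scored as present).
    """

    supersede_requires_feature: bool = True
    unstaged_mash_stage: str = "F0"
    borderline_assertion_sets_mash: bool = True


DEFAULT_POLICY = ClassificationPolicy()
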