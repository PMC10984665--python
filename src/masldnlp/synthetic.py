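"""Synthetic labeled pathology-report corpora.

Real liver-biopsy report corpora carry protected health information and
cannot be redistributed, so this module generates benchmark corpora with
gold labels: report structure (accession headers, clinical context, gross
description, diagnosis body, sign-out footer), era-dependent style
(descriptive fibrosis prose before the 2005 CRN staging rubric, explicit
stage notation after), negation phrasings, diminutives, stage ranges, and
contaminant report types (non-liver organs mentioning liver, fine-needle
aspirations, hepatic tumor biopsies).

Gold labels are generated first and text second — never the reverse — so
gold is independent of the extractor and round-trip validation is not
circular. Output is deterministic: the same spec and seed yield
byte-identical corpora.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .types import Category, RawPathologyReport, Stage

CONTAMINANTS = ("non_liver_organ", "fine_needle_aspiration", "tumor_biopsy")

#: default category mix: MASLD strata dominate, with a contaminant fraction
#: so screening is exercised (proportions sum to 1)
DEFAULT_MIX = {
    "simple_steatosis": 0.14,
    "mash_f0": 0.14,
    "mash_f1": 0.14,
    "mash_f2": 0.14,
    "mash_f3": 0.14,
    "cirrhosis_f4": 0.14,
    "no_steatosis": 0.06,
    "non_liver_organ": 0.04,
    "fine_needle_aspiration": 0.03,
    "tumor_biopsy": 0.03,
}

HOSPITALS = ["General Hospital", "Community Hospital", "University Medical Center"]

PATHOLOGISTS = ["A. Morgan", "J. Rivera", "L. Chen", "P. Okafor", "S. Novak"]


class GenerationError(ValueError):
    """Raised for unreachable label combinations or infeasible specs."""


@dataclass(frozen=True)
class GenerationSpec:
    """Study conditions for a synthetic corpus.

    ``category_mix`` gives proportions over MASLD categories plus
    contaminant types; ``era_mix`` splits reports between pre-2005
    descriptive style and post-2005 CRN stage notation; ``adversarial_rate``
    is the fraction of liver reports drawn from hard templates (stage
    ranges, negation chains, diminutives, scope breaks);
    ``negation_realization_rate`` is the probability that an absent core
    feature is written out as an explicit negation sentence rather than
    omitted. ``min_positives_per_concept`` mirrors a validation design
    requiring at least 100 gold-positive examples of each scored concept.
    """

    n_reports: int = 900
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    era_mix: dict[str, float] = field(
        default_factory=lambda: {"pre_2005": 0.35, "post_2005": 0.65}
    )
    adversarial_rate: float = 0.25
    negation_realization_rate: float = 0.5
    min_positives_per_concept: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("category_mix", self.category_mix), ("era_mix", self.era_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise GenerationError(f"{name} proportions sum to {total}, not 1")
        if self.n_reports <= 0:
            raise GenerationError("n_reports must be positive")


@dataclass
class GoldLabel:
    """Ground truth for one synthetic report, fixed before text is written."""

    report_id: str
    category: str  # Category value or a contaminant type
    contaminant: str | None
    era: str
    adversarial: bool
    steatosis: bool = False
    lobular_inflammation: bool = False
    ballooning: bool = False
    steatohepatitis: bool = False
    cirrhosis: bool = False
    stage: int | None = None  # CRN stage 0-4; None for contaminants
    coincident_diseases: tuple[str, ...] = ()
    diag_start: int = 0
    diag_end: int = 0
    mention_assertions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def stage_onehot(self) -> dict[str, bool]:
        return {f"F{k}": self.stage == k for k in range(5)}


@dataclass(frozen=True)
class FeatureCombo:
    """One cell of the classification truth table."""

    steatosis: bool
    lobular_inflammation: bool
    ballooning: bool
    mash_asserted: bool
    stage: int  # 0-4

    @property
    def category(self) -> Category:
        """Reference categorization under the default policy (hand rule)."""
        if not self.steatosis:
            return Category.NO_STEATOSIS
        if self.stage == 4:
            return Category.CIRRHOSIS_F4
        mash = self.mash_asserted or (
            self.lobular_inflammation and self.ballooning
        )
        if not mash and self.stage in (1, 2, 3):
            mash = self.lobular_inflammation or self.ballooning
        if mash:
            return Category(f"mash_f{self.stage}")
        return Category.SIMPLE_STEATOSIS


def reachable_combos() -> list[FeatureCombo]:
    """The full truth table over the four feature booleans and five stages."""
    out = []
    for st in (False, True):
        for lob in (False, True):
            for ball in (False, True):
                for asserted in (False, True):
                    for stage in range(5):
                        if not st and (lob or ball or asserted):
                            # non-steatotic liver with MASH features is not a
                            # reachable MASLD gold label; keep the table clean
                            continue
                        out.append(FeatureCombo(st, lob, ball, asserted, stage))
    return out


# ---------------------------------------------------------------------------
# text realization


def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


_STEATOSIS_POS = [
    "Moderate macrovesicular steatosis involving approximately 40% of the parenchyma.",
    "Marked macrovesicular and microvesicular steatosis.",
    "Hepatic steatosis is present.",
    "Diffuse fatty change of the liver parenchyma.",
]
_STEATOSIS_POS_ADV = [
    "Minimal patchy steatosis.",
    "Mild macrovesicular steatosis, zone 3 predominant.",
    "Focal steatosis is noted.",
]
_STEATOSIS_NEG = [
    "No steatosis is identified.",
    "Negative for steatosis.",
    "Steatosis is not seen.",
]
_LOB_POS = [
    "Lobular inflammation is present.",
    "Scattered foci of lobular inflammation.",
    "Mild lobular inflammation with occasional acidophil bodies.",
]
_LOB_POS_ADV = [
    "Zone 3 inflammation is identified.",
    "Focal centrilobular inflammation.",
    "Portal and lobular inflammation are present.",
]
_LOB_NEG = [
    "No lobular inflammation is seen.",
    "Lobular inflammation is not identified.",
]
_BALL_POS = [
    "Hepatocyte ballooning is present.",
    "Ballooning degeneration of hepatocytes is identified.",
    "Scattered ballooned hepatocytes are noted.",
]
_BALL_NEG = [
    "No ballooning is seen.",
    "Ballooning is not identified.",
    "Hepatocellular ballooning is absent.",
]
_MASH_POS = [
    "The findings are consistent with steatohepatitis.",
    "Steatohepatitis, active.",
    "Features diagnostic of steatohepatitis.",
]
_MASH_POS_ADV = [
    "Borderline steatohepatitis.",
    "Findings suggestive of early steatohepatitis.",
]
_CIRRHOSIS_POS = [
    "Established cirrhosis.",
    "Cirrhosis with regenerative nodules.",
    "Micronodular cirrhosis.",
]
_DISTRACTORS = [
    "No malignancy is identified.",
    "Mild portal inflammation.",
    "Iron stain is negative.",
    "Adequate core biopsy with intact architecture.",
    "Trichrome and reticulin stains were reviewed.",
]
_COINCIDENT = [
    ("hepatitis C", "The findings are compatible with chronic hepatitis C."),
]

# fibrosis realizations by (era, stage) -> list of sentence templates
_FIBROSIS_POST = {
    0: ["Fibrosis stage 0 of 4.", "Fibrosis stage: 0/4.", "Stage F0."],
    1: ["Fibrosis stage 1 of 4.", "Fibrosis stage: 1/4.", "Stage F1."],
    2: ["Fibrosis stage 2 of 4.", "Fibrosis stage: 2/4.", "Stage F2."],
    3: ["Fibrosis stage 3 of 4.", "Fibrosis stage: 3/4.", "Stage F3."],
    4: [
        "Fibrosis stage 4 of 4, consistent with cirrhosis.",
        "Stage F4, established cirrhosis.",
    ],
}
_FIBROSIS_POST_ADV = {
    2: ["Fibrosis stage F1-F2.", "Fibrosis stage 1 to 2 of 4."],
    3: [
        "Fibrosis stage 2 of 4 with focal areas of bridging.",
        "Fibrosis stage F2-F3.",
        "Fibrosis stage 3 of 6. Bridging fibrosis is present.",
    ],
}
_FIBROSIS_PRE = {
    0: ["No fibrosis is identified.", "Fibrosis is absent."],
    1: [
        "Delicate pericellular fibrosis in zone 3.",
        "Perisinusoidal fibrosis is present.",
        "Zone 3 pericellular fibrosis is noted.",
    ],
    2: [
        "Perisinusoidal and periportal fibrosis is present.",
        "Pericellular fibrosis in zone 3 with portal fibrosis.",
    ],
    3: [
        "Bridging fibrosis is identified.",
        "Early bridging fibrosis is present.",
    ],
    4: [
        "Cirrhosis with nodular architecture.",
        "Established cirrhosis with regenerative nodules.",
    ],
}


def _realize_features(combo: FeatureCombo, era: str, adversarial: bool,
                      negation_rate: float, rng: np.random.Generator,
                      ) -> tuple[list[str], list[tuple[str, str]]]:
    """Diagnosis-body sentences plus gold mention assertions for a combo."""
    sentences: list[str] = []
    assertions: list[tuple[str, str]] = []

    def realize(concept: str, present: bool, pos: list[str], neg: list[str]) -> None:
        if present:
            sentences.append(_pick(rng, pos))
            assertions.append((concept, "present"))
        elif neg and rng.random() < negation_rate:
            sentences.append(_pick(rng, neg))
            assertions.append((concept, "absent"))

    st_pos = _STEATOSIS_POS + (_STEATOSIS_POS_ADV if adversarial else [])
    realize("steatosis", combo.steatosis, st_pos, _STEATOSIS_NEG)

    lob_pos = _LOB_POS + (_LOB_POS_ADV if adversarial else [])
    ball_handled = False
    if (
        adversarial
        and combo.steatosis
        and combo.lobular_inflammation
        and not combo.ballooning
        and rng.random() < 0.4
    ):
        # scope-terminator template: negation ends at "but"
        sentences.append(
            "Steatosis without ballooning, but lobular inflammation is present."
        )
        assertions += [
            ("steatosis", "present"),
            ("ballooning", "absent"),
            ("lobular_inflammation", "present"),
        ]
        ball_handled = True
    else:
        realize("lobular_inflammation", combo.lobular_inflammation, lob_pos, _LOB_NEG)

    if not ball_handled:
        realize("ballooning", combo.ballooning, _BALL_POS, _BALL_NEG)

    mash_pos = _MASH_POS + (_MASH_POS_ADV if adversarial else [])
    # a false assertion is realized by omission only: pathologists rarely
    # deny the summative term while listing its components
    realize("steatohepatitis", combo.mash_asserted, mash_pos, [])

    # fibrosis realization
    if combo.stage == 4:
        sentences.append(_pick(rng, _CIRRHOSIS_POS))
        assertions.append(("cirrhosis", "present"))
        if era == "post_2005":
            sentences.append(_pick(rng, _FIBROSIS_POST[4]))
    else:
        omittable = combo.stage == 0
        if not (omittable and rng.random() > negation_rate):
            table = _FIBROSIS_PRE if era == "pre_2005" else _FIBROSIS_POST
            if adversarial and era == "post_2005" and combo.stage in _FIBROSIS_POST_ADV:
                options = _FIBROSIS_POST_ADV[combo.stage]
            else:
                options = table[combo.stage]
            sentences.append(_pick(rng, options))
        if adversarial and combo.stage == 0 and rng.random() < 0.3:
            sentences.append("No bridging fibrosis, cirrhosis, or nodularity is seen.")
            assertions += [
                ("bridging_fibrosis", "absent"),
                ("cirrhosis", "absent"),
                ("nodularity", "absent"),
            ]

    if rng.random() < 0.4:
        sentences.append(_pick(rng, _DISTRACTORS))
    return sentences, assertions


def _boilerplate(
    report_id: str, year: int, hospital: str, rng: np.random.Generator
) -> tuple[str, str]:
    header = (
        f"Accession Number: S-{year}-{int(rng.integers(10000, 99999))}\n"
        f"Patient: {_pick(rng, ['DOE, JANE', 'SMITH, ALEX', 'LEE, CHRIS'])}    "
        f"MRN: {int(rng.integers(1000000, 9999999))}\n"
        f"Clinical Data: {_pick(rng, ['Elevated liver enzymes.', 'Abnormal imaging.', 'Fatty liver on ultrasound.', 'Evaluation of chronic liver disease.'])}\n"
        f"Gross Description: Received in formalin is a "
        f"{_pick(rng, ['tan-brown', 'pale tan', 'red-brown'])} core of tissue measuring "
        f"{rng.integers(8, 25)} mm in length, entirely submitted.\n"
    )
    footer = (
        f"\nElectronically signed out by {_pick(rng, PATHOLOGISTS)}, MD.\n"
        f"Report Electronically Signed Out {year}.\n"
    )
    return header, footer


_SPECIMEN_LINES = [
    "Liver, needle core biopsy:",
    "Liver, percutaneous needle biopsy:",
    "Liver, transjugular biopsy:",
]


def generate_report(
    combo: FeatureCombo | None,
    era: str,
    rng: np.random.Generator,
    report_id: str = "R0",
    contaminant: str | None = None,
    adversarial: bool = False,
    negation_rate: float = 0.5,
    with_coincident: bool = False,
) -> tuple[RawPathologyReport, GoldLabel]:
    """Realize one gold label as a full report with boilerplate.

    Exactly one of ``combo`` (a liver-biopsy truth-table cell) or
    ``contaminant`` must be given.
    """
    if (combo is None) == (contaminant is None):
        raise GenerationError("exactly one of combo or contaminant is required")
    year = int(rng.integers(1990, 2005) if era == "pre_2005" else rng.integers(2005, 2022))
    hospital = _pick(rng, HOSPITALS)
    header, footer = _boilerplate(report_id, year, hospital, rng)

    if contaminant is not None:
        body, label = _contaminant_body(contaminant, rng)
        label.report_id = report_id
        label.era = era
    else:
        sentences, assertions = _realize_features(
            combo, era, adversarial, negation_rate, rng
        )
        coincident: tuple[str, ...] = ()
        if with_coincident:
            disease, sentence = _COINCIDENT[int(rng.integers(len(_COINCIDENT)))]
            sentences.append(sentence)
            coincident = (disease,)
        if era == "post_2005" and rng.random() < 0.6:
            lines = [f"{i + 1}. {s}" for i, s in enumerate(sentences)]
        else:
            lines = sentences
        body = _pick(rng, _SPECIMEN_LINES) + "\n" + "\n".join(lines) + "\n"
        label = GoldLabel(
            report_id=report_id,
            category=combo.category.value,
            contaminant=None,
            era=era,
            adversarial=adversarial,
            steatosis=combo.steatosis,
            lobular_inflammation=combo.lobular_inflammation,
            ballooning=combo.ballooning,
            steatohepatitis=combo.mash_asserted,
            cirrhosis=combo.stage == 4,
            stage=combo.stage,
            coincident_diseases=coincident,
            mention_assertions=assertions,
        )

    heading = _pick(rng, ["Final Diagnosis:", "DIAGNOSIS:", "Pathologic Diagnosis:"])
    text = header + heading + "\n" + body + footer
    diag_start = len(header) + len(heading) + 1
    diag_end = diag_start + len(body)
    label.diag_start = diag_start
    label.diag_end = diag_end
    report = RawPathologyReport(
        report_id=report_id,
        patient_id=f"P{report_id}",
        report_date=f"{year}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}",
        hospital=hospital,
        text=text,
    )
    return report, label


def _contaminant_body(kind: str, rng: np.random.Generator) -> tuple[str, GoldLabel]:
    if kind == "non_liver_organ":
        body = (
            _pick(
                rng,
                [
                    "Colon, biopsy:\nModerately differentiated adenocarcinoma.\n"
                    "Clinical note: hepatic metastases to be excluded.",
                    "Stomach, biopsy:\nChronic gastritis. Clinical history of "
                    "fatty liver disease.",
                    "Skin, biopsy:\nBasal cell carcinoma. Patient with known "
                    "liver disease per chart.",
                ],
            )
            + "\n"
        )
    elif kind == "fine_needle_aspiration":
        body = (
            _pick(
                rng,
                [
                    "Liver, fine needle aspiration:\nScant benign-appearing hepatocytes.",
                    "Liver, fine-needle aspiration:\nAdequate cellularity; no atypia.",
                ],
            )
            + "\n"
        )
    elif kind == "tumor_biopsy":
        body = (
            _pick(
                rng,
                [
                    "Liver, mass, needle core biopsy:\nHepatocellular carcinoma, "
                    "moderately differentiated.",
                    "Liver, mass, needle core biopsy:\nMetastatic adenocarcinoma, "
                    "consistent with colorectal primary.",
                ],
            )
            + "\n"
        )
    else:
        raise GenerationError(f"unknown contaminant kind {kind!r}")
    label = GoldLabel(
        report_id="",
        category=kind,
        contaminant=kind,
        era="",
        adversarial=False,
        stage=None,
    )
    return body, label


# ---------------------------------------------------------------------------
# corpus generation


def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among mix categories."""
    keys = list(mix)
    exact = np.array([mix[k] * n for k in keys])
    counts = np.floor(exact).astype(int)
    remainder = n - int(counts.sum())
    order = np.argsort(-(exact - counts))
    for i in range(remainder):
        counts[order[i % len(keys)]] += 1
    return dict(zip(keys, counts.tolist()))


# feature realizations per MASLD category: (lob, ball, asserted) options
_REALIZATIONS: dict[str, list[tuple[tuple[bool, bool, bool], float]]] = {
    "simple_steatosis": [
        ((False, False, False), 0.8),
        ((False, True, False), 0.1),  # borderline: ballooning only
        ((True, False, False), 0.1),  # borderline: inflammation only
    ],
    "mash_f0": [
        ((True, True, False), 0.3),
        ((True, True, True), 0.3),
        ((False, False, True), 0.2),
        ((True, False, True), 0.1),
        ((False, True, True), 0.1),
    ],
    "mash_f1": [
        ((True, True, False), 0.25),
        ((True, True, True), 0.25),
        ((False, False, True), 0.15),
        ((True, False, False), 0.2),  # supersede: inflammation + stage
        ((False, True, False), 0.15),  # supersede: ballooning + stage
    ],
    "no_steatosis": [((False, False, False), 1.0)],
}
_REALIZATIONS["mash_f2"] = _REALIZATIONS["mash_f1"]
_REALIZATIONS["mash_f3"] = _REALIZATIONS["mash_f1"]
_REALIZATIONS["cirrhosis_f4"] = [
    ((False, False, False), 0.3),
    ((True, True, True), 0.25),
    ((True, True, False), 0.2),
    ((True, False, False), 0.15),
    ((False, True, False), 0.1),
]

_CATEGORY_STAGE = {
    "simple_steatosis": 0,
    "mash_f0": 0,
    "mash_f1": 1,
    "mash_f2": 2,
    "mash_f3": 3,
    "cirrhosis_f4": 4,
    "no_steatosis": 0,
}

GOLD_COLUMNS = [
    "report_id",
    "category",
    "contaminant",
    "era",
    "adversarial",
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
    "fibrosis_stage",
    "coincident_diseases",
    "diag_start",
    "diag_end",
]


def _draw_combo(category: str, rng: np.random.Generator) -> FeatureCombo:
    stage = _CATEGORY_STAGE[category]
    options = _REALIZATIONS[category]
    weights = np.array([w for _, w in options])
    idx = int(rng.choice(len(options), p=weights / weights.sum()))
    lob, ball, asserted = options[idx][0]
    combo = FeatureCombo(
        steatosis=category != "no_steatosis",
        lobular_inflammation=lob,
        ballooning=ball,
        mash_asserted=asserted,
        stage=stage,
    )
    if combo.category.value != category:
        raise GenerationError(
            f"realization {combo} does not reproduce category {category}"
        )
    return combo


def generate_corpus(
    spec: GenerationSpec,
) -> tuple[list[RawPathologyReport], pd.DataFrame]:
    """Generate a corpus and its gold-label frame from a spec.

    Realized category counts match the requested mix up to integer
    rounding. Raises :class:`GenerationError` when the corpus cannot meet
    ``min_positives_per_concept``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _apportion(spec.n_reports, spec.category_mix)
    eras = list(spec.era_mix)
    era_p = np.array([spec.era_mix[e] for e in eras])

    reports: list[RawPathologyReport] = []
    gold_rows: list[dict] = []
    idx = 0
    for category in sorted(counts):
        for _ in range(counts[category]):
            report_id = f"SYN{idx:05d}"
            idx += 1
            era = eras[int(rng.choice(len(eras), p=era_p))]
            if category in CONTAMINANTS:
                report, label = generate_report(
                    None, era, rng, report_id, contaminant=category
                )
            else:
                adversarial = bool(rng.random() < spec.adversarial_rate)
                combo = _draw_combo(category, rng)
                report, label = generate_report(
                    combo,
                    era,
                    rng,
                    report_id,
                    adversarial=adversarial,
                    negation_rate=spec.negation_realization_rate,
                    with_coincident=bool(
                        category != "no_steatosis" and rng.random() < 0.05
                    ),
                )
            reports.append(report)
            gold_rows.append(_gold_row(label))

    gold = pd.DataFrame(gold_rows, columns=GOLD_COLUMNS)
    if spec.min_positives_per_concept > 0:
        concept_cols = [
            "steatosis", "lobular_inflammation", "ballooning",
            "steatohepatitis", "cirrhosis", "F0", "F1", "F2", "F3", "F4",
        ]
        short = {
            c: int(gold[c].sum())
            for c in concept_cols
            if int(gold[c].sum()) < spec.min_positives_per_concept
        }
        if short:
            raise GenerationError(
                f"corpus of n={spec.n_reports} cannot supply "
                f"{spec.min_positives_per_concept} positives per concept; "
                f"short: {short}"
            )
    return reports, gold


def _gold_row(label: GoldLabel) -> dict:
    row = {
        "report_id": label.report_id,
        "category": label.category,
        "contaminant": label.contaminant or "",
        "era": label.era,
        "adversarial": label.adversarial,
        "steatosis": label.steatosis,
        "lobular_inflammation": label.lobular_inflammation,
        "ballooning": label.ballooning,
        "steatohepatitis": label.steatohepatitis,
        "cirrhosis": label.cirrhosis,
        "fibrosis_stage": "" if label.stage is None else f"F{label.stage}",
        "coincident_diseases": ";".join(label.coincident_diseases),
        "diag_start": label.diag_start,
        "diag_end": label.diag_end,
    }
    for k in range(5):
        row[f"F{k}"] = label.stage == k
    return row


def write_corpus(
    spec: GenerationSpec,
    corpus_path,
    gold_path,
    spec_path=None,
) -> tuple[list[RawPathologyReport], pd.DataFrame]:
    """Generate and write corpus.jsonl + gold.csv (+ spec.yaml record)."""
    from .ingest import write_reports_jsonl

    reports, gold = generate_corpus(spec)
    write_reports_jsonl(reports, corpus_path)
    gold.to_csv(gold_path, index=False)
    if spec_path is not None:
        record = {
            "n_reports": spec.n_reports,
            "category_mix": spec.category_mix,
            "era_mix": spec.era_mix,
            "adversarial_rate": spec.adversarial_rate,
            "negation_realization_rate": spec.negation_realization_rate,
            "min_positives_per_concept": spec.min_positives_per_concept,
            "seed": spec.seed,
        }
        with open(spec_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(record, fh, sort_keys=False)
    return reports, gold
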