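"""Report-level MASLD categorization for cohort strata.

A report is categorized as one of: no steatosis, simple steatosis,
MASH/F0–F3, or cirrhosis (F4). MASH is positive when the pathologist
asserts steatohepatitis, or when all three elements (steatosis, lobular
inflammation, ballooning) are present; in addition, CRN fibrosis staging
supersedes the strict three-element requirement — a steatotic biopsy with
lobular inflammation and stage F2 is MASH/F2 despite absent ballooning.
Under the default policy the supersede rule still requires at least one
MASH co-feature (inflammation, ballooning, or an assertion); promoting
bland fibrotic steatosis is available behind a policy switch.

Borderline reports — steatosis with exactly one of ballooning or lobular
inflammation and nothing else making them MASH — are excluded from the
primary cohort strata and recategorized only in the sensitivity analysis
(ballooning-only becomes MASH/F0, inflammation-only stays simple
steatosis).
"""
from __future__ import annotations

from dataclasses import replace

from .config import DEFAULT_POLICY, ClassificationPolicy
from .types import (
    Borderline,
    Category,
    FibrosisAssessment,
    HistologyFeatureSet,
    MASLDLabel,
    Stage,
)

_MASH_CATEGORY = {
    Stage.F0: Category.MASH_F0,
    Stage.F1: Category.MASH_F1,
    Stage.F2: Category.MASH_F2,
    Stage.F3: Category.MASH_F3,
}


def classify_report(
    features: HistologyFeatureSet,
    fibrosis: FibrosisAssessment,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> MASLDLabel:
    """Combine histology features and fibrosis stage into a MASLD label."""
    stage = fibrosis.resolved_stage
    notes: list[str] = []

    if features.cirrhosis_asserted and stage is not Stage.F4:
        # staging invariant: cirrhosis assertion forces F4
        stage = Stage.F4
        notes.append("cirrhosis assertion forced stage F4")

    if not features.steatosis:
        return MASLDLabel(
            report_id=features.report_id,
            category=Category.NO_STEATOSIS,
            fibrosis_stage=stage,
            audit_notes=notes,
        )

    if stage is Stage.F4:
        return MASLDLabel(
            report_id=features.report_id,
            category=Category.CIRRHOSIS_F4,
            mash=features.mash_asserted
            or (features.lobular_inflammation and features.ballooning),
            fibrosis_stage=Stage.F4,
            audit_notes=notes,
        )

    lob = features.lobular_inflammation
    ball = features.ballooning
    asserted = features.mash_asserted
    mash = asserted or (lob and ball)
    if not mash and stage in (Stage.F1, Stage.F2, Stage.F3):
        if lob or ball or asserted:
            mash = True
            notes.append("stage-supersedes rule promoted report to MASH")
        elif not policy.supersede_requires_feature:
            mash = True
            notes.append(
                "stage-supersedes rule promoted bland fibrotic steatosis (policy)"
            )
        else:
            notes.append(
                "steatosis with fibrosis but no MASH co-feature kept as simple steatosis"
            )

    if mash:
        if stage is Stage.UNSTAGED:
            stage = Stage(policy.unstaged_mash_stage)
            notes.append("unstaged fibrosis defaulted per policy")
        return MASLDLabel(
            report_id=features.report_id,
            category=_MASH_CATEGORY[stage],
            mash=True,
            fibrosis_stage=stage,
            audit_notes=notes,
        )

    if ball and not lob:
        borderline = Borderline.BALLOONING_ONLY
    elif lob and not ball:
        borderline = Borderline.INFLAMMATION_ONLY
    else:
        borderline = Borderline.NONE
    return MASLDLabel(
        report_id=features.report_id,
        category=Category.SIMPLE_STEATOSIS,
        borderline=borderline,
        fibrosis_stage=stage,
        audit_notes=notes,
    )


def apply_borderline_policy(label: MASLDLabel, mode: str = "primary") -> MASLDLabel:
    """Apply the cohort's borderline-MASH policy.

    ``primary``: borderline reports are flagged for exclusion from the
    cohort strata. ``sensitivity``: ballooning-only becomes MASH/F0 and
    inflammation-only is kept as simple steatosis.
    """
    if mode not in ("primary", "sensitivity"):
        raise ValueError(f"unknown borderline mode {mode!r}")
    if label.borderline is Borderline.NONE:
        return label
    if mode == "primary":
        return replace(label, excluded_borderline=True)
    if label.borderline is Borderline.BALLOONING_ONLY:
        return replace(
            label,
            category=Category.MASH_F0,
            mash=True,
            fibrosis_stage=Stage.F0,
            borderline=Borderline.NONE,
            audit_notes=label.audit_notes
            + ["sensitivity analysis recategorized ballooning-only as MASH/F0"],
        )
    return replace(
        label,
        category=Category.SIMPLE_STEATOSIS,
        audit_notes=label.audit_notes
        + ["sensitivity analysis kept inflammation-only as simple steatosis"],
    )
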