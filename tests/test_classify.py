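"""MASLD categorization: truth table, supersede rule, borderline policy."""
import itertools

import pytest

from masldnlp import Borderline, Category, ClassificationPolicy, Stage
from masldnlp.classify import apply_borderline_policy, classify_report
from masldnlp.types import FibrosisAssessment, HistologyFeatureSet


def _inputs(steatosis, lob, ball, asserted, stage, cirrhosis=False):
    features = HistologyFeatureSet(
        report_id="r1",
        steatosis=steatosis,
        lobular_inflammation=lob,
        ballooning=ball,
        mash_asserted=asserted,
        cirrhosis_asserted=cirrhosis,
    )
    fib = FibrosisAssessment(report_id="r1", resolved_stage=stage)
    return features, fib


def _oracle(steatosis, lob, ball, asserted, stage_num):
    """Hand-written reference categorization (default policy).

    Written as a plain decision list, independently of the implementation:
    no steatosis -> no_steatosis; F4 -> cirrhosis; assertion or the full
    triad -> MASH at the stage; F1-F3 with exactly one inflammatory/
    ballooning feature -> MASH at the stage (stage supersedes the triad);
    otherwise simple steatosis.
    """
    if not steatosis:
        return Category.NO_STEATOSIS
    if stage_num == 4:
        return Category.CIRRHOSIS_F4
    if asserted or (lob and ball):
        return Category(f"mash_f{stage_num}")
    if stage_num in (1, 2, 3) and (lob or ball):
        return Category(f"mash_f{stage_num}")
    return Category.SIMPLE_STEATOSIS


class TestTruthTable:
    @pytest.mark.parametrize(
        "steatosis, lob, ball, asserted, stage_num",
        list(
            itertools.product(
                [False, True], [False, True], [False, True], [False, True], range(5)
            )
        ),
    )
    def test_category_matches_hand_oracle(self, steatosis, lob, ball, asserted, stage_num):
        features, fib = _inputs(
            steatosis, lob, ball, asserted, Stage.from_number(stage_num)
        )
        label = classify_report(features, fib)
        assert label.category is _oracle(steatosis, lob, ball, asserted, stage_num)

    def test_no_report_is_both_borderline_and_mash(self):
        for combo in itertools.product([False, True], repeat=4):
            for stage_num in range(5):
                features, fib = _inputs(*combo, Stage.from_number(stage_num))
                label = classify_report(features, fib)
                if label.mash:
                    assert label.borderline is Borderline.NONE


class TestWorkedExamples:
    def test_stage_supersedes_missing_ballooning(self):
        features, fib = _inputs(True, True, False, False, Stage.F2)
        assert classify_report(features, fib).category is Category.MASH_F2

    def test_full_triad_without_assertion_is_mash_f0(self):
        features, fib = _inputs(True, True, True, False, Stage.F0)
        assert classify_report(features, fib).category is Category.MASH_F0

    def test_steatosis_alone_is_simple_steatosis(self):
        features, fib = _inputs(True, False, False, False, Stage.F0)
        label = classify_report(features, fib)
        assert label.category is Category.SIMPLE_STEATOSIS
        assert label.borderline is Borderline.NONE

    def test_ballooning_only_is_borderline(self):
        features, fib = _inputs(True, False, True, False, Stage.F0)
        label = classify_report(features, fib)
        assert label.category is Category.SIMPLE_STEATOSIS
        assert label.borderline is Borderline.BALLOONING_ONLY

    def test_inflammation_only_is_borderline(self):
        features, fib = _inputs(True, True, False, False, Stage.F0)
        label = classify_report(features, fib)
        assert label.borderline is Borderline.INFLAMMATION_ONLY


class TestPolicies:
    def test_bland_fibrotic_steatosis_stays_simple_by_default(self):
        features, fib = _inputs(True, False, False, False, Stage.F2)
        label = classify_report(features, fib)
        assert label.category is Category.SIMPLE_STEATOSIS
        assert label.audit_notes

    def test_policy_switch_promotes_bland_fibrotic_steatosis(self):
        policy = ClassificationPolicy(supersede_requires_feature=False)
        features, fib = _inputs(True, False, False, False, Stage.F2)
        assert classify_report(features, fib, policy).category is Category.MASH_F2

    def test_unstaged_mash_defaults_to_f0_with_audit_note(self):
        features, fib = _inputs(True, True, True, False, Stage.UNSTAGED)
        label = classify_report(features, fib)
        assert label.category is Category.MASH_F0
        assert any("unstaged" in n for n in label.audit_notes)

    def test_cirrhosis_assertion_forces_f4_category(self):
        features, fib = _inputs(True, False, False, False, Stage.F2, cirrhosis=True)
        assert classify_report(features, fib).category is Category.CIRRHOSIS_F4


class TestBorderlinePolicy:
    def _borderline(self, kind):
        if kind == "ball":
            features, fib = _inputs(True, False, True, False, Stage.F0)
        else:
            features, fib = _inputs(True, True, False, False, Stage.F0)
        return classify_report(features, fib)

    def test_primary_mode_flags_for_exclusion(self):
        label = apply_borderline_policy(self._borderline("ball"), "primary")
        assert label.excluded_borderline

    def test_sensitivity_recategorizes_ballooning_only_as_mash_f0(self):
        label = apply_borderline_policy(self._borderline("ball"), "sensitivity")
        assert label.category is Category.MASH_F0
        assert label.mash

    def test_sensitivity_keeps_inflammation_only_as_simple_steatosis(self):
        label = apply_borderline_policy(self._borderline("infl"), "sensitivity")
        assert label.category is Category.SIMPLE_STEATOSIS
        assert not label.mash

    def test_non_borderline_labels_pass_through_unchanged(self):
        features, fib = _inputs(True, True, True, False, Stage.F1)
        label = classify_report(features, fib)
        assert apply_borderline_policy(label, "primary") == label
        assert apply_borderline_policy(label, "sensitivity") == label
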