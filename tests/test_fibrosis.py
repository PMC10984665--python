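"""Explicit stage parsing, component detection, and CRN stage resolution."""
import pytest

from masldnlp import (
    detect_fibrosis_components,
    parse_explicit_stages,
    resolve_fibrosis_stage,
)
from masldnlp.extract import extract_mentions
from masldnlp.types import ExplicitStageMention, Stage, StageSource

NO_COMPONENTS = {
    "perisinusoidal_zone3": False,
    "zone1_periportal": False,
    "bridging": False,
    "nodularity": False,
}


def _components(**kw):
    return {**NO_COMPONENTS, **kw}


class TestExplicitStageParsing:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("fibrosis stage 3 of 4", [(3, 4)]),
            ("stage F1-F2", [(1, None), (2, None)]),
            ("stage 0", [(0, None)]),
            ("fibrosis stage: 2/4", [(2, 4)]),
            ("stage 1 to 2 of 4", [(1, 4), (2, 4)]),
            ("stage iv", [(4, None)]),
            ("stage ii-iii", [(2, None), (3, None)]),
            ("fibrosis 3/6", [(3, 6)]),
            ("F2", [(2, None)]),
            ("F1-F2", [(1, None), (2, None)]),
        ],
    )
    def test_patterns(self, text, expected):
        stages, malformed = parse_explicit_stages([text])
        assert [(s.stage, s.denominator) for s in stages] == expected
        assert not malformed

    def test_out_of_range_stage_is_flagged_and_ignored(self):
        stages, malformed = parse_explicit_stages(["stage 9"])
        assert stages == [] and malformed


class TestComponentDetection:
    def test_present_components_set_flags(self):
        mentions = extract_mentions(
            "Perisinusoidal fibrosis is present. Bridging fibrosis is identified."
        )
        flags, negated = detect_fibrosis_components(mentions)
        assert flags["perisinusoidal_zone3"] and flags["bridging"]
        assert not negated

    def test_negated_component_does_not_set_flag(self):
        mentions = extract_mentions("No bridging fibrosis is seen.")
        flags, negated = detect_fibrosis_components(mentions)
        assert not flags["bridging"]
        assert negated

    def test_cirrhosis_template_sets_nodularity(self):
        mentions = extract_mentions("Established cirrhosis with nodular architecture.")
        flags, _ = detect_fibrosis_components(mentions)
        assert flags["nodularity"]

    def test_fibrosis_negated_requires_no_present_evidence(self):
        mentions = extract_mentions(
            "No fibrosis in zone 1, but perisinusoidal fibrosis is present."
        )
        flags, negated = detect_fibrosis_components(mentions)
        assert flags["perisinusoidal_zone3"]
        assert not negated


class TestStageResolution:
    @pytest.mark.parametrize(
        "components, expected",
        [
            (_components(perisinusoidal_zone3=True), Stage.F1),
            (_components(perisinusoidal_zone3=True, zone1_periportal=True), Stage.F2),
            (_components(bridging=True), Stage.F3),
            (_components(nodularity=True), Stage.F4),
        ],
    )
    def test_component_mapping_reproduces_crn_table(self, components, expected):
        a = resolve_fibrosis_stage("r1", [], components, False)
        assert a.resolved_stage is expected
        assert a.stage_source is StageSource.COMPONENTS

    def test_zone1_alone_maps_conservatively_to_f1(self):
        a = resolve_fibrosis_stage("r1", [], _components(zone1_periportal=True), False)
        assert a.resolved_stage is Stage.F1

    def test_range_resolves_to_upper_bound(self):
        stages = [
            ExplicitStageMention(1, None, 0, 5),
            ExplicitStageMention(2, None, 0, 5),
        ]
        a = resolve_fibrosis_stage("r1", stages, NO_COMPONENTS, False)
        assert a.resolved_stage is Stage.F2

    def test_explicit_stage_plus_bridging_takes_component_maximum(self):
        stages = [ExplicitStageMention(2, 4, 0, 5)]
        a = resolve_fibrosis_stage("r1", stages, _components(bridging=True), False)
        assert a.resolved_stage is Stage.F3

    def test_no_evidence_resolves_f0_by_omission(self):
        a = resolve_fibrosis_stage("r1", [], NO_COMPONENTS, False)
        assert a.resolved_stage is Stage.F0
        assert a.stage_source is StageSource.OMISSION

    def test_negated_fibrosis_resolves_f0_by_negation(self):
        a = resolve_fibrosis_stage("r1", [], NO_COMPONENTS, True)
        assert a.resolved_stage is Stage.F0
        assert a.stage_source is StageSource.NEGATION

    def test_ishak_scale_alone_yields_unstaged_with_flag(self):
        stages = [ExplicitStageMention(3, 6, 0, 5)]
        a = resolve_fibrosis_stage("r1", stages, NO_COMPONENTS, False)
        assert a.resolved_stage is Stage.UNSTAGED
        assert a.scale_mismatch

    def test_ishak_scale_falls_back_to_components(self):
        stages = [ExplicitStageMention(3, 6, 0, 5)]
        a = resolve_fibrosis_stage("r1", stages, _components(bridging=True), False)
        assert a.resolved_stage is Stage.F3
        assert a.scale_mismatch

    def test_cirrhosis_assertion_forces_f4_over_lower_explicit_stage(self):
        stages = [ExplicitStageMention(2, 4, 0, 5)]
        a = resolve_fibrosis_stage(
            "r1", stages, NO_COMPONENTS, False, cirrhosis_asserted=True
        )
        assert a.resolved_stage is Stage.F4

    def test_adding_higher_evidence_never_lowers_the_stage(self):
        base = resolve_fibrosis_stage(
            "r1", [ExplicitStageMention(1, 4, 0, 5)], NO_COMPONENTS, False
        )
        for extra_components, extra_stage in [
            (_components(bridging=True), None),
            (NO_COMPONENTS, ExplicitStageMention(3, 4, 6, 11)),
        ]:
            stages = [ExplicitStageMention(1, 4, 0, 5)]
            if extra_stage:
                stages.append(extra_stage)
            a = resolve_fibrosis_stage("r1", stages, extra_components, False)
            assert a.resolved_stage.number >= base.resolved_stage.number

    def test_adding_lower_evidence_never_raises_the_stage(self):
        base = resolve_fibrosis_stage(
            "r1", [ExplicitStageMention(3, 4, 0, 5)], NO_COMPONENTS, False
        )
        a = resolve_fibrosis_stage(
            "r1",
            [ExplicitStageMention(3, 4, 0, 5), ExplicitStageMention(1, 4, 6, 11)],
            _components(perisinusoidal_zone3=True),
            False,
        )
        assert a.resolved_stage.number == base.resolved_stage.number
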