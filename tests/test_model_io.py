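"""Reading, writing and validating the BPMN/CMMN subsets."""

import pytest
from lxml import etree

from surgflow import model_io
from surgflow.errors import (
    ModelParseError,
    ModelValidationError,
    UnsupportedElementError,
    UnsupportedRuleError,
)
from surgflow.model import NodeKind

BPMN = model_io.BPMN_NS
CMMN = model_io.CMMN_NS

MINIMAL_BPMN = f"""<?xml version="1.0"?>
<definitions xmlns="{BPMN}" targetNamespace="urn:test">
  <process id="p" name="minimal">
    <startEvent id="start"/>
    <userTask id="task_a" name="A"/>
    <endEvent id="end"/>
    <sequenceFlow id="f1" sourceRef="start" targetRef="task_a"/>
    <sequenceFlow id="f2" sourceRef="task_a" targetRef="end"/>
  </process>
</definitions>
"""

MINIMAL_CMMN = f"""<?xml version="1.0"?>
<definitions xmlns="{CMMN}" targetNamespace="urn:test">
  <case id="c" name="minimal">
    <casePlanModel id="c__plan">
      <planItem id="pi__stage_1" definitionRef="stage_1"/>
      <stage id="stage_1" name="S1">
        <planItem id="pi__task_a" definitionRef="task_a">
          <itemControl>
            <requiredRule><condition>true</condition></requiredRule>
            <manualActivationRule><condition>false</condition></manualActivationRule>
          </itemControl>
        </planItem>
        <humanTask id="task_a" name="A"/>
      </stage>
    </casePlanModel>
  </case>
</definitions>
"""


class TestReadBpmn:
    def test_minimal_chain(self, tmp_path):
        path = tmp_path / "m.bpmn"
        path.write_text(MINIMAL_BPMN)
        model = model_io.read_bpmn(path)
        assert len(model.nodes) == 3
        assert len(model.flows) == 2
        assert model.node("task_a").kind is NodeKind.USER_TASK
        assert model.granularity == "one_level"

    def test_dangling_flow_reference(self, tmp_path):
        path = tmp_path / "m.bpmn"
        path.write_text(MINIMAL_BPMN.replace('targetRef="end"',
                                             'targetRef="nowhere"'))
        with pytest.raises(ModelValidationError, match="nowhere"):
            model_io.read_bpmn(path)

    def test_unsupported_element_named(self, tmp_path):
        path = tmp_path / "m.bpmn"
        path.write_text(MINIMAL_BPMN.replace(
            '<userTask id="task_a" name="A"/>',
            '<userTask id="task_a" name="A"/><scriptTask id="s1"/>'))
        with pytest.raises(UnsupportedElementError) as exc:
            model_io.read_bpmn(path)
        assert "scriptTask" in exc.value.elements

    def test_malformed_xml_reports_line(self, tmp_path):
        path = tmp_path / "m.bpmn"
        path.write_text("<definitions><process>")
        with pytest.raises(ModelParseError) as exc:
            model_io.read_bpmn(path)
        assert exc.value.line is not None

    def test_ci_fixture_has_five_phase_containers(self, ci_bundle, tmp_path):
        model_io.write_bpmn(ci_bundle.bpmn, tmp_path / "ci.bpmn")
        model = model_io.read_bpmn(tmp_path / "ci.bpmn")
        subs = [n for n in model.nodes if n.kind is NodeKind.SUB_PROCESS]
        assert len(subs) == 5

    def test_diagram_interchange_ignored(self, tmp_path):
        di = ('<bpmndi:BPMNDiagram '
              'xmlns:bpmndi="http://www.omg.org/spec/BPMN/20100524/DI"/>')
        path = tmp_path / "m.bpmn"
        path.write_text(MINIMAL_BPMN.replace("</definitions>",
                                             di + "</definitions>"))
        # top-level siblings of <process> outside the model namespace are
        # layout scaffolding and must not affect the parsed model
        model = model_io.read_bpmn(path)
        assert len(model.nodes) == 3


class TestReadCmmn:
    def test_stage_with_required_task(self, tmp_path):
        path = tmp_path / "c.cmmn"
        path.write_text(MINIMAL_CMMN)
        case = model_io.read_cmmn(path)
        assert [i.item_id for i in case.plan_items] == ["stage_1"]
        assert case.plan_items[0].children[0].item_id == "task_a"
        assert case.plan_items[0].children[0].required

    def test_unknown_sentry_source_rejected(self, tmp_path):
        bad = MINIMAL_CMMN.replace(
            '<planItem id="pi__task_a" definitionRef="task_a">',
            '<planItem id="pi__task_a" definitionRef="task_a">'
            '<entryCriterion id="ec1" sentryRef="sn1"/>').replace(
            '<humanTask id="task_a" name="A"/>',
            '<humanTask id="task_a" name="A"/>'
            '<sentry id="sn1"><planItemOnPart id="op1" sourceRef="pi__ghost">'
            '<standardEvent>complete</standardEvent></planItemOnPart></sentry>')
        path = tmp_path / "c.cmmn"
        path.write_text(bad)
        with pytest.raises(ModelValidationError, match="ghost"):
            model_io.read_cmmn(path)

    def test_non_constant_rule_rejected(self, tmp_path):
        path = tmp_path / "c.cmmn"
        path.write_text(MINIMAL_CMMN.replace(
            "<condition>true</condition>",
            "<condition>${ expr }</condition>"))
        with pytest.raises(UnsupportedRuleError):
            model_io.read_cmmn(path)

    def test_non_complete_standard_event_rejected(self, tmp_path):
        bad = MINIMAL_CMMN.replace(
            '<humanTask id="task_a" name="A"/>',
            '<humanTask id="task_a" name="A"/>'
            '<sentry id="sn1"><planItemOnPart id="op1" sourceRef="pi__task_a">'
            '<standardEvent>terminate</standardEvent></planItemOnPart></sentry>')
        path = tmp_path / "c.cmmn"
        path.write_text(bad)
        with pytest.raises(UnsupportedRuleError, match="terminate"):
            model_io.read_cmmn(path)

    def test_cross_fixture_task_count_consistency(self, ramie_bundle):
        # the case variant carries exactly the step set of the process variant
        bpmn_tasks = {t.node_id for t in ramie_bundle.bpmn.user_tasks()}
        cmmn_tasks = {t.item_id for t in ramie_bundle.cmmn.human_tasks()}
        assert bpmn_tasks == cmmn_tasks

    def test_optional_encoding_invariant(self, ci_bundle, tmp_path):
        model_io.write_cmmn(ci_bundle.cmmn, tmp_path / "c.cmmn")
        case = model_io.read_cmmn(tmp_path / "c.cmmn")
        optional = [i for i in case.iter_items() if not i.required]
        assert optional, "fixture should contain optional items"
        assert all(i.manual_activation for i in optional)


@pytest.mark.parametrize("intervention", ["ci", "ramie"])
@pytest.mark.parametrize("variant", ["bpmn", "cmmn", "structured", "mixed"])
def test_roundtrip_structural_equality(intervention, variant, ci_bundle,
                                       ramie_bundle, tmp_path):
    bundle = {"ci": ci_bundle, "ramie": ramie_bundle}[intervention]
    model = bundle.variant(variant)
    if variant == "bpmn":
        model_io.write_bpmn(model, tmp_path / "m.bpmn")
        again = model_io.read_bpmn(tmp_path / "m.bpmn")
    elif variant == "cmmn":
        model_io.write_cmmn(model, tmp_path / "m.cmmn")
        again = model_io.read_cmmn(tmp_path / "m.cmmn")
    else:
        model_io.write_combination(model, tmp_path / variant)
        again = model_io.read_combination(tmp_path / variant)
    assert again == model


def test_written_files_stay_inside_subset(ci_bundle, tmp_path):
    """Subset closure: everything the writers emit, the readers accept, and
    the emitted vocabulary is exactly the supported one plus scaffolding."""
    model_io.write_bpmn(ci_bundle.bpmn, tmp_path / "m.bpmn")
    root = etree.parse(str(tmp_path / "m.bpmn")).getroot()
    allowed = {"definitions", "process", "startEvent", "endEvent", "userTask",
               "exclusiveGateway", "parallelGateway", "subProcess",
               "callActivity", "boundaryEvent", "signalEventDefinition",
               "sequenceFlow", "extensionElements", "expectedDuration"}
    seen = {etree.QName(e).localname for e in root.iter() if isinstance(e.tag, str)}
    assert seen <= allowed


def test_empty_name_roundtrips(tmp_path):
    from surgflow.model import FlowNode, ProcessModel, SequenceFlow
    model = ProcessModel(
        model_id="p", name="",
        nodes=[FlowNode("s", NodeKind.START_EVENT),
               FlowNode("t", NodeKind.USER_TASK, name=""),
               FlowNode("e", NodeKind.END_EVENT)],
        flows=[SequenceFlow("f1", "s", "t"), SequenceFlow("f2", "t", "e")])
    model_io.write_bpmn(model, tmp_path / "m.bpmn")
    assert model_io.read_bpmn(tmp_path / "m.bpmn") == model


def test_call_activity_reference_preserved(ci_bundle, tmp_path):
    model_io.write_combination(ci_bundle.structured, tmp_path / "st")
    again = model_io.read_combination(tmp_path / "st")
    refs = {ca.node_id: ca.called_case for ca in again.root.call_activities()}
    orig = {ca.node_id: ca.called_case
            for ca in ci_bundle.structured.root.call_activities()}
    assert refs == orig and len(refs) == 5
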