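"""Reading and writing the BPMN 2.0 / CMMN 1.1 subsets.

The dialect is deliberately vendor-free: plain OMG namespaces, no engine
extension attributes.  The one piece of information the OMG schemas have no
slot for — the expected duration of a step in minutes, needed for the
remaining-surgery-duration estimate — lives in a documented extension
element ``{urn:surgflow:extension}expectedDuration``.

Readers accept exactly the supported element kinds plus the scaffolding
(definitions, extension elements, documentation, diagram-interchange
sections, which are ignored).  Anything else raises
:class:`~surgflow.errors.UnsupportedElementError` listing the offending
element names rather than being silently dropped.
"""

from __future__ import annotations

import os
from pathlib import Path

from lxml import etree

from .errors import (
    ModelParseError,
    ModelValidationError,
    UnsupportedElementError,
    UnsupportedRuleError,
)
from .model import (
    CaseModel,
    CombinationModel,
    FlowNode,
    ItemKind,
    NodeKind,
    PlanItem,
    ProcessModel,
    Sentry,
    SequenceFlow,
)
from .structure import ModelStructure

BPMN_NS = "http://www.omg.org/spec/BPMN/20100524/MODEL"
CMMN_NS = "http://www.omg.org/spec/CMMN/20151109/MODEL"
EXT_NS = "urn:surgflow:extension"

_BPMN_NODE_TAGS = {
    "startEvent": NodeKind.START_EVENT,
    "endEvent": NodeKind.END_EVENT,
    "userTask": NodeKind.USER_TASK,
    "exclusiveGateway": NodeKind.XOR_GATEWAY,
    "parallelGateway": NodeKind.AND_GATEWAY,
}

# scaffolding we accept and ignore on read
_IGNORED_LOCAL = {"documentation", "extensionElements"}


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) and tag[0] == "{" else str(tag)


def _parse_xml(path) -> etree._Element:
    try:
        tree = etree.parse(os.fspath(path))
    except etree.XMLSyntaxError as exc:
        raise ModelParseError(f"malformed XML in {path}: {exc.msg}",
                              line=exc.lineno) from exc
    return tree.getroot()


def _expected_duration(elem) -> float | None:
    for ext in elem.findall(f"{{{BPMN_NS}}}extensionElements") + list(elem):
        if not isinstance(ext.tag, str):
            continue
        if etree.QName(ext).namespace == EXT_NS and _local(ext.tag) == "expectedDuration":
            return float(ext.text)
        if _local(ext.tag) == "extensionElements":
            for sub in ext:
                if (isinstance(sub.tag, str)
                        and etree.QName(sub).namespace == EXT_NS
                        and _local(sub.tag) == "expectedDuration"):
                    return float(sub.text)
    return None


# ---------------------------------------------------------------------------
# BPMN
# ---------------------------------------------------------------------------


def read_bpmn(path) -> ProcessModel:
    """Read a BPMN 2.0 file restricted to the supported element subset."""
    root = _parse_xml(path)
    if _local(root.tag) != "definitions":
        raise ModelParseError(f"{path}: root element is not <definitions>")
    processes = [e for e in root if isinstance(e.tag, str)
                 and _local(e.tag) == "process"]
    if len(processes) != 1:
        raise ModelValidationError(
            f"{path}: expected exactly one <process>, found {len(processes)}")
    proc = processes[0]
    unsupported: list[str] = []
    nodes, flows = _parse_bpmn_container(proc, unsupported)
    if unsupported:
        raise UnsupportedElementError(unsupported)
    model = ProcessModel(
        model_id=proc.get("id", "process"),
        name=proc.get("name", ""),
        nodes=nodes,
        flows=flows,
    )
    model.granularity = (
        "two_level"
        if any(n.kind in (NodeKind.SUB_PROCESS, NodeKind.CALL_ACTIVITY)
               for n in model.iter_nodes())
        else "one_level"
    )
    model.validate()
    try:
        ModelStructure(model).mark_optional_steps()
    except ModelValidationError:
        pass  # not block-structured; engines will refuse at execution time
    return model


def _parse_bpmn_container(elem, unsupported: list[str]):
    nodes: list[FlowNode] = []
    flows: list[SequenceFlow] = []
    for child in elem:
        if not isinstance(child.tag, str):
            continue
        ns = etree.QName(child).namespace
        local = _local(child.tag)
        if local in _IGNORED_LOCAL or ns == EXT_NS:
            continue
        if local in _BPMN_NODE_TAGS:
            nodes.append(FlowNode(
                node_id=child.get("id"),
                kind=_BPMN_NODE_TAGS[local],
                name=child.get("name", ""),
                expected_duration=_expected_duration(child),
            ))
        elif local == "subProcess":
            sub_nodes, sub_flows = _parse_bpmn_container(child, unsupported)
            nodes.append(FlowNode(
                node_id=child.get("id"),
                kind=NodeKind.SUB_PROCESS,
                name=child.get("name", ""),
                children=sub_nodes,
            ))
            flows.extend(sub_flows)
        elif local == "callActivity":
            nodes.append(FlowNode(
                node_id=child.get("id"),
                kind=NodeKind.CALL_ACTIVITY,
                name=child.get("name", ""),
                called_case=child.get("calledElement"),
            ))
        elif local == "boundaryEvent":
            defs = [d for d in child if isinstance(d.tag, str)
                    and _local(d.tag) not in _IGNORED_LOCAL]
            def_names = {_local(d.tag) for d in defs}
            if def_names - {"signalEventDefinition"}:
                unsupported.extend(sorted(def_names - {"signalEventDefinition"}))
            nodes.append(FlowNode(
                node_id=child.get("id"),
                kind=NodeKind.SIGNAL_BOUNDARY_EVENT,
                name=child.get("name", ""),
                attached_to=child.get("attachedToRef"),
            ))
        elif local == "sequenceFlow":
            flows.append(SequenceFlow(
                flow_id=child.get("id"),
                source=child.get("sourceRef"),
                target=child.get("targetRef"),
                label=child.get("name", ""),
            ))
        else:
            unsupported.append(local)
    return nodes, flows


def write_bpmn(model: ProcessModel, path) -> None:
    model.validate()
    nsmap = {None: BPMN_NS, "sf": EXT_NS}
    root = etree.Element(f"{{{BPMN_NS}}}definitions", nsmap=nsmap,
                         targetNamespace=EXT_NS)
    proc = etree.SubElement(root, f"{{{BPMN_NS}}}process",
                            id=model.model_id, name=model.name,
                            isExecutable="true")
    _emit_bpmn_container(proc, model, model.nodes)
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True,
                       encoding="UTF-8"))


_KIND_TO_TAG = {v: k for k, v in _BPMN_NODE_TAGS.items()}


def _emit_bpmn_container(parent, model: ProcessModel, members) -> None:
    member_ids = {n.node_id for n in members}
    for n in members:
        if n.kind in _KIND_TO_TAG:
            e = etree.SubElement(parent, f"{{{BPMN_NS}}}{_KIND_TO_TAG[n.kind]}",
                                 id=n.node_id, name=n.name)
            if n.expected_duration is not None:
                ext = etree.SubElement(e, f"{{{BPMN_NS}}}extensionElements")
                dur = etree.SubElement(ext, f"{{{EXT_NS}}}expectedDuration")
                dur.text = repr(n.expected_duration)
        elif n.kind is NodeKind.SUB_PROCESS:
            e = etree.SubElement(parent, f"{{{BPMN_NS}}}subProcess",
                                 id=n.node_id, name=n.name)
            _emit_bpmn_container(e, model, n.children)
        elif n.kind is NodeKind.CALL_ACTIVITY:
            etree.SubElement(parent, f"{{{BPMN_NS}}}callActivity",
                             id=n.node_id, name=n.name,
                             calledElement=n.called_case or "")
        elif n.kind is NodeKind.SIGNAL_BOUNDARY_EVENT:
            e = etree.SubElement(parent, f"{{{BPMN_NS}}}boundaryEvent",
                                 id=n.node_id, name=n.name,
                                 attachedToRef=n.attached_to or "")
            etree.SubElement(e, f"{{{BPMN_NS}}}signalEventDefinition")
    for f in model.flows:
        if f.source in member_ids:
            etree.SubElement(parent, f"{{{BPMN_NS}}}sequenceFlow",
                             id=f.flow_id, name=f.label,
                             sourceRef=f.source, targetRef=f.target)


# ---------------------------------------------------------------------------
# CMMN
# ---------------------------------------------------------------------------

_PI_PREFIX = "pi__"


def read_cmmn(path) -> CaseModel:
    """Read a CMMN 1.1 file restricted to the supported element subset."""
    root = _parse_xml(path)
    if _local(root.tag) != "definitions":
        raise ModelParseError(f"{path}: root element is not <definitions>")
    cases = [e for e in root if isinstance(e.tag, str) and _local(e.tag) == "case"]
    if len(cases) != 1:
        raise ModelValidationError(
            f"{path}: expected exactly one <case>, found {len(cases)}")
    case_elem = cases[0]
    plans = [e for e in case_elem if isinstance(e.tag, str)
             and _local(e.tag) == "casePlanModel"]
    if len(plans) != 1:
        raise ModelValidationError(f"{path}: expected exactly one <casePlanModel>")
    unsupported: list[str] = []
    items = _parse_stage_content(plans[0], unsupported)
    if unsupported:
        raise UnsupportedElementError(unsupported)
    case = CaseModel(
        case_id=case_elem.get("id", "case"),
        name=case_elem.get("name", ""),
        plan_items=items,
    )
    case.validate()
    return case


def _parse_stage_content(stage_elem, unsupported: list[str]) -> list[PlanItem]:
    plan_items: list[etree._Element] = []
    sentries: dict[str, Sentry] = {}
    defs: dict[str, etree._Element] = {}
    for child in stage_elem:
        if not isinstance(child.tag, str):
            continue
        ns = etree.QName(child).namespace
        local = _local(child.tag)
        if local in _IGNORED_LOCAL or ns == EXT_NS:
            continue
        if local == "planItem":
            plan_items.append(child)
        elif local == "sentry":
            sentries[child.get("id")] = _parse_sentry(child)
        elif local in ("humanTask", "stage", "userEventListener",
                       "timerEventListener"):
            defs[child.get("id")] = child
        else:
            unsupported.append(local)

    items: list[PlanItem] = []
    for pi in plan_items:
        ref = pi.get("definitionRef")
        if ref not in defs:
            raise ModelValidationError(
                f"plan item {pi.get('id')!r} references unknown definition {ref!r}")
        d = defs[ref]
        local = _local(d.tag)
        if local == "humanTask":
            kind = ItemKind.HUMAN_TASK
        elif local == "stage":
            kind = ItemKind.STAGE
        else:
            kind = ItemKind.EVENT_LISTENER
        required, manual = _parse_item_control(pi)
        entry = []
        for ec in pi.findall(f"{{{CMMN_NS}}}entryCriterion"):
            sid = ec.get("sentryRef")
            if sid not in sentries:
                raise ModelValidationError(
                    f"entry criterion references unknown sentry {sid!r}")
            entry.append(sentries[sid])
        children = (_parse_stage_content(d, unsupported)
                    if kind is ItemKind.STAGE else [])
        items.append(PlanItem(
            item_id=ref,
            kind=kind,
            name=d.get("name", ""),
            required=required,
            manual_activation=manual,
            entry_criteria=entry,
            children=children,
            expected_duration=_expected_duration(d),
        ))
    return items


def _parse_sentry(elem) -> Sentry:
    on_parts: list[tuple[str, str]] = []
    for op in elem.findall(f"{{{CMMN_NS}}}planItemOnPart"):
        src = op.get("sourceRef", "")
        if src.startswith(_PI_PREFIX):
            src = src[len(_PI_PREFIX):]
        ev = op.findtext(f"{{{CMMN_NS}}}standardEvent", default="complete").strip()
        if ev != "complete":
            raise UnsupportedRuleError(
                f"sentry {elem.get('id')!r}: only the 'complete' standard event "
                f"is supported, got {ev!r}")
        on_parts.append((src, ev))
    return Sentry(sentry_id=elem.get("id"), on_parts=on_parts)


def _parse_item_control(pi_elem) -> tuple[bool, bool]:
    required, manual = True, False
    ctrl = pi_elem.find(f"{{{CMMN_NS}}}itemControl")
    if ctrl is None:
        return required, manual
    for rule, attr in (("requiredRule", "required"),
                       ("manualActivationRule", "manual")):
        r = ctrl.find(f"{{{CMMN_NS}}}{rule}")
        if r is None:
            continue
        cond = r.findtext(f"{{{CMMN_NS}}}condition", default="").strip()
        if cond not in ("true", "false"):
            raise UnsupportedRuleError(
                f"{rule} on {pi_elem.get('id')!r} must be a literal boolean, "
                f"got {cond!r}")
        value = cond == "true"
        if attr == "required":
            required = value
        else:
            manual = value
    return required, manual


def write_cmmn(case: CaseModel, path) -> None:
    case.validate()
    nsmap = {None: CMMN_NS, "sf": EXT_NS}
    root = etree.Element(f"{{{CMMN_NS}}}definitions", nsmap=nsmap,
                         targetNamespace=EXT_NS)
    case_elem = etree.SubElement(root, f"{{{CMMN_NS}}}case",
                                 id=case.case_id, name=case.name)
    plan = etree.SubElement(case_elem, f"{{{CMMN_NS}}}casePlanModel",
                            id=f"{case.case_id}__plan", name=case.name)
    _emit_stage_content(plan, case.plan_items)
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True,
                       encoding="UTF-8"))


def _emit_stage_content(stage_elem, items: list[PlanItem]) -> None:
    for item in items:
        pi = etree.SubElement(stage_elem, f"{{{CMMN_NS}}}planItem",
                              id=f"{_PI_PREFIX}{item.item_id}",
                              definitionRef=item.item_id)
        for sentry in item.entry_criteria:
            etree.SubElement(pi, f"{{{CMMN_NS}}}entryCriterion",
                             id=f"ec__{sentry.sentry_id}",
                             sentryRef=sentry.sentry_id)
        ctrl = etree.SubElement(pi, f"{{{CMMN_NS}}}itemControl")
        for rule, value in (("requiredRule", item.required),
                            ("manualActivationRule", item.manual_activation)):
            r = etree.SubElement(ctrl, f"{{{CMMN_NS}}}{rule}")
            c = etree.SubElement(r, f"{{{CMMN_NS}}}condition")
            c.text = "true" if value else "false"
    for item in items:
        for sentry in item.entry_criteria:
            s = etree.SubElement(stage_elem, f"{{{CMMN_NS}}}sentry",
                                 id=sentry.sentry_id)
            for src, ev in sentry.on_parts:
                op = etree.SubElement(s, f"{{{CMMN_NS}}}planItemOnPart",
                                      id=f"op__{sentry.sentry_id}__{src}",
                                      sourceRef=f"{_PI_PREFIX}{src}")
                e = etree.SubElement(op, f"{{{CMMN_NS}}}standardEvent")
                e.text = ev
    for item in items:
        if item.kind is ItemKind.HUMAN_TASK:
            d = etree.SubElement(stage_elem, f"{{{CMMN_NS}}}humanTask",
                                 id=item.item_id, name=item.name)
            if item.expected_duration is not None:
                dur = etree.SubElement(d, f"{{{EXT_NS}}}expectedDuration")
                dur.text = repr(item.expected_duration)
        elif item.kind is ItemKind.STAGE:
            d = etree.SubElement(stage_elem, f"{{{CMMN_NS}}}stage",
                                 id=item.item_id, name=item.name)
            _emit_stage_content(d, item.children)
        else:
            etree.SubElement(stage_elem, f"{{{CMMN_NS}}}userEventListener",
                             id=item.item_id, name=item.name)


# ---------------------------------------------------------------------------
# Combination bundles (directory with one root .bpmn + referenced .cmmn)
# ---------------------------------------------------------------------------


def read_combination(directory) -> CombinationModel:
    directory = Path(directory)
    bpmn_files = sorted(directory.glob("*.bpmn"))
    if len(bpmn_files) != 1:
        raise ModelValidationError(
            f"{directory}: expected exactly one root .bpmn, found {len(bpmn_files)}")
    root = read_bpmn(bpmn_files[0])
    cases = {}
    for f in sorted(directory.glob("*.cmmn")):
        case = read_cmmn(f)
        cases[case.case_id] = case
    style = "mixed" if root.user_tasks() else "structured"
    comb = CombinationModel(style=style, root=root, cases=cases)
    comb.validate()
    return comb


def write_combination(comb: CombinationModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_bpmn(comb.root, directory / f"{comb.root.model_id}.bpmn")
    for cid, case in comb.cases.items():
        write_cmmn(case, directory / f"{cid}.cmmn")
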