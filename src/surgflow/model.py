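"""In-memory representations of surgical process models.

Two notations are supported, mirroring how intraoperative workflows are
commonly formalized:

* :class:`ProcessModel` — a BPMN 2.0 process: a graph of flow nodes connected
  by sequence flows.  Surgical phases are sub-processes, steps are user tasks,
  variable-order step groups are parallel (AND) gateway blocks and optional
  steps are exclusive (XOR) gateway bypasses.
* :class:`CaseModel` — a CMMN 1.1 case: a tree of plan items.  Phases are
  stages, steps are human tasks, ordering is expressed through sentries
  (entry criteria firing on completion of referenced items), and optional
  steps carry no required rule but a manual-activation rule.

Only the element subset needed for this transfer concept is represented;
readers reject anything else explicitly (see :mod:`surgflow.model_io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator

import networkx as nx

from .errors import ModelValidationError, UnknownElementError

__all__ = [
    "NodeKind",
    "ItemKind",
    "FlowNode",
    "SequenceFlow",
    "ProcessModel",
    "Sentry",
    "PlanItem",
    "CaseModel",
    "CombinationModel",
    "Trace",
]


class NodeKind(str, enum.Enum):
    USER_TASK = "user_task"
    XOR_GATEWAY = "xor_gateway"
    AND_GATEWAY = "and_gateway"
    START_EVENT = "start_event"
    END_EVENT = "end_event"
    SUB_PROCESS = "sub_process"
    CALL_ACTIVITY = "call_activity"
    SIGNAL_BOUNDARY_EVENT = "signal_boundary_event"


class ItemKind(str, enum.Enum):
    HUMAN_TASK = "human_task"
    STAGE = "stage"
    EVENT_LISTENER = "event_listener"


@dataclass
class FlowNode:
    node_id: str
    kind: NodeKind
    name: str = ""
    optional_step: bool = False
    expected_duration: float | None = None  # minutes
    children: list["FlowNode"] = field(default_factory=list)
    called_case: str | None = None  # call_activity only
    attached_to: str | None = None  # signal_boundary_event only


@dataclass
class SequenceFlow:
    flow_id: str
    source: str
    target: str
    label: str = ""


@dataclass
class ProcessModel:
    model_id: str
    name: str = ""
    nodes: list[FlowNode] = field(default_factory=list)
    flows: list[SequenceFlow] = field(default_factory=list)
    granularity: str = "one_level"  # or "two_level"

    def __eq__(self, other):
        # structural equality: flow order is serialization detail, not meaning
        if not isinstance(other, ProcessModel):
            return NotImplemented
        key = lambda f: f.flow_id  # noqa: E731
        return (self.model_id == other.model_id and self.name == other.name
                and self.granularity == other.granularity
                and self.nodes == other.nodes
                and sorted(self.flows, key=key) == sorted(other.flows, key=key))

    # -- indexing -----------------------------------------------------------

    def iter_nodes(self) -> Iterator[FlowNode]:
        stack = list(self.nodes)
        while stack:
            n = stack.pop(0)
            yield n
            stack = list(n.children) + stack

    def node(self, node_id: str) -> FlowNode:
        for n in self.iter_nodes():
            if n.node_id == node_id:
                return n
        raise UnknownElementError(f"no node {node_id!r} in model {self.model_id!r}")

    def has_node(self, node_id: str) -> bool:
        return any(n.node_id == node_id for n in self.iter_nodes())

    def parent_of(self, node_id: str) -> FlowNode | None:
        """The sub-process containing *node_id*, or None at root level."""
        def walk(container: FlowNode | None, nodes: list[FlowNode]):
            for n in nodes:
                if n.node_id == node_id:
                    return container, True
                found, ok = walk(n, n.children)
                if ok:
                    return found, True
            return None, False

        parent, ok = walk(None, self.nodes)
        if not ok:
            raise UnknownElementError(f"no node {node_id!r} in model {self.model_id!r}")
        return parent

    def outgoing(self, node_id: str) -> list[SequenceFlow]:
        return [f for f in self.flows if f.source == node_id]

    def incoming(self, node_id: str) -> list[SequenceFlow]:
        return [f for f in self.flows if f.target == node_id]

    def user_tasks(self) -> list[FlowNode]:
        return [n for n in self.iter_nodes() if n.kind is NodeKind.USER_TASK]

    def call_activities(self) -> list[FlowNode]:
        return [n for n in self.iter_nodes() if n.kind is NodeKind.CALL_ACTIVITY]

    def phase_of(self, step_id: str) -> str | None:
        """Top-level container (phase) holding *step_id*."""
        for top in self.nodes:
            if top.node_id == step_id:
                return None
            if top.kind is NodeKind.SUB_PROCESS:
                if any(n.node_id == step_id for n in _iter_subtree(top)):
                    return top.node_id
        return None

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        problems: list[str] = []
        ids: list[str] = [n.node_id for n in self.iter_nodes()]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            problems.append(f"duplicate node ids: {sorted(dup)}")
        known = set(ids)

        for f in self.flows:
            for ref in (f.source, f.target):
                if ref not in known:
                    problems.append(f"flow {f.flow_id!r} references unknown node {ref!r}")
        for f in self.flows:
            if f.source == f.target and f.source in known:
                if self.node(f.source).kind is NodeKind.USER_TASK:
                    problems.append(f"flow {f.flow_id!r} is a task self-loop")

        containers: list[tuple[str | None, list[FlowNode]]] = [(None, self.nodes)]
        for n in self.iter_nodes():
            if n.kind is NodeKind.SUB_PROCESS:
                containers.append((n.node_id, n.children))
            if n.kind is not NodeKind.SUB_PROCESS and n.children:
                problems.append(f"non-sub-process node {n.node_id!r} has children")
            if n.kind is NodeKind.CALL_ACTIVITY and not n.called_case:
                problems.append(f"call activity {n.node_id!r} has no case reference")
            if n.kind is NodeKind.SIGNAL_BOUNDARY_EVENT:
                if not n.attached_to or n.attached_to not in known:
                    problems.append(f"boundary event {n.node_id!r} not attached to a node")
                else:
                    host = self.node(n.attached_to)
                    if host.kind not in (NodeKind.USER_TASK, NodeKind.SUB_PROCESS,
                                         NodeKind.CALL_ACTIVITY):
                        problems.append(
                            f"boundary event {n.node_id!r} attached to {host.kind.value}")

        for cid, members in containers:
            kinds = [m.kind for m in members]
            if kinds.count(NodeKind.START_EVENT) != 1:
                problems.append(f"container {cid or 'root'} needs exactly one start event")
            if kinds.count(NodeKind.END_EVENT) < 1:
                problems.append(f"container {cid or 'root'} needs at least one end event")

        for n in self.iter_nodes():
            if n.kind in (NodeKind.XOR_GATEWAY, NodeKind.AND_GATEWAY):
                if not self.incoming(n.node_id) or not self.outgoing(n.node_id):
                    problems.append(f"gateway {n.node_id!r} lacks incoming or outgoing flows")

        if not problems:
            g = nx.DiGraph()
            g.add_nodes_from(known)
            for f in self.flows:
                g.add_edge(f.source, f.target)
            # membership edges let reachability cross container boundaries
            for n in self.iter_nodes():
                for c in n.children:
                    g.add_edge(n.node_id, c.node_id)
            starts = [m.node_id for m in self.nodes if m.kind is NodeKind.START_EVENT]
            reachable = set()
            for s in starts:
                reachable |= {s} | nx.descendants(g, s)
            boundary = {n.node_id for n in self.iter_nodes()
                        if n.kind is NodeKind.SIGNAL_BOUNDARY_EVENT}
            unreachable = known - reachable - boundary
            # boundary events and their one-step successors sit off the main path
            for b in boundary:
                unreachable -= {f.target for f in self.outgoing(b)}
            if unreachable:
                problems.append(f"unreachable nodes: {sorted(unreachable)}")

        if problems:
            raise ModelValidationError(f"invalid process model {self.model_id!r}", problems)


def _iter_subtree(node: FlowNode) -> Iterator[FlowNode]:
    for c in node.children:
        yield c
        yield from _iter_subtree(c)


@dataclass
class Sentry:
    sentry_id: str
    #: (source plan-item id, lifecycle event); only "complete" is supported
    on_parts: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PlanItem:
    item_id: str
    kind: ItemKind
    name: str = ""
    required: bool = True
    manual_activation: bool = False
    entry_criteria: list[Sentry] = field(default_factory=list)
    children: list["PlanItem"] = field(default_factory=list)
    expected_duration: float | None = None  # minutes

    @property
    def optional(self) -> bool:
        return (not self.required) and self.manual_activation


@dataclass
class CaseModel:
    case_id: str
    name: str = ""
    plan_items: list[PlanItem] = field(default_factory=list)

    def iter_items(self) -> Iterator[PlanItem]:
        stack = list(self.plan_items)
        while stack:
            i = stack.pop(0)
            yield i
            stack = list(i.children) + stack

    def item(self, item_id: str) -> PlanItem:
        for i in self.iter_items():
            if i.item_id == item_id:
                return i
        raise UnknownElementError(f"no plan item {item_id!r} in case {self.case_id!r}")

    def has_item(self, item_id: str) -> bool:
        return any(i.item_id == item_id for i in self.iter_items())

    def parent_of(self, item_id: str) -> PlanItem | None:
        def walk(container, items):
            for i in items:
                if i.item_id == item_id:
                    return container, True
                found, ok = walk(i, i.children)
                if ok:
                    return found, True
            return None, False

        parent, ok = walk(None, self.plan_items)
        if not ok:
            raise UnknownElementError(f"no plan item {item_id!r} in case {self.case_id!r}")
        return parent

    def human_tasks(self) -> list[PlanItem]:
        return [i for i in self.iter_items() if i.kind is ItemKind.HUMAN_TASK]

    def stages(self) -> list[PlanItem]:
        return [i for i in self.iter_items() if i.kind is ItemKind.STAGE]

    def stage_of(self, item_id: str) -> str | None:
        parent = self.parent_of(item_id)
        return parent.item_id if parent is not None else None

    def validate(self) -> None:
        problems: list[str] = []
        ids = [i.item_id for i in self.iter_items()]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            problems.append(f"duplicate plan-item ids: {sorted(dup)}")
        known = set(ids)
        for i in self.iter_items():
            if i.kind is not ItemKind.STAGE and i.children:
                problems.append(f"non-stage item {i.item_id!r} has children")
            for s in i.entry_criteria:
                for src, event in s.on_parts:
                    if src not in known:
                        problems.append(
                            f"sentry {s.sentry_id!r} references unknown item {src!r}")
                    if event != "complete":
                        problems.append(
                            f"sentry {s.sentry_id!r} uses unsupported event {event!r}")
            if i.kind is ItemKind.HUMAN_TASK and not i.required and not i.manual_activation:
                problems.append(
                    f"item {i.item_id!r}: optional items must combine required=false "
                    "with a manual activation rule")
        if problems:
            raise ModelValidationError(f"invalid case model {self.case_id!r}", problems)


@dataclass
class CombinationModel:
    """A BPMN root process referring to CMMN cases via call activities."""

    style: str  # "mixed" | "structured"
    root: ProcessModel
    cases: dict[str, CaseModel] = field(default_factory=dict)

    def validate(self) -> None:
        self.root.validate()
        problems: list[str] = []
        for ca in self.root.call_activities():
            if ca.called_case not in self.cases:
                problems.append(
                    f"call activity {ca.node_id!r} references unknown case "
                    f"{ca.called_case!r}")
        if self.style == "structured" and self.root.user_tasks():
            problems.append("structured combination root must not contain user tasks")
        for case in self.cases.values():
            case.validate()
        if problems:
            raise ModelValidationError("invalid combination model", problems)

    def case_of(self, step_id: str) -> str | None:
        for cid, case in self.cases.items():
            if case.has_item(step_id):
                return cid
        return None


@dataclass
class Trace:
    """Ordered list of completed step identifiers (tasks only)."""

    steps: list[str] = field(default_factory=list)

    def append(self, step_id: str) -> None:
        self.steps.append(step_id)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self):
        return len(self.steps)

    def __contains__(self, step_id):
        return step_id in self.steps

    def __getitem__(self, idx):
        return self.steps[idx]

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(self.steps)

    def copy(self) -> "Trace":
        return Trace(list(self.steps))


def clone_node(node: FlowNode) -> FlowNode:
    return replace(node, children=[clone_node(c) for c in node.children])
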