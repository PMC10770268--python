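"""Process knowledge derived from surgical process models.

Everything a situation-recognition loop wants to know from the model side:
which steps can plausibly come next (statically from the modeled sequence,
or dynamically by replaying the executed trace), which running activity
instances a newly recognized situation allows to complete, whether a
candidate situation is reasonable at all, and the remaining surgery
duration (RSD) with the current delay.

By default process knowledge is read from the BPMN variant of the
intervention even when another notation is being controlled, since the
sequence-flow structure states the expected course most explicitly; callers
can pass a different source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bpmn import replay
from .errors import UnknownElementError
from .model import (
    CaseModel,
    CombinationModel,
    ItemKind,
    NodeKind,
    PlanItem,
    ProcessModel,
)
from .structure import Block, ModelStructure, Sequence, SubProcessRegion, TaskLeaf

__all__ = [
    "ProcessKnowledge",
    "DurationEstimate",
    "static_next_steps",
    "dynamic_next_steps",
    "completable_instances",
    "remaining_duration",
]

START = "start"  # sentinel for "before the first step"


@dataclass
class ProcessKnowledge:
    next_steps: set[str] = field(default_factory=set)
    completable: list[str] = field(default_factory=list)
    reasonable: bool = False
    source_model: str = ""


@dataclass
class DurationEstimate:
    rsd: float  # remaining surgery duration, minutes
    delay: float  # signed: positive = behind schedule
    expected_elapsed: float


# ---------------------------------------------------------------------------
# next steps
# ---------------------------------------------------------------------------


def static_next_steps(model: ProcessModel | CombinationModel, current: str,
                      depth: int = 1) -> set[str]:
    """Next possible steps from *current*, by the modeled sequence alone.

    Recursive traversal of the sequence flows: both branches of an XOR
    gateway and every branch of an AND gateway are expanded, sub-processes
    (and, for combination models, referenced cases) are descended into, and
    each path terminates at the first step encountered.  ``current="start"``
    asks for the first step(s) of the whole model.
    """
    result = {current}
    for _ in range(depth):
        result = set().union(*(_successors(model, c) for c in result)) if result else set()
    return result


def _successors(model, current: str) -> set[str]:
    if isinstance(model, CombinationModel):
        return _comb_successors(model, current)
    if current == START:
        start = next(n for n in model.nodes if n.kind is NodeKind.START_EVENT)
        return _first_tasks(model, model.outgoing(start.node_id))
    node = model.node(current)  # raises UnknownElementError
    if node.kind not in (NodeKind.USER_TASK, NodeKind.CALL_ACTIVITY):
        raise UnknownElementError(f"{current!r} is not a step")
    return _first_tasks(model, model.outgoing(current))


def _first_tasks(model: ProcessModel, flows, cases: dict | None = None) -> set[str]:
    result: set[str] = set()
    frontier = list(flows)
    seen: set[str] = set()
    while frontier:
        flow = frontier.pop(0)
        node = model.node(flow.target)
        if node.node_id in seen:
            continue
        seen.add(node.node_id)
        kind = node.kind
        if kind is NodeKind.USER_TASK:
            result.add(node.node_id)
        elif kind is NodeKind.CALL_ACTIVITY:
            if cases is not None and node.called_case in cases:
                result |= _case_entry_items(cases[node.called_case])
            else:
                result.add(node.node_id)
        elif kind is NodeKind.SUB_PROCESS:
            inner = next(c for c in node.children if c.kind is NodeKind.START_EVENT)
            frontier.extend(model.outgoing(inner.node_id))
        elif kind in (NodeKind.XOR_GATEWAY, NodeKind.AND_GATEWAY):
            frontier.extend(model.outgoing(node.node_id))
        elif kind is NodeKind.END_EVENT:
            container = model.parent_of(node.node_id)
            if container is not None:
                frontier.extend(model.outgoing(container.node_id))
    return result


def _case_entry_items(case: CaseModel, items: list[PlanItem] | None = None) -> set[str]:
    """First startable steps of a case: items without entry criteria."""
    result: set[str] = set()
    for item in (case.plan_items if items is None else items):
        if item.entry_criteria:
            continue
        if item.kind is ItemKind.HUMAN_TASK:
            result.add(item.item_id)
        elif item.kind is ItemKind.STAGE:
            result |= _case_entry_items(case, item.children)
    return result


def _comb_successors(comb: CombinationModel, current: str) -> set[str]:
    root = comb.root
    if current == START or root.has_node(current):
        steps = _first_tasks(root,
                             root.outgoing(current) if current != START else
                             root.outgoing(next(n for n in root.nodes
                                                if n.kind is NodeKind.START_EVENT).node_id),
                             cases=comb.cases)
        return steps
    case_id = comb.case_of(current)
    if case_id is None:
        raise UnknownElementError(f"{current!r} not found in combination model")
    case = comb.cases[case_id]
    successors = _sentry_successors(case, current)
    if successors:
        return successors
    # terminal item of the case: continue from its call activity in the root
    for ca in root.call_activities():
        if ca.called_case == case_id:
            return _first_tasks(root, root.outgoing(ca.node_id), cases=comb.cases)
    return set()


def _sentry_successors(case: CaseModel, item_id: str) -> set[str]:
    result: set[str] = set()
    for item in case.iter_items():
        if any(src == item_id for s in item.entry_criteria for src, _ in s.on_parts):
            if item.kind is ItemKind.HUMAN_TASK:
                result.add(item.item_id)
            elif item.kind is ItemKind.STAGE:
                result |= _case_entry_items(case, item.children)
    return result


def dynamic_next_steps(model: ProcessModel, trace,
                       camunda_compat: bool = True) -> set[str]:
    """Activatable steps after replaying *trace* on a fresh instance.

    Equals :func:`static_next_steps` outside parallel blocks; mid-block the
    replay accounts for already completed branch tasks and join states.
    Raises :class:`~surgflow.errors.ReplayError` on an invalid prefix.
    """
    inst = replay(model, trace, camunda_compat=camunda_compat)
    return inst.activatable_tasks()


def completable_instances(model: ProcessModel, trace, candidate: str,
                          running: set[str]) -> ProcessKnowledge:
    """Judge a candidate situation against trace and running activities.

    ``completable`` lists every running activity whose modeled successors
    include the candidate — completing them is what lets the candidate's
    task activate.  ``reasonable`` is true when the candidate is activatable
    after the replayed trace, or is one modeled step ahead of a running
    activity, or repeats the current (last completed) step.
    """
    completable = []
    for t in sorted(running):
        try:
            if candidate in static_next_steps(model, t):
                completable.append(t)
        except UnknownElementError:
            continue
    try:
        dyn = dynamic_next_steps(model, trace)
    except Exception:
        dyn = set()
    repetition = len(trace) > 0 and trace[-1] == candidate
    reasonable = candidate in dyn or bool(completable) or repetition
    return ProcessKnowledge(
        next_steps=dyn,
        completable=completable,
        reasonable=reasonable,
        source_model=model.model_id,
    )


# ---------------------------------------------------------------------------
# remaining surgery duration
# ---------------------------------------------------------------------------


def remaining_duration(model: ProcessModel, trace, clock: float) -> DurationEstimate | None:
    """RSD and delay from modeled expected durations (process knowledge only).

    RSD sums the expected durations of required steps not yet in the trace;
    optional steps are excluded, parallel branches contribute their sum and
    exclusive branches the maximum-duration branch (a conservative upper
    estimate) — unless the trace already committed to a branch, whose
    remainder is then used.  Returns ``None`` when required durations are
    missing (the estimate is unavailable, never an exception).
    """
    structure = ModelStructure(model)
    structure.mark_optional_steps()
    done = set(trace)
    rsd = _region_remaining(structure, structure.root, done)
    if rsd is None:
        return None
    elapsed = 0.0
    for step in trace:
        d = model.node(step).expected_duration
        if d is None:
            return None
        elapsed += d
    return DurationEstimate(rsd=rsd, delay=clock - elapsed, expected_elapsed=elapsed)


def _region_remaining(structure: ModelStructure, region, done: set[str]) -> float | None:
    if isinstance(region, Sequence):
        total = 0.0
        for item in region.items:
            v = _region_remaining(structure, item, done)
            if v is None:
                return None
            total += v
        return total
    if isinstance(region, TaskLeaf):
        node = region.node
        if node.optional_step or node.node_id in done:
            return 0.0
        if node.expected_duration is None:
            return None
        return node.expected_duration
    if isinstance(region, SubProcessRegion):
        return _region_remaining(structure, region.body, done)
    if isinstance(region, Block):
        values = []
        for idx, branch in enumerate(region.branches):
            v = _region_remaining(structure, branch, done)
            if v is None:
                return None
            values.append(v)
        if region.kind == "and":
            return sum(values)
        # XOR: committed branch if the trace already entered one, else max
        for idx in range(len(region.branches)):
            if any(t in done for t in structure.branch_tasks(region, idx)):
                return values[idx]
        return max(values) if values else 0.0
    raise TypeError(f"unexpected region {region!r}")
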