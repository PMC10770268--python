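"""Plan-item lifecycle execution of CMMN case models.

Items move through ``available -> enabled/active -> completed`` (optionals
can end ``disabled`` when their stage closes).  An item leaves ``available``
once its entry criteria (sentries firing on completion of referenced items)
are satisfied and its containing stage is active: required items activate
automatically, optional items — modeled with no required rule but a manual
activation rule — become ``enabled`` and must be started manually.

Two behaviors documented for the reference engine are reproduced on
purpose, because they produce the flexibility (and the false-positive
classes) this kind of model shows at runtime:

* a stage with optional children is **not** auto-completed; the controlling
  system must complete it explicitly, which disables un-run optionals.
  Stages with only required children auto-complete on the last completion.
* until the stage closes, optional items stay startable — so delayed
  optional tasks and "both branches" of an exclusive choice modeled as
  optional siblings are accepted, unlike in the BPMN variant.
"""

from __future__ import annotations

from .errors import (
    CaseIncompleteError,
    ClosedCaseError,
    LifecycleError,
    ReplayError,
    StageBusyError,
    StageIncompleteError,
    SurgflowError,
    UnknownElementError,
)
from .model import CaseModel, ItemKind, PlanItem, Trace

__all__ = ["CaseInstance", "start_case", "replay_case"]

AVAILABLE = "available"
ENABLED = "enabled"
ACTIVE = "active"
COMPLETED = "completed"
DISABLED = "disabled"


class CaseInstance:
    """Runtime state of one executing :class:`CaseModel`."""

    def __init__(self, case: CaseModel, instance_id: str | None = None):
        case.validate()
        self.case = case
        self.instance_id = instance_id or case.case_id
        self.item_states: dict[str, str] = {
            i.item_id: AVAILABLE for i in case.iter_items()}
        self.case_state = ACTIVE
        self.trace = Trace()
        self.clock: float = 0.0
        self.events: list[dict] = []
        self._parents: dict[str, str | None] = {}
        for item in case.iter_items():
            self._parents[item.item_id] = case.stage_of(item.item_id)
        self._evaluate()

    # -- helpers ------------------------------------------------------------

    def _log(self, element: str, transition: str) -> None:
        self.events.append({
            "clock": self.clock,
            "instance": self.instance_id,
            "element": element,
            "transition": transition,
        })

    def _item(self, item_id: str) -> PlanItem:
        return self.case.item(item_id)

    def _parent_active(self, item_id: str) -> bool:
        parent = self._parents[item_id]
        if parent is None:
            return self.case_state == ACTIVE
        return self.item_states[parent] == ACTIVE

    def _criteria_satisfied(self, item: PlanItem) -> bool:
        if not item.entry_criteria:
            return True
        # any satisfied entry criterion suffices; each needs all on-parts
        return any(
            all(self.item_states.get(src) == COMPLETED for src, _ in s.on_parts)
            for s in item.entry_criteria)

    def _evaluate(self) -> None:
        """Fire sentries and auto-complete all-required stages to fixpoint."""
        changed = True
        while changed:
            changed = False
            for item in self.case.iter_items():
                state = self.item_states[item.item_id]
                if state != AVAILABLE:
                    continue
                if item.kind is ItemKind.EVENT_LISTENER:
                    continue  # parsed but without runtime semantics
                if not self._parent_active(item.item_id):
                    continue
                if not self._criteria_satisfied(item):
                    continue
                if item.kind is ItemKind.STAGE:
                    self.item_states[item.item_id] = ACTIVE
                    self._log(item.item_id, "stage-activated")
                elif item.manual_activation:
                    self.item_states[item.item_id] = ENABLED
                    self._log(item.item_id, "enabled")
                else:
                    self.item_states[item.item_id] = ACTIVE
                    self._log(item.item_id, "activated")
                changed = True
            for stage in self.case.stages():
                if self._auto_completable(stage):
                    self.item_states[stage.item_id] = COMPLETED
                    self._log(stage.item_id, "auto-completed")
                    changed = True

    def _children(self, stage: PlanItem) -> list[PlanItem]:
        return [c for c in stage.children if c.kind is not ItemKind.EVENT_LISTENER]

    def _auto_completable(self, stage: PlanItem) -> bool:
        if self.item_states[stage.item_id] != ACTIVE:
            return False
        children = self._children(stage)
        if any(c.optional for c in children):
            return False  # needs manual completion by the controlling system
        return all(self.item_states[c.item_id] == COMPLETED for c in children)

    def _check_open(self) -> None:
        if self.case_state == "closed":
            raise ClosedCaseError("case is closed; no further transitions")

    # -- queries ------------------------------------------------------------

    def active_tasks(self) -> set[str]:
        return {i for i, s in self.item_states.items()
                if s == ACTIVE and self._item(i).kind is ItemKind.HUMAN_TASK}

    def enabled_tasks(self) -> set[str]:
        return {i for i, s in self.item_states.items()
                if s == ENABLED and self._item(i).kind is ItemKind.HUMAN_TASK}

    def startable_tasks(self) -> set[str]:
        return self.active_tasks() | self.enabled_tasks()

    def first_stage_items(self) -> set[str]:
        for item in self.case.plan_items:
            if item.kind is ItemKind.STAGE:
                return {c.item_id for c in item.children}
        return {i.item_id for i in self.case.plan_items
                if i.kind is ItemKind.HUMAN_TASK}

    def is_closed(self) -> bool:
        return self.case_state == "closed"

    def required_done(self) -> bool:
        return all(
            self.item_states[i.item_id] == COMPLETED
            for i in self.case.iter_items()
            if i.required and i.kind is not ItemKind.EVENT_LISTENER)

    # -- transitions --------------------------------------------------------

    def manually_start(self, item_id: str, at: float | None = None) -> "CaseInstance":
        """Start an enabled (optional, manually activated) item."""
        self._check_open()
        state = self.item_states.get(item_id)
        if state is None:
            raise UnknownElementError(f"unknown plan item {item_id!r}")
        if state != ENABLED:
            raise LifecycleError(
                f"cannot manually start {item_id!r} in state {state!r}")
        if at is not None:
            self.clock = max(self.clock, at)
        self.item_states[item_id] = ACTIVE
        self._log(item_id, "manually-started")
        return self

    def complete_task(self, item_id: str, at: float | None = None) -> "CaseInstance":
        """Complete an active human task; sentries referencing it re-evaluate."""
        self._check_open()
        state = self.item_states.get(item_id)
        if state is None:
            raise UnknownElementError(f"unknown plan item {item_id!r}")
        item = self._item(item_id)
        if item.kind is not ItemKind.HUMAN_TASK:
            raise LifecycleError(f"{item_id!r} is a {item.kind.value}, not a task")
        if state != ACTIVE:
            raise LifecycleError(
                f"cannot complete {item_id!r} in state {state!r}")
        if at is not None:
            self.clock = max(self.clock, at)
        self.item_states[item_id] = COMPLETED
        self.trace.append(item_id)
        self._log(item_id, "completed")
        self._evaluate()
        return self

    def complete_stage(self, stage_id: str, at: float | None = None) -> "CaseInstance":
        """Manually complete a stage, disabling its un-run optional items.

        A no-op when the stage already auto-completed (no optional children).
        """
        self._check_open()
        state = self.item_states.get(stage_id)
        if state is None:
            raise UnknownElementError(f"unknown plan item {stage_id!r}")
        stage = self._item(stage_id)
        if stage.kind is not ItemKind.STAGE:
            raise LifecycleError(f"{stage_id!r} is not a stage")
        if state == COMPLETED:
            return self
        if state != ACTIVE:
            raise LifecycleError(f"cannot complete stage {stage_id!r} in state {state!r}")
        children = self._children(stage)
        missing = [c.item_id for c in children
                   if c.required and self.item_states[c.item_id] != COMPLETED]
        if missing:
            raise StageIncompleteError(
                f"stage {stage_id!r} has incomplete required children: "
                f"{sorted(missing)}")
        busy = [c.item_id for c in children
                if self.item_states[c.item_id] == ACTIVE]
        if busy:
            raise StageBusyError(
                f"stage {stage_id!r} has active children: {sorted(busy)}")
        if at is not None:
            self.clock = max(self.clock, at)
        for c in children:
            if self.item_states[c.item_id] in (ENABLED, AVAILABLE):
                self.item_states[c.item_id] = DISABLED
                self._log(c.item_id, "disabled")
        self.item_states[stage_id] = COMPLETED
        self._log(stage_id, "stage-completed")
        self._evaluate()
        return self

    def complete_case(self, at: float | None = None) -> "CaseInstance":
        """Complete the case once every required item is completed."""
        self._check_open()
        if self.case_state == COMPLETED:
            return self
        missing = [i.item_id for i in self.case.iter_items()
                   if i.required and i.kind is not ItemKind.EVENT_LISTENER
                   and self.item_states[i.item_id] != COMPLETED]
        if missing:
            raise CaseIncompleteError(
                f"case {self.case.case_id!r} has incomplete required items: "
                f"{sorted(missing)}")
        busy = [i for i, s in self.item_states.items() if s == ACTIVE]
        if busy:
            raise CaseIncompleteError(
                f"case {self.case.case_id!r} has active items: {sorted(busy)}")
        if at is not None:
            self.clock = max(self.clock, at)
        for i, s in self.item_states.items():
            if s in (ENABLED, AVAILABLE):
                self.item_states[i] = DISABLED
                self._log(i, "disabled")
        self.case_state = COMPLETED
        self._log(self.case.case_id, "case-completed")
        return self

    def close_case(self, at: float | None = None) -> "CaseInstance":
        """Close a completed case; a closed case accepts no transitions."""
        self._check_open()
        if self.case_state != COMPLETED:
            raise LifecycleError("case must be completed before closing")
        if at is not None:
            self.clock = max(self.clock, at)
        self.case_state = "closed"
        self._log(self.case.case_id, "case-closed")
        return self

    # -- plumbing -----------------------------------------------------------

    def copy(self) -> "CaseInstance":
        clone = object.__new__(CaseInstance)
        clone.case = self.case
        clone.instance_id = self.instance_id
        clone.item_states = dict(self.item_states)
        clone.case_state = self.case_state
        clone.trace = self.trace.copy()
        clone.clock = self.clock
        clone.events = list(self.events)
        clone._parents = self._parents
        return clone

    def state_snapshot(self) -> tuple:
        return (tuple(sorted(self.item_states.items())), self.case_state,
                self.trace.as_tuple())


def start_case(case: CaseModel) -> CaseInstance:
    """Start a case: criteria-free items activate (or enable, if optional)."""
    return CaseInstance(case)


def replay_case(case: CaseModel, trace) -> CaseInstance:
    """Replay a step trace, inserting manual starts and stage completions.

    This is the acceptance relation used by the oracle comparison: an
    observation-level trace is accepted if each step can be started (with a
    manual start for enabled optionals and manual completion of blocked
    stages along the way) and completed in order.
    """
    inst = start_case(case)
    for step in trace:
        try:
            _force_startable(inst, step)
            if inst.item_states.get(step) == ENABLED:
                inst.manually_start(step)
            inst.complete_task(step)
        except SurgflowError as exc:
            raise ReplayError(f"trace invalid at {step!r}: {exc}") from exc
    return inst


def _force_startable(inst: CaseInstance, step: str) -> None:
    """Complete blocked stages (required done, no active child) until *step*
    is startable; raises if no progress can be made."""
    while inst.item_states.get(step) == AVAILABLE:
        progressed = False
        for stage in inst.case.stages():
            if inst.item_states[stage.item_id] != ACTIVE:
                continue
            children = inst._children(stage)
            if any(c.item_id == step for c in children):
                continue
            if any(inst.item_states[c.item_id] == ACTIVE for c in children):
                continue
            if all(inst.item_states[c.item_id] == COMPLETED
                   for c in children if c.required):
                inst.complete_stage(stage.item_id)
                progressed = True
                break
        if not progressed:
            raise LifecycleError(f"item {step!r} cannot be made startable")
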