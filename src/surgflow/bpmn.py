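"""Token-based execution of BPMN process models.

The engine advances tokens from the start event through gateways until they
rest on user tasks (or call activities).  Parallel (AND) gateways activate
every branch — the workaround used to model surgical steps whose order is
variable; exclusive (XOR) gateways register a *pending decision*: no branch
condition is evaluated, instead completing the first task of a branch
implicitly selects it, and the tasks of the other branches are bypassed.

A ``camunda_compat`` flag (default on) reproduces an engine peculiarity that
shapes the observable behavior for optional steps inside AND blocks: an
undecided XOR guarding an optional task resolves to its bypass as soon as a
task on a sibling branch of the same AND block completes.  Attempting the
optional afterwards is refused as a late optional.  With the flag off the
optional remains activatable until the parallel join.
"""

from __future__ import annotations

from .errors import (
    LateOptionalError,
    OutOfOrderError,
    RegressionError,
    ReplayError,
    SurgflowError,
    UnknownElementError,
)
from .model import NodeKind, ProcessModel, Trace
from .structure import ModelStructure

__all__ = ["ProcessInstance", "start_process", "replay"]

INACTIVE = "inactive"
ACTIVE = "active"
COMPLETED = "completed"
BYPASSED = "bypassed"

_STEP_KINDS = (NodeKind.USER_TASK, NodeKind.CALL_ACTIVITY)


class ProcessInstance:
    """Runtime state of one executing :class:`ProcessModel`."""

    def __init__(self, model: ProcessModel, camunda_compat: bool = True,
                 instance_id: str | None = None):
        model.validate()
        self.model = model
        self.camunda_compat = camunda_compat
        self.instance_id = instance_id or model.model_id
        self.structure = ModelStructure(model)
        self.structure.mark_optional_steps()
        self.task_states: dict[str, str] = {
            n.node_id: INACTIVE for n in model.iter_nodes() if n.kind in _STEP_KINDS}
        self.pending_decisions: set[str] = set()
        self.trace = Trace()
        self.clock: float = 0.0
        self.events: list[dict] = []
        self._join_arrivals: dict[str, set[str]] = {}
        self._sp_completed: set[str] = set()
        self._root_ended = False
        # AND split id -> branch idx -> XOR splits guarding an optional there
        self._optional_guards: dict[str, dict[int, list[str]]] = {}
        for block in self.structure.blocks.values():
            guarded = self.structure.optional_guard(block)
            if guarded is None:
                continue
            for blk, idx in self.structure.enclosing[guarded]:
                if blk.kind == "and":
                    self._optional_guards.setdefault(blk.split, {}) \
                        .setdefault(idx, []).append(block.split)
        self._start()

    # -- token movement -----------------------------------------------------

    def _log(self, element: str, transition: str) -> None:
        self.events.append({
            "clock": self.clock,
            "instance": self.instance_id,
            "element": element,
            "transition": transition,
        })

    def _start(self) -> None:
        start = next(n for n in self.model.nodes if n.kind is NodeKind.START_EVENT)
        self._log(start.node_id, "triggered")
        for flow in self.model.outgoing(start.node_id):
            self._arrive(flow)

    def _arrive(self, flow) -> None:
        node = self.model.node(flow.target)
        kind = node.kind
        if kind in _STEP_KINDS:
            if self.task_states[node.node_id] == INACTIVE:
                self.task_states[node.node_id] = ACTIVE
                self._log(node.node_id, "activated")
        elif kind is NodeKind.XOR_GATEWAY:
            if len(self.model.outgoing(node.node_id)) > 1:
                self.pending_decisions.add(node.node_id)
                self._log(node.node_id, "decision-pending")
            else:
                self._arrive(self.model.outgoing(node.node_id)[0])
        elif kind is NodeKind.AND_GATEWAY:
            outgoing = self.model.outgoing(node.node_id)
            if len(outgoing) > 1:
                for out in outgoing:
                    self._arrive(out)
            else:
                arrived = self._join_arrivals.setdefault(node.node_id, set())
                arrived.add(flow.flow_id)
                needed = {f.flow_id for f in self.model.incoming(node.node_id)}
                if arrived == needed:
                    del self._join_arrivals[node.node_id]
                    self._arrive(outgoing[0])
        elif kind is NodeKind.SUB_PROCESS:
            self._log(node.node_id, "started")
            inner_start = next(c for c in node.children
                               if c.kind is NodeKind.START_EVENT)
            for out in self.model.outgoing(inner_start.node_id):
                self._arrive(out)
        elif kind is NodeKind.END_EVENT:
            container = self.model.parent_of(node.node_id)
            if container is None:
                self._root_ended = True
                self._log(node.node_id, "process-completed")
            else:
                self._sp_completed.add(container.node_id)
                self._log(container.node_id, "completed")
                for out in self.model.outgoing(container.node_id):
                    self._arrive(out)
        else:  # pragma: no cover - boundary events never sit on the flow path
            raise SurgflowError(f"token arrived at unexpected node {node.node_id!r}")

    def _choose(self, split_id: str, branch_idx: int) -> None:
        """Resolve a pending XOR decision to one branch; bypass the others."""
        block = self.structure.blocks[split_id]
        self.pending_decisions.discard(split_id)
        self._log(split_id, f"decided-branch-{branch_idx}")
        for j in range(len(block.branches)):
            if j == branch_idx:
                continue
            for task in self.structure.branch_tasks(block, j):
                if self.task_states[task] == INACTIVE:
                    self.task_states[task] = BYPASSED
                    self._log(task, "bypassed")
        self._arrive(self.model.outgoing(split_id)[branch_idx])

    # -- queries ------------------------------------------------------------

    def active_tasks(self) -> set[str]:
        """User tasks currently holding a token (state ``active``)."""
        return {t for t, s in self.task_states.items()
                if s == ACTIVE and self.model.node(t).kind is NodeKind.USER_TASK}

    def active_elements(self) -> set[str]:
        """Active user tasks and call activities."""
        return {t for t, s in self.task_states.items() if s == ACTIVE}

    def _state_key(self):
        return (frozenset(self.pending_decisions),
                frozenset(t for t, s in self.task_states.items() if s == ACTIVE))

    def _explore_decisions(self):
        """Yield (instance, choices) for every reachable decision resolution."""
        seen = {self._state_key()}
        frontier: list[tuple[ProcessInstance, list[tuple[str, int]]]] = [(self, [])]
        while frontier:
            inst, choices = frontier.pop(0)
            yield inst, choices
            for g in sorted(inst.pending_decisions):
                block = inst.structure.blocks[g]
                for i in range(len(block.branches)):
                    clone = inst.copy()
                    clone._choose(g, i)
                    key = clone._state_key()
                    if key not in seen:
                        seen.add(key)
                        frontier.append((clone, choices + [(g, i)]))

    def activatable_tasks(self) -> set[str]:
        """Active tasks plus tasks reachable by resolving pending decisions.

        For each pending XOR decision the first task of every branch —
        including tasks past the join when a bypass branch is taken — is
        reported, matching what a tasklist would show as startable.
        """
        result: set[str] = set()
        for inst, _ in self._explore_decisions():
            result |= inst.active_elements()
        return result

    def make_active(self, task_id: str) -> None:
        """Resolve pending decisions (if needed) so *task_id* becomes active."""
        if task_id not in self.task_states:
            raise UnknownElementError(f"unknown task {task_id!r}")
        if self.task_states[task_id] == ACTIVE:
            return
        for inst, choices in self._explore_decisions():
            if inst.task_states[task_id] == ACTIVE:
                for g, i in choices:
                    self._choose(g, i)
                return
        state = self.task_states[task_id]
        if state == BYPASSED:
            if self.model.node(task_id).optional_step:
                raise LateOptionalError(
                    f"optional task {task_id!r} was already bypassed")
            raise OutOfOrderError(f"task {task_id!r} lies on a bypassed branch")
        raise OutOfOrderError(f"task {task_id!r} is not activatable")

    def skip_pending_optionals(self) -> None:
        """Resolve every pending decision that has a bypass branch to it.

        This is the explicit counterpart of skipping optional steps: tokens
        waiting at the exclusive split of an un-run optional move through
        the empty branch, letting joins and end events fire.
        """
        changed = True
        while changed:
            changed = False
            for g in sorted(self.pending_decisions):
                block = self.structure.blocks[g]
                bypass = self.structure.bypass_branch(block)
                if bypass is not None:
                    self._choose(g, bypass)
                    changed = True

    def is_complete(self) -> bool:
        return self._root_ended

    # -- transitions --------------------------------------------------------

    def complete_task(self, task_id: str, at: float | None = None) -> "ProcessInstance":
        """Complete an active (or activatable) task and advance tokens.

        Skipping ahead or regressing is refused: completing a task that is
        neither active nor activatable raises :class:`OutOfOrderError`;
        re-completing a completed task raises :class:`RegressionError`.
        """
        if task_id not in self.task_states:
            raise UnknownElementError(f"unknown task {task_id!r}")
        state = self.task_states[task_id]
        if state == COMPLETED:
            raise RegressionError(f"task {task_id!r} already completed")
        if state != ACTIVE:
            self.make_active(task_id)  # raises OutOfOrder/LateOptional if impossible
        if at is not None:
            self.clock = max(self.clock, at)
        self.task_states[task_id] = COMPLETED
        node = self.model.node(task_id)
        if node.kind is NodeKind.USER_TASK:
            self.trace.append(task_id)
        self._log(task_id, "completed")
        if self.camunda_compat:
            self._auto_bypass_sibling_optionals(task_id)
        for out in self.model.outgoing(task_id):
            self._arrive(out)
        return self

    def _auto_bypass_sibling_optionals(self, task_id: str) -> None:
        for blk, idx in self.structure.enclosing.get(task_id, []):
            if blk.kind != "and":
                continue
            guards = self._optional_guards.get(blk.split, {})
            for j, splits in guards.items():
                if j == idx:
                    continue
                for split in splits:
                    if split in self.pending_decisions:
                        bypass = self.structure.bypass_branch(
                            self.structure.blocks[split])
                        self._choose(split, bypass)

    # -- plumbing -----------------------------------------------------------

    def copy(self) -> "ProcessInstance":
        clone = object.__new__(ProcessInstance)
        clone.model = self.model
        clone.camunda_compat = self.camunda_compat
        clone.instance_id = self.instance_id
        clone.structure = self.structure
        clone.task_states = dict(self.task_states)
        clone.pending_decisions = set(self.pending_decisions)
        clone.trace = self.trace.copy()
        clone.clock = self.clock
        clone.events = list(self.events)
        clone._join_arrivals = {k: set(v) for k, v in self._join_arrivals.items()}
        clone._sp_completed = set(self._sp_completed)
        clone._root_ended = self._root_ended
        clone._optional_guards = self._optional_guards
        return clone

    def state_snapshot(self) -> tuple:
        """Hashable snapshot of all runtime state (used for idempotence tests)."""
        return (
            tuple(sorted(self.task_states.items())),
            frozenset(self.pending_decisions),
            tuple(sorted((k, frozenset(v)) for k, v in self._join_arrivals.items())),
            frozenset(self._sp_completed),
            self._root_ended,
            self.trace.as_tuple(),
        )


def start_process(model: ProcessModel, camunda_compat: bool = True) -> ProcessInstance:
    """Start a process: tokens advance until resting on user tasks."""
    return ProcessInstance(model, camunda_compat=camunda_compat)


def replay(model: ProcessModel, trace, camunda_compat: bool = True) -> ProcessInstance:
    """Replay a trace prefix on a fresh instance.

    Raises :class:`ReplayError` if the prefix is not accepted.
    """
    inst = start_process(model, camunda_compat=camunda_compat)
    for step in trace:
        try:
            inst.complete_task(step)
        except SurgflowError as exc:
            raise ReplayError(f"trace prefix invalid at {step!r}: {exc}") from exc
    return inst
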