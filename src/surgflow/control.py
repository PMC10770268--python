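"""Driving an executing model from recognized situations.

The controller implements the *process situation knowledge* loop: every
observation is interpreted (see :mod:`surgflow.recognition`), and the step
recognized with the highest probability is treated as the situation that is
now starting.  The controller then

1. secures the recognized step on the runtime — resolving an exclusive
   decision so its token can rest on the step (BPMN) or manually starting an
   enabled optional item (CMMN);
2. completes the previously started steps that the model says precede it —
   "the matching running task is completed, so that the next possible
   user/human tasks are activated automatically";
3. performs the bookkeeping the notation requires: manually completing
   stages blocked by un-run optional items, completing and closing cases,
   and advancing the root process over call activities in combination
   models.

Every attempt runs on a copy of the runtime: a refused observation leaves
the runtime state bit-identical and surfaces as a refusal row in the
session report, never as a partial state change.  Tolerance policy lives
here, not in the engines: repeating the current step is a no-op, and (for
case models) candidates in the first stage can bypass the reasonableness
veto, reflecting the shallower plausibility checking reported for case
control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import knowledge as pk_mod
from .bpmn import ProcessInstance, start_process
from .cmmn import CaseInstance, start_case
from .config import RunConfig
from .errors import EngineError, ReplayError, SurgflowError
from .model import CaseModel, CombinationModel, ItemKind, NodeKind, ProcessModel
from .recognition import ImpactConfig, SensorObservation, SituationRule, fuse

__all__ = [
    "ControlAction",
    "SessionReport",
    "make_runtime",
    "step_controller",
    "run_session",
]


@dataclass(frozen=True)
class ControlAction:
    kind: str  # complete_task | manual_start | complete_stage | complete_case
    #        | close_case | enter_call_activity | none
    element: str = ""
    reason: str = ""


# ---------------------------------------------------------------------------
# runtime adapters
# ---------------------------------------------------------------------------


class BpmnRuntime:
    """Adapter driving a BPMN :class:`ProcessInstance`."""

    notation = "bpmn"

    def __init__(self, model: ProcessModel, config: RunConfig):
        self.model = model
        self.instance = start_process(model, camunda_compat=config.camunda_compat)

    def copy(self):
        clone = object.__new__(BpmnRuntime)
        clone.model = self.model
        clone.instance = self.instance.copy()
        return clone

    def possible_steps(self) -> set[str]:
        return self.instance.activatable_tasks()

    def step_completed(self, step: str) -> bool:
        return self.instance.task_states.get(step) == "completed"

    def try_start(self, step: str, at=None) -> list[ControlAction]:
        self.instance.make_active(step)
        return []

    def complete_step(self, step: str, at=None) -> list[ControlAction]:
        self.instance.complete_task(step, at=at)
        return [ControlAction("complete_task", step)]

    def bookkeeping_toward(self, step: str, at=None) -> list[ControlAction]:
        return []  # token movement is fully automatic in BPMN

    def finalize(self, at=None) -> list[ControlAction]:
        self.instance.skip_pending_optionals()
        return []

    def first_stage_items(self) -> set[str]:
        return set()

    def is_done(self) -> bool:
        return self.instance.is_complete()

    def trace(self):
        return self.instance.trace

    def snapshot(self):
        return self.instance.state_snapshot()

    def events(self):
        return self.instance.events


class CmmnRuntime:
    """Adapter driving a CMMN :class:`CaseInstance`."""

    notation = "cmmn"

    def __init__(self, case: CaseModel, config: RunConfig):
        self.case = case
        self.instance = start_case(case)

    def copy(self):
        clone = object.__new__(CmmnRuntime)
        clone.case = self.case
        clone.instance = self.instance.copy()
        return clone

    def possible_steps(self) -> set[str]:
        return self.instance.startable_tasks()

    def step_completed(self, step: str) -> bool:
        return self.instance.item_states.get(step) == "completed"

    def try_start(self, step: str, at=None) -> list[ControlAction]:
        state = self.instance.item_states.get(step)
        if state == "active":
            return []
        if state == "enabled":
            self.instance.manually_start(step, at=at)
            return [ControlAction("manual_start", step)]
        raise EngineError(f"item {step!r} is not startable (state {state!r})")

    def complete_step(self, step: str, at=None) -> list[ControlAction]:
        actions = []
        if self.instance.item_states.get(step) == "enabled":
            self.instance.manually_start(step, at=at)
            actions.append(ControlAction("manual_start", step))
        self.instance.complete_task(step, at=at)
        actions.append(ControlAction("complete_task", step))
        return actions

    def bookkeeping_toward(self, step: str, at=None) -> list[ControlAction]:
        """Manually complete stages blocked by un-run optionals until *step*
        becomes startable."""
        actions: list[ControlAction] = []
        while self.instance.item_states.get(step) == "available":
            stage_id = self._completable_stage(exclude_member=step)
            if stage_id is None:
                raise EngineError(f"item {step!r} cannot be made startable")
            self.instance.complete_stage(stage_id, at=at)
            actions.append(ControlAction("complete_stage", stage_id))
        return actions

    def _completable_stage(self, exclude_member: str | None = None) -> str | None:
        inst = self.instance
        for stage in inst.case.stages():
            if inst.item_states[stage.item_id] != "active":
                continue
            children = inst._children(stage)
            if exclude_member and any(c.item_id == exclude_member for c in children):
                continue
            if any(inst.item_states[c.item_id] == "active" for c in children):
                continue
            if all(inst.item_states[c.item_id] == "completed"
                   for c in children if c.required):
                return stage.item_id
        return None

    def finalize(self, at=None) -> list[ControlAction]:
        """Complete blocked stages, then complete and close the case."""
        actions: list[ControlAction] = []
        while True:
            stage_id = self._completable_stage()
            if stage_id is None:
                break
            self.instance.complete_stage(stage_id, at=at)
            actions.append(ControlAction("complete_stage", stage_id))
        self.instance.complete_case(at=at)
        actions.append(ControlAction("complete_case", self.case.case_id))
        self.instance.close_case(at=at)
        actions.append(ControlAction("close_case", self.case.case_id))
        return actions

    def first_stage_items(self) -> set[str]:
        return self.instance.first_stage_items()

    def is_done(self) -> bool:
        return self.instance.is_closed()

    def trace(self):
        return self.instance.trace

    def snapshot(self):
        return self.instance.state_snapshot()

    def events(self):
        return self.instance.events


class CombinationRuntime:
    """Adapter driving a BPMN root whose call activities refer to cases."""

    notation = "combination"

    def __init__(self, comb: CombinationModel, config: RunConfig):
        self.comb = comb
        self.process = start_process(comb.root, camunda_compat=config.camunda_compat)
        self.cases: dict[str, CaseInstance] = {}
        self._auto_actions: list[ControlAction] = []
        self._auto_enter()

    def copy(self):
        clone = object.__new__(CombinationRuntime)
        clone.comb = self.comb
        clone.process = self.process.copy()
        clone.cases = {k: v.copy() for k, v in self.cases.items()}
        clone._auto_actions = list(self._auto_actions)
        return clone

    def drain_auto_actions(self) -> list[ControlAction]:
        actions, self._auto_actions = self._auto_actions, []
        return actions

    def _auto_enter(self) -> None:
        """The root token jumps to call activities automatically; entering
        one starts the referenced case."""
        for ca in sorted(self.process.active_elements()):
            node = self.comb.root.node(ca)
            if node.kind is NodeKind.CALL_ACTIVITY and node.called_case not in self.cases:
                self.cases[node.called_case] = start_case(
                    self.comb.cases[node.called_case])
                self._auto_actions.append(
                    ControlAction("enter_call_activity", ca))

    def _locate(self, step: str) -> str | None:
        """Case id holding *step*, or None for a root-level step."""
        if self.comb.root.has_node(step):
            return None
        return self.comb.case_of(step)

    def _case_runtime(self, case_id: str) -> CmmnRuntime:
        rt = object.__new__(CmmnRuntime)
        rt.case = self.comb.cases[case_id]
        rt.instance = self.cases[case_id]
        return rt

    def possible_steps(self) -> set[str]:
        steps: set[str] = set()
        for ca in self.process.active_elements():
            node = self.comb.root.node(ca)
            if node.kind is NodeKind.USER_TASK:
                steps.add(ca)
            elif node.called_case in self.cases:
                steps |= self.cases[node.called_case].startable_tasks()
        return steps

    def step_completed(self, step: str) -> bool:
        cid = self._locate(step)
        if cid is None:
            return self.process.task_states.get(step) == "completed"
        inst = self.cases.get(cid)
        return inst is not None and inst.item_states.get(step) == "completed"

    def try_start(self, step: str, at=None) -> list[ControlAction]:
        cid = self._locate(step)
        if cid is None:
            self.process.make_active(step)
            return []
        if cid not in self.cases:
            raise EngineError(f"case {cid!r} for step {step!r} not entered yet")
        return self._case_runtime(cid).try_start(step, at=at)

    def complete_step(self, step: str, at=None) -> list[ControlAction]:
        cid = self._locate(step)
        if cid is None:
            self.process.complete_task(step, at=at)
            self._auto_enter()
            return [ControlAction("complete_task", step)] + self.drain_auto_actions()
        if cid not in self.cases:
            raise EngineError(f"case {cid!r} for step {step!r} not entered yet")
        return self._case_runtime(cid).complete_step(step, at=at)

    def bookkeeping_toward(self, step: str, at=None) -> list[ControlAction]:
        """Close out running cases (and advance the root) until *step* is
        startable in its own, newly entered case."""
        actions: list[ControlAction] = []
        target = self._locate(step)
        self._auto_enter()
        actions += self.drain_auto_actions()
        for _ in range(len(self.comb.cases) + 2):
            if target is not None and target in self.cases:
                inst = self.cases[target]
                if inst.item_states.get(step) in ("active", "enabled"):
                    return actions
                rt = self._case_runtime(target)
                return actions + rt.bookkeeping_toward(step, at=at)
            if target is None and self.process.task_states.get(step) != "inactive":
                return actions
            actions += self._close_current_case(at=at)
        raise EngineError(f"step {step!r} cannot be reached")

    def _close_current_case(self, at=None) -> list[ControlAction]:
        for ca in sorted(self.process.active_elements()):
            node = self.comb.root.node(ca)
            if node.kind is not NodeKind.CALL_ACTIVITY:
                continue
            inst = self.cases.get(node.called_case)
            if inst is None or inst.is_closed():
                continue
            rt = self._case_runtime(node.called_case)
            actions = rt.finalize(at=at)
            self.process.complete_task(ca, at=at)
            self._auto_enter()
            return actions + self.drain_auto_actions()
        raise EngineError("no running case to close")

    def finalize(self, at=None) -> list[ControlAction]:
        actions: list[ControlAction] = []
        while not self.process.is_complete():
            actions += self._close_current_case(at=at)
        return actions

    def first_stage_items(self) -> set[str]:
        # the tolerance only applies when the intervention *starts* in a case
        root = self.comb.root
        start = next(n for n in root.nodes if n.kind is NodeKind.START_EVENT)
        out = root.outgoing(start.node_id)
        if not out:
            return set()
        first = root.node(out[0].target)
        if first.kind is not NodeKind.CALL_ACTIVITY or first.called_case is None:
            return set()
        return {i.item_id for i in self.comb.cases[first.called_case].iter_items()
                if i.kind is ItemKind.HUMAN_TASK}

    def is_done(self) -> bool:
        return self.process.is_complete()

    def trace(self):
        from .model import Trace
        merged: list[str] = []
        # completed-step order is preserved per case; cases run sequentially
        events = []
        for inst in self.cases.values():
            for e in inst.events:
                if e["transition"] == "completed" and inst.case.has_item(e["element"]):
                    if inst.case.item(e["element"]).kind is ItemKind.HUMAN_TASK:
                        events.append((e["clock"], len(events), e["element"], inst))
        # rebuild global order from per-case traces in case entry order
        order: list[str] = []
        for ca in self._root_sequence():
            node = self.comb.root.node(ca)
            if node.kind is NodeKind.USER_TASK:
                if self.process.task_states.get(ca) == "completed":
                    order.append(ca)
            elif node.called_case in self.cases:
                order.extend(self.cases[node.called_case].trace)
        return Trace(order)

    def _root_sequence(self) -> list[str]:
        """Root steps / call activities in modeled order."""
        out = []
        structure = self.process.structure
        from .structure import Sequence, TaskLeaf, Block, SubProcessRegion

        def walk(seq):
            for item in seq.items:
                if isinstance(item, TaskLeaf):
                    out.append(item.node.node_id)
                elif isinstance(item, SubProcessRegion):
                    walk(item.body)
                elif isinstance(item, Block):
                    for b in item.branches:
                        walk(b)
        walk(structure.root)
        return out

    def snapshot(self):
        return (self.process.state_snapshot(),
                tuple(sorted((k, v.state_snapshot()) for k, v in self.cases.items())))

    def events(self):
        evs = list(self.process.events)
        for inst in self.cases.values():
            evs.extend(inst.events)
        return sorted(evs, key=lambda e: e["clock"])


def make_runtime(model, config: RunConfig | None = None):
    config = config or RunConfig()
    if isinstance(model, ProcessModel):
        return BpmnRuntime(model, config)
    if isinstance(model, CaseModel):
        return CmmnRuntime(model, config)
    if isinstance(model, CombinationModel):
        return CombinationRuntime(model, config)
    raise TypeError(f"cannot build a runtime for {type(model).__name__}")


# ---------------------------------------------------------------------------
# controller
# ---------------------------------------------------------------------------


def _step_bypassed(runtime, step: str) -> bool:
    if isinstance(runtime, BpmnRuntime):
        return runtime.instance.task_states.get(step) == "bypassed"
    if isinstance(runtime, CombinationRuntime):
        cid = runtime._locate(step)
        if cid is None:
            return runtime.process.task_states.get(step) == "bypassed"
        inst = runtime.cases.get(cid)
        return inst is not None and inst.item_states.get(step) == "disabled"
    return runtime.instance.item_states.get(step) == "disabled"


def _try_start_guarded(runtime, best: str, started: list[str], at=None):
    """Try securing *best* on a copy of *runtime*.

    Returns ``(actions, new_runtime)`` on success, ``None`` on failure.  A
    start that would bypass a previously started (observed, uncompleted)
    step — stealing an exclusive decision already committed by observation —
    counts as failure: the second path of an exclusive choice must be
    refused, not silently selected.
    """
    probe = runtime.copy()
    try:
        actions = probe.try_start(best, at=at)
    except SurgflowError:
        return None
    for t in started:
        if t != best and _step_bypassed(probe, t) and not _step_bypassed(runtime, t):
            return None
    return actions, probe


def _attempt(runtime, best: str, started: list[str], at=None):
    """Secure *best*, completing predecessors and doing stage / case
    bookkeeping as needed.  Returns ``(actions, new_runtime)``; raises on
    refusal.  The input runtime is never mutated."""
    if runtime.step_completed(best):
        raise EngineError(f"step {best!r} was already completed (regression)")
    res = _try_start_guarded(runtime, best, started, at=at)
    if res is not None:
        return res
    # the previously started situations have ended; complete them in
    # observation order
    rt = runtime.copy()
    actions: list[ControlAction] = []
    for t in started:
        if t != best and not rt.step_completed(t):
            actions += rt.complete_step(t, at=at)
    if hasattr(rt, "drain_auto_actions"):
        actions += rt.drain_auto_actions()
    res = _try_start_guarded(rt, best, started, at=at)
    if res is not None:
        return actions + res[0], res[1]
    actions += rt.bookkeeping_toward(best, at=at)
    res = _try_start_guarded(rt, best, started, at=at)
    if res is None:
        raise EngineError(f"step {best!r} is not startable")
    return actions + res[0], res[1]


def step_controller(sk, runtime, started: list[str] | None = None,
                    at=None, first_stage_tolerant: bool = True):
    """One control decision for a recognized situation.

    Returns ``(actions, runtime)``; the input runtime is never mutated.  A
    non-reasonable candidate yields a single ``none`` action with the
    refusal reason and the unchanged runtime.
    """
    started = list(started or [])
    if sk.best is None:
        return [ControlAction("none", reason="no-evidence")], runtime
    if sk.best in started and not runtime.step_completed(sk.best):
        # the recognized situation is still running: a repetition, not a
        # regression — tolerated without any control action
        return [ControlAction("none", sk.best, reason="repetition")], runtime
    try:
        return _attempt(runtime, sk.best, started, at=at)
    except SurgflowError as exc:
        if first_stage_tolerant and sk.best in runtime.first_stage_items():
            return [ControlAction("none", sk.best,
                                  reason="first-stage-tolerated")], runtime
        return [ControlAction("none", sk.best,
                              reason=f"unreasonable: {exc}")], runtime


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


@dataclass
class SessionReport:
    rows: list[dict] = field(default_factory=list)
    refusals: int = 0
    complete: bool = False
    trace: list[str] = field(default_factory=list)
    duration: pk_mod.DurationEstimate | None = None
    flush_actions: list[ControlAction] = field(default_factory=list)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")
            fh.write(json.dumps({
                "summary": True,
                "complete": self.complete,
                "refusals": self.refusals,
                "trace": self.trace,
            }) + "\n")

    def summary(self) -> str:
        lines = [
            f"{'time':>8}  {'recognized':<40} {'ok':<3} actions",
            "-" * 78,
        ]
        for row in self.rows:
            ok = "yes" if row["accepted"] else "NO"
            acts = "; ".join(a["kind"] + (":" + a["element"] if a["element"] else "")
                             for a in row["actions"]) or "-"
            lines.append(f"{row['time']:>8.1f}  {str(row['best']):<40} {ok:<3} {acts}")
        lines.append("-" * 78)
        status = "complete" if self.complete else "INCOMPLETE"
        lines.append(f"session {status}; {self.refusals} refusal(s); "
                     f"{len(self.trace)} steps completed")
        if self.duration is not None:
            lines.append(f"RSD {self.duration.rsd:.0f} min, "
                         f"delay {self.duration.delay:+.0f} min")
        return "\n".join(lines)


def _prior_steps(runtime, knowledge_model, config) -> set[str]:
    if config.knowledge_source == "bpmn" and knowledge_model is not None:
        try:
            return pk_mod.dynamic_next_steps(
                knowledge_model, runtime.trace(),
                camunda_compat=config.camunda_compat)
        except (ReplayError, SurgflowError):
            pass  # executed course diverged from the structured variant
    return runtime.possible_steps()


def run_session(model, stream, rules: list[SituationRule],
                config: RunConfig | None = None,
                knowledge_model: ProcessModel | None = None) -> SessionReport:
    """Run a full recognition-and-control session over an observation stream.

    *model* is the variant to control (process, case, or combination);
    *knowledge_model* is the structured (BPMN) variant used as the process-
    knowledge source when available.  All anomalies become report rows.
    """
    config = config or RunConfig()
    impact = ImpactConfig(sensor_weight=config.sensor_weight)
    if knowledge_model is None and isinstance(model, ProcessModel):
        knowledge_model = model
    runtime = make_runtime(model, config)
    if hasattr(runtime, "drain_auto_actions"):
        runtime.drain_auto_actions()
    report = SessionReport()
    started: list[str] = []
    last_time = 0.0

    for obs in stream:
        if isinstance(obs, dict):
            obs = SensorObservation.from_dict(obs)
        last_time = max(last_time, obs.time)
        from .recognition import score_sensors
        sensor_scores = score_sensors(obs, rules)
        prior = _prior_steps(runtime, knowledge_model, config)
        pk = pk_mod.ProcessKnowledge(next_steps=prior,
                                     source_model=getattr(knowledge_model, "model_id", ""))
        current = started[-1] if started else None
        sk = fuse(sensor_scores, pk, impact, current=current)
        actions, new_runtime = step_controller(
            sk, runtime, started, at=obs.time,
            first_stage_tolerant=config.first_stage_tolerant)
        accepted = new_runtime is not runtime or (
            actions and actions[0].reason in ("repetition",))
        refused = bool(actions) and actions[0].kind == "none" and \
            actions[0].reason.startswith("unreasonable")
        if new_runtime is not runtime:
            runtime = new_runtime
            started = [t for t in started if not runtime.step_completed(t)]
            started.append(sk.best)
        if refused:
            report.refusals += 1
        report.rows.append({
            "time": obs.time,
            "best": sk.best,
            "probability": round(sk.best_probability, 6),
            "accepted": bool(accepted),
            "actions": [{"kind": a.kind, "element": a.element, "reason": a.reason}
                        for a in actions],
        })

    # end of stream: the started situations have ended; wind the model down
    try:
        for t in list(started):
            if not runtime.step_completed(t):
                report.flush_actions += runtime.complete_step(t, at=last_time)
        report.flush_actions += runtime.finalize(at=last_time)
    except SurgflowError:
        pass  # incomplete sessions are reported, not raised
    report.complete = runtime.is_done()
    report.trace = list(runtime.trace())
    if knowledge_model is not None:
        report.duration = pk_mod.remaining_duration(
            knowledge_model, runtime.trace(), clock=last_time)
    return report
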