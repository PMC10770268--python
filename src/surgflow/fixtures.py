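"""Synthetic intervention fixtures: models, situation rules, sensor streams.

Two intervention families are generated, mirroring the study setup this
engine targets:

* **RAMIE** (robot-assisted minimally invasive esophagectomy): nine phases
  with steps in variable order, optional steps, and one exclusive choice of
  anastomosis technique.  Its simulated sensor channel is instrument usage
  plus actor positions.  The phase/step names are clinically plausible
  placeholders, not a validated surgical process model.
* **CI** (cochlea implantation): five phases — preparation, access,
  operation under and after the microscope, follow-up — more linear, with
  an implant-dependent exclusive path.  Its simulated sensor channel is the
  step name itself.

From one :class:`InterventionSpec`, four model variants are built with
identical step-id sets: a two-granularity BPMN (phases as sub-processes;
variable groups as AND blocks, optional steps as XOR bypasses, exclusive
paths as XOR branches), a two-granularity CMMN (phases as stages; ordering
via sentries; optional steps and exclusive branches as not-required,
manually activated items — deliberately reproducing that a case model
cannot distinguish "one path" from "any subset of paths"), and a mixed and
a structured BPMN+CMMN combination.

Observation streams are sampled deterministically from a seed: a valid
stream replays one accepted order; each distortion kind injects exactly one
anomaly class (skipping a required or optional step, regression,
repetition, a second exclusive path, or a delayed optional).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from .errors import ModelValidationError
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
from .recognition import SensorObservation, SituationRule
from .structure import ModelStructure

__all__ = [
    "StepSpec",
    "PhaseSpec",
    "InterventionSpec",
    "Scenario",
    "SCENARIO_KINDS",
    "ModelBundle",
    "ramie_spec",
    "ci_spec",
    "minimal_spec",
    "build_models",
    "build_rules",
    "simulate_stream",
    "sample_valid_trace",
    "write_stream",
    "read_stream",
]

SCENARIO_KINDS = (
    "valid",
    "shuffled_variable",
    "skip_required",
    "skip_optional",
    "regress",
    "repeat",
    "wrong_path",
    "delayed_optional",
)

DEFAULT_DURATION = 10.0  # minutes per step keeps RSD arithmetic legible


@dataclass(frozen=True)
class StepSpec:
    slug: str
    optional: bool = False
    variable_group: str | None = None
    exclusive_group: str | None = None
    branch: int = 0
    duration: float = DEFAULT_DURATION

    @property
    def name(self) -> str:
        return self.slug.replace("_", " ")


@dataclass(frozen=True)
class PhaseSpec:
    slug: str
    steps: tuple[StepSpec, ...]

    @property
    def name(self) -> str:
        return self.slug.replace("_", " ")


@dataclass(frozen=True)
class InterventionSpec:
    name: str
    phases: tuple[PhaseSpec, ...]
    label_based: bool = False  # True: streams carry step names directly
    instruments: tuple[str, ...] = ()
    zones: tuple[str, ...] = ()
    actors: tuple[str, ...] = ("surgeon", "assistant")

    # -- identifiers --------------------------------------------------------

    def phase_id(self, p: int) -> str:
        return f"phase_{p + 1:02d}_{self.phases[p].slug}"

    def step_id(self, p: int, s: int) -> str:
        return f"s{p + 1:02d}_{s + 1:02d}_{self.phases[p].steps[s].slug}"

    def step_table(self) -> list[tuple[str, int, int, StepSpec]]:
        """(step id, phase index, step index, spec) in modeled order."""
        out = []
        for p, phase in enumerate(self.phases):
            for s, step in enumerate(phase.steps):
                out.append((self.step_id(p, s), p, s, step))
        return out

    def step_ids(self) -> list[str]:
        return [sid for sid, *_ in self.step_table()]

    def durations(self) -> dict[str, float]:
        return {sid: st.duration for sid, _, _, st in self.step_table()}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        problems = []
        if not self.phases:
            problems.append("at least one phase required")
        groups: dict[str, int] = {}
        branches: dict[str, set[int]] = {}
        for _, _, _, st in self.step_table():
            if st.variable_group and st.exclusive_group:
                problems.append(f"step {st.slug!r} in both group kinds")
            if st.variable_group:
                groups[st.variable_group] = groups.get(st.variable_group, 0) + 1
            if st.exclusive_group:
                branches.setdefault(st.exclusive_group, set()).add(st.branch)
        for g, n in groups.items():
            if n < 2:
                problems.append(f"variable group {g!r} needs >= 2 members")
        for g, b in branches.items():
            if len(b) < 2:
                problems.append(f"exclusive group {g!r} needs >= 2 branches")
        ids = self.step_ids()
        if len(ids) != len(set(ids)):
            problems.append("duplicate step ids")
        if not self.label_based and len(self.instruments) < 2:
            problems.append("instrument-based spec needs an instrument vocabulary")
        if problems:
            raise ModelValidationError(f"invalid intervention spec {self.name!r}",
                                       problems)


@dataclass(frozen=True)
class Scenario:
    kind: str
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")


@dataclass
class ModelBundle:
    spec: InterventionSpec
    bpmn: ProcessModel
    cmmn: CaseModel
    mixed: CombinationModel
    structured: CombinationModel

    def variant(self, name: str):
        return {"bpmn": self.bpmn, "cmmn": self.cmmn,
                "mixed": self.mixed, "structured": self.structured}[name]


# ---------------------------------------------------------------------------
# intervention specifications
# ---------------------------------------------------------------------------


def ramie_spec() -> InterventionSpec:
    """Nine-phase esophagectomy fixture with variable and optional steps."""
    P, S = PhaseSpec, StepSpec
    spec = InterventionSpec(
        name="ramie",
        phases=(
            P("preparation", (S("patient_positioning"), S("sterile_draping"))),
            P("abdominal_access", (
                S("port_placement"), S("robot_docking"),
                S("diagnostic_laparoscopy", optional=True))),
            P("gastric_mobilization", (
                S("greater_curvature_dissection", variable_group="mobilization"),
                S("lesser_curvature_dissection", variable_group="mobilization"),
                S("hiatal_dissection", optional=True, variable_group="mobilization"),
                S("left_gastric_pedicle_division"))),
            P("gastric_conduit", (
                S("gastric_tube_formation"), S("leak_test", optional=True))),
            P("abdominal_lymphadenectomy", (
                S("celiac_lymphadenectomy", variable_group="abd_lnd"),
                S("hepatoduodenal_lymphadenectomy", variable_group="abd_lnd"),
                S("hemostasis_check"))),
            P("thoracic_access", (S("repositioning"), S("thoracic_port_placement"))),
            P("esophageal_dissection", (
                S("esophageal_mobilization"),
                S("thoracic_duct_clipping", optional=True),
                S("mediastinal_lymphadenectomy"))),
            P("anastomosis", (
                S("circular_stapler_anastomosis", exclusive_group="technique", branch=0),
                S("hand_sewn_anastomosis", exclusive_group="technique", branch=1),
                S("anastomosis_check"))),
            P("closure", (S("drain_placement", optional=True), S("wound_closure"))),
        ),
        label_based=False,
        instruments=("grasper", "scissors", "clip_applier", "stapler", "hook",
                     "needle_driver", "suction", "retractor"),
        zones=("abdomen_left", "abdomen_right", "thorax", "console", "periphery"),
    )
    spec.validate()
    return spec


def ci_spec() -> InterventionSpec:
    """Five-phase cochlea-implantation fixture; streams carry step names."""
    P, S = PhaseSpec, StepSpec
    spec = InterventionSpec(
        name="ci",
        phases=(
            P("preparation", (S("patient_positioning"), S("sterile_draping"))),
            P("access", (S("skin_incision"), S("mastoidectomy"),
                         S("posterior_tympanotomy"))),
            P("operation_under_microscope", (
                S("round_window_insertion", exclusive_group="insertion_route", branch=0),
                S("cochleostomy_drilling", exclusive_group="insertion_route", branch=1),
                S("electrode_insertion"))),
            P("operation_after_microscope", (
                S("electrode_testing", variable_group="testing"),
                S("impedance_measurement", optional=True, variable_group="testing"),
                S("electrode_fixation"))),
            P("follow_up", (S("wound_closure"), S("bandage_application"))),
        ),
        label_based=True,
        instruments=("drill", "forceps", "elevator", "suction"),
        zones=("head_left", "head_right", "microscope", "periphery"),
    )
    spec.validate()
    return spec


def minimal_spec(n_steps: int = 2) -> InterventionSpec:
    """A one-phase chain of required steps; handy for desk checks."""
    spec = InterventionSpec(
        name="minimal",
        phases=(PhaseSpec("only_phase",
                          tuple(StepSpec(f"step_{i + 1}") for i in range(n_steps))),),
        label_based=True,
        instruments=("probe", "clamp"),
        zones=("table",),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# units: contiguous runs of grouped steps
# ---------------------------------------------------------------------------


def _units(spec: InterventionSpec, p: int):
    """Partition a phase's steps into units: ("step"|"var"|"xor", [(sid, spec)])."""
    steps = spec.phases[p].steps
    out = []
    i = 0
    while i < len(steps):
        st = steps[i]
        if st.variable_group:
            j = i
            while j < len(steps) and steps[j].variable_group == st.variable_group:
                j += 1
            out.append(("var", [(spec.step_id(p, k), steps[k]) for k in range(i, j)]))
            i = j
        elif st.exclusive_group:
            j = i
            while j < len(steps) and steps[j].exclusive_group == st.exclusive_group:
                j += 1
            out.append(("xor", [(spec.step_id(p, k), steps[k]) for k in range(i, j)]))
            i = j
        else:
            out.append(("step", [(spec.step_id(p, i), st)]))
            i += 1
    return out


# ---------------------------------------------------------------------------
# BPMN construction
# ---------------------------------------------------------------------------


class _FlowFactory:
    def __init__(self):
        self.flows: list[SequenceFlow] = []
        self._n = 0

    def add(self, src: str, tgt: str, label: str = "") -> None:
        self._n += 1
        self.flows.append(SequenceFlow(f"f{self._n:03d}", src, tgt, label))


def _task_node(sid: str, st: StepSpec) -> FlowNode:
    return FlowNode(sid, NodeKind.USER_TASK, name=st.name,
                    expected_duration=st.duration)


def _emit_unit(kind: str, members, ff: _FlowFactory, entry: str,
               uid: str) -> tuple[list[FlowNode], str]:
    """Emit nodes for one unit, wiring from *entry*; returns (nodes, exit id)."""
    nodes: list[FlowNode] = []
    if kind == "step":
        sid, st = members[0]
        if not st.optional:
            nodes.append(_task_node(sid, st))
            ff.add(entry, sid)
            return nodes, sid
        split, join = f"xor_{uid}_split", f"xor_{uid}_join"
        nodes += [FlowNode(split, NodeKind.XOR_GATEWAY),
                  _task_node(sid, st),
                  FlowNode(join, NodeKind.XOR_GATEWAY)]
        ff.add(entry, split)
        ff.add(split, sid, label=st.name)
        ff.add(sid, join)
        ff.add(split, join, label="skip")
        return nodes, join
    if kind == "var":
        split, join = f"and_{uid}_split", f"and_{uid}_join"
        nodes += [FlowNode(split, NodeKind.AND_GATEWAY),
                  FlowNode(join, NodeKind.AND_GATEWAY)]
        ff.add(entry, split)
        for sid, st in members:
            if st.optional:
                xs, xj = f"xor_{sid}_split", f"xor_{sid}_join"
                nodes += [FlowNode(xs, NodeKind.XOR_GATEWAY),
                          _task_node(sid, st),
                          FlowNode(xj, NodeKind.XOR_GATEWAY)]
                ff.add(split, xs)
                ff.add(xs, sid, label=st.name)
                ff.add(sid, xj)
                ff.add(xs, xj, label="skip")
                ff.add(xj, join)
            else:
                nodes.append(_task_node(sid, st))
                ff.add(split, sid)
                ff.add(sid, join)
        return nodes, join
    # exclusive paths
    split, join = f"xor_{uid}_split", f"xor_{uid}_join"
    nodes += [FlowNode(split, NodeKind.XOR_GATEWAY),
              FlowNode(join, NodeKind.XOR_GATEWAY)]
    ff.add(entry, split)
    by_branch: dict[int, list] = {}
    for sid, st in members:
        by_branch.setdefault(st.branch, []).append((sid, st))
    for b in sorted(by_branch):
        prev = None
        for sid, st in by_branch[b]:
            nodes.append(_task_node(sid, st))
            ff.add(prev if prev else split, sid,
                   label="" if prev else f"path_{b}")
            prev = sid
        ff.add(prev, join)
    return nodes, join


def _emit_phase_children(spec: InterventionSpec, p: int,
                         ff: _FlowFactory) -> list[FlowNode]:
    pid = spec.phase_id(p)
    start, end = f"{pid}_start", f"{pid}_end"
    nodes: list[FlowNode] = [FlowNode(start, NodeKind.START_EVENT)]
    entry = start
    for u, (kind, members) in enumerate(_units(spec, p)):
        unit_nodes, entry = _emit_unit(kind, members, ff, entry,
                                       uid=f"{pid}_u{u + 1}")
        nodes += unit_nodes
    nodes.append(FlowNode(end, NodeKind.END_EVENT))
    ff.add(entry, end)
    return nodes


def build_bpmn(spec: InterventionSpec) -> ProcessModel:
    """Two-granularity BPMN: one sub-process per phase."""
    ff = _FlowFactory()
    nodes: list[FlowNode] = [FlowNode("root_start", NodeKind.START_EVENT)]
    entry = "root_start"
    for p in range(len(spec.phases)):
        pid = spec.phase_id(p)
        sp = FlowNode(pid, NodeKind.SUB_PROCESS, name=spec.phases[p].name,
                      children=_emit_phase_children(spec, p, ff))
        nodes.append(sp)
        ff.add(entry, pid)
        entry = pid
    nodes.append(FlowNode("root_end", NodeKind.END_EVENT))
    ff.add(entry, "root_end")
    model = ProcessModel(model_id=f"{spec.name}_bpmn", name=spec.name,
                         nodes=nodes, flows=ff.flows, granularity="two_level")
    model.validate()
    ModelStructure(model).mark_optional_steps()
    return model


# ---------------------------------------------------------------------------
# CMMN construction
# ---------------------------------------------------------------------------


def _phase_items(spec: InterventionSpec, p: int) -> list[PlanItem]:
    """Plan items of one phase: sentries encode the anchored ordering.

    Optional items (and exclusive branches, which become optional siblings)
    never join the anchor, so following steps depend only on required
    predecessors — the deliberate looseness of the case variant.
    """
    items: list[PlanItem] = []
    anchor: list[str] = []

    def sentry_for(sid: str, sources: list[str]) -> list[Sentry]:
        if not sources:
            return []
        return [Sentry(f"sn_{sid}", [(src, "complete") for src in sources])]

    for kind, members in _units(spec, p):
        if kind == "step":
            sid, st = members[0]
            items.append(PlanItem(
                item_id=sid, kind=ItemKind.HUMAN_TASK, name=st.name,
                required=not st.optional, manual_activation=st.optional,
                entry_criteria=sentry_for(sid, anchor),
                expected_duration=st.duration))
            if not st.optional:
                anchor = [sid]
        elif kind == "var":
            for sid, st in members:
                items.append(PlanItem(
                    item_id=sid, kind=ItemKind.HUMAN_TASK, name=st.name,
                    required=not st.optional, manual_activation=st.optional,
                    entry_criteria=sentry_for(sid, anchor),
                    expected_duration=st.duration))
            anchor = [sid for sid, st in members if not st.optional]
        else:  # exclusive paths become optional siblings
            by_branch: dict[int, list] = {}
            for sid, st in members:
                by_branch.setdefault(st.branch, []).append((sid, st))
            for b in sorted(by_branch):
                prev: list[str] = anchor
                for sid, st in by_branch[b]:
                    items.append(PlanItem(
                        item_id=sid, kind=ItemKind.HUMAN_TASK, name=st.name,
                        required=False, manual_activation=True,
                        entry_criteria=sentry_for(sid, prev),
                        expected_duration=st.duration))
                    prev = [sid]
            # anchor unchanged: the next step follows the pre-choice anchor
    return items


def build_cmmn(spec: InterventionSpec) -> CaseModel:
    """Two-granularity CMMN: one stage per phase, chained by sentries."""
    stages: list[PlanItem] = []
    prev_stage: str | None = None
    for p in range(len(spec.phases)):
        pid = spec.phase_id(p)
        entry = ([] if prev_stage is None else
                 [Sentry(f"sn_{pid}", [(prev_stage, "complete")])])
        stages.append(PlanItem(
            item_id=pid, kind=ItemKind.STAGE, name=spec.phases[p].name,
            entry_criteria=entry, children=_phase_items(spec, p)))
        prev_stage = pid
    case = CaseModel(case_id=f"{spec.name}_cmmn", name=spec.name,
                     plan_items=stages)
    case.validate()
    return case


# ---------------------------------------------------------------------------
# combination construction
# ---------------------------------------------------------------------------


def _phase_is_variable(spec: InterventionSpec, p: int) -> bool:
    return any(st.optional or st.variable_group or st.exclusive_group
               for st in spec.phases[p].steps)


def build_structured(spec: InterventionSpec) -> CombinationModel:
    """Structured combination: the root BPMN holds only call activities
    (one per phase), each referring to a case with that phase's steps."""
    ff = _FlowFactory()
    nodes = [FlowNode("root_start", NodeKind.START_EVENT)]
    cases: dict[str, CaseModel] = {}
    entry = "root_start"
    for p in range(len(spec.phases)):
        pid = spec.phase_id(p)
        case_id = f"{spec.name}_{pid}"
        cases[case_id] = CaseModel(case_id=case_id, name=spec.phases[p].name,
                                   plan_items=_phase_items(spec, p))
        ca = FlowNode(f"call_{pid}", NodeKind.CALL_ACTIVITY,
                      name=spec.phases[p].name, called_case=case_id)
        nodes.append(ca)
        ff.add(entry, ca.node_id)
        entry = ca.node_id
    nodes.append(FlowNode("root_end", NodeKind.END_EVENT))
    ff.add(entry, "root_end")
    root = ProcessModel(model_id=f"{spec.name}_structured_root", name=spec.name,
                        nodes=nodes, flows=ff.flows, granularity="two_level")
    comb = CombinationModel(style="structured", root=root, cases=cases)
    comb.validate()
    return comb


def build_mixed(spec: InterventionSpec) -> CombinationModel:
    """Mixed combination: straightforward phases stay inline BPMN
    sub-processes; variable phases become call activities to cases."""
    ff = _FlowFactory()
    nodes = [FlowNode("root_start", NodeKind.START_EVENT)]
    cases: dict[str, CaseModel] = {}
    entry = "root_start"
    for p in range(len(spec.phases)):
        pid = spec.phase_id(p)
        if _phase_is_variable(spec, p):
            case_id = f"{spec.name}_{pid}"
            cases[case_id] = CaseModel(case_id=case_id,
                                       name=spec.phases[p].name,
                                       plan_items=_phase_items(spec, p))
            node = FlowNode(f"call_{pid}", NodeKind.CALL_ACTIVITY,
                            name=spec.phases[p].name, called_case=case_id)
        else:
            node = FlowNode(pid, NodeKind.SUB_PROCESS, name=spec.phases[p].name,
                            children=_emit_phase_children(spec, p, ff))
        nodes.append(node)
        ff.add(entry, node.node_id)
        entry = node.node_id
    nodes.append(FlowNode("root_end", NodeKind.END_EVENT))
    ff.add(entry, "root_end")
    root = ProcessModel(model_id=f"{spec.name}_mixed_root", name=spec.name,
                        nodes=nodes, flows=ff.flows, granularity="two_level")
    root.validate()
    ModelStructure(root).mark_optional_steps()
    comb = CombinationModel(style="mixed", root=root, cases=cases)
    comb.validate()
    return comb


def build_models(spec: InterventionSpec) -> ModelBundle:
    """All four model variants of one intervention, sharing step ids."""
    spec.validate()
    return ModelBundle(
        spec=spec,
        bpmn=build_bpmn(spec),
        cmmn=build_cmmn(spec),
        mixed=build_mixed(spec),
        structured=build_structured(spec),
    )


# ---------------------------------------------------------------------------
# situation rules
# ---------------------------------------------------------------------------


def build_rules(spec: InterventionSpec, seed: int = 0) -> list[SituationRule]:
    """One rule per step, with distinguishable signatures.

    Label-based interventions get a label rule per step; instrument-based
    ones get a unique instrument pair plus an actor position drawn
    deterministically from the spec vocabularies.
    """
    rng = random.Random(seed)
    rules: list[SituationRule] = []
    table = spec.step_table()
    if spec.label_based:
        for sid, *_ in table:
            rules.append(SituationRule(
                rule_id=f"rule_{sid}", target_step=sid, label_match=sid,
                base_score=1.0))
        return rules
    pairs = list(combinations(spec.instruments, 2))
    if len(pairs) < len(table):
        raise ModelValidationError(
            f"instrument vocabulary too small for {len(table)} steps")
    rng.shuffle(pairs)
    for i, (sid, p, _, _) in enumerate(table):
        zone = spec.zones[(p + rng.randrange(len(spec.zones))) % len(spec.zones)] \
            if spec.zones else None
        positions = {spec.actors[0]: zone} if zone else {}
        rules.append(SituationRule(
            rule_id=f"rule_{sid}", target_step=sid,
            instrument_match=frozenset(pairs[i]),
            position_match=tuple(sorted(positions.items())),
            base_score=0.9))
    return rules


# ---------------------------------------------------------------------------
# observation streams
# ---------------------------------------------------------------------------


def sample_valid_trace(spec: InterventionSpec, rng: random.Random,
                       include_optional: float = 0.7,
                       forbid: frozenset[str] = frozenset(),
                       force_include: frozenset[str] = frozenset(),
                       branch_choice: dict[str, int] | None = None) -> list[str]:
    """One accepted complete step order, sampled from the spec structure."""
    trace: list[str] = []
    branch_choice = branch_choice or {}
    for p in range(len(spec.phases)):
        for kind, members in _units(spec, p):
            if kind == "step":
                sid, st = members[0]
                if st.optional and sid not in force_include and (
                        sid in forbid or rng.random() >= include_optional):
                    continue
                trace.append(sid)
            elif kind == "var":
                chosen = []
                for sid, st in members:
                    if st.optional and sid not in force_include and (
                            sid in forbid or rng.random() >= include_optional):
                        continue
                    chosen.append(sid)
                rng.shuffle(chosen)
                trace.extend(chosen)
            else:
                group = members[0][1].exclusive_group
                by_branch: dict[int, list[str]] = {}
                for sid, st in members:
                    by_branch.setdefault(st.branch, []).append(sid)
                b = branch_choice.get(group, rng.choice(sorted(by_branch)))
                trace.extend(by_branch[b])
    return trace


def _observation(spec: InterventionSpec, sid: str, time: float,
                 rules_by_step: dict[str, SituationRule]) -> SensorObservation:
    if spec.label_based:
        return SensorObservation.make(time=time, step_label=sid)
    rule = rules_by_step[sid]
    return SensorObservation.make(
        time=time,
        instruments=set(rule.instrument_match),
        positions=dict(rule.position_match),
    )


def _optional_in_var_group(spec: InterventionSpec) -> tuple[str, str] | None:
    """(optional step id, id of a later step in the same phase), if any."""
    for p in range(len(spec.phases)):
        units = _units(spec, p)
        for u, (kind, members) in enumerate(units):
            if kind != "var":
                continue
            for sid, st in members:
                if st.optional:
                    for kind2, members2 in units[u + 1:]:
                        later = [m for m in members2 if not m[1].optional]
                        if later:
                            return sid, later[0][0]
    return None


def _exclusive_groups(spec: InterventionSpec) -> dict[str, dict[int, list[str]]]:
    out: dict[str, dict[int, list[str]]] = {}
    for sid, _, _, st in spec.step_table():
        if st.exclusive_group:
            out.setdefault(st.exclusive_group, {}).setdefault(st.branch, []) \
                .append(sid)
    return out


def simulate_stream(spec: InterventionSpec, scenario: Scenario,
                    rules: list[SituationRule] | None = None
                    ) -> list[SensorObservation]:
    """Deterministic observation stream for one scenario.

    ``valid`` (and ``shuffled_variable``, which is a valid stream with a
    different variable-group order) replays an accepted trace; each
    distortion perturbs a valid stream in its single documented way.
    """
    rng = random.Random(scenario.seed)
    rules = rules if rules is not None else build_rules(spec, seed=scenario.seed)
    rules_by_step = {r.target_step: r for r in rules}
    durations = spec.durations()
    required_ids = [sid for sid, _, _, st in spec.step_table()
                    if not st.optional and not st.exclusive_group]
    optional_ids = frozenset(sid for sid, _, _, st in spec.step_table()
                             if st.optional)

    kind = scenario.kind
    if kind in ("valid", "shuffled_variable"):
        if kind == "shuffled_variable":
            rng.random()  # decouple the permutation from the valid stream
        steps = sample_valid_trace(spec, rng)
    elif kind == "skip_optional":
        steps = sample_valid_trace(spec, rng, forbid=optional_ids)
    elif kind == "skip_required":
        steps = sample_valid_trace(spec, rng)
        candidates = [s for s in steps[:-1] if s in required_ids]
        steps.remove(rng.choice(candidates))
    elif kind == "regress":
        # re-observe a step from two phases back, which is certainly
        # completed by then (phase boundaries force completion)
        steps = sample_valid_trace(spec, rng)
        phase_of = {sid: p for sid, p, _, _ in spec.step_table()}
        cands = [s for s in steps if s in required_ids
                 and phase_of[s] <= len(spec.phases) - 3]
        x = rng.choice(cands)
        j = next(idx for idx, s in enumerate(steps)
                 if phase_of[s] >= phase_of[x] + 2)
        steps = steps[:j] + [x] + steps[j:]
    elif kind == "repeat":
        steps = sample_valid_trace(spec, rng)
        i = rng.randrange(len(steps))
        steps = steps[:i + 1] + [steps[i]] + steps[i + 1:]
    elif kind == "wrong_path":
        groups = _exclusive_groups(spec)
        if not groups:
            raise ModelValidationError(
                f"spec {spec.name!r} has no exclusive paths to distort")
        group = sorted(groups)[0]
        branches = groups[group]
        chosen = rng.choice(sorted(branches))
        other = next(b for b in sorted(branches) if b != chosen)
        steps = sample_valid_trace(spec, rng, branch_choice={group: chosen})
        insert_at = steps.index(branches[chosen][-1]) + 1
        steps = steps[:insert_at] + [branches[other][0]] + steps[insert_at:]
    elif kind == "delayed_optional":
        found = _optional_in_var_group(spec)
        if found is None:
            raise ModelValidationError(
                f"spec {spec.name!r} has no optional step inside a variable group")
        opt, later = found
        steps = sample_valid_trace(spec, rng, forbid=frozenset({opt}))
        insert_at = steps.index(later) + 1
        steps = steps[:insert_at] + [opt] + steps[insert_at:]
    else:  # pragma: no cover
        raise ValueError(kind)

    stream: list[SensorObservation] = []
    t = 0.0
    for sid in steps:
        stream.append(_observation(spec, sid, round(t, 2), rules_by_step))
        t += durations[sid] * rng.uniform(0.9, 1.1)
    return stream


def write_stream(stream: list[SensorObservation], path) -> None:
    with open(path, "w") as fh:
        for obs in stream:
            fh.write(json.dumps(obs.to_dict(), sort_keys=True) + "\n")


def read_stream(path) -> list[SensorObservation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(SensorObservation.from_dict(json.loads(line)))
    return out
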