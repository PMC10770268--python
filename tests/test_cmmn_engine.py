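"""Plan-item lifecycle semantics of the CMMN engine."""

import random

import pytest

from surgflow.cmmn import replay_case, start_case
from surgflow.errors import (
    CaseIncompleteError,
    ClosedCaseError,
    LifecycleError,
    StageBusyError,
    StageIncompleteError,
)
from surgflow.fixtures import build_cmmn
from surgflow.model import CaseModel, ItemKind, PlanItem, Sentry

from conftest import chain_spec, exclusive_spec, variable_block_spec


def two_stage_case() -> CaseModel:
    """S1{A req, B req, C opt} -> S2{D req} with S2 gated on S1 completion."""
    s1 = PlanItem("s1", ItemKind.STAGE, children=[
        PlanItem("a", ItemKind.HUMAN_TASK),
        PlanItem("b", ItemKind.HUMAN_TASK),
        PlanItem("c", ItemKind.HUMAN_TASK, required=False, manual_activation=True),
    ])
    s2 = PlanItem("s2", ItemKind.STAGE,
                  entry_criteria=[Sentry("sn_s2", [("s1", "complete")])],
                  children=[PlanItem("d", ItemKind.HUMAN_TASK)])
    case = CaseModel("two_stage", plan_items=[s1, s2])
    case.validate()
    return case


class TestStartCase:
    def test_criteria_free_items_activate_or_enable(self):
        inst = start_case(two_stage_case())
        assert inst.active_tasks() == {"a", "b"}
        assert inst.enabled_tasks() == {"c"}

    def test_later_stage_children_stay_available(self):
        inst = start_case(two_stage_case())
        assert inst.item_states["s2"] == "available"
        assert inst.item_states["d"] == "available"

    def test_single_required_task_case(self):
        case = CaseModel("solo", plan_items=[PlanItem("t", ItemKind.HUMAN_TASK)])
        inst = start_case(case)
        assert inst.active_tasks() == {"t"}


class TestManualStart:
    def test_enabled_optional_becomes_active(self):
        inst = start_case(two_stage_case())
        inst.manually_start("c")
        assert inst.item_states["c"] == "active"

    def test_available_item_cannot_be_started(self):
        inst = start_case(two_stage_case())
        with pytest.raises(LifecycleError):
            inst.manually_start("d")

    def test_disabled_item_cannot_be_started(self):
        inst = start_case(two_stage_case())
        inst.complete_task("a").complete_task("b")
        inst.complete_stage("s1")
        with pytest.raises(LifecycleError):
            inst.manually_start("c")


class TestCompleteTask:
    def test_delayed_optional_still_startable(self):
        # unlike the process variant, an optional stays startable after the
        # other variable tasks completed
        inst = start_case(two_stage_case())
        inst.complete_task("a").complete_task("b")
        inst.manually_start("c")
        inst.complete_task("c")
        assert list(inst.trace) == ["a", "b", "c"]

    def test_both_exclusive_paths_can_run(self):
        # the known limitation: paths modeled as optional siblings cannot
        # forbid executing more than one of them
        case = build_cmmn(exclusive_spec((1, 1)))
        inst = start_case(case)
        for item in ("s01_01_path0_0", "s01_02_path1_0"):
            inst.manually_start(item)
            inst.complete_task(item)
        assert len(inst.trace) == 2

    def test_not_yet_entered_stage_task_refused(self):
        inst = start_case(two_stage_case())
        with pytest.raises(LifecycleError):
            inst.complete_task("d")


class TestCompleteStage:
    def test_manual_completion_disables_optionals_and_opens_next_stage(self):
        inst = start_case(two_stage_case())
        inst.complete_task("a").complete_task("b")
        assert inst.item_states["s1"] == "active"  # optional child blocks auto
        inst.complete_stage("s1")
        assert inst.item_states["c"] == "disabled"
        assert inst.item_states["s2"] == "active"
        assert inst.item_states["d"] == "active"

    def test_all_required_stage_auto_completes(self):
        case = build_cmmn(chain_spec(2))
        inst = start_case(case)
        stage = case.plan_items[0].item_id
        inst.complete_task("s01_01_t0").complete_task("s01_02_t1")
        assert inst.item_states[stage] == "completed"
        inst.complete_stage(stage)  # explicit call is a no-op

    def test_incomplete_required_child_refused(self):
        inst = start_case(two_stage_case())
        inst.complete_task("a")
        with pytest.raises(StageIncompleteError):
            inst.complete_stage("s1")

    def test_active_child_blocks_completion(self):
        inst = start_case(two_stage_case())
        inst.complete_task("a").complete_task("b")
        inst.manually_start("c")
        with pytest.raises(StageBusyError):
            inst.complete_stage("s1")


class TestCaseLifecycle:
    def _finish(self, inst):
        inst.complete_task("a").complete_task("b")
        inst.complete_stage("s1")
        inst.complete_task("d")
        return inst

    def test_complete_then_close(self):
        inst = self._finish(start_case(two_stage_case()))
        inst.complete_case()
        inst.close_case()
        assert inst.is_closed()

    def test_premature_completion_refused(self):
        inst = start_case(two_stage_case())
        with pytest.raises(CaseIncompleteError):
            inst.complete_case()

    def test_closed_case_is_immutable(self):
        inst = self._finish(start_case(two_stage_case()))
        inst.complete_case().close_case()
        with pytest.raises(ClosedCaseError):
            inst.complete_task("a")

    def test_full_fixture_trace_completes_and_closes(self, ramie_bundle):
        trace = [t for t in ramie_bundle.spec.step_ids()]
        inst = replay_case(ramie_bundle.cmmn, trace)
        inst.complete_stage(ramie_bundle.spec.phase_id(8))
        inst.complete_case()
        inst.close_case()
        assert inst.is_closed()


class TestLifecycleLegality:
    LEGAL = {
        ("available", "enabled"), ("available", "active"),
        ("available", "disabled"), ("enabled", "active"),
        ("enabled", "disabled"), ("active", "completed"),
    }

    def test_random_transition_sequences_stay_legal(self):
        case = build_cmmn(variable_block_spec(2, 2, post=True))
        items = [i.item_id for i in case.iter_items()]
        rng = random.Random(7)
        for _ in range(30):
            inst = start_case(case)
            prev = dict(inst.item_states)
            for _ in range(40):
                item = rng.choice(items)
                op = rng.choice(["start", "complete", "stage", "case"])
                try:
                    if op == "start":
                        inst.manually_start(item)
                    elif op == "complete":
                        inst.complete_task(item)
                    elif op == "stage":
                        inst.complete_stage(item)
                    else:
                        inst.complete_case()
                except LifecycleError:
                    pass
                for iid, state in inst.item_states.items():
                    if prev[iid] != state:
                        assert (prev[iid], state) in self.LEGAL, (iid, prev[iid], state)
                    if inst.case.item(iid).required:
                        assert state != "disabled"
                prev = dict(inst.item_states)
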