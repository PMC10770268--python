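"""Token semantics of the BPMN engine."""

import random

import pytest

from surgflow.bpmn import replay, start_process
from surgflow.errors import (
    LateOptionalError,
    OutOfOrderError,
    RegressionError,
    ReplayError,
)
from surgflow.fixtures import build_bpmn
from surgflow.oracle import enumerate_traces

from conftest import chain_spec, exclusive_spec, variable_block_spec


def _tasks(model):
    return sorted(t.node_id for t in model.user_tasks())


class TestChain:
    def test_start_rests_on_first_task(self):
        model = build_bpmn(chain_spec(3))
        inst = start_process(model)
        assert inst.active_tasks() == {"s01_01_t0"}
        assert not inst.is_complete()

    def test_complete_in_order_reaches_end(self):
        model = build_bpmn(chain_spec(3))
        inst = start_process(model)
        for t in _tasks(model):
            inst.complete_task(t)
        assert inst.is_complete()
        assert list(inst.trace) == _tasks(model)
        assert inst.active_tasks() == set()

    def test_skipping_ahead_refused(self):
        model = build_bpmn(chain_spec(3))
        inst = start_process(model)
        with pytest.raises(OutOfOrderError):
            inst.complete_task("s01_03_t2")

    def test_recompletion_is_regression(self):
        model = build_bpmn(chain_spec(2))
        inst = start_process(model)
        inst.complete_task("s01_01_t0")
        with pytest.raises(RegressionError):
            inst.complete_task("s01_01_t0")


class TestParallelBlock:
    def test_and_split_activates_all_required(self):
        model = build_bpmn(variable_block_spec(2, 1, post=True))
        inst = start_process(model)
        assert inst.active_tasks() == {"s01_01_req_0", "s01_02_req_1"}
        # the optional sits behind its exclusive bypass: activatable, not active
        assert "s01_03_opt_0" in inst.activatable_tasks()

    def test_variable_order_any_permutation(self):
        model = build_bpmn(variable_block_spec(3, 0, post=True))
        tasks = ["s01_01_req_0", "s01_02_req_1", "s01_03_req_2"]
        for perm in ([2, 0, 1], [1, 2, 0], [0, 1, 2]):
            inst = start_process(model)
            for i in perm:
                inst.complete_task(tasks[i])
            inst.complete_task("s01_04_post_step")
            assert inst.is_complete()

    def test_join_waits_for_all_branches(self):
        model = build_bpmn(variable_block_spec(2, 0, post=True))
        inst = start_process(model)
        inst.complete_task("s01_01_req_0")
        with pytest.raises(OutOfOrderError):
            inst.complete_task("s01_03_post_step")
        assert inst.active_tasks() == {"s01_02_req_1"}

    def test_optional_skipped_bypasses_it(self):
        model = build_bpmn(variable_block_spec(2, 1, post=True))
        inst = start_process(model)
        inst.complete_task("s01_01_req_0")  # compat: optional auto-bypassed
        inst.complete_task("s01_02_req_1")
        inst.complete_task("s01_04_post_step")
        assert inst.is_complete()
        assert inst.task_states["s01_03_opt_0"] == "bypassed"
        assert "s01_03_opt_0" not in inst.trace


class TestCamundaCompat:
    def test_sibling_completion_autoskips_optional(self):
        model = build_bpmn(variable_block_spec(1, 1, post=True))
        inst = start_process(model, camunda_compat=True)
        inst.complete_task("s01_01_req_0")
        with pytest.raises(LateOptionalError):
            inst.complete_task("s01_02_opt_0")
        # the refusal is recorded in the exception, not reflected in state
        assert inst.task_states["s01_02_opt_0"] == "bypassed"

    def test_compat_off_keeps_optional_activatable(self):
        model = build_bpmn(variable_block_spec(1, 1, post=True))
        inst = start_process(model, camunda_compat=False)
        inst.complete_task("s01_01_req_0")
        inst.complete_task("s01_02_opt_0")
        inst.complete_task("s01_03_post_step")
        assert inst.is_complete()
        assert "s01_02_opt_0" in inst.trace


class TestExclusivePaths:
    def test_first_completed_task_selects_branch(self):
        model = build_bpmn(exclusive_spec((2, 1)))
        inst = start_process(model)
        assert inst.activatable_tasks() >= {"s01_01_path0_0", "s01_03_path1_0"}
        inst.complete_task("s01_03_path1_0")
        assert inst.task_states["s01_01_path0_0"] == "bypassed"
        assert inst.task_states["s01_02_path0_1"] == "bypassed"

    def test_bypassed_branch_refused(self):
        model = build_bpmn(exclusive_spec((1, 1)))
        inst = start_process(model)
        inst.complete_task("s01_01_path0_0")
        with pytest.raises(OutOfOrderError):
            inst.complete_task("s01_02_path1_0")


class TestSubProcess:
    def test_token_jumps_into_first_task(self, ci_bundle):
        inst = start_process(ci_bundle.bpmn)
        assert inst.active_tasks() == {"s01_01_patient_positioning"}

    def test_sub_process_auto_completes_at_end_event(self, ci_bundle):
        inst = start_process(ci_bundle.bpmn)
        inst.complete_task("s01_01_patient_positioning")
        inst.complete_task("s01_02_sterile_draping")
        # phase 1 ended; token rests on phase 2's first task
        assert inst.active_tasks() == {"s02_01_skin_incision"}
        assert "phase_01_preparation" in inst._sp_completed


class TestProperties:
    @pytest.mark.parametrize("k,m", [(2, 1), (3, 1), (2, 2)])
    def test_required_conservation_and_optional_skip(self, k, m):
        model = build_bpmn(variable_block_spec(k, m, post=True))
        required = {t.node_id for t in model.user_tasks() if not t.optional_step}
        optionals = {t.node_id for t in model.user_tasks() if t.optional_step}
        traces = enumerate_traces(model).traces
        for tr in traces:
            for r in required:
                assert list(tr).count(r) == 1
        for o in optionals:
            assert any(o not in tr for tr in traces)
            assert any(o in tr for tr in traces)

    def test_monotonic_completion_under_random_ops(self):
        model = build_bpmn(variable_block_spec(3, 1, post=True))
        rng = random.Random(42)
        for _ in range(25):
            inst = start_process(model, camunda_compat=False)
            completed: set[str] = set()
            for _ in range(30):
                choice = rng.choice(sorted(inst.task_states))
                try:
                    inst.complete_task(choice)
                except (OutOfOrderError, RegressionError):
                    pass
                now = {t for t, s in inst.task_states.items() if s == "completed"}
                assert completed <= now  # nothing un-completes
                completed = now
                assert list(inst.trace) == [t for t in inst.trace]
                if inst.is_complete():
                    break

    def test_trace_contains_only_user_tasks_in_completion_order(self, ci_bundle):
        structured = ci_bundle.structured
        inst = start_process(structured.root)
        # call activities never enter the step trace
        for ca in sorted(t for t in inst.task_states):
            while inst.task_states[ca] == "active":
                inst.complete_task(ca)
        assert list(inst.trace) == []
        assert inst.is_complete()


def test_replay_rejects_invalid_prefix():
    model = build_bpmn(chain_spec(3))
    with pytest.raises(ReplayError):
        replay(model, ["s01_02_t1"])
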