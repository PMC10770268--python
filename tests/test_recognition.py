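"""Sensor scoring and knowledge fusion."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from surgflow.fixtures import Scenario, simulate_stream
from surgflow.knowledge import ProcessKnowledge
from surgflow.recognition import (
    ImpactConfig,
    SensorObservation,
    SituationRule,
    fuse,
    recognize,
    score_sensors,
)


def obs(**kw):
    return SensorObservation.make(time=kw.pop("time", 0.0), **kw)


RULES = [
    SituationRule("r1", "step_a", instrument_match=frozenset({"hook", "grasper"}),
                  base_score=0.9),
    SituationRule("r2", "step_b", instrument_match=frozenset({"stapler"}),
                  base_score=0.9),
    SituationRule("r3", "step_c",
                  position_match=(("surgeon", "console"),), base_score=0.5),
]


class TestScoreSensors:
    def test_step_label_scores_named_step(self):
        assert score_sensors(obs(step_label="access_01"), RULES) == {"access_01": 1.0}

    def test_instrument_superset_fires_rule(self):
        scores = score_sensors(obs(instruments={"hook", "grasper", "suction"}),
                               RULES)
        assert scores == {"step_a": 1.0}

    def test_equal_scores_normalize_uniformly(self):
        rules = [
            SituationRule("r1", "s1", instrument_match=frozenset({"x"}),
                          base_score=0.5),
            SituationRule("r2", "s2", instrument_match=frozenset({"x"}),
                          base_score=0.5),
        ]
        scores = score_sensors(obs(instruments={"x"}), rules)
        assert scores == {"s1": 0.5, "s2": 0.5}

    def test_unknown_instruments_give_empty_map(self):
        assert score_sensors(obs(instruments={"banjo"}), RULES) == {}

    def test_position_mismatch_blocks_rule(self):
        scores = score_sensors(obs(positions={"surgeon": "periphery"}), RULES)
        assert scores == {}

    def test_observation_requires_some_evidence(self):
        with pytest.raises(ValueError):
            SensorObservation.make(time=0.0)


class TestFuse:
    def test_worked_example(self):
        # sensor 60/40 for two steps, process prior on the second,
        # weights 80/20: the prior flips the ranking
        sk = fuse({"s1": 0.6, "s2": 0.4},
                  ProcessKnowledge(next_steps={"s2"}, reasonable=True),
                  ImpactConfig(0.8))
        assert sk.candidates["s1"] == pytest.approx(0.48)
        assert sk.candidates["s2"] == pytest.approx(0.52)
        assert sk.best == "s2"

    def test_pure_sensor_weight_reproduces_sensor_ranking(self):
        sk = fuse({"s1": 0.6, "s2": 0.4},
                  ProcessKnowledge(next_steps={"s2"}), ImpactConfig(1.0))
        assert sk.candidates["s1"] == pytest.approx(0.6)
        assert sk.best == "s1"

    def test_pure_process_weight_reproduces_prior(self):
        sk = fuse({"s1": 0.9, "s2": 0.1},
                  ProcessKnowledge(next_steps={"s2", "s3"}), ImpactConfig(0.0))
        assert sk.candidates["s2"] == pytest.approx(0.5)
        assert sk.candidates["s3"] == pytest.approx(0.5)

    def test_empty_sensor_falls_back_to_process_prior(self):
        sk = fuse({}, ProcessKnowledge(next_steps={"a", "b"}), ImpactConfig(0.8))
        assert sk.candidates == {"a": 0.5, "b": 0.5}
        assert sk.best == "a"  # deterministic lexical tie-break

    def test_no_evidence_yields_no_recognition(self):
        sk = fuse({}, ProcessKnowledge(next_steps=set()), ImpactConfig(0.8))
        assert sk.best is None

    @settings(max_examples=60, derandomize=True)
    @given(st.dictionaries(st.sampled_from("abcdef"),
                           st.floats(0.01, 1.0), min_size=1),
           st.sets(st.sampled_from("abcdef")),
           st.floats(0.0, 1.0))
    def test_normalization(self, raw, next_steps, w):
        total = sum(raw.values())
        p = {k: v / total for k, v in raw.items()}
        sk = fuse(p, ProcessKnowledge(next_steps=next_steps), ImpactConfig(w))
        assert math.isclose(sum(sk.candidates.values()), 1.0, rel_tol=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.45),
           st.floats(0.05, 0.95))
    def test_monotonicity_in_process_weight(self, w_lo, delta, p_in):
        # raising the process weight never lowers an in-next-steps step
        # relative to one outside the prior support (score ratio only grows)
        p = {"inside": p_in, "outside": 1.0 - p_in}
        pk = ProcessKnowledge(next_steps={"inside"})
        lo = fuse(p, pk, ImpactConfig(1.0 - w_lo))
        hi = fuse(p, pk, ImpactConfig(1.0 - w_lo - delta))
        ratio_lo = lo.candidates["inside"] / lo.candidates["outside"]
        ratio_hi = hi.candidates["inside"] / hi.candidates["outside"]
        assert ratio_hi >= ratio_lo - 1e-9


class TestRecognize:
    def test_valid_stream_recognizes_each_simulated_step(self, ci_bundle, ci_rules):
        stream = simulate_stream(ci_bundle.spec, Scenario("valid", seed=11),
                                 rules=ci_rules)
        trace: list[str] = []
        for o in stream:
            sk = recognize(o, ci_bundle.bpmn, list(trace), ci_rules)
            assert sk.best == o.step_label
            trace.append(sk.best)

    def test_downstream_step_flagged_unreasonable(self, ci_bundle, ci_rules):
        o = obs(step_label="s03_03_electrode_insertion")
        sk = recognize(o, ci_bundle.bpmn, [], ci_rules)
        assert sk.best == "s03_03_electrode_insertion"
        assert not sk.reasonable

    def test_phase_attached_to_best_step(self, ci_bundle, ci_rules):
        o = obs(step_label="s02_01_skin_incision")
        sk = recognize(o, ci_bundle.bpmn, ["s01_01_patient_positioning",
                                           "s01_02_sterile_draping"], ci_rules)
        assert sk.phase == "phase_02_access"

    def test_instrument_streams_recognize_ramie_steps(self, ramie_bundle,
                                                      ramie_rules):
        stream = simulate_stream(ramie_bundle.spec, Scenario("valid", seed=5),
                                 rules=ramie_rules)
        by_step = {r.target_step: r for r in ramie_rules}
        for o in stream[:8]:
            scores = score_sensors(o, ramie_rules)
            best = max(scores, key=scores.get)
            assert o.instruments == by_step[best].instrument_match
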