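"""Situation recognition: sensor evidence fused with process knowledge.

A simulated observation (instruments in use, actor positions, or directly a
step label) is first interpreted with declarative situation rules, giving a
distribution over candidate steps from sensor knowledge alone.  That
distribution is then blended with a process prior — uniform over the next
possible steps and the current one — using a configurable impact weight:
``fused(c) = w_sensor * p_sensor(c) + w_process * q(c)``, renormalized.
The defaults weigh sensor knowledge 80% and process knowledge 20%.

The fusion formula is this package's definition of the knowledge
combination; the weights are the configurable *impact* factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import knowledge as pk_mod
from .model import CombinationModel, ProcessModel

__all__ = [
    "SensorObservation",
    "SituationRule",
    "ImpactConfig",
    "SituationKnowledge",
    "score_sensors",
    "fuse",
    "recognize",
]


@dataclass(frozen=True)
class SensorObservation:
    """One time-stamped simulated observation.

    At least one evidence channel must be present: a set of instrument
    names, a map from actor to zone label, or a step-name label.
    """

    time: float  # minutes since intervention start
    instruments: frozenset[str] = frozenset()
    positions: tuple[tuple[str, str], ...] = ()  # (actor, zone), sorted
    step_label: str | None = None

    def __post_init__(self):
        if not self.instruments and not self.positions and self.step_label is None:
            raise ValueError("observation carries no evidence")

    @property
    def position_map(self) -> dict[str, str]:
        return dict(self.positions)

    @staticmethod
    def make(time: float, instruments=(), positions=None, step_label=None):
        return SensorObservation(
            time=time,
            instruments=frozenset(instruments),
            positions=tuple(sorted((positions or {}).items())),
            step_label=step_label,
        )

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "instruments": sorted(self.instruments),
            "positions": dict(self.positions),
            "step_label": self.step_label,
        }

    @staticmethod
    def from_dict(d: dict) -> "SensorObservation":
        return SensorObservation.make(
            time=d["time"],
            instruments=d.get("instruments") or (),
            positions=d.get("positions") or {},
            step_label=d.get("step_label"),
        )


@dataclass(frozen=True)
class SituationRule:
    """Maps a sensor signature (instruments / positions / label) to a step."""

    rule_id: str
    target_step: str
    instrument_match: frozenset[str] = frozenset()
    position_match: tuple[tuple[str, str], ...] = ()
    label_match: str | None = None
    base_score: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.base_score <= 1.0:
            raise ValueError("base_score must be in (0, 1]")

    def fires(self, obs: SensorObservation) -> bool:
        if self.label_match is not None:
            return obs.step_label == self.label_match
        if not self.instrument_match and not self.position_match:
            return False
        if self.instrument_match and not self.instrument_match <= obs.instruments:
            return False
        obs_pos = obs.position_map
        for actor, zone in self.position_match:
            if obs_pos.get(actor) != zone:
                return False
        return True


@dataclass(frozen=True)
class ImpactConfig:
    """Relative influence of sensor vs. process knowledge on the fusion."""

    sensor_weight: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.sensor_weight <= 1.0:
            raise ValueError("sensor_weight must be in [0, 1]")

    @property
    def process_weight(self) -> float:
        return 1.0 - self.sensor_weight


@dataclass
class SituationKnowledge:
    candidates: dict[str, float] = field(default_factory=dict)
    best: str | None = None
    best_probability: float = 0.0
    reasonable: bool = False
    level: str = "step"  # "phase" | "step" | "activity"
    phase: str | None = None
    completable: list[str] = field(default_factory=list)


def score_sensors(obs: SensorObservation,
                  rules: list[SituationRule]) -> dict[str, float]:
    """Distribution over steps from sensor knowledge alone.

    Every firing rule contributes its base score to its target step; a step
    label directly scores its named step 1.0.  Scores are normalized; an
    empty map signals that no sensor evidence matched.
    """
    scores: dict[str, float] = {}
    for rule in rules:
        if rule.fires(obs):
            scores[rule.target_step] = scores.get(rule.target_step, 0.0) + rule.base_score
    if obs.step_label is not None and not any(
            r.label_match == obs.step_label and r.fires(obs) for r in rules):
        scores[obs.step_label] = scores.get(obs.step_label, 0.0) + 1.0
    total = sum(scores.values())
    if total <= 0:
        return {}
    return {s: v / total for s, v in scores.items()}


def fuse(sensor_scores: dict[str, float], pk: pk_mod.ProcessKnowledge,
         impact: ImpactConfig | None = None,
         current: str | None = None) -> SituationKnowledge:
    """Blend the sensor distribution with the process prior.

    The process prior is uniform over the next possible steps plus the
    current one.  With no evidence on either side, a no-recognition result
    (``best=None``) is returned.  Ties break deterministically on the
    lexically smallest step id.
    """
    impact = impact or ImpactConfig()
    prior_support = set(pk.next_steps)
    if current is not None:
        prior_support.add(current)
    candidates = set(sensor_scores) | prior_support
    if not candidates:
        return SituationKnowledge(reasonable=pk.reasonable)
    q = {c: (1.0 / len(prior_support) if c in prior_support else 0.0)
         for c in candidates}
    has_sensor = bool(sensor_scores)
    has_prior = bool(prior_support)
    fused = {}
    for c in candidates:
        p = sensor_scores.get(c, 0.0)
        if has_sensor and has_prior:
            fused[c] = impact.sensor_weight * p + impact.process_weight * q[c]
        elif has_sensor:
            fused[c] = p
        else:
            fused[c] = q[c]
    total = sum(fused.values())
    if total <= 0:
        return SituationKnowledge(reasonable=pk.reasonable)
    fused = {c: v / total for c, v in fused.items()}
    best = min(fused, key=lambda c: (-fused[c], c))
    return SituationKnowledge(
        candidates=fused,
        best=best,
        best_probability=fused[best],
        reasonable=pk.reasonable,
        completable=list(pk.completable),
    )


def recognize(obs: SensorObservation, model: ProcessModel, trace,
              rules: list[SituationRule], impact: ImpactConfig | None = None,
              running: set[str] | None = None) -> SituationKnowledge:
    """Full step-level pipeline: sensor scoring, knowledge lookup, fusion.

    The phase is derived as the phase container of the best step.  When the
    running activity set is not supplied it is taken from a replay of the
    trace.
    """
    sensor_scores = score_sensors(obs, rules)
    current = trace[-1] if len(trace) else None
    if running is None:
        try:
            running = pk_mod.dynamic_next_steps(model, trace)
        except Exception:
            running = set()
    try:
        dyn = pk_mod.dynamic_next_steps(model, trace)
    except Exception:
        dyn = set()
    pk = pk_mod.ProcessKnowledge(next_steps=dyn, source_model=model.model_id)
    sk = fuse(sensor_scores, pk, impact, current=current)
    if sk.best is not None:
        judged = pk_mod.completable_instances(model, trace, sk.best, running)
        sk.reasonable = judged.reasonable
        sk.completable = judged.completable
        sk.phase = _phase_of(model, sk.best)
    return sk


def _phase_of(model, step_id):
    try:
        if isinstance(model, CombinationModel):
            return model.case_of(step_id)
        return model.phase_of(step_id)
    except Exception:
        return None
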