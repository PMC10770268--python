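"""Declarative run configuration (YAML).

One small dialect covers everything a session needs beyond the models and
the observation stream: the impact weights of the fusion, the engine
compatibility switches, the knowledge source and the controller tolerance
flags.  All values have defaults; ``surgflow show-config`` prints them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .recognition import ImpactConfig, SituationRule

__all__ = ["RunConfig", "load_config", "dump_config", "load_rules", "dump_rules"]


@dataclass
class RunConfig:
    #: factor of the sensor knowledge in the fusion (process gets 1 - this)
    sensor_weight: float = 0.8
    #: reproduce the reference engine's auto-skip of optional tasks in AND
    #: blocks once a sibling branch task completes
    camunda_compat: bool = True
    #: tolerate first-stage candidates that fail the reasonableness check
    #: when controlling a case model
    first_stage_tolerant: bool = True
    #: where process knowledge comes from: the intervention's BPMN variant
    #: ("bpmn", with automatic fallback when the executed trace no longer
    #: replays on it) or the controlled runtime itself ("runtime")
    knowledge_source: str = "bpmn"
    #: seed for stream simulation and rule generation
    seed: int = 0

    @property
    def impact(self) -> ImpactConfig:
        return ImpactConfig(sensor_weight=self.sensor_weight)


def load_config(path=None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig | None = None) -> str:
    return yaml.safe_dump(asdict(cfg or RunConfig()), sort_keys=True)


def load_rules(path) -> list[SituationRule]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    rules = []
    for d in data:
        rules.append(SituationRule(
            rule_id=d["rule_id"],
            target_step=d["target_step"],
            instrument_match=frozenset(d.get("instruments") or ()),
            position_match=tuple(sorted((d.get("positions") or {}).items())),
            label_match=d.get("label"),
            base_score=float(d.get("base_score", 1.0)),
        ))
    return rules


def dump_rules(rules: list[SituationRule], path) -> None:
    data = []
    for r in rules:
        data.append({
            "rule_id": r.rule_id,
            "target_step": r.target_step,
            "instruments": sorted(r.instrument_match),
            "positions": dict(r.position_match),
            "label": r.label_match,
            "base_score": r.base_score,
        })
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
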