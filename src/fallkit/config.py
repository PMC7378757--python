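"""Pipeline configuration: YAML/JSON round-trippable settings for every stage.

Unknown keys are rejected so typos fail loudly; every default reproduces
the study protocol (50 Hz sampling, 2 s peak-centred segments, 0.5-5 /
5-10 / 10-20 Hz bands, k in {1,3,5,7}, selection threshold 0.0002).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import ActivityTemplate, SimulationConfig

__all__ = ["SegmentationSettings", "EvaluationSettings", "PipelineConfig"]


def _check_keys(section: str, data: dict, cls) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {section!r} config: {sorted(unknown)}")


@dataclass(frozen=True)
class SegmentationSettings:
    search_halfwidth_s: float = 2.5


@dataclass(frozen=True)
class EvaluationSettings:
    task: str = "binary"  # binary | multiclass
    classifier: str = "linear_svm"
    k: int = 5
    feature_set: str = "full"  # full | reference-13 | total-acceleration
    selection_threshold: float = 0.0002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.feature_set not in ("full", "reference-13", "total-acceleration"):
            raise ValueError(f"unknown feature set {self.feature_set!r}")


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        _check_keys("pipeline", data, cls)
        sim_data = dict(data.get("simulation", {}))
        _check_keys("simulation", sim_data, SimulationConfig)
        if "events_per_subject" in sim_data:
            sim_data["events_per_subject"] = tuple(
                _template_from_dict(t) for t in sim_data["events_per_subject"]
            )
        seg_data = dict(data.get("segmentation", {}))
        _check_keys("segmentation", seg_data, SegmentationSettings)
        eval_data = dict(data.get("evaluation", {}))
        _check_keys("evaluation", eval_data, EvaluationSettings)
        if "rest_gap" in sim_data:
            sim_data["rest_gap"] = tuple(sim_data["rest_gap"])
        return cls(
            simulation=SimulationConfig(**sim_data),
            segmentation=SegmentationSettings(**seg_data),
            evaluation=EvaluationSettings(**eval_data),
        )

    def to_dict(self) -> dict:
        data = asdict(self)
        sim = data["simulation"]
        sim["rest_gap"] = list(sim["rest_gap"])
        sim["events_per_subject"] = [
            _template_to_dict(t) for t in self.simulation.events_per_subject
        ]
        return data

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _template_to_dict(t: ActivityTemplate) -> dict:
    return {
        "label": t.label,
        "duration": t.duration,
        "peak_amplitude": list(t.peak_amplitude),
        "frequency": t.frequency,
        "orientation": list(t.orientation),
        "kind": t.kind,
    }


def _template_from_dict(data: dict) -> ActivityTemplate:
    _check_keys("activity template", data, ActivityTemplate)
    data = dict(data)
    for key in ("peak_amplitude", "orientation"):
        if key in data:
            data[key] = tuple(data[key])
    return ActivityTemplate(**data)
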