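"""YAML config plumbing for the command-line workflows.

One file describes a whole experiment: the world (population size, frame
geometry, noise), the drift scenario, the training recipe, the retraining
policy, and the classifier bank.  Keys mirror the dataclass field names.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .classifiers import ClassifierSpec, default_specs
from .extractor import TrainConfig
from .store import RetrainPolicy
from .world import DriftScenario


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    return raw


def scenario_from_config(raw: dict) -> DriftScenario:
    section = raw.get("scenario", {})
    return DriftScenario(
        duration=int(section.get("duration", 10)),
        morph_rate=float(section.get("morph_rate", 0.0)),
        env_events=tuple(
            (int(t), int(k)) for t, k in section.get("env_events", [])),
        population_events=tuple(
            (int(t), str(kind), str(ident))
            for t, kind, ident in section.get("population_events", [])),
    )


def train_config_from_config(raw: dict) -> TrainConfig:
    section = dict(raw.get("train", {}))
    if "stages" in section:
        section["stages"] = tuple(section["stages"])
    return TrainConfig(**section)


def policy_from_config(raw: dict) -> RetrainPolicy:
    return RetrainPolicy(**raw.get("policy", {}))


def classifier_specs_from_config(raw: dict) -> list[ClassifierSpec]:
    section = raw.get("classifiers")
    if not section:
        return default_specs(seed=int(raw.get("seed", 0)))
    return [ClassifierSpec(**spec) for spec in section]


def world_params(raw: dict) -> dict:
    section = dict(raw.get("world", {}))
    section.setdefault("n_identities", 5)
    section.setdefault("frames_per_session", 3)
    section.setdefault("sessions_per_tick", 4)
    section.setdefault("noise_sigma", 0.02)
    return section
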