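"""Experiment configuration: YAML-backed, hashable, fully serializable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .models import ModelSpec
from .preprocess import PreprocConfig
from .simulate import SimulationConfig


@dataclass
class EvaluationConfig:
    n_folds: int = 6
    window_s: float = 1.0
    step_ms: float = 60.0
    hit_window_s: float = 1.2
    normal_guard_s: float = 2.0
    grid: dict = field(default_factory=dict)  # optional m/M/W candidate lists


@dataclass
class ExperimentConfig:
    """One reproducible run: subjects x model grid, offline + pseudo-online."""

    n_subjects: int = 1
    seed: int = 0
    test_n_trials: int = 20  # held-out session length for pseudo-online
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    preproc: dict = field(default_factory=dict)  # PreprocConfig overrides
    models: list = field(default_factory=lambda: [
        {"model": "hbci_fl", "strategy": "tree", "feature_kind": "spectral"},
        {"model": "hbci_se1", "strategy": "ovr", "feature_kind": "spectral"},
        {"model": "eeg", "strategy": "tree", "feature_kind": "spectral"},
        {"model": "emg", "strategy": "tree", "feature_kind": "spectral"},
    ])
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.evaluation, dict):
            self.evaluation = EvaluationConfig(**self.evaluation)
        self._check_keys(self.simulation, SimulationConfig, "simulation")
        self._check_keys(self.preproc, PreprocConfig, "preproc")
        for spec in self.models:
            self._check_keys(spec, ModelSpec, "models")

    @staticmethod
    def _check_keys(overrides: dict, cls, section: str) -> None:
        allowed = {f.name for f in fields(cls)}
        bad = sorted(set(overrides) - allowed)
        if bad:
            raise ValueError(f"unknown keys in {section!r} config: {bad}")

    def model_specs(self, seed: int = 0) -> list:
        return [ModelSpec(**{**m, "seed": seed}) for m in self.models]

    def preproc_config(self) -> PreprocConfig:
        return PreprocConfig(**self.preproc)

    def simulation_config(self, seed: int, **extra) -> SimulationConfig:
        return SimulationConfig(**{**self.simulation, **extra, "seed": seed})

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_jsonable(self.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
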