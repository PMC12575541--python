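"""Experiment configuration, seeding and provenance.

One YAML-serialisable :class:`ExperimentConfig` describes a full run:
simulator settings, vocabulary, model and training hyper-parameters, and
metric settings.  Every artefact a command writes records the SHA-256 hash
of the effective configuration and the seed that produced it, so a run can
be re-executed bit-identically and outputs can be traced to their inputs.

A single global seed fans out into named per-purpose streams
(:func:`seed_stream`), so adding a consumer never perturbs the draws of
existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decoders import TrainConfig
from .encoder import ModelConfig
from .timelines import PhaseVocabulary

__all__ = ["ExperimentConfig", "seed_stream", "derive_seed", "config_hash"]


def derive_seed(global_seed: int, name: str) -> int:
    """A stable sub-seed (< 2**31) for a named consumer of the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def seed_stream(global_seed: int, name: str) -> np.random.Generator:
    """A named RNG stream derived from the global seed."""
    return np.random.default_rng(derive_seed(global_seed, name))


@dataclass(frozen=True)
class SimulatorSettings:
    n_videos: int = 20
    d_obs: int = 16
    noise_level: float = 0.6
    skip_prob: float = 0.05
    repeat_prob: float = 0.05
    deterministic: bool = False
    durations_s: tuple[int, ...] | None = None  # deterministic mode only


@dataclass(frozen=True)
class MetricSettings:
    horizons: tuple[int, ...] = (2, 5, 15)
    eos_cap: int = 4
    iou_threshold: float = 0.5
    probe_stride_s: int = 60


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one pipeline run."""

    phase_names: tuple[str, ...] = PhaseVocabulary.default().names
    seed: int = 0
    simulator: SimulatorSettings = field(default_factory=SimulatorSettings)
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(n_classes=8))
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricSettings = field(default_factory=MetricSettings)

    @property
    def vocabulary(self) -> PhaseVocabulary:
        return PhaseVocabulary(self.phase_names)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        obj = dict(obj)
        kw: dict = {}
        if "phase_names" in obj:
            kw["phase_names"] = tuple(obj["phase_names"])
        if "seed" in obj:
            kw["seed"] = int(obj["seed"])
        if "simulator" in obj:
            sim = dict(obj["simulator"])
            if sim.get("durations_s") is not None:
                sim["durations_s"] = tuple(sim["durations_s"])
            kw["simulator"] = SimulatorSettings(**sim)
        if "model" in obj:
            kw["model"] = ModelConfig(**obj["model"])
        if "train" in obj:
            tr = dict(obj["train"])
            if tr.get("class_weights") is not None:
                tr["class_weights"] = tuple(tr["class_weights"])
            kw["train"] = TrainConfig(**tr)
        if "metrics" in obj:
            met = dict(obj["metrics"])
            if "horizons" in met:
                met["horizons"] = tuple(met["horizons"])
            kw["metrics"] = MetricSettings(**met)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with Path(path).open() as fh:
            obj = yaml.safe_load(fh) or {}
        return cls.from_dict(obj)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True))

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_hash(obj: dict) -> str:
    """SHA-256 of the canonical JSON form of a configuration dict."""
    blob = json.dumps(_jsonable(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
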