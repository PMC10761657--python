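"""Experiment configuration: YAML round-trip and deterministic seed fan-out."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .networks import NetworkConfig
from .nlm import NLMConfig
from .phantom import AcquisitionModel
from .pipeline import DeskProfile
from .training import LossConfig, TrainConfig

__all__ = ["ExperimentConfig", "subseed"]


def subseed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31) from the global seed.

    The stage name is hashed (CRC32) and mixed with the global seed so every
    pipeline stage is independently reproducible from the one seed.
    """
    h = zlib.crc32(stage.encode("utf-8"))
    return int((h ^ (global_seed * 2654435761)) % (2 ** 31))


def _build(cls, payload: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(payload)
    for key in ("grid_shape", "voxel_size_mm", "durations_s", "kernel",
                "fusion_scales"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


@dataclass
class ExperimentConfig:
    """Composition of every stage's configuration plus the global seed."""
    seed: int = 0
    out_dir: str = "petrestore_run"
    profile: DeskProfile = field(default_factory=DeskProfile)
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    nlm: NLMConfig = field(default_factory=NLMConfig)

    _SECTIONS = {"profile": DeskProfile, "acquisition": AcquisitionModel,
                 "network": NetworkConfig, "train": TrainConfig,
                 "loss": LossConfig, "nlm": NLMConfig}

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in payload.items():
            if key in cls._SECTIONS:
                kwargs[key] = _build(cls._SECTIONS[key], value or {})
            elif key in {"seed", "out_dir"}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        payload = {"seed": self.seed, "out_dir": self.out_dir}
        for key, _ in self._SECTIONS.items():
            section = asdict(getattr(self, key))
            section.pop("_extractor", None)
            payload[key] = section
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        return subseed(self.seed, stage)
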