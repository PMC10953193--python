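"""Hierarchical run configuration with YAML round-trip.

A :class:`RunConfig` composes the per-stage configs; every pipeline run
writes a frozen copy of its resolved configuration next to its outputs so
the run can be reproduced bit-for-bit at the detection-list level.
Validation happens in the component dataclasses' ``__post_init__`` hooks,
so an invalid field is rejected before any compute starts.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .froc import EvalConfig
from .inference import InferenceConfig
from .model import ModelConfig
from .phantom import PhantomConfig
from .training import AugmentConfig, TrainConfig
from .volume import PreprocessConfig


@dataclass
class RunConfig:
    seed: int = 0
    n_scans: int = 8
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig | None = None
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "phantom": PhantomConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "augment": AugmentConfig,
    "inference": InferenceConfig,
    "eval": EvalConfig,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = None if value is None else _build(_SECTIONS[key], value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration, for log lines."""
    return f"{zlib.crc32(yaml.safe_dump(_to_plain(cfg), sort_keys=True).encode()):08x}"


def derive_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31, independent of PYTHONHASHSEED."""
    return (seed * 1000003 + zlib.crc32(tag.encode())) % (2 ** 31 - 1)


def desk_config(seed: int = 0) -> RunConfig:
    """Desk-scale preset: CPU-sized end-to-end run on synthetic phantoms.

    Uses the reduced-width CSP-ResNeXt + FPN + nearest-anchor detector and a
    short training schedule (30 epochs over ~24 patches of 64 voxels cubed)
    with the plain-Adam optimizer option: at a few hundred optimizer steps
    the rectified-Adam warm-up of the full-scale Ranger recipe would consume
    most of the schedule.  The full-scale defaults in
    :class:`noduledet.training.TrainConfig` keep the published recipe
    (Ranger, 200 epochs).
    """
    from .training import AugmentConfig, TrainConfig

    return RunConfig(
        seed=seed,
        n_scans=6,
        train=TrainConfig(optimizer="adam", epochs=30, batch_size=1),
        augment=AugmentConfig(),
    )
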