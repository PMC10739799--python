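"""YAML run configuration: one file, one block per pipeline stage.

Blocks map directly onto the stage parameter dataclasses
(``scene:`` -> SceneParams, ``preprocess:`` -> AugmentSpec + CLAHE options,
``model:`` -> ModelConfig, ``train:`` -> TrainConfig, ``loss:`` ->
LossConfig, ``analysis:`` -> free options). A global ``seed`` propagates to
every stochastic stage unless a block pins its own.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .losses import LossConfig
from .nn.dcau import ModelConfig
from .preprocess import AugmentSpec
from .synthetic import SceneParams
from .training import TrainConfig

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


def _build(cls, block: dict, label: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"unknown keys in '{label}:' block: {sorted(unknown)}")
    kw = dict(block)
    for key in ("rotations", "flips", "cell_ecc_range"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    try:
        return cls(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{label}:' block: {exc}") from exc


@dataclasses.dataclass
class RunConfig:
    scene: SceneParams
    augment: AugmentSpec
    model: ModelConfig
    train: TrainConfig
    loss: LossConfig
    clahe: dict
    analysis: dict
    seed: int
    out_root: Path
    log_level: str
    raw: dict

    @classmethod
    def from_dict(cls, d: dict, path: Path | None = None) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        seed = int(d.get("seed", 0))

        def seeded(block: dict) -> dict:
            out = dict(block)
            out.setdefault("seed", seed)
            return out

        pre = dict(d.get("preprocess", {}))
        clahe = {"clip_limit": pre.pop("clip_limit", 0.01),
                 "grid": tuple(pre.pop("grid", (8, 8))),
                 "before_crop": pre.pop("before_crop", True)}
        return cls(
            scene=_build(SceneParams, seeded(d.get("scene", {})), "scene"),
            augment=_build(AugmentSpec, seeded(pre), "preprocess"),
            model=_build(ModelConfig, seeded(d.get("model", {})), "model"),
            train=_build(TrainConfig, seeded(d.get("train", {})), "train"),
            loss=_build(LossConfig, d.get("loss", {}), "loss"),
            clahe=clahe,
            analysis=dict(d.get("analysis", {})),
            seed=seed,
            out_root=Path(d.get("out_root", "gobletseg_out")),
            log_level=str(d.get("log_level", "INFO")),
            raw=d,
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    return RunConfig.from_dict(d, path)
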