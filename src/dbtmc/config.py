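"""Single structured run configuration with strict key checking.

One document drives a whole experiment: phantom parameters, slab depth N,
architecture variants for both branches, ensemble weights and training
settings.  Unknown keys are rejected so typos fail loudly, and every run
writes its resolved configuration beside its outputs.

The defaults describe a desk-scale experiment (small ROIs and
reduced-width networks) that a CPU completes in minutes; the full-width
architectures of the published design are selected by overriding the
``net2d``/``net3d`` sections and the phantom ROI shape.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .networks import Aniso3dNetConfig
from .phantom import PhantomParams
from .preprocess import SlabConfig
from .training import TrainConfig

__all__ = ["Net2dConfig", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class Net2dConfig:
    """Residual-depth configuration of the 2D branch.

    (3, 4, 6, 3) x (64, 128, 256, 512) is the 34-layer design; the default
    here is a reduced-width desk variant.
    """

    block_modules: tuple[int, ...] = (1, 1, 1, 1)
    block_channels: tuple[int, ...] = (8, 16, 32, 64)
    dropout_p: float = 0.5

    @classmethod
    def resnet34(cls) -> "Net2dConfig":
        return cls(block_modules=(3, 4, 6, 3), block_channels=(64, 128, 256, 512))


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    phantom: PhantomParams = field(
        default_factory=lambda: PhantomParams.easy_desk(50, 50)
    )
    slab: SlabConfig = field(
        default_factory=lambda: SlabConfig(n_slices=8, resize_2d=(56, 56))
    )
    net2d: Net2dConfig = field(default_factory=Net2dConfig)
    net3d: Aniso3dNetConfig = field(default_factory=Aniso3dNetConfig.desk)
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(batch_size=8, augment_factors=(4, 4))
    )
    ensemble_weights: tuple[float, ...] = (0.5, 0.3, 0.7)
    use_oracle_focus: bool = True


_SECTIONS = {
    "phantom": PhantomParams,
    "slab": SlabConfig,
    "net2d": Net2dConfig,
    "net3d": Aniso3dNetConfig,
    "train": TrainConfig,
}


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path_or_dict) -> RunConfig:
    """Build a RunConfig from a YAML file or a plain dict; strict keys."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_dict)
    top_known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {})
    for name in ("seed", "use_oracle_focus"):
        if name in data:
            kwargs[name] = data[name]
    if "ensemble_weights" in data:
        kwargs["ensemble_weights"] = tuple(data["ensemble_weights"])
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML."""

    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(plain(cfg), fh, sort_keys=False)
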