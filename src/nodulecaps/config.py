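"""Run configuration: presets, seeds and the plain-text config format.

Two presets exist. ``tiny`` is the desk-scale configuration used throughout
the tests: 40x40 patch grids, 8 convolution maps and 4 primary-capsule
channels, which one CPU trains in seconds per scale. ``paper`` instantiates
the full-scale architecture (80x80 inputs, 256 maps, 32 primary channels,
fusion hidden sizes 1028/512/256); it is provided for completeness and for
architecture checks — training it requires real data and far more compute.

Config files are plain ``key = value`` lines (``#`` comments allowed), with
dotted keys reaching into sub-configs, e.g.::

    preset = tiny
    seed = 7
    cohort.n_patients = 30
    train.epochs_scale = 20
    bce.alpha = 2
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

from .baseline import TINY_BASELINE, BaselineSpec
from .capsule import TINY_CAPSNET, CapsNetConfig, MarginLossParams
from .fusion import TINY_FUSION, FusionSpec, WeightedBCEParams
from .synthetic import SyntheticConfig


@dataclass(frozen=True)
class TrainSettings:
    """Adam optimizer settings shared by all trained networks."""

    lr: float = 1e-3
    epochs_scale: int = 25
    epochs_fusion: int = 200
    batch_size: int = 16


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every stage derives its seed from here."""

    preset: str = "tiny"
    seed: int = 0
    out_size: int = 40
    cohort: SyntheticConfig = field(default_factory=SyntheticConfig)
    capsnet: CapsNetConfig = TINY_CAPSNET
    baseline: BaselineSpec = TINY_BASELINE
    fusion: FusionSpec = TINY_FUSION
    margin: MarginLossParams = MarginLossParams()
    bce: WeightedBCEParams = WeightedBCEParams()
    train: TrainSettings = TrainSettings()
    with_baseline: bool = True

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "RunConfig":
        cfg = cls(preset="tiny", seed=seed, cohort=SyntheticConfig(seed=seed))
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def paper(cls, seed: int = 0) -> "RunConfig":
        return cls(
            preset="paper",
            seed=seed,
            out_size=80,
            cohort=SyntheticConfig(seed=seed),
            capsnet=CapsNetConfig(),
            baseline=BaselineSpec(),
            fusion=FusionSpec(),
        )

    @classmethod
    def from_preset(cls, name: str, seed: int = 0) -> "RunConfig":
        if name == "tiny":
            return cls.tiny(seed)
        if name == "paper":
            return cls.paper(seed)
        raise ValueError(f"unknown preset {name!r}; choose 'tiny' or 'paper'")

    def resolved(self) -> dict:
        """All resolved values, for the run manifest."""
        return dataclasses.asdict(self)


def _coerce(current, text: str):
    if isinstance(current, bool):
        return text.strip().lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(text)
    if isinstance(current, float):
        return float(text)
    if isinstance(current, tuple):
        parts = [p for p in text.replace(",", " ").split() if p]
        elem = current[0] if current else 0
        return tuple(type(elem)(p) if not isinstance(elem, float) else float(p) for p in parts)
    return text.strip()


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a key = value config file into a RunConfig."""
    lines = Path(path).read_text().splitlines()
    kv: dict[str, str] = {}
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {raw!r}")
        k, v = (p.strip() for p in line.split("=", 1))
        kv[k] = v
    cfg = RunConfig.from_preset(kv.pop("preset", "tiny"), seed=int(kv.pop("seed", "0")))
    cfg.cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    for key, text in kv.items():
        obj, attr = cfg, key
        if "." in key:
            prefix, attr = key.split(".", 1)
            if not hasattr(cfg, prefix):
                raise ValueError(f"unknown config section {prefix!r}")
            obj = getattr(cfg, prefix)
        if not hasattr(obj, attr):
            raise ValueError(f"unknown config key {key!r}")
        value = _coerce(getattr(obj, attr), text)
        if obj is cfg:
            setattr(cfg, attr, value)
        else:
            setattr(cfg, key.split(".", 1)[0], dataclasses.replace(obj, **{attr: value}))
    return cfg
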