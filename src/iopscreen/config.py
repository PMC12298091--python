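"""Run configuration: nested, strictly validated, JSON/YAML round-trippable."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


def _strict_from_dict(cls, data: dict):
    import typing

    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        ftype = hints.get(f.name, f.type)
        if dataclasses.is_dataclass(ftype) and isinstance(v, dict):
            v = _strict_from_dict(ftype, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class SynthSection:
    n: int = 200
    image_size: int = 64
    noise_sd: float = 0.05


@dataclass
class AugmentSection:
    mode: str = "classic"          # {"classic", "cyclegan"}
    n_per_class: int = 100
    epochs: int = 5                # cyclegan only
    cycle_weight: float = 10.0
    width: int = 8


@dataclass
class QCSection:
    enabled: bool = True
    threshold: float = 0.7
    feature_nodes: int = 200
    enhancement_nodes: int = 100
    ridge_lambda: float = 1e-2


@dataclass
class BackboneSection:
    preset: str = "tiny"           # {"tiny", "full"}
    init: str = "phantom-pretrain"  # {"random", "phantom-pretrain"}
    pretrain_epochs: int = 5
    epochs: int = 8
    freeze: tuple[str, ...] = ("patch_embed", "stage0")
    lr: float = 3e-3


@dataclass
class FusionSection:
    width: int = 16
    n_knots: int = 16
    degree: int = 3
    l1_lambda: float = 1e-4
    dropout_p0: float = 0.2
    dropout_beta: float = 0.1
    epochs: int = 60
    patience: int = 10


@dataclass
class ExplainSection:
    stage: int = 1
    n_images: int = 20


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; all randomness flows from ``seed``."""

    seed: int = 0
    out_dir: str = "runs/out"
    verbosity: int = 1
    synth: SynthSection = field(default_factory=SynthSection)
    augment: AugmentSection = field(default_factory=AugmentSection)
    qc: QCSection = field(default_factory=QCSection)
    backbone: BackboneSection = field(default_factory=BackboneSection)
    fusion: FusionSection = field(default_factory=FusionSection)
    explain: ExplainSection = field(default_factory=ExplainSection)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _strict_from_dict(cls, data)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.as_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))
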