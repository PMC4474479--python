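"""Structured run configuration (YAML), with strict unknown-key rejection."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import (
    CONTROL_EFFECTS,
    DetectionParams,
    DrugEffect,
    HitCriteria,
    KineticsParams,
    ParameterError,
    RenderParams,
    SegmentationParams,
    params_from_dict,
)
from .platemap import PlateMap, read_platemap

_TOP_KEYS = {
    "kinetics",
    "render",
    "segmentation",
    "detection",
    "criteria",
    "effects",
    "seed",
    "fields_per_well",
    "simulate",
    "write_images",
    "platemap",
    "images_dir",
    "out_dir",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, validated sub-block by sub-block."""

    kinetics: KineticsParams = field(default_factory=KineticsParams)
    render: RenderParams = field(default_factory=RenderParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    criteria: HitCriteria = field(default_factory=HitCriteria)
    effects: dict[str, DrugEffect] = field(default_factory=lambda: dict(CONTROL_EFFECTS))
    seed: int = 0
    fields_per_well: int = 4
    simulate: bool = True
    write_images: bool = False
    platemap: str | None = None
    images_dir: str | None = None
    out_dir: str = "fociscreen_out"

    def load_platemap(self) -> PlateMap:
        if self.platemap is None:
            raise ParameterError("config has no platemap path")
        return read_platemap(self.platemap)

    def echo(self) -> dict:
        """Plain-dict parameter echo for the run manifest."""
        from dataclasses import asdict

        return {
            "kinetics": asdict(self.kinetics),
            "render": asdict(self.render),
            "segmentation": asdict(self.segmentation),
            "detection": asdict(self.detection),
            "criteria": asdict(self.criteria),
            "effects": {k: asdict(v) for k, v in self.effects.items()},
            "seed": self.seed,
            "fields_per_well": self.fields_per_well,
            "simulate": self.simulate,
            "write_images": self.write_images,
            "platemap": self.platemap,
            "images_dir": self.images_dir,
        }


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    blocks = {
        "kinetics": KineticsParams,
        "render": RenderParams,
        "segmentation": SegmentationParams,
        "detection": DetectionParams,
        "criteria": HitCriteria,
    }
    for name, cls in blocks.items():
        if name in data:
            kwargs[name] = params_from_dict(cls, data[name] or {}, context=name)
    if "effects" in data:
        effects = {}
        for comp, block in (data["effects"] or {}).items():
            effects[str(comp)] = params_from_dict(DrugEffect, block or {}, context=f"effects.{comp}")
        kwargs["effects"] = effects
    for name in ("seed", "fields_per_well", "simulate", "write_images", "platemap", "images_dir", "out_dir"):
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must hold a mapping")
    return config_from_dict(data)


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"
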