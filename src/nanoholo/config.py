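"""Pipeline configuration: strict, file-round-trippable dataclass wiring."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detection import FrangiParams
from .holography import AcquisitionGeometry
from .levelset import SfmParams
from .phantom import CellSpec, PhantomSpec

__all__ = ["ConfigError", "PipelineConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _strict_build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _plain(value):
    """Recursively convert to YAML-safe builtins."""
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    return value


@dataclass
class PipelineConfig:
    """Everything one hierarchical run needs, losslessly file-representable."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    frangi: FrangiParams = field(default_factory=lambda: FrangiParams.for_gray_range(1.0))
    sfm: SfmParams = field(default_factory=SfmParams)
    roi_shape: tuple[int, int, int] = (96, 96, 96)
    prescan_bin: int = 2
    min_overlap: float = 0.5  # sensitivity matching criterion
    output_dir: str = "runs"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.roi_shape = tuple(int(s) for s in self.roi_shape)
        if len(self.roi_shape) != 3 or any(s <= 0 for s in self.roi_shape):
            raise ConfigError(f"roi_shape must be three positive ints, got {self.roi_shape}")
        if self.prescan_bin < 1:
            raise ConfigError("prescan_bin must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "phantom": dataclasses.asdict(self.phantom),
            "geometry": dataclasses.asdict(self.geometry),
            "frangi": dataclasses.asdict(self.frangi),
            "sfm": dataclasses.asdict(self.sfm),
            "roi_shape": list(self.roi_shape),
            "prescan_bin": self.prescan_bin,
            "min_overlap": self.min_overlap,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return _plain(d)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
        kwargs = dict(data)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            cells = ph.pop("cells", [])
            spec = _strict_build(PhantomSpec, ph, "phantom")
            spec.cells = [_strict_build(CellSpec, dict(c), f"phantom.cells[{i}]")
                          for i, c in enumerate(cells)]
            kwargs["phantom"] = spec
        if "geometry" in kwargs:
            kwargs["geometry"] = _strict_build(AcquisitionGeometry,
                                               dict(kwargs["geometry"]), "geometry")
        if "frangi" in kwargs:
            kwargs["frangi"] = _strict_build(FrangiParams, dict(kwargs["frangi"]), "frangi")
        if "sfm" in kwargs:
            kwargs["sfm"] = _strict_build(SfmParams, dict(kwargs["sfm"]), "sfm")
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)
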