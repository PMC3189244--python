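"""Flat key=value pipeline configuration.

One namespace covers the segmentation and gridding parameters plus the
mapping options; unknown keys are rejected so typos never silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

from .gridding import GriddingParams
from .segmentation import SegmentationParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with their module defaults."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    gridding: GriddingParams = field(default_factory=GriddingParams)
    orientation: str = "R0"
    downsample: int = 100

    _SCALARS = ("orientation", "downsample")

    def flat(self) -> dict[str, str]:
        """Flatten to the key=value form used by config files."""
        out: dict[str, str] = {}
        for f in fields(self.segmentation):
            out[f.name] = str(getattr(self.segmentation, f.name))
        for f in fields(self.gridding):
            val = getattr(self.gridding, f.name)
            if isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            out[f.name] = str(val)
        out["orientation"] = self.orientation
        out["downsample"] = str(self.downsample)
        return out

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.flat().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        pairs: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines()):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {i + 1}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            pairs[key] = val
        return cls.from_pairs(pairs)

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "PipelineConfig":
        """Build a config from string key/value pairs; unknown keys raise."""
        seg_fields = {f.name: f for f in fields(SegmentationParams)}
        grid_fields = {f.name: f for f in fields(GriddingParams)}
        seg_kw, grid_kw, scalar_kw = {}, {}, {}
        for key, val in pairs.items():
            if key in seg_fields:
                seg_kw[key] = _coerce(val, seg_fields[key].type)
            elif key in grid_fields:
                if key == "kmeans_seeds":
                    grid_kw[key] = tuple(float(v) for v in val.split(","))
                else:
                    grid_kw[key] = _coerce(val, grid_fields[key].type)
            elif key == "orientation":
                scalar_kw[key] = val
            elif key == "downsample":
                scalar_kw[key] = int(val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(
            segmentation=SegmentationParams(**seg_kw),
            gridding=GriddingParams(**grid_kw),
            **scalar_kw,
        )

    def replace(self, **overrides) -> "PipelineConfig":
        """Config with the given flat keys overridden (string values)."""
        pairs = self.flat()
        pairs.update({k: str(v) for k, v in overrides.items()})
        return self.from_pairs(pairs)


def _coerce(value: str, annotation) -> object:
    ann = str(annotation)
    if "int" in ann:
        return int(value)
    if "float" in ann:
        return float(value)
    return value
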