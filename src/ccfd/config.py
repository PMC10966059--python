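"""Pipeline configuration with lossless JSON/YAML round-tripping.

``PipelineConfig`` bundles the generator conditions (:class:`SynthConfig`)
with the analysis tunables (:class:`AnalysisParams`).  Every numeric constant
of the canonical protocol appears here with its standard value as default:
the 3-px threshold radius, the 24 um minimum deficit diameter, the 100 um
ring width, and the three 10-um slabs at 11/21/31 um below the RPE-fit
centreline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .binarize import PhansalkarParams
from .compensation import CompensationParams
from .geometry import ImageGeometry, SlabSpec
from .pipeline import AnalysisParams
from .synthetic import SynthConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    log_level: str = "INFO"

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [enc(x) for x in obj]
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = dict(d.get("synth", {}))
        if "geometry" in synth:
            synth["geometry"] = ImageGeometry(**synth["geometry"])
        if "slabs" in synth:
            synth["slabs"] = tuple(SlabSpec(**s) for s in synth["slabs"])
        analysis = dict(d.get("analysis", {}))
        if "compensation" in analysis:
            analysis["compensation"] = CompensationParams(**analysis["compensation"])
        if "phansalkar" in analysis:
            analysis["phansalkar"] = PhansalkarParams(**analysis["phansalkar"])
        return cls(
            synth=SynthConfig(**synth),
            analysis=AnalysisParams(**analysis),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
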