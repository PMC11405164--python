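"""Run configuration: every tunable of the pipeline in one serializable block.

Defaults are the instrument's published operating point: 90 Hz sampling,
125 lux pulses, 3 cycles, 1/9 mm diameter cut-offs, 90-sample maximum gap,
100-sample running mean.  Round-trips losslessly through YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from .protocol import ProtocolTimeline, build_default_timeline

__all__ = [
    "TimelineConfig",
    "PreprocessConfig",
    "ReflexConfig",
    "DiagnosticsConfig",
    "RunConfig",
]


class TimelineConfig(BaseModel):
    sample_rate_hz: float = 90.0
    intensity_lux: float = 125.0
    n_cycles: int = 3
    dark_adapt_s: float = 5.0
    pulse_s: float = 1.0
    dark_s: float = 3.0
    cycle_order: Literal["alternating", "blocked"] = "alternating"


class PreprocessConfig(BaseModel):
    lo_mm: float = 1.0
    hi_mm: float = 9.0
    max_gap_samples: int = 90
    smooth_window: int = 100
    #: reproduce the literal published order (smooth, then cut-offs, then
    #: interpolation) instead of the default flag -> interpolate -> smooth
    paper_order: bool = False

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.lo_mm < self.hi_mm):
            raise ValueError("need 0 < lo_mm < hi_mm")
        return self


class ReflexConfig(BaseModel):
    baseline_window_s: float = 0.5
    response_window_s: float = 2.5
    efferent_ratio: float = 1.25
    aggregate: Literal["mean", "median"] = "mean"


class DiagnosticsConfig(BaseModel):
    quantile: float = 0.25
    seed: int = 0


class RunConfig(BaseModel):
    timeline: TimelineConfig = Field(default_factory=TimelineConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    reflex: ReflexConfig = Field(default_factory=ReflexConfig)
    diagnostics: DiagnosticsConfig = Field(default_factory=DiagnosticsConfig)

    def build_timeline(self) -> ProtocolTimeline:
        t = self.timeline
        return build_default_timeline(
            sample_rate_hz=t.sample_rate_hz,
            intensity_lux=t.intensity_lux,
            n_cycles=t.n_cycles,
            dark_adapt_s=t.dark_adapt_s,
            pulse_s=t.pulse_s,
            dark_s=t.dark_s,
            cycle_order=t.cycle_order,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
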