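"""Automated swinging-flashlight stimulus timeline.

The default protocol follows the clinical convention for automated RAPD
testing: an initial dark-adaptation period, a binocular conditioning pulse,
then alternating monocular light pulses (left eye first), each pulse followed
by a fixed dark interval.  Times are seconds from recording start; intervals
are half-open ``[start, end)``; sample ``i`` of a recording covers time
``i / sample_rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

__all__ = [
    "Eye",
    "StimEpoch",
    "ProtocolTimeline",
    "AnalysisWindow",
    "build_default_timeline",
    "analysis_windows",
]


class Eye(str, Enum):
    """Which eye an epoch stimulates (or which pupil responds)."""

    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"
    NONE = "none"

    @property
    def fellow(self) -> "Eye":
        if self is Eye.LEFT:
            return Eye.RIGHT
        if self is Eye.RIGHT:
            return Eye.LEFT
        raise ValueError(f"{self} has no fellow eye")


@dataclass(frozen=True)
class StimEpoch:
    """One stimulation epoch: an optional light pulse plus the dark interval
    that follows it.  Dark-only epochs have ``eye_stimulated = Eye.NONE`` and
    zero pulse duration."""

    eye_stimulated: Eye
    onset_s: float
    pulse_duration_s: float
    dark_duration_s: float
    intensity_lux: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("epoch onset must be >= 0")
        if self.eye_stimulated is Eye.NONE:
            if self.pulse_duration_s != 0:
                raise ValueError("dark epoch cannot carry a light pulse")
        elif self.pulse_duration_s <= 0:
            raise ValueError("light epoch needs a positive pulse duration")
        if self.dark_duration_s < 0:
            raise ValueError("dark duration must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.pulse_duration_s + self.dark_duration_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def is_light(self) -> bool:
        return self.eye_stimulated is not Eye.NONE

    @property
    def is_monocular(self) -> bool:
        return self.eye_stimulated in (Eye.LEFT, Eye.RIGHT)

    def to_dict(self) -> dict:
        return {
            "eye_stimulated": self.eye_stimulated.value,
            "onset_s": self.onset_s,
            "pulse_duration_s": self.pulse_duration_s,
            "dark_duration_s": self.dark_duration_s,
            "intensity_lux": self.intensity_lux,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimEpoch":
        return cls(
            eye_stimulated=Eye(d["eye_stimulated"]),
            onset_s=float(d["onset_s"]),
            pulse_duration_s=float(d["pulse_duration_s"]),
            dark_duration_s=float(d["dark_duration_s"]),
            intensity_lux=float(d.get("intensity_lux", 0.0)),
        )


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered, contiguous stimulation epochs tiling ``[0, total_duration_s)``."""

    epochs: tuple[StimEpoch, ...]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if not self.epochs:
            raise ValueError("timeline needs at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        t = 0.0
        for ep in self.epochs:
            if abs(ep.onset_s - t) > 1e-9:
                raise ValueError(
                    f"epochs must be contiguous: expected onset {t}, got {ep.onset_s}"
                )
            t = ep.end_s

    @property
    def total_duration_s(self) -> float:
        return sum(ep.duration_s for ep in self.epochs)

    @property
    def n_samples(self) -> int:
        return round(self.total_duration_s * self.sample_rate_hz)

    @property
    def light_epochs(self) -> tuple[StimEpoch, ...]:
        return tuple(ep for ep in self.epochs if ep.is_light)

    @property
    def monocular_epochs(self) -> tuple[StimEpoch, ...]:
        return tuple(ep for ep in self.epochs if ep.is_monocular)

    def pulses_for(self, eye: Eye) -> tuple[StimEpoch, ...]:
        return tuple(ep for ep in self.epochs if ep.eye_stimulated is eye)

    def preceding_epoch(self, epoch: StimEpoch) -> StimEpoch | None:
        idx = self.epochs.index(epoch)
        return self.epochs[idx - 1] if idx > 0 else None

    def __iter__(self) -> Iterator[StimEpoch]:
        return iter(self.epochs)

    def to_dict(self) -> dict:
        return {
            "sample_rate_hz": self.sample_rate_hz,
            "epochs": [ep.to_dict() for ep in self.epochs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolTimeline":
        return cls(
            epochs=tuple(StimEpoch.from_dict(e) for e in d["epochs"]),
            sample_rate_hz=float(d["sample_rate_hz"]),
        )


def build_default_timeline(
    sample_rate_hz: float = 90.0,
    intensity_lux: float = 125.0,
    n_cycles: int = 3,
    *,
    dark_adapt_s: float = 5.0,
    pulse_s: float = 1.0,
    dark_s: float = 3.0,
    cycle_order: str = "alternating",
) -> ProtocolTimeline:
    """Build the standard stimulation sequence.

    Dark adaptation (5 s), a binocular 1 s pulse + 3 s dark, then ``n_cycles``
    of [left 1 s pulse + 3 s dark, right 1 s pulse + 3 s dark].  The left eye
    is always stimulated first.  ``cycle_order`` selects per-cycle alternation
    (``"alternating"``, the swinging-flashlight convention, default) or a
    blocked order (``"blocked"``: all left pulses, then all right); total
    duration is identical either way.

    Defaults: 90 Hz sampling, 125 lux, 3 cycles, total 5 + 4 + 3*8 = 33 s.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if cycle_order not in ("alternating", "blocked"):
        raise ValueError("cycle_order must be 'alternating' or 'blocked'")

    epochs: list[StimEpoch] = [
        StimEpoch(Eye.NONE, 0.0, 0.0, dark_adapt_s),
        StimEpoch(Eye.BOTH, dark_adapt_s, pulse_s, dark_s, intensity_lux),
    ]
    t = dark_adapt_s + pulse_s + dark_s
    if cycle_order == "alternating":
        order = [Eye.LEFT, Eye.RIGHT] * n_cycles
    else:
        order = [Eye.LEFT] * n_cycles + [Eye.RIGHT] * n_cycles
    for eye in order:
        epochs.append(StimEpoch(eye, t, pulse_s, dark_s, intensity_lux))
        t += pulse_s + dark_s
    return ProtocolTimeline(epochs=tuple(epochs), sample_rate_hz=sample_rate_hz)


@dataclass(frozen=True)
class AnalysisWindow:
    """Baseline and response intervals (half-open, seconds) for a light epoch."""

    epoch: StimEpoch
    baseline: tuple[float, float]
    response: tuple[float, float]

    @property
    def cycle_key(self) -> tuple[str, float]:
        return (self.epoch.eye_stimulated.value, self.epoch.onset_s)


def analysis_windows(
    timeline: ProtocolTimeline,
    baseline_window_s: float = 0.5,
    response_window_s: float = 2.5,
) -> list[AnalysisWindow]:
    """Derive per-epoch measurement windows for every light epoch.

    The baseline interval is the last ``baseline_window_s`` of the dark period
    immediately preceding the pulse; the response interval runs from pulse
    onset for ``response_window_s``.
    """
    if baseline_window_s <= 0 or response_window_s <= 0:
        raise ValueError("analysis windows must be positive")
    out: list[AnalysisWindow] = []
    for ep in timeline.light_epochs:
        prev = timeline.preceding_epoch(ep)
        if prev is None:
            raise ValueError("light epoch has no preceding dark interval")
        if baseline_window_s > prev.dark_duration_s + 1e-9:
            raise ValueError(
                f"baseline window {baseline_window_s}s exceeds preceding dark "
                f"duration {prev.dark_duration_s}s"
            )
        if response_window_s > ep.duration_s + 1e-9:
            raise ValueError(
                f"response window {response_window_s}s exceeds pulse+dark "
                f"duration {ep.duration_s}s"
            )
        out.append(
            AnalysisWindow(
                epoch=ep,
                baseline=(ep.onset_s - baseline_window_s, ep.onset_s),
                response=(ep.onset_s, ep.onset_s + response_window_s),
            )
        )
    return out
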