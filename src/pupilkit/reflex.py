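"""Pupillary light reflex measurement and RAPD scoring.

For every monocular light pulse, each pupil's constriction is expressed as the
percentage change from its dark-adapted baseline just before the pulse:

    constriction% = 100 * (baseline - trough) / baseline

where the baseline is the mean diameter over the tail of the preceding dark
interval and the trough is the minimum over the response window.  The response
of the stimulated eye is the direct reflex; the fellow eye's simultaneous
response is the consensual reflex.

The RAPD score is the ratio of the two eyes' mean direct constrictions, taken
stronger over weaker so it is always >= 1 (one-tailed); the raw OD/OS ratio
(two-tailed) is also reported.  A consensual-asymmetry screen withholds the
score when the response pattern indicates an efferent (motor) rather than
afferent (sensory) defect: an efferent defect weakens one pupil regardless of
which eye is stimulated, whereas an afferent defect weakens both pupils'
responses only when the affected eye is stimulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .preprocess import QualityReport
from .protocol import AnalysisWindow, Eye, ProtocolTimeline, analysis_windows
from .trace import PupilTrace, sample_slice

__all__ = [
    "ReflexMeasurement",
    "ReflexSummary",
    "EfferentScreen",
    "RAPDResult",
    "measure_epoch",
    "summarize",
    "detect_efferent_defect",
    "rapd_score",
]

DEFAULT_EFFERENT_RATIO = 1.25


@dataclass(frozen=True)
class ReflexMeasurement:
    stimulated_eye: Eye
    responding_eye: Eye
    cycle_index: int
    baseline_mm: float
    trough_mm: float
    constriction_pct: float
    #: raw percentage before flooring dilations at zero
    raw_constriction_pct: float = 0.0

    @property
    def is_direct(self) -> bool:
        return self.stimulated_eye is self.responding_eye

    def to_dict(self) -> dict:
        return {
            "stimulated_eye": self.stimulated_eye.value,
            "responding_eye": self.responding_eye.value,
            "cycle_index": self.cycle_index,
            "baseline_mm": self.baseline_mm,
            "trough_mm": self.trough_mm,
            "constriction_pct": self.constriction_pct,
            "raw_constriction_pct": self.raw_constriction_pct,
        }


@dataclass
class ReflexSummary:
    """Per-cycle reflex measurements plus per-eye aggregates."""

    measurements: list[ReflexMeasurement]
    aggregate: str = "mean"  # or "median"

    def _agg(self, values: list[float]) -> float:
        if not values:
            raise ValueError("no measurements to aggregate")
        return float(median(values)) if self.aggregate == "median" else float(np.mean(values))

    def replicates(self, stimulated: Eye, responding: Eye) -> list[float]:
        return [
            m.constriction_pct
            for m in self.measurements
            if m.stimulated_eye is stimulated and m.responding_eye is responding
        ]

    def response_pct(self, stimulated: Eye, responding: Eye) -> float:
        return self._agg(self.replicates(stimulated, responding))

    def direct_pct(self, eye: Eye) -> float:
        return self.response_pct(eye, eye)

    def consensual_pct(self, eye: Eye) -> float:
        """Response of ``eye`` while the fellow eye is stimulated."""
        return self.response_pct(eye.fellow, eye)

    def direct_sd(self, eye: Eye) -> float:
        reps = self.replicates(eye, eye)
        return float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0

    def consensual_sd(self, eye: Eye) -> float:
        reps = self.replicates(eye.fellow, eye)
        return float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0

    def to_dict(self) -> dict:
        out: dict = {"measurements": [m.to_dict() for m in self.measurements]}
        for eye in (Eye.LEFT, Eye.RIGHT):
            out[f"direct_{eye.value}_pct"] = self.direct_pct(eye)
            out[f"direct_{eye.value}_sd"] = self.direct_sd(eye)
            out[f"consensual_{eye.value}_pct"] = self.consensual_pct(eye)
            out[f"consensual_{eye.value}_sd"] = self.consensual_sd(eye)
        return out


@dataclass(frozen=True)
class EfferentScreen:
    flag: bool
    reason: str = ""
    #: within-stimulation larger/smaller response ratio per stimulated side
    asymmetry: dict = field(default_factory=dict)


@dataclass
class RAPDResult:
    """One subject's RAPD outcome.

    ``score_one_tailed`` is stronger/weaker mean direct constriction (>= 1);
    ``score_two_tailed`` is OD/OS.  Scores are absent (None) when the quality
    gate fails, the efferent screen trips, or the weaker eye is non-reactive.
    """

    score_one_tailed: float | None
    weaker_eye: Eye
    score_two_tailed: float | None
    efferent_flag: bool
    quality: QualityReport
    reason: str = ""

    @property
    def scorable(self) -> bool:
        return self.score_one_tailed is not None

    def to_dict(self) -> dict:
        return {
            "score_one_tailed": self.score_one_tailed,
            "weaker_eye": self.weaker_eye.value,
            "score_two_tailed": self.score_two_tailed,
            "efferent_flag": self.efferent_flag,
            "quality": self.quality.to_dict(),
            "reason": self.reason,
        }


def measure_epoch(
    trace: PupilTrace,
    window: AnalysisWindow | tuple[tuple[float, float], tuple[float, float]],
    stimulated_eye: Eye,
    responding_eye: Eye,
    cycle_index: int = 0,
) -> ReflexMeasurement:
    """Measure one pupil's constriction for one light epoch.

    Baseline = mean diameter over the baseline interval; trough = minimum over
    the response interval; negative constrictions (net dilation) are floored
    at zero so downstream ratios stay defined, with the raw value retained.
    """
    if isinstance(window, AnalysisWindow):
        baseline_iv, response_iv = window.baseline, window.response
    else:
        baseline_iv, response_iv = window
    vals = trace.values(responding_eye)
    b = vals[sample_slice(baseline_iv, trace.sample_rate_hz, trace.n_samples)]
    r = vals[sample_slice(response_iv, trace.sample_rate_hz, trace.n_samples)]
    if np.any(np.isnan(b)) or np.any(np.isnan(r)):
        raise ValueError("measurement windows contain missing samples; preprocess first")
    baseline = float(np.mean(b))
    trough = float(np.min(r))
    raw_pct = 100.0 * (baseline - trough) / baseline
    return ReflexMeasurement(
        stimulated_eye=stimulated_eye,
        responding_eye=responding_eye,
        cycle_index=cycle_index,
        baseline_mm=baseline,
        trough_mm=trough,
        constriction_pct=max(raw_pct, 0.0),
        raw_constriction_pct=raw_pct,
    )


def summarize(
    trace: PupilTrace,
    timeline: ProtocolTimeline,
    baseline_window_s: float = 0.5,
    response_window_s: float = 2.5,
    aggregate: str = "mean",
) -> ReflexSummary:
    """Measure both pupils' responses to every monocular pulse.

    The binocular conditioning pulse serves light adaptation and is excluded.
    With the default 3-cycle protocol this yields 12 measurements
    (6 pulses x 2 responding eyes).
    """
    windows = analysis_windows(timeline, baseline_window_s, response_window_s)
    cycle_counter = {Eye.LEFT: 0, Eye.RIGHT: 0}
    measurements: list[ReflexMeasurement] = []
    for w in windows:
        stim = w.epoch.eye_stimulated
        if stim not in (Eye.LEFT, Eye.RIGHT):
            continue
        cycle = cycle_counter[stim]
        cycle_counter[stim] += 1
        for responding in (Eye.LEFT, Eye.RIGHT):
            measurements.append(
                measure_epoch(trace, w, stim, responding, cycle_index=cycle)
            )
    return ReflexSummary(measurements=measurements, aggregate=aggregate)


def detect_efferent_defect(
    summary: ReflexSummary,
    asymmetry_ratio: float = DEFAULT_EFFERENT_RATIO,
) -> EfferentScreen:
    """Screen the consensual responses for an efferent-pathway defect.

    For each stimulated side, compare the two pupils' responses *within that
    same stimulation* (direct vs consensual).  The flag trips iff the same
    pupil is the weaker responder under both left- and right-eye stimulation
    and both within-stimulation ratios exceed ``asymmetry_ratio``.  An
    afferent defect attenuates both pupils together when the affected eye is
    stimulated and therefore never trips the flag.  A non-reactive pupil
    (zero constriction in a denominator) is flagged outright.
    """
    if asymmetry_ratio <= 1:
        raise ValueError("asymmetry_ratio must exceed 1")
    weaker_by_side: dict[str, Eye | None] = {}
    ratios: dict[str, float] = {}
    for stim in (Eye.LEFT, Eye.RIGHT):
        resp = {eye: summary.response_pct(stim, eye) for eye in (Eye.LEFT, Eye.RIGHT)}
        weaker = min(resp, key=resp.get)  # type: ignore[arg-type]
        lo, hi = resp[weaker], max(resp.values())
        if lo <= 0:
            return EfferentScreen(
                flag=True,
                reason="non-reactive pupil",
                asymmetry={stim.value: float("inf") if hi > 0 else 1.0},
            )
        ratio = hi / lo
        ratios[stim.value] = ratio
        weaker_by_side[stim.value] = weaker if hi > lo else None
    same_pupil_weak = (
        weaker_by_side["left"] is not None
        and weaker_by_side["left"] is weaker_by_side["right"]
    )
    flag = same_pupil_weak and all(r > asymmetry_ratio for r in ratios.values())
    return EfferentScreen(
        flag=flag,
        reason="consensual asymmetry consistent with efferent defect" if flag else "",
        asymmetry=ratios,
    )


def rapd_score(
    summary: ReflexSummary,
    efferent: EfferentScreen | None = None,
    quality: QualityReport | None = None,
) -> RAPDResult:
    """Compute the RAPD score from the per-eye mean direct constrictions.

    Two-tailed score = OD direct % / OS direct %; one-tailed score =
    max(r, 1/r) = stronger/weaker, so values above 1 always indicate the
    weaker (suspect) eye.  Withheld when quality fails or the efferent
    screen trips.
    """
    quality = quality if quality is not None else QualityReport(passed=True)
    efferent_flag = efferent.flag if efferent is not None else False
    if not quality.passed:
        return RAPDResult(None, Eye.NONE, None, efferent_flag, quality,
                          reason=quality.reason or "poor data quality")
    if efferent_flag:
        return RAPDResult(None, Eye.NONE, None, True, quality,
                          reason=efferent.reason or "efferent defect suspected")
    od = summary.direct_pct(Eye.RIGHT)
    os_ = summary.direct_pct(Eye.LEFT)
    weaker = min(od, os_)
    if weaker <= 0:
        return RAPDResult(None, Eye.NONE, None, False, quality,
                          reason="weaker eye non-reactive; score undefined")
    two_tailed = od / os_
    one_tailed = max(two_tailed, 1.0 / two_tailed)
    if od == os_:
        weaker_eye = Eye.NONE
    else:
        weaker_eye = Eye.RIGHT if od < os_ else Eye.LEFT
    return RAPDResult(one_tailed, weaker_eye, two_tailed, False, quality)
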