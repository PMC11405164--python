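"""Per-subject RAPD analysis as a model/results pair.

``RAPDModel`` binds one binocular trace to a stimulation timeline and a run
configuration; ``fit()`` executes the full chain — artifact flagging, gap
interpolation, smoothing, per-epoch reflex measurement, efferent screening and
RAPD scoring — and returns an ``RAPDAnalysisResults`` carrying the processed
trace, the per-cycle measurements, the quality and efferent status, and the
score, with ``summary()`` and JSON export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .preprocess import QualityReport, preprocess
from .protocol import Eye, ProtocolTimeline
from .reflex import (
    EfferentScreen,
    RAPDResult,
    ReflexSummary,
    detect_efferent_defect,
    rapd_score,
    summarize,
)
from .trace import PupilTrace, read_trace_csv

__all__ = ["RAPDModel", "RAPDAnalysisResults", "analyze_cohort"]


class RAPDModel:
    """Swinging-flashlight analysis of one subject's binocular pupil trace."""

    def __init__(
        self,
        trace: PupilTrace,
        timeline: ProtocolTimeline | None = None,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        self.timeline = timeline or self.config.build_timeline()
        expected = self.timeline.n_samples
        if trace.n_samples != expected:
            raise ValueError(
                f"trace has {trace.n_samples} samples but the timeline "
                f"implies {expected} at {self.timeline.sample_rate_hz} Hz"
            )
        self.trace = trace

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        timeline: ProtocolTimeline | None = None,
        config: RunConfig | None = None,
    ) -> "RAPDModel":
        config = config or RunConfig()
        tl = timeline or config.build_timeline()
        return cls(read_trace_csv(path, sample_rate_hz=tl.sample_rate_hz), tl, config)

    def fit(self) -> "RAPDAnalysisResults":
        cfg = self.config
        processed, quality = preprocess(
            self.trace,
            lo_mm=cfg.preprocess.lo_mm,
            hi_mm=cfg.preprocess.hi_mm,
            max_gap_samples=cfg.preprocess.max_gap_samples,
            window_samples=cfg.preprocess.smooth_window,
            paper_order=cfg.preprocess.paper_order,
        )
        if not quality.passed:
            result = rapd_score(ReflexSummary(measurements=[]), quality=quality)
            return RAPDAnalysisResults(self, processed, quality, None, None, result)
        summary = summarize(
            processed,
            self.timeline,
            baseline_window_s=cfg.reflex.baseline_window_s,
            response_window_s=cfg.reflex.response_window_s,
            aggregate=cfg.reflex.aggregate,
        )
        efferent = detect_efferent_defect(summary, cfg.reflex.efferent_ratio)
        result = rapd_score(summary, efferent=efferent, quality=quality)
        return RAPDAnalysisResults(self, processed, quality, summary, efferent, result)


@dataclass
class RAPDAnalysisResults:
    model: RAPDModel
    trace: PupilTrace  # processed
    quality: QualityReport
    reflex_summary: ReflexSummary | None
    efferent: EfferentScreen | None
    result: RAPDResult

    @property
    def scorable(self) -> bool:
        return self.result.scorable

    @property
    def score(self) -> float | None:
        return self.result.score_one_tailed

    def measurements_frame(self) -> pd.DataFrame:
        if self.reflex_summary is None:
            return pd.DataFrame()
        return pd.DataFrame([m.to_dict() for m in self.reflex_summary.measurements])

    def to_dict(self) -> dict:
        d: dict = {"rapd": self.result.to_dict(), "quality": self.quality.to_dict()}
        if self.reflex_summary is not None:
            d["reflex"] = self.reflex_summary.to_dict()
        if self.efferent is not None:
            d["efferent"] = {
                "flag": self.efferent.flag,
                "reason": self.efferent.reason,
                "asymmetry": self.efferent.asymmetry,
            }
        return d

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [
            "RAPD analysis (swinging-flashlight protocol)",
            "=" * 48,
        ]
        q = self.quality
        lines.append(
            f"quality             {'pass' if q.passed else 'FAIL'}"
            + (f" ({q.reason})" if q.reason else "")
        )
        if self.reflex_summary is not None:
            s = self.reflex_summary
            for eye, code in ((Eye.RIGHT, "OD"), (Eye.LEFT, "OS")):
                lines.append(
                    f"direct {code}           "
                    f"{s.direct_pct(eye):5.2f} +/- {s.direct_sd(eye):4.2f} %"
                )
            for eye, code in ((Eye.RIGHT, "OD"), (Eye.LEFT, "OS")):
                lines.append(
                    f"consensual {code}       "
                    f"{s.consensual_pct(eye):5.2f} +/- {s.consensual_sd(eye):4.2f} %"
                )
        if self.efferent is not None:
            lines.append(
                f"efferent screen     {'FLAGGED' if self.efferent.flag else 'clear'}"
                + (f" ({self.efferent.reason})" if self.efferent.reason else "")
            )
        r = self.result
        if r.scorable:
            lines.append(f"RAPD score (1-tail) {r.score_one_tailed:.3f}")
            lines.append(f"RAPD score (OD/OS)  {r.score_two_tailed:.3f}")
            lines.append(f"weaker eye          {r.weaker_eye.value}")
        else:
            lines.append(f"RAPD score          not emitted ({r.reason})")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_trace

        return plot_trace(self.trace, self.model.timeline, ax=ax)


def analyze_cohort(cohort, config: RunConfig | None = None) -> pd.DataFrame:
    """Score every subject of a simulated cohort through the full pipeline.

    Returns a labeled score table (one row per subject) suitable for
    :class:`~pupilkit.diagnostics.DiagnosticModel`; unscorable subjects carry
    NaN scores and the reason.
    """
    config = config or RunConfig()
    rows = []
    for trace, (_, truth) in zip(cohort.traces, cohort.truth.iterrows()):
        res = RAPDModel(trace, timeline=cohort.timeline, config=config).fit()
        rows.append(
            {
                "subject_id": truth["subject_id"],
                "score": res.score if res.scorable else float("nan"),
                "label": truth["label"],
                "grade": truth["grade"],
                "true_score": truth["true_score"],
                "weaker_eye": res.result.weaker_eye.value,
                "scorable": res.scorable,
                "reason": res.result.reason,
            }
        )
    return pd.DataFrame(rows)
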