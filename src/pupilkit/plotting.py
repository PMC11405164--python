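"""Matplotlib views: binocular trace with stimulus bands, and ROC curves."""

from __future__ import annotations

from .protocol import Eye, ProtocolTimeline
from .trace import PupilTrace

__all__ = ["plot_trace", "plot_roc"]

_BAND_COLORS = {Eye.BOTH: "#2ca02c", Eye.LEFT: "#1f77b4", Eye.RIGHT: "#d62728"}


def plot_trace(trace: PupilTrace, timeline: ProtocolTimeline | None = None, ax=None):
    """Plot both pupils over time, shading light pulses by stimulated eye."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.2))
    t = trace.t
    ax.plot(t, trace.right_mm, label="OD (right)", lw=1.0, color="#d62728")
    ax.plot(t, trace.left_mm, label="OS (left)", lw=1.0, color="#1f77b4")
    if timeline is not None:
        for ep in timeline.light_epochs:
            ax.axvspan(
                ep.onset_s,
                ep.onset_s + ep.pulse_duration_s,
                color=_BAND_COLORS.get(ep.eye_stimulated, "grey"),
                alpha=0.25,
                lw=0,
            )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pupil diameter (mm)")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_roc(report, ax=None, label: str | None = None):
    """ROC polyline with the Youden operating point marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pts = report.roc_points.sort_values("fpr")
    lbl = label or f"AUROC {report.auroc:.2f}"
    (line,) = ax.plot(pts["fpr"], pts["sensitivity"], drawstyle="steps-post", label=lbl)
    ax.plot(
        [1 - report.specificity_pct / 100],
        [report.sensitivity_pct / 100],
        "o",
        color=line.get_color(),
    )
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    return ax
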