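"""Synthetic binocular pupil traces with known ground truth.

The generator reproduces the statistical structure the analysis chain relies
on: a light-reflex kernel with latency, exponential constriction and
redilation; multiplicative afferent (per stimulated eye) and efferent (per
responding pupil) gains; conjugate hippus; Gaussian sensor noise; and
bilateral blink dropouts.  Because the gains enter multiplicatively, a subject
with afferent gain ``g`` in one eye has an exact ground-truth RAPD score of
``1/g``, which makes end-to-end parameter recovery testable in closed form.

Redilation decays exponentially but is tapered smoothly to zero within
``redilate_complete_s`` after the drive ends, so the pupil is fully
re-dilated before the next pulse's baseline window — as a healthy pupil is
after a brief pulse.  The drive is normalised so a default-length pulse
attains exactly the commanded constriction fraction ``amplitude_frac``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import Eye, ProtocolTimeline, build_default_timeline
from .trace import PupilTrace, Validity

__all__ = [
    "SubjectParams",
    "SimulatedCohort",
    "plr_kernel",
    "simulate_subject",
    "simulate_cohort",
    "MILD_GAIN_BAND",
    "MODERATE_GAIN_BAND",
]

#: afferent-gain bands by severity; mild RAPD vs moderate-or-worse
MILD_GAIN_BAND = (0.55, 0.85)
MODERATE_GAIN_BAND = (0.20, 0.55)

#: default cohort severity mix, matching the study composition (50 mild and
#: 27 moderate-or-worse of 77 cases)
DEFAULT_GRADE_MIX = {"mild": 50 / 77, "moderate": 27 / 77}


@dataclass(frozen=True)
class SubjectParams:
    """Physiological and instrumental parameters of one simulated subject.

    Defaults describe a healthy adult: 6 mm dark-adapted pupils, 38% maximal
    constriction (the healthy-control mean), 250 ms reflex latency, 0.35 s
    constriction and 1.5 s redilation time constants, 0.1 mm hippus at 0.2 Hz,
    0.05 mm sensor noise, and ~6 blinks/min of 200 ms each.
    """

    baseline_left_mm: float = 6.0
    baseline_right_mm: float = 6.0
    amplitude_frac: float = 0.38
    latency_s: float = 0.25
    tau_constrict_s: float = 0.35
    tau_redilate_s: float = 1.5
    afferent_gain_left: float = 1.0
    afferent_gain_right: float = 1.0
    efferent_gain_left: float = 1.0
    efferent_gain_right: float = 1.0
    hippus_amp_mm: float = 0.1
    hippus_freq_hz: float = 0.2
    noise_sd_mm: float = 0.05
    blink_rate_hz: float = 0.1
    blink_duration_s: float = 0.2
    #: redilation is complete this long after drive end (cosine taper over the
    #: final 0.1 s).  Must not exceed the time between drive end and the point
    #: the next pulse's smoothed baseline window can reach back to (~1.69 s in
    #: the default protocol), or residual constriction leaks into the baseline
    redilate_complete_s: float = 1.6
    #: optional extreme-diameter spike artifacts (per eye, per second), to
    #: exercise the cut-off filter; spikes alternate 0.5 and 9.5 mm
    spike_rate_hz: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("afferent_gain_left", "afferent_gain_right",
                     "efferent_gain_left", "efferent_gain_right"):
            g = getattr(self, name)
            if not (0 < g <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 < self.amplitude_frac < 1):
            raise ValueError("amplitude_frac must be in (0, 1)")
        if self.tau_constrict_s <= 0 or self.tau_redilate_s <= 0:
            raise ValueError("time constants must be positive")

    def afferent_gain(self, eye: Eye) -> float:
        return self.afferent_gain_left if eye is Eye.LEFT else self.afferent_gain_right

    def efferent_gain(self, eye: Eye) -> float:
        return self.efferent_gain_left if eye is Eye.LEFT else self.efferent_gain_right

    def baseline_mm(self, eye: Eye) -> float:
        return self.baseline_left_mm if eye is Eye.LEFT else self.baseline_right_mm


def plr_kernel(
    t: np.ndarray | float,
    pulse_duration_s: float,
    params: SubjectParams,
) -> np.ndarray:
    """Light-reflex drive as a fraction of its asymptotic maximum.

    Zero before the latency; rises as ``1 - exp(-(t - latency)/tau_c)`` while
    the drive lasts (pulse duration, shifted by the latency); then decays
    exponentially with ``tau_redilate_s`` from its value at drive end,
    smoothly tapered to zero by ``redilate_complete_s`` after drive end.
    Continuous everywhere.
    """
    t = np.asarray(t, dtype=float)
    lat = params.latency_s
    t_end = lat + pulse_duration_s
    k = np.zeros_like(t)

    rising = (t >= lat) & (t < t_end)
    k[rising] = 1.0 - np.exp(-(t[rising] - lat) / params.tau_constrict_s)

    k_end = 1.0 - np.exp(-pulse_duration_s / params.tau_constrict_s)
    decaying = t >= t_end
    u = t[decaying] - t_end
    decay = k_end * np.exp(-u / params.tau_redilate_s)
    # cosine fade over the final 0.1 s of the recovery interval
    u1 = params.redilate_complete_s
    u0 = max(u1 - 0.1, 0.0)
    taper = np.ones_like(u)
    fade = (u > u0) & (u < u1)
    taper[fade] = 0.5 * (1.0 + np.cos(np.pi * (u[fade] - u0) / (u1 - u0)))
    taper[u >= u1] = 0.0
    k[decaying] = decay * taper
    return k


def simulate_subject(
    params: SubjectParams,
    timeline: ProtocolTimeline | None = None,
    rng: np.random.Generator | None = None,
) -> PupilTrace:
    """Render one subject's binocular trace over a stimulation timeline.

    Each pupil's diameter is ``baseline * (1 - afferent_S * efferent_P * A0 *
    kernel(t))`` for the pulse stimulating eye S; the binocular conditioning
    pulse uses the larger of the two afferent gains.  The drive is normalised
    by the kernel's pulse-end maximum so the commanded ``amplitude_frac`` is
    attained exactly.  Conjugate hippus (one random-phase sinusoid added to
    both eyes), per-eye Gaussian noise, and bilateral Poisson blinks (both
    eyes missing) complete the trace.
    """
    timeline = timeline or build_default_timeline()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rate = timeline.sample_rate_hz
    n = timeline.n_samples
    t = np.arange(n) / rate

    drive = {Eye.LEFT: np.zeros(n), Eye.RIGHT: np.zeros(n)}
    for ep in timeline.light_epochs:
        k = plr_kernel(t - ep.onset_s, ep.pulse_duration_s, params)
        k_max = 1.0 - np.exp(-ep.pulse_duration_s / params.tau_constrict_s)
        if ep.eye_stimulated is Eye.BOTH:
            aff = max(params.afferent_gain_left, params.afferent_gain_right)
        else:
            aff = params.afferent_gain(ep.eye_stimulated)
        for pupil in (Eye.LEFT, Eye.RIGHT):
            drive[pupil] += (
                aff * params.efferent_gain(pupil) * params.amplitude_frac * k / k_max
            )

    hippus = params.hippus_amp_mm * np.sin(
        2 * np.pi * params.hippus_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    eyes = {}
    for pupil in (Eye.LEFT, Eye.RIGHT):
        d = params.baseline_mm(pupil) * (1.0 - drive[pupil]) + hippus
        d = d + rng.normal(0.0, params.noise_sd_mm, size=n)
        eyes[pupil] = np.maximum(d, 0.05)  # tracker never reports <= 0

    missing = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(params.blink_rate_hz * timeline.total_duration_s)
    blink_len = max(1, round(params.blink_duration_s * rate))
    for onset in rng.uniform(0, timeline.total_duration_s, size=n_blinks):
        a = int(onset * rate)
        missing[a : a + blink_len] = True
    for pupil in (Eye.LEFT, Eye.RIGHT):
        eyes[pupil][missing] = np.nan

    if params.spike_rate_hz > 0:
        n_spikes = rng.poisson(params.spike_rate_hz * timeline.total_duration_s * 2)
        idx = rng.integers(0, n, size=n_spikes)
        for j, i in enumerate(idx):
            side = Eye.LEFT if rng.random() < 0.5 else Eye.RIGHT
            eyes[side][i] = 0.5 if j % 2 == 0 else 9.5

    return PupilTrace.from_arrays(rate, eyes[Eye.LEFT], eyes[Eye.RIGHT])


@dataclass
class SimulatedCohort:
    """Traces plus per-subject ground truth for end-to-end evaluation."""

    traces: list[PupilTrace]
    truth: pd.DataFrame  # subject_id, label, grade, affected_eye, afferent_gain, true_score
    params: list[SubjectParams] = field(default_factory=list)
    timeline: ProtocolTimeline | None = None

    def __len__(self) -> int:
        return len(self.traces)


def _jittered_defaults(rng: np.random.Generator, seed: int) -> dict:
    """Per-subject nuisance parameters scattered around healthy defaults."""
    baseline = float(np.clip(rng.normal(6.0, 0.5), 4.5, 7.5))
    return {
        "baseline_left_mm": baseline + float(rng.normal(0, 0.05)),
        "baseline_right_mm": baseline + float(rng.normal(0, 0.05)),
        # healthy-control constriction 38 +/- 2%
        "amplitude_frac": float(np.clip(rng.normal(0.38, 0.021), 0.20, 0.60)),
        "latency_s": float(np.clip(rng.normal(0.25, 0.02), 0.18, 0.35)),
        "tau_constrict_s": float(np.clip(rng.normal(0.35, 0.03), 0.25, 0.50)),
        "tau_redilate_s": float(np.clip(rng.normal(1.5, 0.1), 1.0, 1.9)),
        "seed": seed,
    }


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    grade_mix: dict[str, float] | None = None,
    control_asymmetry_max: float = 0.2,
    seed: int = 0,
    timeline: ProtocolTimeline | None = None,
    **param_overrides,
) -> SimulatedCohort:
    """Generate a labeled case/control cohort with ground truth.

    Cases draw an affected eye uniformly and an afferent gain from their
    severity band (mild: 0.55-0.85 mapped to clinical grades 1-2;
    moderate-or-worse: 0.20-0.55, grades 3-5); the fellow eye keeps gain 1, so
    the true score is 1/gain.  Controls carry only physiologic asymmetry: an
    interocular gain ratio uniform on [1, 1 + control_asymmetry_max]
    (healthy pupillomotor output varies by up to ~20% between eyes), weaker
    side random.  Fully reproducible from ``seed``; per-subject nuisance
    parameters are jittered around defaults.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("cohort counts must be >= 0")
    grade_mix = grade_mix or DEFAULT_GRADE_MIX
    if not np.isclose(sum(grade_mix.values()), 1.0):
        raise ValueError("grade_mix proportions must sum to 1")
    timeline = timeline or build_default_timeline()
    rng = np.random.default_rng(seed)

    traces: list[PupilTrace] = []
    all_params: list[SubjectParams] = []
    rows: list[dict] = []
    bands = {"mild": MILD_GAIN_BAND, "moderate": MODERATE_GAIN_BAND}
    severities = list(grade_mix)
    probs = np.array([grade_mix[s] for s in severities])

    for i in range(n_cases + n_controls):
        is_case = i < n_cases
        subj_seed = int(rng.integers(0, 2**31 - 1))
        kw = _jittered_defaults(rng, subj_seed)
        kw.update(param_overrides)
        if is_case:
            severity = severities[int(rng.choice(len(severities), p=probs))]
            lo, hi = bands[severity]
            gain = float(rng.uniform(lo, hi))
            affected = Eye.LEFT if rng.random() < 0.5 else Eye.RIGHT
            grade = int(rng.integers(1, 3)) if severity == "mild" else int(rng.integers(3, 6))
        else:
            ratio = float(rng.uniform(1.0, 1.0 + control_asymmetry_max))
            gain = 1.0 / ratio
            affected = Eye.LEFT if rng.random() < 0.5 else Eye.RIGHT
            grade = 0
        if affected is Eye.LEFT:
            kw["afferent_gain_left"] = gain
        else:
            kw["afferent_gain_right"] = gain
        params = SubjectParams(**kw)
        traces.append(simulate_subject(params, timeline))
        all_params.append(params)
        rows.append(
            {
                "subject_id": f"{'case' if is_case else 'ctrl'}{i:04d}",
                "label": "case" if is_case else "control",
                "grade": grade,
                "affected_eye": affected.value,
                "afferent_gain": gain,
                "true_score": 1.0 / gain,
            }
        )
    return SimulatedCohort(
        traces=traces,
        truth=pd.DataFrame(rows),
        params=all_params,
        timeline=timeline,
    )


def noiseless(params: SubjectParams | None = None, **overrides) -> SubjectParams:
    """Convenience: params with hippus, noise and blinks switched off."""
    base = params or SubjectParams()
    kw = {
        "hippus_amp_mm": 0.0,
        "noise_sd_mm": 0.0,
        "blink_rate_hz": 0.0,
        "spike_rate_hz": 0.0,
    }
    kw.update(overrides)
    return replace(base, **kw)
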