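"""Binocular pupil-diameter trace container and delimited-text I/O.

Eye naming is fixed throughout the package: OD = right eye, OS = left eye,
column order ``od,os``.  This is stated everywhere it matters because a silent
left/right swap is the single most damaging failure mode for a RAPD tool.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import Eye

__all__ = ["Validity", "PupilTrace", "read_trace_csv", "write_trace_csv", "sample_slice"]


class Validity(enum.IntEnum):
    VALID = 0
    MISSING = 1
    INTERPOLATED = 2


_VALIDITY_NAMES = {v: v.name.lower() for v in Validity}
_VALIDITY_FROM_NAME = {name: v for v, name in _VALIDITY_NAMES.items()}


@dataclass
class PupilTrace:
    """Uniformly sampled binocular pupil diameters (mm) with per-sample,
    per-eye validity.  Missing samples hold NaN.

    Sample ``i`` covers time ``i / sample_rate_hz``.
    """

    sample_rate_hz: float
    left_mm: np.ndarray
    right_mm: np.ndarray
    left_validity: np.ndarray
    right_validity: np.ndarray

    def __post_init__(self) -> None:
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        self.left_validity = np.asarray(self.left_validity, dtype=np.uint8)
        self.right_validity = np.asarray(self.right_validity, dtype=np.uint8)
        n = len(self.left_mm)
        if not (len(self.right_mm) == len(self.left_validity) == len(self.right_validity) == n):
            raise ValueError("all trace arrays must share one length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        for vals, valid in ((self.left_mm, self.left_validity),
                            (self.right_mm, self.right_validity)):
            present = valid != Validity.MISSING
            if not np.all(np.isfinite(vals[present])):
                raise ValueError("non-missing samples must be finite")
            if np.any(vals[present] <= 0):
                raise ValueError("pupil diameters must be positive")

    @classmethod
    def from_arrays(
        cls,
        sample_rate_hz: float,
        left_mm: np.ndarray,
        right_mm: np.ndarray,
    ) -> "PupilTrace":
        """Build a trace from diameter arrays; NaN marks missing samples."""
        left = np.asarray(left_mm, dtype=float)
        right = np.asarray(right_mm, dtype=float)
        lv = np.where(np.isnan(left), Validity.MISSING, Validity.VALID).astype(np.uint8)
        rv = np.where(np.isnan(right), Validity.MISSING, Validity.VALID).astype(np.uint8)
        return cls(sample_rate_hz, left, right, lv, rv)

    @property
    def n_samples(self) -> int:
        return len(self.left_mm)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def values(self, eye: Eye | str) -> np.ndarray:
        eye = Eye(eye)
        if eye is Eye.LEFT:
            return self.left_mm
        if eye is Eye.RIGHT:
            return self.right_mm
        raise ValueError("values() takes left or right")

    def validity(self, eye: Eye | str) -> np.ndarray:
        eye = Eye(eye)
        if eye is Eye.LEFT:
            return self.left_validity
        if eye is Eye.RIGHT:
            return self.right_validity
        raise ValueError("validity() takes left or right")

    def has_missing(self) -> bool:
        return bool(
            np.any(self.left_validity == Validity.MISSING)
            or np.any(self.right_validity == Validity.MISSING)
        )

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            self.sample_rate_hz,
            self.left_mm.copy(),
            self.right_mm.copy(),
            self.left_validity.copy(),
            self.right_validity.copy(),
        )

    def to_frame(self, include_validity: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_s": self.t, "od_mm": self.right_mm, "os_mm": self.left_mm}
        )
        if include_validity:
            df["validity_od"] = [_VALIDITY_NAMES[Validity(v)] for v in self.right_validity]
            df["validity_os"] = [_VALIDITY_NAMES[Validity(v)] for v in self.left_validity]
        return df


def sample_slice(interval: tuple[float, float], sample_rate_hz: float, n_samples: int) -> slice:
    """Indices of samples whose time falls in the half-open interval [a, b)."""
    a, b = interval
    if b <= a:
        raise ValueError("empty interval")
    # tolerate float jitter at the boundary
    lo = int(np.ceil(a * sample_rate_hz - 1e-9))
    hi = int(np.ceil(b * sample_rate_hz - 1e-9))
    lo = max(lo, 0)
    hi = min(hi, n_samples)
    if hi <= lo:
        raise ValueError(f"interval [{a}, {b}) contains no samples")
    return slice(lo, hi)


def read_trace_csv(path: str | Path, sample_rate_hz: float | None = None) -> PupilTrace:
    """Read a trace file: header ``time_s,od_mm,os_mm``, one row per sample,
    empty diameter field = missing.  Optional ``validity_od,validity_os``
    columns are honoured.  Sampling must be uniform within 1e-6 s.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unparseable trace file") from exc
    for col in ("time_s", "od_mm", "os_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        bad = int(np.argmax(np.abs(dt - dt[0]) > 1e-6)) + 1
        raise ValueError(f"{path}: non-uniform sampling at row {bad + 1}")
    rate = sample_rate_hz if sample_rate_hz is not None else 1.0 / dt[0]
    right = df["od_mm"].to_numpy(dtype=float)
    left = df["os_mm"].to_numpy(dtype=float)
    trace = PupilTrace.from_arrays(rate, left, right)
    if "validity_od" in df.columns and "validity_os" in df.columns:
        trace.right_validity = np.array(
            [_VALIDITY_FROM_NAME[str(v)] for v in df["validity_od"]], dtype=np.uint8
        )
        trace.left_validity = np.array(
            [_VALIDITY_FROM_NAME[str(v)] for v in df["validity_os"]], dtype=np.uint8
        )
    return trace


def write_trace_csv(trace: PupilTrace, path: str | Path, include_validity: bool = False) -> None:
    """Write the reader's dialect back out (missing samples as empty fields)."""
    df = trace.to_frame(include_validity=include_validity)
    # 9 decimals keeps 1/90 s steps uniform within the reader's 1e-6 tolerance
    df.to_csv(path, index=False, float_format="%.9f")
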