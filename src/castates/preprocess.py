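"""Fluorescence calibration, low-pass filtering and trajectory features.

Raw fluorescence is converted to free calcium with the single-wavelength
indicator formula ``Ca = Kd * (F - Fmin) / (Fmax - F)``.  Traces are
truncated to the post-stimulus window and smoothed with a zero-phase
Butterworth filter after mirror-padding (reflective boundary), which
keeps the sharp initial rise undistorted.  Six scalar features summarize
each trajectory: basal value, time to half maximum, time to maximum,
maximum, decay time to half maximum, and final steady-state level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "CalciumTrace",
    "TraceFeatures",
    "CalibrationError",
    "calibrate",
    "smooth",
    "noise_floor",
    "extract_features",
]


class CalibrationError(ValueError):
    """Fluorescence at or above Fmax without clamping enabled."""


@dataclass(frozen=True)
class CalciumTrace:
    """A single cell's calcium time series with sampling metadata.

    Attributes
    ----------
    values : numpy.ndarray
        Calcium concentration series (uM).
    dt : float
        Sampling interval (s).
    stim_index : int
        Index of the stimulus-addition frame.
    cell_id : str
        Opaque identifier.
    calibration : tuple or None
        ``(Kd, Fmin, Fmax)`` when the series still needs calibrating.
    """

    values: np.ndarray
    dt: float
    stim_index: int = 0
    cell_id: str = ""
    calibration: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.cell_id!r} has non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.stim_index < len(self.values):
            raise ValueError(
                f"stim_index {self.stim_index} outside trace of length "
                f"{len(self.values)}")
        if self.calibration is not None:
            kd, fmin, fmax = self.calibration
            if not fmin < fmax:
                raise ValueError("calibration requires Fmin < Fmax")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def truncated(self) -> "CalciumTrace":
        """Post-stimulus window only; first point becomes the basal level."""
        return replace(self, values=self.values[self.stim_index:],
                       stim_index=0)


@dataclass(frozen=True)
class TraceFeatures:
    """Six-number summary of one calcium trajectory.

    ``responder`` is False for flat traces whose features are undefined;
    ``plateau`` is True when the trace never decays below half maximum
    (``t50d`` then holds the time to the end of the trace).
    """

    f0: float
    t50u: float
    tm: float
    fm: float
    t50d: float
    ff: float
    responder: bool = True
    plateau: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.t50u, self.tm,
                         self.fm, self.t50d, self.ff])


FEATURE_NAMES = ("f0", "t50u", "tm", "fm", "t50d", "ff")


def calibrate(raw_f: np.ndarray, kd: float, fmin: float, fmax: float,
              clamp: bool = False) -> np.ndarray:
    """Convert raw fluorescence to free calcium (uM).

    Applies ``Ca = Kd * (F - Fmin) / (Fmax - F)`` elementwise.  Values
    with ``F >= Fmax`` are an error unless ``clamp`` is set, in which
    case F is clamped just below Fmax (one part in 1e6 of the dynamic
    range).  ``F < Fmin`` maps to small negative calcium and is clamped
    to zero.
    """
    if not fmin < fmax:
        raise ValueError(f"need Fmin < Fmax, got {fmin} >= {fmax}")
    f = np.asarray(raw_f, dtype=float)
    if np.any(f >= fmax):
        if not clamp:
            raise CalibrationError(
                "fluorescence at or above Fmax; enable clamping to proceed")
        f = np.minimum(f, fmax - 1e-6 * (fmax - fmin))
    ca = kd * (f - fmin) / (fmax - f)
    return np.clip(ca, 0.0, None)


def _butter_sos(cutoff_hz: float, dt: float, order: int):
    nyquist = 0.5 / dt
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist:.4g}) Hz")
    return butter(order, cutoff_hz / nyquist, btype="low", output="sos")


def smooth(trace: CalciumTrace, cutoff: float = 0.1,
           order: int = 2) -> CalciumTrace:
    """Zero-phase low-pass filter with reflective boundary.

    The trace is expected to be truncated to the post-stimulus window.
    A full-length mirror image is concatenated at both ends before
    forward-backward Butterworth filtering, so the sharp onset is not
    damped by edge effects.  The first output point is pinned to the
    trace's first (basal) point.
    """
    x = trace.values
    n = len(x)
    if n < 8:
        raise ValueError(f"trace too short to filter (n={n})")
    sos = _butter_sos(cutoff, trace.dt, order)
    y = sosfiltfilt(sos, x, padtype="even", padlen=n - 1)
    y = y.copy()
    y[0] = x[0]  # basal level point is kept verbatim
    return replace(trace, values=y)


def noise_floor(raw: CalciumTrace, processed: CalciumTrace,
                score_fn: Callable[[np.ndarray, np.ndarray], float]
                ) -> float:
    """Per-cell acceptance threshold: score of raw against processed data.

    A simulation that matches the raw data at least as well as plain
    smoothing does is a good fit, so the raw-vs-processed score is the
    natural per-cell noise floor.
    """
    if len(raw) != len(processed) or raw.dt != processed.dt:
        raise ValueError("raw and processed traces must share a grid")
    return float(score_fn(raw.values, processed.values))


def _cross_time(times: np.ndarray, values: np.ndarray, level: float,
                rising: bool) -> float:
    """First crossing time of ``level``, linearly interpolated."""
    v = values - level
    if rising:
        idx = np.nonzero(v >= 0)[0]
    else:
        idx = np.nonzero(v <= 0)[0]
    if idx.size == 0:
        return math.nan
    i = int(idx[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (t1 - t0) * (-v0) / (v1 - v0))


def extract_features(trace: CalciumTrace, tail_fraction: float = 0.1,
                     response_floor: float = 1e-3) -> TraceFeatures:
    """Extract the six trajectory features from a processed trace.

    Threshold crossings are linearly interpolated between samples.  The
    final value ``ff`` is the mean of the trailing ``tail_fraction`` of
    frames.  A trace whose excursion ``fm - f0`` is below
    ``response_floor`` is flagged a non-responder.
    """
    x = trace.values
    t = trace.times
    f0 = float(x[0])
    i_max = int(np.argmax(x))
    fm = float(x[i_max])
    tm = float(t[i_max])
    n_tail = max(1, int(round(tail_fraction * len(x))))
    ff = float(np.mean(x[-n_tail:]))

    if fm - f0 < response_floor:
        return TraceFeatures(f0=f0, t50u=math.nan, tm=math.nan, fm=fm,
                             t50d=math.nan, ff=ff, responder=False)

    half = 0.5 * (f0 + fm)
    t50u = _cross_time(t[: i_max + 1], x[: i_max + 1], half, rising=True)
    t_fall = _cross_time(t[i_max:], x[i_max:], half, rising=False)
    if math.isnan(t_fall):
        # sustained plateau: never decays below half maximum
        return TraceFeatures(f0=f0, t50u=t50u, tm=tm, fm=fm,
                             t50d=float(t[-1] - tm), ff=ff, plateau=True)
    return TraceFeatures(f0=f0, t50u=t50u, tm=tm, fm=fm,
                         t50d=float(t_fall - tm), ff=ff)
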