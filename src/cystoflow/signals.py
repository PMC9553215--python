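"""Trace-level signal processing: smoothing, flow rate, conductance.

The volume trace (image timebase, nominally 30 samples/s) is smoothed with
a Savitzky-Golay filter before differentiation; the urethral flow rate is

    UFR(t) = -dV_ves/dt        (µl/s, positive = outflow)

and, where a synchronized intravesical pressure trace exists (nominally
50 Hz, resampled onto the image timebase), the urethral flow conductance is

    UFC(t) = max(UFR, 0) / p_ves(t)   (µl s^-1 cmH2O^-1)

left undefined (NaN) wherever p_ves falls below a floor, to avoid
division blow-ups between contractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .volumetry import VolumeTrace

#: Default pressure floor (cmH2O) below which UFC is undefined.
DEFAULT_PRESSURE_FLOOR = 3.0


@dataclass
class PressureTrace:
    """Time-stamped intravesical pressure p_ves (cmH2O)."""

    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if len(self.time) != len(self.pressure):
            raise ValueError("time and pressure must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            bad = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise ValueError(f"pressure time not strictly increasing at sample {bad}")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FlowTrace:
    """Urethral flow rate / conductance on the image timebase.

    ufr : µl/s, positive during voiding.  ufc : µl s^-1 cmH2O^-1, NaN
    where undefined (no pressure, or pressure below the floor).
    """

    time: np.ndarray
    ufr: np.ndarray
    ufc: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ufr = np.asarray(self.ufr, dtype=float)
        if len(self.time) != len(self.ufr):
            raise ValueError("time and ufr must have equal length")
        if self.ufc is not None:
            self.ufc = np.asarray(self.ufc, dtype=float)
            if len(self.ufc) != len(self.time):
                raise ValueError("ufc must match the timebase")

    def __len__(self) -> int:
        return len(self.time)


def _filled_volume(v: VolumeTrace) -> np.ndarray:
    """Volume with invalid samples filled by linear interpolation (edges
    held at the nearest valid value)."""
    if v.valid.all():
        return v.volume.copy()
    if not v.valid.any():
        raise ValueError("volume trace has no valid samples")
    return np.interp(v.time, v.time[v.valid], v.volume[v.valid])


def smooth_volume(v: VolumeTrace, window: int = 31, polyorder: int = 3) -> VolumeTrace:
    """Savitzky-Golay smoothing of the volume trace.

    Least-squares local polynomial smoothing; edges are handled by
    evaluating the boundary polynomial fits (``mode='interp'``), so a
    trace that is exactly a polynomial of degree <= ``polyorder`` passes
    through unchanged.  Invalid samples are pre-interpolated for the fit
    and keep their invalid flag.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > len(v):
        raise ValueError(f"window {window} exceeds trace length {len(v)}")
    filled = _filled_volume(v)
    smoothed = savgol_filter(filled, window, polyorder, mode="interp")
    return VolumeTrace(v.time.copy(), np.maximum(smoothed, 0.0), v.valid.copy())


def compute_ufr(v: VolumeTrace) -> FlowTrace:
    """Urethral flow rate as the negative time derivative of volume.

    Central differences on interior samples, one-sided at the edges.
    Expects a smoothed trace; invalid samples are pre-interpolated.
    """
    if int(v.valid.sum()) < 3:
        raise ValueError("need at least 3 valid samples to differentiate")
    filled = _filled_volume(v)
    ufr = -np.gradient(filled, v.time)
    return FlowTrace(v.time.copy(), ufr)


def align_pressure(p: PressureTrace, timebase: np.ndarray) -> np.ndarray:
    """Resample a pressure trace onto the image timebase.

    Linear interpolation; queries beyond the recorded span (at most one
    sample, by precondition) clamp to the nearest recorded sample.
    """
    timebase = np.asarray(timebase, dtype=float)
    if len(p) == 0 or len(timebase) == 0:
        raise ValueError("cannot align empty traces")
    dt = np.median(np.diff(p.time)) if len(p) > 1 else 0.0
    if timebase[0] > p.time[-1] + dt or timebase[-1] < p.time[0] - dt:
        raise ValueError(
            f"pressure span [{p.time[0]:.3f}, {p.time[-1]:.3f}] s does not overlap "
            f"image span [{timebase[0]:.3f}, {timebase[-1]:.3f}] s"
        )
    return np.interp(timebase, p.time, p.pressure)


def compute_ufc(
    flow: FlowTrace,
    p_aligned: np.ndarray,
    pressure_floor: float = DEFAULT_PRESSURE_FLOOR,
) -> FlowTrace:
    """Fill the conductance channel of a flow trace.

    UFC = max(UFR, 0) / p_ves where p_ves >= ``pressure_floor``; NaN
    elsewhere.  Negative flow (filling) maps to zero conductance.
    """
    p_aligned = np.asarray(p_aligned, dtype=float)
    if len(p_aligned) != len(flow):
        raise ValueError("pressure and flow must share a timebase")
    ufc = np.full(len(flow), np.nan)
    defined = p_aligned >= pressure_floor
    ufc[defined] = np.maximum(flow.ufr[defined], 0.0) / p_aligned[defined]
    return FlowTrace(flow.time.copy(), flow.ufr.copy(), ufc)
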