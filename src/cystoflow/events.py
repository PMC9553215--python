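"""Void-event detection and per-void / per-cycle parameterization.

From a smoothed volume trace and its derived flow trace, voiding episodes
are detected by thresholding the urethral flow rate (with hysteresis at a
fraction of each void's peak flow), and each void is parameterized:

    BC          bladder capacity, V at void onset (µl)
    RV          residual volume, V at void end (µl)
    E_voiding   100 * (BC - RV) / BC (%)
    t20-80      time for V to fall from 20% to 80% of the voided volume (s)
    UFR_max / UFC_max / p_max   maxima over the void

Per-cycle statistics are the intercontractile interval (ICI, onset to
onset) and the count of nonvoiding contractions (NVCs) in a fixed window
(default 80 s) preceding each void: pressure excursions above a rolling-
median baseline that move no volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .signals import FlowTrace
from .volumetry import VolumeTrace

logger = logging.getLogger(__name__)


@dataclass
class EventParams:
    """Void-detection tunables.

    ufr_on_threshold : µl/s flow above which a candidate void opens.
    min_voided : µl, smallest accepted voided volume.
    hysteresis_frac : onset/end refined to where UFR crosses this fraction
        of the void's peak flow.
    merge_gap : s, candidates closer than this are merged.
    """

    ufr_on_threshold: float = 2.0
    min_voided: float = 10.0
    hysteresis_frac: float = 0.05
    merge_gap: float = 3.0


@dataclass
class NvcParams:
    """Nonvoiding-contraction counting rules (common cystometry practice).

    amplitude : cmH2O above the rolling-median baseline.
    min_duration : s, minimum excursion length.
    max_volume_drop : µl; a larger concomitant volume decrease marks the
        excursion as a voiding/leak event, not an NVC.
    baseline_window : s, rolling-median window.
    """

    amplitude: float = 5.0
    min_duration: float = 1.0
    max_volume_drop: float = 2.0
    baseline_window: float = 15.0


@dataclass
class VoidEvent:
    """One voiding episode and its urodynamic parameters.

    Pressure-dependent fields (``ufc_max``, ``p_max``) are None when no
    pressure trace was recorded (noninvasive mode).
    """

    onset: float
    end: float
    capacity: Optional[float] = None  # BC, µl
    residual: Optional[float] = None  # RV, µl
    voided: Optional[float] = None  # µl
    efficiency: Optional[float] = None  # %
    t20_80: Optional[float] = None  # s
    ufr_max: Optional[float] = None  # µl/s
    ufc_max: Optional[float] = None
    p_max: Optional[float] = None

    @property
    def duration(self) -> float:
        return self.end - self.onset


def detect_voids(
    v: VolumeTrace, flow: FlowTrace, params: EventParams | None = None
) -> list[VoidEvent]:
    """Detect voiding episodes in a (smoothed) volume/flow trace pair.

    Maximal intervals with UFR above ``ufr_on_threshold`` are candidates;
    candidates separated by less than ``merge_gap`` seconds are merged;
    onset and end are then widened to where UFR crosses
    ``hysteresis_frac`` of that void's peak flow; candidates moving less
    than ``min_voided`` µl are dropped.  Returns onset/end times only.
    """
    params = params or EventParams()
    ufr = flow.ufr
    t = flow.time
    n = len(ufr)
    above = ufr > params.ufr_on_threshold
    if not above.any():
        return []

    # maximal runs above threshold
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)

    # merge close candidates
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and t[s] - t[merged[-1][1] - 1] < params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[VoidEvent] = []
    for s, e in merged:
        peak = float(ufr[s:e].max())
        low = params.hysteresis_frac * peak
        i0, i1 = s, e - 1
        while i0 > 0 and ufr[i0 - 1] > low:
            i0 -= 1
        while i1 < n - 1 and ufr[i1 + 1] > low:
            i1 += 1
        # extend to the flow reversal: outflow starts (ends) where the net
        # flow crosses zero, before (after) the hysteresis crossing
        while i0 > 0 and ufr[i0 - 1] > 0:
            i0 -= 1
        while i1 < n - 1 and ufr[i1 + 1] > 0:
            i1 += 1
        # anchor onset/end at the volume extrema around the flow peak: the
        # pre-void maximum and post-void minimum are robust to brief
        # segmentation artifacts swept up by merging/hysteresis
        ipk = s + int(np.argmax(ufr[s:e]))
        i0 = i0 + int(np.argmax(v.volume[i0 : ipk + 1]))
        i1 = ipk + int(np.argmin(v.volume[ipk : i1 + 1]))
        voided = float(v.volume[i0] - v.volume[i1])
        if voided < params.min_voided:
            logger.debug("candidate at %.2f s dropped: voided %.1f µl", t[s], voided)
            continue
        if events and t[i0] <= events[-1].end:
            continue  # hysteresis expansion overlapped the previous event
        events.append(VoidEvent(onset=float(t[i0]), end=float(t[i1])))
    return events


def _crossing_time(t: np.ndarray, v: np.ndarray, target: float) -> float:
    """First time within the window at which v falls to ``target``,
    linearly interpolated between bracketing samples."""
    below = np.nonzero(v <= target)[0]
    if len(below) == 0:
        return float(t[-1])
    j = int(below[0])
    if j == 0 or v[j - 1] == v[j]:
        return float(t[j])
    frac = (v[j - 1] - target) / (v[j - 1] - v[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def void_parameters(
    events: Sequence[VoidEvent],
    v: VolumeTrace,
    flow: FlowTrace,
    p_aligned: Optional[np.ndarray] = None,
    detection_floor: float = 4.0,
) -> list[VoidEvent]:
    """Fill the urodynamic parameters of detected voids.

    BC and RV are the trace volumes at onset and end; t20-80 crossing
    times are linearly interpolated between samples.  With no pressure
    trace, UFC/p fields stay None.

    Residuals at the segmentation detection limit are censored: when the
    bladder became undetectable around the void end, or the in-void volume
    minimum fell to ``detection_floor`` (µl, the smallest volume the mask
    pipeline resolves), the bladder is taken as emptied and RV is 0.
    """
    out: list[VoidEvent] = []
    for ev in events:
        sl = (v.time >= ev.onset - 1e-9) & (v.time <= ev.end + 1e-9)
        idx = np.nonzero(sl)[0]
        if len(idx) < 2:
            raise ValueError(f"void [{ev.onset}, {ev.end}] s spans fewer than 2 samples")
        tw, vw = v.time[idx], v.volume[idx]
        bc = float(vw[0])
        rv = float(vw[-1])
        # an undetectable bladder at void end means the volume fell below
        # the segmentation floor (a few µl): the bladder emptied, so the
        # residual is reported as 0 rather than the floor-interpolated value
        tail = np.nonzero((v.time >= ev.end - 0.5) & (v.time <= ev.end + 0.5))[0]
        undetectable = len(tail) > 0 and not v.valid[tail].all()
        if undetectable or float(vw.min()) <= detection_floor:
            logger.info("void at %.2f s: bladder at/below the detection floor "
                        "at end; residual reported as 0", ev.onset)
            rv = 0.0
        voided = bc - rv
        if bc <= 0:
            logger.warning("void at %.2f s has BC = 0; efficiency undefined", ev.onset)
            eff = None
        else:
            eff = 100.0 * voided / bc
        t20 = _crossing_time(tw, vw, bc - 0.2 * voided)
        t80 = _crossing_time(tw, vw, bc - 0.8 * voided)
        ufr_max = float(flow.ufr[idx].max())
        ufc_max = p_max = None
        if p_aligned is not None:
            p_aligned = np.asarray(p_aligned, dtype=float)
            p_max = float(p_aligned[idx].max())
            if flow.ufc is not None:
                window_ufc = flow.ufc[idx]
                if np.any(np.isfinite(window_ufc)):
                    ufc_max = float(np.nanmax(window_ufc))
        out.append(
            VoidEvent(
                onset=ev.onset, end=ev.end, capacity=bc, residual=rv, voided=voided,
                efficiency=eff, t20_80=max(t80 - t20, 0.0), ufr_max=ufr_max,
                ufc_max=ufc_max, p_max=p_max,
            )
        )
    return out


def intercontractile_intervals(events: Sequence[VoidEvent]) -> list[Optional[float]]:
    """Onset-to-onset interval preceding each void (None for the first)."""
    out: list[Optional[float]] = [None]
    for prev, cur in zip(events, events[1:]):
        out.append(cur.onset - prev.onset)
    return out


def count_nvcs(
    p_aligned: np.ndarray,
    v: VolumeTrace,
    void_onset: float,
    window: float = 80.0,
    params: NvcParams | None = None,
) -> int:
    """Count nonvoiding contractions in the window preceding a void.

    An NVC is a pressure excursion exceeding ``params.amplitude`` above a
    rolling-median baseline, lasting at least ``params.min_duration``
    seconds, during which the bladder volume does not drop by more than
    ``params.max_volume_drop`` µl.  Overlapping excursions form one run
    and count once.  Counting uses pressure already aligned onto the
    volume timebase.
    """
    params = params or NvcParams()
    p_aligned = np.asarray(p_aligned, dtype=float)
    if len(p_aligned) != len(v):
        raise ValueError("aligned pressure must match the volume timebase")
    t = v.time
    dt = float(np.median(np.diff(t)))
    size = max(3, int(round(params.baseline_window / dt)) | 1)
    baseline = median_filter(p_aligned, size=size, mode="nearest")
    # dual threshold: an excursion spans the region above half the
    # amplitude criterion but must peak above the full criterion, so its
    # duration is the width of the pulse, not the time above the peak bar
    elev = p_aligned - baseline
    excursion = elev >= 0.5 * params.amplitude

    lo, hi = void_onset - window, void_onset
    count = 0
    edges = np.diff(excursion.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if excursion[0]:
        starts.insert(0, 0)
    if excursion[-1]:
        ends.append(len(excursion))
    for s, e in zip(starts, ends):
        if elev[s:e].max() < params.amplitude:
            continue
        t_peak = t[s + int(np.argmax(p_aligned[s:e]))]
        if not (lo <= t_peak < hi):
            continue
        if t[e - 1] - t[s] < params.min_duration:
            continue
        drop = float(v.volume[max(s - 1, 0)] - v.volume[s:e].min())
        if drop > params.max_volume_drop:
            logger.debug("excursion at %.1f s excluded: %.1f µl volume drop", t[s], drop)
            continue
        count += 1
    return count
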