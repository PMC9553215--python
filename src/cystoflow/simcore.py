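"""Synthetic lower-urinary-tract dynamics and fluoroscopy rendering.

Generates ground-truth bladder volume/pressure traces with voiding and
nonvoiding contractions, and renders them as fluoroscopy-like image
sequences (dark contrast-filled prolate-spheroid bladder, moving
high-contrast background "bones", sensor noise) together with
ground-truth masks, so that every downstream stage — segmentation,
volumetry, flow derivation, event parameterization, Dice benchmarking —
can be validated without animal data.

Model
-----
The bladder fills at a constant rate (renal output or pump infusion).
When the volume reaches the capacity threshold a voiding contraction is
triggered: intravesical pressure rises by a raised-cosine pulse above
baseline, the urethral conductance opens with the same raised-cosine
profile (peaking mid-void), and the outflow is conductance x pressure.
The void ends when the volume reaches ``residual_fraction x capacity``.
Nonvoiding contractions (NVCs) are raised-cosine pressure pulses placed
at seeded Poisson times during filling; they move no volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .segmentation import FrameSequence, MaskSequence
from .signals import PressureTrace
from .volumetry import VolumeTrace, axes_from_volume

logger = logging.getLogger(__name__)

#: Internal integration grid for void outflow quadrature (Hz); a common
#: multiple of the 30 frames/s and 50 Hz acquisition rates so sampled
#: points fall on integration knots.
FINE_RATE = 600.0

# rendering constants (intensity scale 0..1)
BACKGROUND_INTENSITY = 0.85
BAR_TRANSMISSION = 0.52  # multiplicative attenuation of a background bar
ATTENUATION_PER_MM = 6.0  # contrast-agent attenuation coefficient (1/mm)


class SimVoid(NamedTuple):
    """One ground-truth voiding episode."""

    onset: float  # s
    end: float  # s
    voided: float  # µl


@dataclass
class SimConfig:
    """Conditions of one simulated cystometry / volumetry session.

    Defaults reproduce a catheterized mouse session: pump infusion at
    20 µl/min, functional capacity ~100 µl, complete voiding, pressure
    sampled at 50 Hz and imaging at 30 frames/s.

    Parameters
    ----------
    fill_rate : µl/min, constant filling rate.
    capacity_threshold : µl, volume that triggers a void.
    residual_fraction : fraction of capacity left after a void, in [0, 1].
    void_conductance : µl s^-1 cmH2O^-1, peak urethral conductance mid-void.
    contraction_pressure : cmH2O, peak voiding-contraction amplitude above
        baseline.
    baseline_pressure : cmH2O.
    nvc_rate : nonvoiding contractions per minute of filling.
    nvc_amplitude : cmH2O, NVC pulse height.
    nvc_duration : s, NVC pulse width.
    duration : s, session length.
    initial_volume : µl at t = 0.
    image_shape : (rows, cols) pixels.
    pixel_size : mm/pixel (isotropic).
    frame_rate : frames/s (default 30).
    pressure_rate : samples/s (default 50).
    aspect_ratio : long/short semi-axis of the rendered prolate spheroid.
    background_motion_amplitude : px, stationary s.d. of the bladder/bone
        drift processes (0 freezes all motion).
    noise_sd : additive Gaussian sensor noise s.d., intensity units.
    n_bars : number of high-contrast background bars ("bones").
    seed : master seed; one seed sequence drives all randomness.
    """

    fill_rate: float = 20.0
    capacity_threshold: float = 100.0
    residual_fraction: float = 0.0
    void_conductance: float = 1.5
    contraction_pressure: float = 30.0
    baseline_pressure: float = 10.0
    nvc_rate: float = 2.25
    nvc_amplitude: float = 8.0
    nvc_duration: float = 2.0
    duration: float = 120.0
    initial_volume: float = 0.0
    image_shape: tuple[int, int] = (224, 224)
    pixel_size: float = 0.1
    frame_rate: float = 30.0
    pressure_rate: float = 50.0
    aspect_ratio: float = 1.5
    background_motion_amplitude: float = 2.0
    noise_sd: float = 0.03
    n_bars: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.fill_rate < 0:
            raise ValueError(f"fill_rate must be >= 0, got {self.fill_rate}")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")
        if self.frame_rate <= 0 or self.pressure_rate <= 0:
            raise ValueError("frame_rate and pressure_rate must be positive")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio must be >= 1")
        if self.capacity_threshold <= 0:
            raise ValueError("capacity_threshold must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.void_conductance < 0 or self.contraction_pressure < 0:
            raise ValueError("conductance and contraction pressure must be >= 0")
        if self.baseline_pressure < 0 or self.nvc_rate < 0 or self.nvc_amplitude < 0:
            raise ValueError("pressure parameters must be >= 0")
        if self.initial_volume < 0:
            raise ValueError("initial_volume must be >= 0")
        if self.noise_sd < 0 or self.background_motion_amplitude < 0:
            raise ValueError("noise_sd and background_motion_amplitude must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def catheterized(cls, **overrides) -> "SimConfig":
        """Pump-infused session: 20 µl/min fill, ~100 µl capacity."""
        return replace(cls(), **overrides)

    @classmethod
    def noninvasive(cls, **overrides) -> "SimConfig":
        """Diuresis-driven session: ~7.3 µl/min fill, ~360 µl capacity,
        no catheter (the pressure channel is typically discarded)."""
        base = cls(fill_rate=7.3, capacity_threshold=360.0, nvc_rate=0.0)
        return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Everything the simulator knows: the reference for validation.

    ``masks`` is populated by :func:`render_frames`; ``axes_per_frame``
    holds the (long, short) spheroid semi-axes in mm per frame.
    """

    volume_trace: VolumeTrace
    pressure_trace: PressureTrace
    axes_per_frame: np.ndarray
    void_events: list[SimVoid]
    nvc_times: list[float]
    masks: Optional[MaskSequence] = None
    # fine-grid record of the void outflow for conservation checks:
    # list of (times, outflow µl/s) arrays, one per void
    outflow_profiles: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _raised_cosine(tau: np.ndarray, width: float) -> np.ndarray:
    """Smooth single-peak pulse on [0, width], zero outside, peak 1."""
    out = np.zeros_like(tau, dtype=float)
    inside = (tau >= 0) & (tau <= width)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[inside] / width))
    return out


def _void_duration(config: SimConfig, drain: float) -> float:
    """Nominal pulse width making the raised-cosine void drain ``drain`` µl.

    Over one pulse the mean of the conductance profile is 1/2 and the mean
    of its square 3/8, so the expected outflow integral is
    g0*T*(p_base/2 + 3/8*p_contr); filling continues during the void.
    """
    fill_s = config.fill_rate / 60.0
    mean_outflow = config.void_conductance * (
        config.baseline_pressure / 2.0 + 0.375 * config.contraction_pressure
    )
    if mean_outflow <= fill_s:
        raise ValueError(
            "void outflow cannot exceed filling: increase void_conductance or "
            "contraction/baseline pressure, or lower fill_rate"
        )
    return drain / (mean_outflow - fill_s)


def simulate_dynamics(config: SimConfig) -> GroundTruth:
    """Simulate volume, pressure, and event ground truth (no images).

    Event-driven integration: filling phases are linear in time and handled
    analytically; each void's outflow (conductance profile x pressure) is
    integrated on a fine grid by cumulative trapezoid, so the volume drop
    across a void equals the outflow integral by construction.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    dyn_ss, _render_ss = ss.spawn(2)
    rng = np.random.default_rng(dyn_ss)

    fill_s = config.fill_rate / 60.0
    cap = config.capacity_threshold
    duration = config.duration

    knots_t = [0.0]
    knots_v = [min(config.initial_volume, cap)]
    voids: list[SimVoid] = []
    outflow_profiles: list[tuple[np.ndarray, np.ndarray]] = []
    void_pulses: list[tuple[float, float]] = []  # (onset, width) for pressure
    fill_windows: list[tuple[float, float]] = []  # NVC-eligible intervals

    t = knots_t[0]
    v = knots_v[0]
    while t < duration:
        if v >= cap - 1e-12:
            t_trig = t
        elif fill_s > 0:
            t_trig = t + (cap - v) / fill_s
        else:
            t_trig = np.inf
        if t_trig >= duration:
            fill_windows.append((t, duration))
            knots_t.append(duration)
            knots_v.append(v + fill_s * (duration - t))
            break
        if t_trig > t:
            fill_windows.append((t, t_trig))
            knots_t.append(t_trig)
            knots_v.append(cap)
            v = cap
        # --- void ---
        target = config.residual_fraction * cap
        width = _void_duration(config, v - target)
        n = max(int(np.ceil(width * FINE_RATE)), 8)
        tau = np.linspace(0.0, width, n + 1)
        profile = _raised_cosine(tau, width)
        p_inst = config.baseline_pressure + config.contraction_pressure * profile
        outflow = config.void_conductance * profile * p_inst
        dt = tau[1] - tau[0]
        # cumulative trapezoid of (fill - outflow)
        net = fill_s - outflow
        v_fine = v + np.concatenate([[0.0], np.cumsum(0.5 * (net[1:] + net[:-1]) * dt)])
        hit = np.nonzero(v_fine <= target + 1e-9)[0]
        end_i = int(hit[0]) if len(hit) else n
        v_fine = np.maximum(v_fine[: end_i + 1], 0.0)
        end_t = t_trig + tau[end_i]
        v_end = float(v_fine[-1])
        knots_t.extend((t_trig + tau[1 : end_i + 1]).tolist())
        knots_v.extend(v_fine[1:].tolist())
        voids.append(SimVoid(onset=t_trig, end=min(end_t, duration), voided=v - v_end))
        outflow_profiles.append((t_trig + tau[: end_i + 1], outflow[: end_i + 1]))
        void_pulses.append((t_trig, width))
        t, v = end_t, v_end
        if t >= duration:
            break

    knots_t = np.asarray(knots_t)
    knots_v = np.asarray(knots_v)
    # de-duplicate coincident knots (zero-length fill before immediate void)
    keep = np.concatenate([[True], np.diff(knots_t) > 0])
    knots_t, knots_v = knots_t[keep], knots_v[keep]

    # --- NVC placement: Poisson times during filling, seeded jitter ---
    nvc_times: list[float] = []
    if config.nvc_rate > 0 and config.nvc_amplitude > 0:
        margin = config.nvc_duration
        for start, stop in fill_windows:
            lo, hi = start + margin, stop - margin
            if hi <= lo:
                continue
            k = rng.poisson(config.nvc_rate / 60.0 * (hi - lo))
            times = np.sort(rng.uniform(lo, hi, size=k))
            for tc in times:
                if nvc_times and tc - nvc_times[-1] < 2.0 * config.nvc_duration:
                    continue
                nvc_times.append(float(tc))

    # --- sampled traces ---
    n_frames = int(np.floor(duration * config.frame_rate)) + 1
    t_frames = np.arange(n_frames) / config.frame_rate
    v_frames = np.interp(t_frames, knots_t, knots_v)
    volume_trace = VolumeTrace(t_frames, v_frames, np.ones(n_frames, dtype=bool))

    n_p = int(np.floor(duration * config.pressure_rate)) + 1
    t_p = np.arange(n_p) / config.pressure_rate
    p = np.full(n_p, config.baseline_pressure)
    for onset, width in void_pulses:
        p += config.contraction_pressure * _raised_cosine(t_p - onset, width)
    for tc in nvc_times:
        p += config.nvc_amplitude * _raised_cosine(
            t_p - (tc - config.nvc_duration / 2.0), config.nvc_duration
        )
    pressure_trace = PressureTrace(t_p, p)

    axes = np.asarray(
        [axes_from_volume(float(vi), config.aspect_ratio) for vi in v_frames]
    )

    logger.info(
        "simulated %.1f s: %d voids, %d NVCs, final volume %.1f µl",
        duration, len(voids), len(nvc_times), knots_v[-1],
    )
    return GroundTruth(
        volume_trace=volume_trace,
        pressure_trace=pressure_trace,
        axes_per_frame=axes,
        void_events=voids,
        nvc_times=nvc_times,
        outflow_profiles=outflow_profiles,
    )


def _ar1_walk(rng: np.random.Generator, n: int, sd: float, rho: float = 0.995) -> np.ndarray:
    """Mean-zero AR(1) drift with stationary standard deviation ``sd``."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    steps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    out = np.empty(n)
    acc = rng.normal(0.0, sd)
    for i in range(n):
        acc = rho * acc + steps[i]
        out[i] = acc
    return out


def render_frames(truth: GroundTruth, config: SimConfig) -> tuple[FrameSequence, MaskSequence]:
    """Render a ground truth as a fluoroscopy-like sequence with masks.

    Each frame composites, on a bright background, ``n_bars`` rigid
    high-contrast bars translating/rotating with a bladder-independent
    drift, and the projected prolate spheroid: attenuation follows the
    X-ray chord length through the spheroid (Beer-Lambert with coefficient
    :data:`ATTENUATION_PER_MM`), so the bladder is darkest at its center.
    Additive Gaussian noise of s.d. ``noise_sd`` is applied last.  The
    ground-truth mask is the exact ellipse support.

    Raises
    ------
    ValueError
        If the bladder at some frame cannot fit the image, naming the
        first offending frame.
    """
    config.validate()
    v = truth.volume_trace.volume
    if np.any(v < -1e-9):
        raise ValueError("volume trace must be nonnegative")
    n = len(v)
    h, w = config.image_shape
    axes_px = truth.axes_per_frame / config.pixel_size  # (n, 2): a, b in px

    too_big = np.nonzero(2.0 * axes_px[:, 0] + 8 > min(h, w))[0]
    if len(too_big):
        i = int(too_big[0])
        raise ValueError(
            f"frame {i}: bladder long axis {2 * axes_px[i, 0]:.1f} px does not fit "
            f"image shape {config.image_shape}"
        )

    ss = np.random.SeedSequence(config.seed)
    _dyn_ss, render_ss = ss.spawn(2)
    rng = np.random.default_rng(render_ss)

    amp = config.background_motion_amplitude
    cy = (h - 1) / 2.0 + _ar1_walk(rng, n, amp)
    cx = (w - 1) / 2.0 + _ar1_walk(rng, n, amp)
    theta0 = rng.uniform(0.0, np.pi)
    theta = theta0 + np.cumsum(rng.normal(0.0, 0.01 if amp > 0 else 0.0, size=n))
    theta = gaussian_filter1d(theta, 3) if n > 1 else theta

    # clamp centers so the ellipse always stays inside with a margin
    margin = axes_px[:, 0] + 3
    cy = np.clip(cy, margin, h - 1 - margin)
    cx = np.clip(cx, margin, w - 1 - margin)

    # background bars: fixed geometry in a drifting, rotating bone frame
    bar_angle = rng.uniform(0.0, np.pi, size=config.n_bars)
    bar_offset = rng.uniform(-0.35, 0.35, size=config.n_bars) * min(h, w)
    bar_width = rng.uniform(6.0, 11.0, size=config.n_bars)
    bone_dy = _ar1_walk(rng, n, 1.5 * amp)
    bone_dx = _ar1_walk(rng, n, 1.5 * amp)
    bone_rot = np.cumsum(rng.normal(0.0, 0.002 if amp > 0 else 0.0, size=n))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    yc, xc = (h - 1) / 2.0, (w - 1) / 2.0

    frames = np.empty((n, h, w), dtype=np.float32)
    masks = np.zeros((n, h, w), dtype=bool)
    mu = ATTENUATION_PER_MM

    for i in range(n):
        img = np.full((h, w), BACKGROUND_INTENSITY)
        # bones
        dy = yy - yc - bone_dy[i]
        dx = xx - xc - bone_dx[i]
        for j in range(config.n_bars):
            ang = bar_angle[j] + bone_rot[i]
            dist = dx * np.sin(ang) - dy * np.cos(ang) - bar_offset[j]
            img[np.abs(dist) < bar_width[j] / 2.0] *= BAR_TRANSMISSION
        # bladder
        a_px, b_px = axes_px[i]
        if b_px > 1e-6:
            ct, st = np.cos(theta[i]), np.sin(theta[i])
            u = (xx - cx[i]) * ct + (yy - cy[i]) * st
            q = -(xx - cx[i]) * st + (yy - cy[i]) * ct
            m = 1.0 - (u / a_px) ** 2 - (q / b_px) ** 2
            inside = m > 0
            masks[i] = inside
            chord_mm = 2.0 * (b_px * config.pixel_size) * np.sqrt(m[inside])
            img[inside] *= np.exp(-mu * chord_mm)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[i] = np.clip(img, 0.0, 1.0)

    seq = FrameSequence(frames, truth.volume_trace.time.copy(), config.pixel_size)
    mask_seq = MaskSequence(masks, masks.any(axis=(1, 2)))
    truth.masks = mask_seq
    return seq, mask_seq


def simulate(config: SimConfig) -> tuple[GroundTruth, FrameSequence, MaskSequence]:
    """Convenience wrapper: dynamics plus rendering."""
    truth = simulate_dynamics(config)
    frames, masks = render_frames(truth, config)
    return truth, frames, masks
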