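"""Simulator: conservation, determinism, NVC separability, rendering geometry."""

import dataclasses

import numpy as np
import pytest

from cystoflow.simcore import SimConfig, render_frames, simulate_dynamics
from cystoflow.volumetry import fit_spheroid


def test_constant_fill_integrates_analytically():
    cfg = SimConfig(fill_rate=20.0, capacity_threshold=1000.0, duration=60.0,
                    nvc_rate=0.0, initial_volume=0.0)
    truth = simulate_dynamics(cfg)
    v = truth.volume_trace.volume
    assert truth.void_events == []
    assert v[-1] - v[0] == pytest.approx(20.0, abs=1e-9)


def test_quiescent_config_keeps_volume_and_pressure_constant():
    cfg = SimConfig(fill_rate=0.0, nvc_rate=0.0, duration=30.0, initial_volume=40.0)
    truth = simulate_dynamics(cfg)
    assert np.allclose(truth.volume_trace.volume, 40.0)
    assert np.allclose(truth.pressure_trace.pressure, cfg.baseline_pressure)


def test_void_conserves_volume_against_outflow_quadrature():
    """Voided volume equals the time integral of the generated outflow."""
    cfg = SimConfig(fill_rate=20.0, capacity_threshold=100.0, residual_fraction=0.5,
                    initial_volume=99.0, duration=30.0, nvc_rate=0.0, seed=1)
    truth = simulate_dynamics(cfg)
    assert len(truth.void_events) == 1
    ev = truth.void_events[0]
    assert ev.voided == pytest.approx(50.0, rel=0.01)
    t_of, outflow = truth.outflow_profiles[0]
    fill_in = cfg.fill_rate / 60.0 * (ev.end - ev.onset)
    assert np.trapezoid(outflow, t_of) - fill_in == pytest.approx(ev.voided, rel=0.01)


def test_every_void_conserves_volume(realistic_truth):
    _, truth = realistic_truth
    assert len(truth.void_events) == 2
    for (t_of, outflow), ev in zip(truth.outflow_profiles, truth.void_events):
        net = np.trapezoid(outflow, t_of) - 20.0 / 60.0 * (ev.end - ev.onset)
        assert net == pytest.approx(ev.voided, rel=0.01)


def test_nvc_pulses_move_no_volume(realistic_truth):
    """Pressure excursions flagged as NVCs coincide with zero net volume
    change beyond the constant fill."""
    cfg, truth = realistic_truth
    assert len(truth.nvc_times) > 0
    t, v = truth.volume_trace.time, truth.volume_trace.volume
    for tc in truth.nvc_times:
        sel = (t >= tc - cfg.nvc_duration) & (t <= tc + cfg.nvc_duration)
        dv = v[sel][-1] - v[sel][0]
        expected_fill = cfg.fill_rate / 60.0 * (t[sel][-1] - t[sel][0])
        assert abs(dv - expected_fill) < 0.5


def test_identical_seed_is_bit_identical():
    cfg = SimConfig(duration=10.0, initial_volume=90.0, capacity_threshold=95.0,
                    fill_rate=60.0, seed=5)
    a = simulate_dynamics(cfg)
    b = simulate_dynamics(cfg)
    assert np.array_equal(a.volume_trace.volume, b.volume_trace.volume)
    assert np.array_equal(a.pressure_trace.pressure, b.pressure_trace.pressure)
    fa, ma = render_frames(a, cfg)
    fb, mb = render_frames(b, cfg)
    assert np.array_equal(fa.frames, fb.frames)
    assert np.array_equal(ma.masks, mb.masks)


@pytest.mark.parametrize("bad", [
    {"fill_rate": -1.0}, {"residual_fraction": 1.5}, {"aspect_ratio": 0.5},
    {"capacity_threshold": 0.0}, {"frame_rate": 0.0}, {"noise_sd": -0.1},
])
def test_nonphysical_configs_rejected(bad):
    with pytest.raises(ValueError):
        simulate_dynamics(SimConfig(**bad))


def test_zero_volume_frames_have_empty_masks():
    cfg = SimConfig(fill_rate=0.0, initial_volume=0.0, duration=1.0, nvc_rate=0.0)
    truth = simulate_dynamics(cfg)
    _, masks = render_frames(truth, cfg)
    assert not masks.masks.any()
    assert not masks.valid.any()


def test_sphere_renders_at_analytic_radius():
    """A 33.51 µl sphere (aspect ratio 1) has radius 2 mm: the recovered
    equivalent-ellipse radii of the rendered mask match."""
    v = (4.0 / 3.0) * np.pi * 8.0  # r = 2 mm -> 33.51 µl
    cfg = SimConfig(fill_rate=0.0, initial_volume=v, duration=0.05, aspect_ratio=1.0,
                    nvc_rate=0.0, noise_sd=0.0, background_motion_amplitude=0.0)
    truth = simulate_dynamics(cfg)
    assert truth.axes_per_frame[0] == pytest.approx([2.0, 2.0], rel=1e-6)
    _, masks = render_frames(truth, cfg)
    geo = fit_spheroid(masks.masks[0], cfg.pixel_size)
    assert geo.long_radius == pytest.approx(2.0, rel=0.02)
    assert geo.short_radius == pytest.approx(2.0, rel=0.02)


def test_mask_area_matches_analytic_ellipse(noisefree_session):
    cfg, truth, _, masks = noisefree_session
    areas = masks.areas()
    ab = truth.axes_per_frame / cfg.pixel_size
    analytic = np.pi * ab[:, 0] * ab[:, 1]
    sel = analytic > 300  # rasterization error dominates tiny ellipses
    assert np.all(np.abs(areas[sel] / analytic[sel] - 1.0) < 0.02)


def test_rendering_roundtrip_recovers_axes(noisefree_session):
    """Noise-free ground-truth masks fit back to the generating semi-axes."""
    cfg, truth, _, masks = noisefree_session
    for i in range(0, len(masks), 97):
        a_mm, b_mm = truth.axes_per_frame[i]
        if b_mm < 0.8:
            continue
        geo = fit_spheroid(masks.masks[i], cfg.pixel_size)
        assert geo.long_radius == pytest.approx(a_mm, rel=0.02)
        assert geo.short_radius == pytest.approx(b_mm, rel=0.02)


def test_oversized_bladder_names_offending_frame():
    cfg = SimConfig(fill_rate=0.0, initial_volume=5000.0, duration=0.05,
                    capacity_threshold=10000.0, nvc_rate=0.0)
    truth = simulate_dynamics(cfg)
    with pytest.raises(ValueError, match="frame 0"):
        render_frames(truth, cfg)
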