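"""Savitzky-Golay smoothing, flow-rate derivation, pressure alignment, UFC."""

import numpy as np
import pytest

from cystoflow.signals import (PressureTrace, align_pressure, compute_ufc,
                               compute_ufr, smooth_volume)
from cystoflow.volumetry import VolumeTrace


def _trace(volume, rate=30.0, valid=None):
    volume = np.asarray(volume, dtype=float)
    t = np.arange(len(volume)) / rate
    if valid is None:
        valid = np.ones(len(volume), dtype=bool)
    return VolumeTrace(t, volume, valid)


class TestSmoothVolume:
    def test_polynomial_passes_through(self):
        t = np.arange(100) / 30.0
        poly = 5.0 + 3.0 * t - 0.8 * t**2 + 0.1 * t**3
        out = smooth_volume(_trace(poly), window=31, polyorder=3)
        assert np.allclose(out.volume, poly, atol=1e-8)

    def test_constant_unchanged(self):
        out = smooth_volume(_trace(np.full(50, 42.0)), window=11, polyorder=2)
        assert np.allclose(out.volume, 42.0)

    def test_noise_rmse_reduced_on_sine(self):
        rng = np.random.default_rng(12)
        t = np.arange(300) / 30.0
        clean = 50.0 + 10.0 * np.sin(2.0 * np.pi * t / 10.0)
        noisy = clean + rng.normal(0.0, 2.0, len(t))
        out = smooth_volume(_trace(noisy), window=31, polyorder=3)
        rmse_out = np.sqrt(np.mean((out.volume - clean) ** 2))
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_out < rmse_in

    def test_window_validation(self):
        with pytest.raises(ValueError):
            smooth_volume(_trace(np.zeros(10)), window=4, polyorder=2)
        with pytest.raises(ValueError):
            smooth_volume(_trace(np.zeros(10)), window=31, polyorder=3)
        with pytest.raises(ValueError):
            smooth_volume(_trace(np.zeros(10)), window=5, polyorder=5)

    def test_total_change_unbiased(self, realistic_truth):
        """SG smoothing does not bias the total volume change."""
        _, truth = realistic_truth
        v = truth.volume_trace
        out = smooth_volume(v, 31, 3)
        total_in = v.volume[-1] - v.volume[0]
        total_out = out.volume[-1] - out.volume[0]
        assert total_out == pytest.approx(total_in, rel=0.01)


class TestComputeUfr:
    def test_linear_decline_gives_constant_outflow(self):
        v = np.linspace(100.0, 0.0, 61)  # 2 s at 30 samples/s
        flow = compute_ufr(_trace(v))
        assert np.allclose(flow.ufr[1:-1], 50.0)

    def test_constant_volume_gives_zero_flow(self):
        flow = compute_ufr(_trace(np.full(30, 70.0)))
        assert np.allclose(flow.ufr, 0.0)

    def test_filling_at_20ul_per_min_reads_minus_one_third(self):
        t = np.arange(90) / 30.0
        v = 10.0 + 20.0 / 60.0 * t
        flow = compute_ufr(VolumeTrace(t, v, np.ones(90, bool)))
        assert np.allclose(flow.ufr, -1.0 / 3.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_ufr(_trace(np.array([1.0, 2.0])))


class TestAlignPressure:
    def test_constant_pressure(self):
        p = PressureTrace(np.arange(0, 10, 0.02), np.full(500, 12.0))
        out = align_pressure(p, np.arange(0, 9, 1 / 30))
        assert np.allclose(out, 12.0)

    def test_linear_ramp_midpoint(self):
        p = PressureTrace(np.linspace(0, 10, 501), np.linspace(0, 10, 501))
        assert align_pressure(p, np.array([5.0]))[0] == pytest.approx(5.0)

    def test_query_at_knot_is_exact(self):
        t = np.arange(0, 2, 0.02)
        vals = np.sin(t) + 10
        p = PressureTrace(t, vals)
        out = align_pressure(p, t[[10, 50, 73]])
        assert np.array_equal(out, vals[[10, 50, 73]])

    def test_disjoint_ranges_rejected(self):
        p = PressureTrace(np.arange(0.0, 1.0, 0.02), np.full(50, 5.0))
        with pytest.raises(ValueError, match="overlap"):
            align_pressure(p, np.arange(100.0, 101.0, 0.1))


class TestComputeUfc:
    def test_direct_division(self):
        flow = compute_ufr(_trace(np.linspace(100, 0, 121)))  # 25 µl/s
        out = compute_ufc(flow, np.full(121, 25.0))
        assert np.allclose(out.ufc[1:-1], 1.0)

    def test_zero_flow_zero_conductance(self):
        flow = compute_ufr(_trace(np.full(30, 50.0)))
        out = compute_ufc(flow, np.full(30, 20.0))
        assert np.allclose(out.ufc, 0.0)

    def test_below_floor_undefined(self):
        flow = compute_ufr(_trace(np.linspace(100, 0, 30)))
        p = np.full(30, 1.0)
        out = compute_ufc(flow, p, pressure_floor=3.0)
        assert np.all(np.isnan(out.ufc))

    def test_finite_nonnegative_where_defined(self, realistic_truth):
        _, truth = realistic_truth
        sm = smooth_volume(truth.volume_trace, 31, 3)
        flow = compute_ufr(sm)
        p = align_pressure(truth.pressure_trace, sm.time)
        out = compute_ufc(flow, p)
        defined = ~np.isnan(out.ufc)
        assert np.all(np.isfinite(out.ufc[defined]))
        assert np.all(out.ufc[defined] >= 0.0)


def test_flow_volume_consistency_on_simulated_voids(realistic_truth):
    """The UFR integral over each void equals the volume drop within 2%."""
    from cystoflow.events import EventParams, detect_voids
    _, truth = realistic_truth
    sm = smooth_volume(truth.volume_trace, 31, 3)
    flow = compute_ufr(sm)
    events = detect_voids(sm, flow)
    assert len(events) == len(truth.void_events)
    t, v = truth.volume_trace.time, truth.volume_trace.volume
    for ev in events:
        sel = (t >= ev.onset) & (t <= ev.end)
        drop = v[sel][0] - v[sel][-1]
        quad = np.trapezoid(flow.ufr[sel], t[sel])
        assert quad == pytest.approx(drop, rel=0.02)
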