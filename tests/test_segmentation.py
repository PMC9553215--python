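"""Reference segmentation: rolling average, object selection, robustness."""

import dataclasses

import numpy as np
import pytest

from cystoflow.benchmark import dice
from cystoflow.segmentation import (FrameSequence, SegmentationParams,
                                    largest_component, rolling_average,
                                    segment_frame, segment_sequence)
from cystoflow.simcore import SimConfig, render_frames, simulate_dynamics


def _seq(frames, frame_rate=30.0, pixel_size=0.1):
    t = np.arange(len(frames)) / frame_rate
    return FrameSequence(np.asarray(frames, dtype=float), t, pixel_size)


class TestRollingAverage:
    def test_constant_sequence_unchanged(self):
        seq = _seq(np.full((20, 8, 8), 3.0))
        out = rolling_average(seq, 15)
        assert np.allclose(out.frames, seq.frames)
        assert np.array_equal(out.timestamps, seq.timestamps)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        seq = _seq(rng.random((5, 6, 6)))
        assert np.array_equal(rolling_average(seq, 1).frames, seq.frames)

    def test_impulse_is_averaged_over_window(self):
        frames = np.zeros((31, 4, 4))
        frames[15, 2, 2] = 15.0
        out = rolling_average(_seq(frames), 15)
        # full 15-frame windows containing the impulse read 1 at that pixel
        for i in range(15 - 7, 15 + 8):
            assert out.frames[i, 2, 2] == pytest.approx(1.0)
        assert out.frames[15, 0, 0] == 0.0
        assert out.frames[0, 2, 2] == 0.0  # edge window shrinks to 1 frame

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            rolling_average(_seq(np.zeros((4, 3, 3))), 4)


class TestSegmentFrame:
    def test_blank_frame_is_invalid(self):
        mask, ok = segment_frame(np.full((64, 64), 0.7))
        assert not ok and not mask.any()

    def test_largest_of_two_blobs_retained(self):
        """Two dark blobs: only the biggest is kept as the bladder."""
        frame = np.full((80, 80), 0.9)
        yy, xx = np.mgrid[0:80, 0:80]
        big = (yy - 30) ** 2 + (xx - 30) ** 2 <= 12.6**2  # ~500 px
        small = (yy - 65) ** 2 + (xx - 65) ** 2 <= 5**2  # ~80 px
        frame[big] = 0.1
        frame[small] = 0.1
        params = SegmentationParams(min_area_px=50, closing_radius=0)
        mask, ok = segment_frame(frame, params)
        assert ok
        assert mask[big].all() and not mask[small].any()

    def test_noise_free_render_reaches_high_dice(self, noisefree_session):
        cfg, truth, frames, gt = noisefree_session
        i = int(np.argmax(truth.volume_trace.volume))
        mask, ok = segment_frame(frames.frames[i], pixel_size=cfg.pixel_size)
        assert ok
        assert dice(gt.masks[i], mask) >= 0.98

    def test_nonfinite_frame_rejected(self):
        frame = np.full((16, 16), np.nan)
        with pytest.raises(ValueError):
            segment_frame(frame)


class TestSegmentSequence:
    def test_identical_frames_give_identical_valid_masks(self):
        frame = np.full((64, 64), 0.9)
        yy, xx = np.mgrid[0:64, 0:64]
        frame[(yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2] = 0.1
        seq = _seq(np.repeat(frame[None], 6, axis=0))
        out = segment_sequence(seq, SegmentationParams(min_area_px=50), rolling_window=1)
        assert out.valid.all()
        assert all(np.array_equal(out.masks[0], m) for m in out.masks)

    def test_blanked_frames_are_flagged_invalid(self):
        frame = np.full((64, 64), 0.9)
        yy, xx = np.mgrid[0:64, 0:64]
        frame[(yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2] = 0.1
        frames = np.repeat(frame[None], 8, axis=0)
        frames[3] = 0.9
        frames[4] = 0.9
        out = segment_sequence(_seq(frames), SegmentationParams(min_area_px=50),
                               rolling_window=1)
        assert list(out.valid) == [True, True, True, False, False, True, True, True]

    def test_voided_segment_flags_follow_ground_truth(self):
        """A fully-voided stretch yields invalid frames exactly where the
        bladder is gone or below the detectable area."""
        cfg = SimConfig(fill_rate=120.0, capacity_threshold=60.0, residual_fraction=0.0,
                        initial_volume=58.0, duration=20.0, nvc_rate=0.0,
                        noise_sd=0.0, seed=3)
        truth = simulate_dynamics(cfg)
        frames, gt = render_frames(truth, cfg)
        pred = segment_sequence(frames, rolling_window=1)
        params = SegmentationParams()
        min_area = params.resolved_min_area(cfg.pixel_size)
        gt_area = gt.areas()
        # comfortably above the floor -> detected; empty truth -> invalid
        assert pred.valid[gt_area >= 2 * min_area].all()
        assert not pred.valid[gt_area == 0].any()


class TestInvariants:
    def test_largest_component_selection_is_idempotent(self):
        rng = np.random.default_rng(4)
        blobs = rng.random((40, 40)) < 0.3
        once = largest_component(blobs)
        assert np.array_equal(largest_component(once), once)

    def test_valid_masks_have_single_component(self, rendered_session):
        from scipy import ndimage
        _, _, frames, _ = rendered_session
        sub = FrameSequence(frames.frames[::40], frames.timestamps[::40],
                            frames.pixel_size)
        pred = segment_sequence(sub, rolling_window=1)
        for m, ok in zip(pred.masks, pred.valid):
            if ok:
                _, n = ndimage.label(m, structure=np.ones((3, 3)))
                assert n == 1

    def test_median_dice_degrades_with_noise(self):
        """Median Dice over a short render is non-increasing in noise."""
        medians = []
        for noise in (0.0, 0.12, 0.3):
            cfg = SimConfig(fill_rate=300.0, capacity_threshold=100.0,
                            initial_volume=60.0, duration=3.0, nvc_rate=0.0,
                            noise_sd=noise, seed=9)
            truth = simulate_dynamics(cfg)
            frames, gt = render_frames(truth, cfg)
            pred = segment_sequence(frames)
            ds = [dice(gt.masks[i], pred.masks[i]) if pred.valid[i] else 0.0
                  for i in range(len(pred)) if gt.valid[i]]
            medians.append(np.median(ds))
        assert medians[0] >= medians[1] >= medians[2]
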