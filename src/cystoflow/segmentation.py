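"""Per-frame bladder segmentation for time-lapse fluoroscopy.

The contrast-filled bladder is the most X-ray-opaque (darkest) compact
object in the field of view.  The reference segmentation here is a
classical pipeline — contrast normalization, dark-object thresholding,
morphological closing, hole filling, and largest-component selection —
standing in for any learned per-frame predictor with the same contract
(one binary mask per frame, a validity flag when no bladder is found).
A custom predictor can be plugged in via :func:`segment_sequence`'s
``predictor`` hook.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology
from skimage.segmentation import clear_border

logger = logging.getLogger(__name__)

#: Smallest bladder volume (µl) the paper-scale setup resolves reliably;
#: used to derive the default minimum mask area at a given pixel size.
MIN_DETECTABLE_VOLUME_UL = 4.0


@dataclass
class FrameSequence:
    """Ordered grayscale fluoroscopy frames with timestamps and pixel size.

    Attributes
    ----------
    frames : (n, H, W) float array
        Grayscale intensities (any monotone scale; bladder dark).
    timestamps : (n,) float array
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_size : float
        Isotropic pixel size in mm/pixel.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MaskSequence:
    """Per-frame binary bladder masks with validity flags.

    ``valid[i]`` is False when no bladder object was found in frame ``i``
    (the corresponding mask is empty).  Every valid mask contains exactly
    one 8-connected component.
    """

    masks: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n, H, W) stack")
        if len(self.valid) != len(self.masks):
            raise ValueError("valid flags and masks must have equal length")

    def __len__(self) -> int:
        return len(self.masks)

    def areas(self) -> np.ndarray:
        """Pixel area of each mask."""
        return self.masks.sum(axis=(1, 2))


@dataclass
class SegmentationParams:
    """Tunables of the reference segmentation operator.

    threshold : manual intensity threshold on the normalized [0, 1] frame;
        ``None`` selects it automatically (three-class Otsu, lowest cut).
    min_area_px : smallest acceptable component, pixels.  ``None`` derives
        it from ``pixel_size`` as the projected disk area of a
        :data:`MIN_DETECTABLE_VOLUME_UL` sphere.
    closing_radius : disk radius (px) of the morphological closing.
    norm_percentiles : robust (low, high) percentiles mapped to [0, 1].
    """

    threshold: Optional[float] = None
    min_area_px: Optional[int] = None
    closing_radius: int = 2
    norm_percentiles: tuple[float, float] = (0.1, 99.5)
    discard_border: bool = True

    def resolved_min_area(self, pixel_size: float) -> int:
        if self.min_area_px is not None:
            return int(self.min_area_px)
        r_mm = (3.0 * MIN_DETECTABLE_VOLUME_UL / (4.0 * np.pi)) ** (1.0 / 3.0)
        return max(1, int(round(np.pi * r_mm**2 / pixel_size**2)))


def min_area_for_volume(volume_ul: float, pixel_size: float) -> int:
    """Projected-disk pixel area of a sphere of ``volume_ul`` µl."""
    r_mm = (3.0 * volume_ul / (4.0 * np.pi)) ** (1.0 / 3.0)
    return max(1, int(round(np.pi * r_mm**2 / pixel_size**2)))


def rolling_average(seq: FrameSequence, window: int = 15) -> FrameSequence:
    """Centered temporal rolling average of the frame stack.

    Each output frame is the mean of up to ``window`` input frames centered
    on it; at the sequence edges the window shrinks symmetrically so the
    output stays unbiased.  Timestamps are unchanged.

    Parameters
    ----------
    window : odd int
        Full window length in frames (default 15).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return FrameSequence(seq.frames.copy(), seq.timestamps.copy(), seq.pixel_size)
    n = len(seq)
    half = window // 2
    # cumulative sum along time lets every symmetric window be a difference
    csum = np.cumsum(seq.frames.astype(np.float64), axis=0)
    csum = np.concatenate([np.zeros((1,) + seq.frame_shape), csum], axis=0)
    out = np.empty_like(seq.frames, dtype=np.float64)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return FrameSequence(out.astype(seq.frames.dtype, copy=False), seq.timestamps.copy(), seq.pixel_size)


def _normalize(frame: np.ndarray, percentiles: tuple[float, float]) -> Optional[np.ndarray]:
    lo, hi = np.percentile(frame, percentiles)
    if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo < 1e-9:
        return None
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def _auto_threshold(norm: np.ndarray) -> Optional[float]:
    """Lowest cut of a three-class Otsu; falls back to plain Otsu."""
    try:
        return float(filters.threshold_multiotsu(norm, classes=3)[0])
    except ValueError:
        try:
            return float(filters.threshold_otsu(norm))
        except ValueError:
            return None


def segment_frame(
    frame: np.ndarray, params: SegmentationParams | None = None, pixel_size: float = 0.1
) -> tuple[np.ndarray, bool]:
    """Segment the bladder in one grayscale frame.

    Pipeline: robust contrast normalization -> dark-object threshold
    (manual or automatic) -> morphological closing and hole filling ->
    discard border-touching components (field-spanning bones) -> keep the
    single largest 8-connected component above the minimum area.

    Returns
    -------
    (mask, valid) : (2-D bool array, bool)
        Empty mask and ``valid=False`` when no acceptable object exists.
        Degenerate frames never raise.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    empty = np.zeros(frame.shape, dtype=bool)

    norm = _normalize(frame, params.norm_percentiles)
    if norm is None:  # flat frame: no contrast, no object
        return empty, False

    if params.threshold is not None:
        thresholds = [params.threshold]
    else:
        thr = _auto_threshold(norm)
        if thr is None:
            return empty, False
        thresholds = [thr]
        # a small bladder can leave the three-class split separating bones
        # from background instead; a second Otsu inside the dark class then
        # isolates the truly contrast-opaque object
        dark = norm[norm < thr]
        if dark.size > 64:
            try:
                thresholds.append(float(filters.threshold_otsu(dark)))
            except ValueError:
                pass

    min_area = params.resolved_min_area(pixel_size)
    for thr in thresholds:
        binary = norm < thr
        if not binary.any() or binary.mean() > 0.6:  # degenerate split
            continue
        mask = _select_object(binary, params, min_area)
        if mask is not None:
            return mask, True
    return empty, False


def _select_object(
    binary: np.ndarray, params: SegmentationParams, min_area: int
) -> Optional[np.ndarray]:
    """Closing, hole filling, border clearing, largest-component selection.

    Morphology runs on the padded bounding box of the foreground, which is
    equivalent to full-frame processing (the pad exceeds the closing
    radius) and much faster.  Returns None when no acceptable object
    remains.
    """
    ys, xs = np.nonzero(binary)
    pad = params.closing_radius + 3
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, binary.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, binary.shape[1])
    sub = binary[y0:y1, x0:x1]

    if params.closing_radius > 0:
        sub = morphology.closing(sub, morphology.disk(params.closing_radius))
    sub = ndimage.binary_fill_holes(sub)
    if params.discard_border:
        # only crop edges coinciding with the true frame border can carry
        # foreground (the pad keeps interior crop edges clear)
        sub = clear_border(sub)

    labels = measure.label(sub, connectivity=2)
    if labels.max() == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(areas)) + 1
    if areas[biggest - 1] < min_area:
        return None
    mask = np.zeros(binary.shape, dtype=bool)
    mask[y0:y1, x0:x1] = ndimage.binary_fill_holes(labels == biggest)
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component of a binary mask (idempotent)."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    if labels.max() == 0:
        return np.zeros(mask.shape, dtype=bool)
    areas = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(areas)) + 1)


def segment_sequence(
    seq: FrameSequence,
    params: SegmentationParams | None = None,
    rolling_window: int = 15,
    predictor: Optional[Callable[[np.ndarray], tuple[np.ndarray, bool]]] = None,
) -> MaskSequence:
    """Segment every frame of a sequence.

    Applies :func:`rolling_average` (window ``rolling_window``) followed by
    :func:`segment_frame` per frame, logging every frame in which no
    bladder was found.  ``predictor`` replaces the reference per-frame
    operator with any callable of the same contract.
    """
    params = params or SegmentationParams()
    smoothed = rolling_average(seq, rolling_window) if rolling_window > 1 else seq
    n = len(seq)
    masks = np.zeros((n,) + seq.frame_shape, dtype=bool)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if predictor is not None:
            mask, ok = predictor(smoothed.frames[i])
        else:
            mask, ok = segment_frame(smoothed.frames[i], params, seq.pixel_size)
        masks[i] = mask
        valid[i] = ok
        if not ok:
            logger.info("frame %d (t=%.3f s): no bladder object found", i, seq.timestamps[i])
    return MaskSequence(masks, valid)
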