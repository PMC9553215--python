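"""Prolate-spheroid bladder volumetry from binary masks.

The segmented bladder outline is reduced to the equivalent ellipse (the
ellipse with the same normalized second central moments as the mask), and
volume follows from the prolate-spheroid approximation

    V_ves = (4/3) * pi * a * b**2

with ``a`` the long and ``b`` the short in-plane semi-axis in mm; the
out-of-plane semi-axis is taken equal to ``b``.  1 mm^3 = 1 µl.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .segmentation import MaskSequence


class EmptyMaskError(ValueError):
    """Raised when geometry is requested for an empty mask."""


@dataclass
class BladderGeometry:
    """Equivalent-ellipse geometry of one segmented bladder.

    long_radius, short_radius : semi-axes in mm (long >= short >= 0).
    center : (row, col) centroid in 0-based pixel coordinates.
    orientation : angle (radians) of the major axis, measured from the
        column (x) axis, counter-clockwise in (row up) convention,
        in (-pi/2, pi/2].
    """

    long_radius: float
    short_radius: float
    center: tuple[float, float]
    orientation: float


def fit_spheroid(mask: np.ndarray, pixel_size: float) -> BladderGeometry:
    """Fit the equivalent ellipse of a binary mask.

    Semi-axes derive from the eigenvalues of the normalized second central
    moment matrix (rotation invariant); they are scaled to mm by
    ``pixel_size``.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixels; the caller marks the sample
        invalid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot fit geometry to an empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    a_px = props.axis_major_length / 2.0
    b_px = props.axis_minor_length / 2.0
    # orientation: skimage measures from the row axis; convert to angle
    # from the column axis for conventional (x, y) reporting
    theta = np.pi / 2.0 - props.orientation
    theta = (theta + np.pi / 2.0) % np.pi - np.pi / 2.0
    return BladderGeometry(
        long_radius=a_px * pixel_size,
        short_radius=b_px * pixel_size,
        center=tuple(props.centroid),
        orientation=float(theta),
    )


def volume_from_axes(long_radius: float, short_radius: float) -> float:
    """Prolate-spheroid volume (µl) from semi-axes in mm.

    V = (4/3) * pi * long_radius * short_radius**2.
    """
    if long_radius < 0 or short_radius < 0:
        raise ValueError("semi-axes must be nonnegative")
    if long_radius < short_radius:
        raise ValueError("long_radius must be >= short_radius")
    return (4.0 / 3.0) * np.pi * long_radius * short_radius**2


def axes_from_volume(volume: float, aspect_ratio: float) -> tuple[float, float]:
    """Invert the spheroid formula: semi-axes (a, b) in mm for a volume in
    µl at a fixed aspect ratio a/b >= 1."""
    if volume < 0:
        raise ValueError("volume must be nonnegative")
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    b = (3.0 * volume / (4.0 * np.pi * aspect_ratio)) ** (1.0 / 3.0)
    return aspect_ratio * b, b


@dataclass
class VolumeTrace:
    """Time-stamped bladder volume V_ves with per-sample validity.

    time : seconds, strictly increasing.  volume : µl (NaN where invalid).
    """

    time: np.ndarray
    volume: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.time) == len(self.volume) == len(self.valid)):
            raise ValueError("time, volume, valid must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.volume[self.valid] < 0):
            raise ValueError("volume must be nonnegative where valid")

    def __len__(self) -> int:
        return len(self.time)


def build_volume_trace(
    masks: MaskSequence,
    timestamps: np.ndarray,
    pixel_size: float,
    max_gap: int = 2,
) -> VolumeTrace:
    """Per-frame volume trace from a mask sequence, with short-gap repair.

    Each valid mask yields a volume via :func:`fit_spheroid` +
    :func:`volume_from_axes`.  Runs of at most ``max_gap`` consecutive
    invalid frames flanked by valid frames on both sides (typical brief
    segmentation failures of one or two frames) are filled by linear
    interpolation in time and marked valid; longer runs stay invalid.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != len(masks):
        raise ValueError("masks and timestamps must be aligned")
    n = len(masks)
    volume = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if not masks.valid[i]:
            continue
        try:
            geo = fit_spheroid(masks.masks[i], pixel_size)
        except EmptyMaskError:
            continue
        volume[i] = volume_from_axes(geo.long_radius, geo.short_radius)
        valid[i] = True
    if not valid.any():
        raise ValueError("all frames invalid: no bladder was segmented anywhere")

    # repair interior gaps of <= max_gap frames
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        if i > 0 and j < n and run <= max_gap:
            volume[i:j] = np.interp(timestamps[i:j], [timestamps[i - 1], timestamps[j]],
                                    [volume[i - 1], volume[j]])
            valid[i:j] = True
        i = j
    return VolumeTrace(timestamps, volume, valid)
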