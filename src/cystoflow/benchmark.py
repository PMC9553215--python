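"""Segmentation benchmarking with the Dice similarity index.

Dice (DISI) between a ground-truth mask X and a predicted mask Y is

    DISI = 2 * |X ∩ Y| / (|X| + |Y|)

in [0, 1], 1 for perfect agreement.  Evaluation follows a holdout
protocol: a seeded random fraction (default 20%) of the annotated frames
is set aside and per-frame Dice statistics are reported on it.  Frames
where both masks are empty leave the formula 0/0 and are excluded from
the report (and logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .segmentation import MaskSequence

logger = logging.getLogger(__name__)


@dataclass
class DiceReport:
    """Per-frame Dice values on the evaluation set with summary stats."""

    per_frame: np.ndarray
    median: float
    mean: float
    sd: float
    n_frames: int

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DiceReport":
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            raise ValueError("cannot summarize an empty set of Dice values")
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return cls(
            per_frame=values,
            median=float(np.median(values)),
            mean=float(np.mean(values)),
            sd=sd,
            n_frames=len(values),
        )


def dice(x_mask: np.ndarray, y_mask: np.ndarray) -> float:
    """Dice similarity index of two binary masks (symmetric).

    Raises
    ------
    ValueError
        If the masks differ in shape, or are both empty (0/0 undefined;
        callers exclude such frames).
    """
    x = np.asarray(x_mask, dtype=bool)
    y = np.asarray(y_mask, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    sx = int(x.sum())
    sy = int(y.sum())
    if sx + sy == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * int((x & y).sum()) / (sx + sy)


def holdout_evaluate(
    pred: MaskSequence,
    truth: MaskSequence,
    holdout_fraction: float = 0.2,
    seed: int | None = None,
) -> DiceReport:
    """Dice statistics on a seeded random holdout of frames.

    ``ceil(holdout_fraction * n)`` frames are drawn without replacement
    (so a nonzero fraction never yields an empty set); frames where both
    masks are empty are excluded from the statistics.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and ground truth must be aligned and equal length")
    n = len(pred)
    if n == 0 or not 0.0 < holdout_fraction <= 1.0:
        raise ValueError("need a nonempty sequence and fraction in (0, 1]")
    k = math.ceil(holdout_fraction * n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))

    values = []
    excluded = 0
    for i in idx:
        try:
            values.append(dice(truth.masks[i], pred.masks[i]))
        except ValueError:
            excluded += 1
            logger.info("frame %d excluded from Dice report: both masks empty", i)
    if excluded:
        logger.info("%d/%d holdout frames excluded (both masks empty)", excluded, k)
    if not values:
        raise ValueError("evaluation set empty after excluding both-empty frames")
    return DiceReport.from_values(np.asarray(values))
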