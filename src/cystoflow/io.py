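"""File I/O, run configuration, and the end-to-end analysis pipeline.

Supported on-disk formats are deliberately plain: multi-page TIFF (or a
directory of lexicographically ordered PNG frames) for image and mask
stacks, and headered CSV for traces and event tables.  AVI recordings are
expected to be converted to an image sequence beforehand (e.g. with FIJI
or ``ffmpeg -i rec.avi frames/f%06d.png``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .benchmark import DiceReport
from .events import (EventParams, NvcParams, VoidEvent, count_nvcs,
                     detect_voids, intercontractile_intervals, void_parameters)
from .segmentation import (FrameSequence, MaskSequence, SegmentationParams,
                           segment_sequence)
from .signals import (DEFAULT_PRESSURE_FLOOR, PressureTrace, _filled_volume,
                      align_pressure, compute_ufc, compute_ufr, smooth_volume)
from .volumetry import VolumeTrace, build_volume_trace

logger = logging.getLogger(__name__)

VOID_CSV_COLUMNS = [
    "void_id", "onset_s", "end_s", "BC_ul", "RV_ul", "voided_ul",
    "efficiency_pct", "t20_80_s", "ufr_max_ul_s", "ufc_max", "p_max_cmH2O",
    "ici_s", "nvc_count",
]


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    All filter windows must be odd; every effective value is echoed to the
    run log so no parameter defaults silently.
    """

    frames_path: Optional[str] = None
    pressure_path: Optional[str] = None
    output_dir: str = "."
    pixel_size: float = 0.1  # mm/pixel
    frame_rate: float = 30.0  # frames/s
    rolling_window: int = 15  # frames
    sg_window: int = 31  # samples
    sg_polyorder: int = 3
    max_gap: int = 2  # frames repaired by interpolation
    pressure_floor: float = DEFAULT_PRESSURE_FLOOR  # cmH2O
    nvc_window: float = 80.0  # s before each void
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    events: EventParams = field(default_factory=EventParams)
    nvc: NvcParams = field(default_factory=NvcParams)

    def validate(self) -> None:
        for name in ("rolling_window", "sg_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {w}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("segmentation", SegmentationParams),
                         ("events", EventParams), ("nvc", NvcParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def log_parameters(self) -> list[str]:
        """Flat ``key = value`` lines covering every effective parameter."""
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, dict):
                for k2, v2 in value.items():
                    lines.append(f"{key}.{k2} = {v2}")
            else:
                lines.append(f"{key} = {value}")
        return lines


# ---------------------------------------------------------------------------
# frames and masks

def read_frames(path: str | Path, frame_rate: float = 30.0, pixel_size: float = 0.1) -> FrameSequence:
    """Load a frame stack from a multi-page TIFF or a directory of PNGs.

    Integer bit depths (8/16) are normalized to [0, 1]; float data is
    taken as-is.  Timestamps are synthesized from ``frame_rate``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames found in directory {path}")
        arrays = []
        for f in files:
            try:
                arrays.append(np.asarray(iio.imread(f)))
            except Exception as exc:  # pragma: no cover - corrupt file path
                raise ValueError(f"unreadable frame file {f}: {exc}") from exc
        shapes = {a.shape for a in arrays}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        stack = np.stack(arrays)
    else:
        if not path.exists():
            raise ValueError(f"unreadable frame file {path}: no such file")
        try:
            stack = np.asarray(tifffile.imread(path))
        except Exception as exc:
            raise ValueError(f"unreadable frame file {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected grayscale frames, got shape {stack.shape}")
    if stack.dtype == np.uint8:
        stack = stack.astype(np.float64) / 255.0
    elif stack.dtype == np.uint16:
        stack = stack.astype(np.float64) / 65535.0
    else:
        stack = stack.astype(np.float64)
    timestamps = np.arange(len(stack)) / frame_rate
    return FrameSequence(stack, timestamps, pixel_size)


def write_frames(path: str | Path, frames: np.ndarray) -> None:
    """Write a frame stack as 8-bit multi-page TIFF (floats taken in [0, 1])."""
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        frames = (np.clip(frames, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    tifffile.imwrite(path, frames, photometric="minisblack")


def read_masks(path: str | Path) -> MaskSequence:
    """Load a 0/255 mask stack; empty masks are flagged invalid."""
    stack = np.asarray(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    masks = stack > 127
    return MaskSequence(masks, masks.any(axis=(1, 2)))


def write_masks(path: str | Path, masks: MaskSequence) -> None:
    tifffile.imwrite(path, (masks.masks.astype(np.uint8) * 255),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# traces

def read_pressure(path: str | Path) -> PressureTrace:
    """Read a ``time_s,pressure_cmH2O`` CSV into a pressure trace."""
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_cmH2O"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if len(bad):
            raise ValueError(f"{path}: time not strictly increasing at row {int(bad[0]) + 1}")
    return PressureTrace(t, df["pressure_cmH2O"].to_numpy(dtype=float))


def write_pressure(path: str | Path, trace: PressureTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "pressure_cmH2O": trace.pressure}).to_csv(
        path, index=False)


def write_volume(path: str | Path, trace: VolumeTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "volume_ul": trace.volume,
                  "valid": trace.valid.astype(int)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineResult:
    """Outputs of one end-to-end run."""

    volume: VolumeTrace  # smoothed trace used for event analysis
    trace_table: pd.DataFrame
    voids: list[VoidEvent]
    void_table: pd.DataFrame
    masks: MaskSequence


def analyze_sequence(
    seq: FrameSequence,
    config: RunConfig,
    pressure: Optional[PressureTrace] = None,
    masks: Optional[MaskSequence] = None,
) -> PipelineResult:
    """Run the in-memory pipeline on a frame sequence.

    segmentation -> volumetry (with short-gap repair) -> Savitzky-Golay
    smoothing -> UFR -> (pressure alignment -> UFC) -> void detection ->
    per-void parameters -> NVC counting.  ``masks`` short-circuits
    segmentation (e.g. externally predicted masks).
    """
    config.validate()
    if masks is None:
        masks = segment_sequence(seq, config.segmentation, config.rolling_window)
    raw = build_volume_trace(masks, seq.timestamps, seq.pixel_size, config.max_gap)
    sg_window = min(config.sg_window, len(raw) if len(raw) % 2 else len(raw) - 1)
    smoothed = smooth_volume(raw, sg_window, config.sg_polyorder)
    flow = compute_ufr(smoothed)
    # volumes for BC/RV/t20-80 come from the unsmoothed (gap-repaired) trace:
    # smoothing is only needed ahead of differentiation and would round off
    # the volume peak at void onset
    raw_filled = VolumeTrace(raw.time, _filled_volume(raw), raw.valid)

    p_aligned = None
    if pressure is not None:
        p_aligned = align_pressure(pressure, smoothed.time)
        flow = compute_ufc(flow, p_aligned, config.pressure_floor)

    events = detect_voids(smoothed, flow, config.events)
    voids = void_parameters(events, raw_filled, flow, p_aligned)
    icis = intercontractile_intervals(voids)
    nvc_counts: list[Optional[int]] = []
    for ev in voids:
        if p_aligned is None:
            nvc_counts.append(None)
        else:
            nvc_counts.append(count_nvcs(p_aligned, smoothed, ev.onset,
                                         config.nvc_window, config.nvc))

    trace = {
        "time_s": smoothed.time,
        "volume_ul": smoothed.volume,
        "ufr_ul_s": flow.ufr,
        "valid": smoothed.valid.astype(int),
    }
    if p_aligned is not None:
        trace["pressure_cmH2O"] = p_aligned
        trace["ufc"] = flow.ufc
    trace_table = pd.DataFrame(trace)

    rows = []
    for i, (ev, ici, nvc) in enumerate(zip(voids, icis, nvc_counts)):
        row = {
            "void_id": i, "onset_s": ev.onset, "end_s": ev.end,
            "BC_ul": ev.capacity, "RV_ul": ev.residual, "voided_ul": ev.voided,
            "efficiency_pct": ev.efficiency, "t20_80_s": ev.t20_80,
            "ufr_max_ul_s": ev.ufr_max, "ici_s": ici,
        }
        if p_aligned is not None:
            row["ufc_max"] = ev.ufc_max
            row["p_max_cmH2O"] = ev.p_max
            row["nvc_count"] = nvc
        rows.append(row)
    columns = [c for c in VOID_CSV_COLUMNS
               if p_aligned is not None or c not in ("ufc_max", "p_max_cmH2O", "nvc_count")]
    void_table = pd.DataFrame(rows, columns=columns)
    return PipelineResult(volume=smoothed, trace_table=trace_table,
                          voids=voids, void_table=void_table, masks=masks)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-to-file pipeline run: frames (+ optional pressure) in,
    per-frame trace CSV + per-void CSV + run log out.

    Deterministic given identical inputs and configuration: reruns produce
    byte-identical CSV outputs.  On a stage failure every partial output
    is removed and the error names the stage.
    """
    config.validate()
    if config.frames_path is None:
        raise ValueError("config.frames_path is required")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = [outdir / "trace.csv", outdir / "voids.csv", outdir / "run.log",
               outdir / "masks.tif"]

    stage = "read inputs"
    try:
        seq = read_frames(config.frames_path, config.frame_rate, config.pixel_size)
        pressure = read_pressure(config.pressure_path) if config.pressure_path else None
        stage = "analysis"
        result = analyze_sequence(seq, config, pressure)
        stage = "write outputs"
        result.trace_table.to_csv(outputs[0], index=False)
        result.void_table.to_csv(outputs[1], index=False)
        write_masks(outputs[3], result.masks)
        log_lines = ["cystoflow run parameters"]
        log_lines += config.log_parameters()
        log_lines.append(f"n_frames = {len(seq)}")
        log_lines.append(f"n_voids = {len(result.voids)}")
        outputs[2].write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        for f in outputs:
            f.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    for line in config.log_parameters():
        logger.info("%s", line)
    return result


def write_dice_report(path: str | Path, report: DiceReport) -> None:
    df = pd.DataFrame({"frame": np.arange(report.n_frames), "dice": report.per_frame})
    df.to_csv(path, index=False)
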