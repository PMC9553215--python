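"""Shared synthetic fixtures; expensive renders are session-scoped."""

import numpy as np
import pytest

from cystoflow.io import RunConfig, analyze_sequence
from cystoflow.protocols import _session_config
from cystoflow.simcore import SimConfig, render_frames, simulate_dynamics


@pytest.fixture(scope="session")
def realistic_truth():
    """Catheterized-regime dynamics at paper time scales (no images):
    20 µl/min fill, 100 µl capacity, two complete voids 300 s apart."""
    cfg = SimConfig(fill_rate=20.0, capacity_threshold=100.0, residual_fraction=0.0,
                    initial_volume=50.0, duration=620.0, nvc_rate=2.25, seed=11)
    return cfg, simulate_dynamics(cfg)


@pytest.fixture(scope="session")
def rendered_session():
    """Compressed 100 µl session rendered at default noise/background,
    two voids with residual, pressure and NVCs included."""
    cfg = _session_config(100.0, 0.25, seed=42)
    truth = simulate_dynamics(cfg)
    frames, gt_masks = render_frames(truth, cfg)
    return cfg, truth, frames, gt_masks


@pytest.fixture(scope="session")
def noisefree_session():
    """Same compressed session rendered without sensor noise."""
    cfg = _session_config(100.0, 0.25, seed=42, noise_sd=0.0)
    truth = simulate_dynamics(cfg)
    frames, gt_masks = render_frames(truth, cfg)
    return cfg, truth, frames, gt_masks


@pytest.fixture(scope="session")
def rendered_analysis(rendered_session):
    """Full pipeline result on the rendered compressed session."""
    cfg, truth, frames, _ = rendered_session
    res = analyze_sequence(frames, RunConfig(pixel_size=cfg.pixel_size),
                           pressure=truth.pressure_trace)
    return cfg, truth, res
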