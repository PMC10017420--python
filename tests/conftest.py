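"""Shared fixtures: calibrated kinetics, small synthetic scenes, and the
study-shaped cohort feature table. All synthetic data is generated at test
time with fixed seeds."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from icgdyn.perfusion_features import compute_feature_table
from icgdyn.synth_scene import (
    SceneConfig,
    calibrate_kinetics,
    render_sequence,
    simulate_cohort,
)
from icgdyn.trace_extraction import ROITrace


@pytest.fixture(scope="session")
def calibrated():
    """Reference-calibrated per-class kinetics (crlm, healthy)."""
    return calibrate_kinetics()


@pytest.fixture(scope="session")
def static_pair():
    """Motion-free, noise-free small scene with its ground truth."""
    cfg = SceneConfig(
        height=72, width=96, fps=10.0, duration_s=40.0,
        affine_step_sd_px=0.0, rotation_step_sd_rad=0.0,
        respiration_amplitude_px=0.0, noise_sd=0.0, amplitude_jitter_sd=0.0,
    )
    return render_sequence(cfg, seed=3)


@pytest.fixture(scope="session")
def moving_pair():
    """Small scene with camera walk + respiration and mild noise."""
    cfg = SceneConfig(
        height=80, width=104, fps=10.0, duration_s=40.0, noise_sd=1.5,
    )
    return render_sequence(cfg, seed=5)


@pytest.fixture(scope="session")
def static_field(static_pair):
    """Stabilized field of the static scene."""
    from icgdyn.field_mapping import stabilize

    return stabilize(static_pair[0])


@pytest.fixture(scope="session")
def moving_field(moving_pair):
    """Stabilized field of the moving scene, with composed warps kept."""
    from icgdyn.field_mapping import StabilizationConfig, stabilize

    return stabilize(moving_pair[0], StabilizationConfig(keep_warps=True))


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of the full 132/24/6 synthetic cohort (seed 1)."""
    traces = simulate_cohort(seed=1)
    return compute_feature_table(traces)


def make_trace(values, fps=30.0, label="crlm", roi_id="t") -> ROITrace:
    values = np.asarray(values, dtype=float)
    return ROITrace(
        times=np.arange(len(values)) / fps,
        intensities=values,
        fps=fps,
        label=label,
        roi_id=roi_id,
    )


@pytest.fixture()
def trace_factory():
    return make_trace


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fewer rows than folds.*")
        yield
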