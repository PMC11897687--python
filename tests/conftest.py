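"""Shared fixtures: hand-built tracking tables and simulated trials."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from beamwalk import (
    ALL_KEYPOINTS,
    BeamGeometry,
    SimParams,
    TrackingTable,
    clean_track,
    detect_beam_type,
    generate_trial,
    locate_region,
)


def make_track(
    overrides: dict | None = None,
    frames: int = 10,
    fps: float = 120.0,
    video_id: str = "toy",
) -> TrackingTable:
    """A minimal tracking table: every keypoint parked at (100, 300) with
    likelihood 1 unless overridden with (x, y[, likelihood]) arrays or
    scalars."""
    overrides = overrides or {}
    cols = {}
    for part in ALL_KEYPOINTS:
        x = np.full(frames, 100.0)
        y = np.full(frames, 300.0)
        lik = np.ones(frames)
        if part in overrides:
            spec = overrides[part]
            x = np.broadcast_to(np.asarray(spec[0], dtype=float), (frames,)).copy()
            y = np.broadcast_to(np.asarray(spec[1], dtype=float), (frames,)).copy()
            if len(spec) > 2:
                lik = np.broadcast_to(np.asarray(spec[2], dtype=float), (frames,)).copy()
        cols[(part, "x")] = x
        cols[(part, "y")] = y
        cols[(part, "likelihood")] = lik
    data = pd.DataFrame(cols)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodyparts", "coords"])
    return TrackingTable(data=data, fps=fps, video_id=video_id)


def similarity_transform(
    track: TrackingTable, scale: float, angle: float = 0.0, tx: float = 0.0, ty: float = 0.0
) -> TrackingTable:
    """Apply a global rotation+scale+translation to every keypoint."""
    c, s = np.cos(angle), np.sin(angle)
    data = track.data.copy()
    for part in track.keypoints:
        x = data[(part, "x")].to_numpy()
        y = data[(part, "y")].to_numpy()
        data[(part, "x")] = scale * (c * x - s * y) + tx
        data[(part, "y")] = scale * (s * x + c * y) + ty
    return TrackingTable(data=data, fps=track.fps, video_id=track.video_id,
                         mouse_id=track.mouse_id)


@pytest.fixture(scope="session")
def rigid_params() -> SimParams:
    """A perfectly rigid, noiseless crossing (no gait, no slips)."""
    return SimParams(gait={}, noise_sd=0.0, dropout_rate=0.0, n_slips=0)


@pytest.fixture(scope="session")
def rigid_trial(rigid_params):
    return generate_trial(rigid_params, seed=0, video_id="rigid", mouse_id="m0")


@pytest.fixture(scope="session")
def noisy_trial():
    """A default-condition trial with three planted slips, cleaned and
    calibrated."""
    params = SimParams(n_slips=3)
    track, truth = generate_trial(params, seed=11, video_id="noisy", mouse_id="m1")
    clean = clean_track(track)
    geom = locate_region(clean, detect_beam_type(clean))
    return clean, truth, geom, params


#: Scaled nested-CV configuration used throughout the tests (small forests,
#: aggressive elimination, single-point grid).
FAST_CV = dict(
    rfe_step=0.5,
    hyper_grid={"n_estimators": [8]},
    rfe_params={"n_estimators": 8},
)
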