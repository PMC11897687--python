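"""Classical beam-walk endpoints and their evaluation against human raters.

Two endpoints are automated from keypoint trajectories:

* **time to cross** -- the duration for the nose to enter and exit the
  central 80-cm region of the beam;
* **number of foot slips** -- downward excursions of the hindpaw beyond a
  spatial threshold below the beam surface (default 18 px, ~9 mm at
  2 px/mm), with excursions closer than a temporal merge gap (default 32
  frames, ~250 ms at 120 fps) amalgamated into a single event.

The evaluation harness matches detected events against human-annotated
slip frames (greedy one-to-one within a frame tolerance), sweeps the
spatial threshold for a precision/recall curve, and scores per-video
count agreement with Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .io_keypoints import BeamGeometry, BeamwalkError, TrackingTable, height_above_beam


class CrossingError(BeamwalkError):
    """The nose never entered, or never exited, the central region."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the threshold-based slip detector.

    ``spatial_threshold`` is the depth below the beam surface (pixels) a
    hindpaw excursion must reach; ``merge_gap`` the frame gap under which
    consecutive excursions merge; ``match_tolerance`` the +/- frame window
    for matching detections to human annotations.
    """

    spatial_threshold: float = 18.0
    merge_gap: int = 32
    match_tolerance: int = 30

    def __post_init__(self) -> None:
        if self.spatial_threshold <= 0 or self.merge_gap <= 0 or self.match_tolerance <= 0:
            raise ValueError("all detection parameters must be > 0")


@dataclass(frozen=True)
class SlipEvent:
    onset_frame: int
    offset_frame: int          # inclusive
    nadir_frame: int
    depth: float               # pixels below the surface, positive

    def __post_init__(self) -> None:
        if not self.onset_frame <= self.nadir_frame <= self.offset_frame:
            raise ValueError("slip event must satisfy onset <= nadir <= offset")


@dataclass(frozen=True)
class EndpointResult:
    video_id: str
    time_to_cross: float       # seconds
    direction: str             # "left_to_right" / "right_to_left"
    slips: tuple[SlipEvent, ...]
    entry_frame: int
    exit_frame: int

    @property
    def n_slips(self) -> int:
        return len(self.slips)


@dataclass(frozen=True)
class MatchResult:
    TP: int
    FP: int
    FN: int
    undefined_precision: bool = False
    undefined_recall: bool = False

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


# --------------------------------------------------------------------------
# Time to cross
# --------------------------------------------------------------------------


def crossing_window(track: TrackingTable, geom: BeamGeometry) -> tuple[int, int, str]:
    """Nose-based (entry_frame, exit_frame, direction) for one trial.

    Entry is the first frame with the nose x inside ``[x_left, x_right)``;
    exit is the first later frame with the nose beyond the boundary
    opposite the entry side.  Re-entries between the two are ignored.
    """
    x = track.x("nose")
    inside = np.asarray(geom.in_region(x))
    if not inside.any():
        raise CrossingError(f"{track.video_id}: nose never entered the central region")
    entry = int(np.argmax(inside))
    before = x[entry - 1] if entry > 0 else x[entry]
    # entry side: which boundary was the nose nearer/behind just before entry
    if before <= (geom.x_left + geom.x_right) / 2:
        direction = "left_to_right"
        past_far = x[entry:] >= geom.x_right
    else:
        direction = "right_to_left"
        past_far = x[entry:] < geom.x_left
    if not past_far.any():
        raise CrossingError(f"{track.video_id}: nose never exited past the far boundary")
    exit_ = entry + int(np.argmax(past_far))
    return entry, exit_, direction


def time_to_cross(track: TrackingTable, geom: BeamGeometry) -> tuple[float, str]:
    """Seconds for the nose to transit the central region, plus direction."""
    entry, exit_, direction = crossing_window(track, geom)
    return (exit_ - entry) / track.fps, direction


# --------------------------------------------------------------------------
# Foot-slip detection
# --------------------------------------------------------------------------


def _merge_runs(
    runs: list[tuple[int, int]], merge_gap: int
) -> list[tuple[int, int]]:
    """Amalgamate runs whose inter-run gap (frames strictly between them)
    is below ``merge_gap``."""
    if not runs:
        return []
    merged = [runs[0]]
    for onset, offset in runs[1:]:
        prev_onset, prev_offset = merged[-1]
        if onset - prev_offset - 1 < merge_gap:
            merged[-1] = (prev_onset, max(prev_offset, offset))
        else:
            merged.append((onset, offset))
    return merged


def detect_foot_slips(
    height: np.ndarray,
    params: DetectionParams = DetectionParams(),
    frame_offset: int = 0,
) -> list[SlipEvent]:
    """Threshold-based slip events on a surface-relative height series.

    Raw events are maximal runs of frames with ``height < -spatial_threshold``
    (hindpaw deeper than the threshold below the surface); runs separated
    by fewer than ``merge_gap`` intervening frames are merged into one
    event whose nadir is the deepest frame.  ``frame_offset`` shifts the
    reported frame indices when ``height`` is a slice of a longer trial.
    """
    height = np.asarray(height, dtype=float)
    if height.size == 0:
        return []
    below = height < -params.spatial_threshold
    if not below.any():
        return []
    # maximal runs of consecutive True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    runs = [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]
    merged = _merge_runs(runs, params.merge_gap)
    events = []
    for onset, offset in merged:
        seg = height[onset : offset + 1]
        nadir = onset + int(np.argmin(seg))
        events.append(
            SlipEvent(
                onset_frame=onset + frame_offset,
                offset_frame=offset + frame_offset,
                nadir_frame=nadir + frame_offset,
                depth=float(-seg.min()),
            )
        )
    return events


def detect_trial_slips(
    track: TrackingTable,
    geom: BeamGeometry,
    params: DetectionParams = DetectionParams(),
) -> list[SlipEvent]:
    """Slip events for one trial, restricted to the central region.

    The hindpaw height series is evaluated only on the contiguous frame
    span where the hindpaw x lies inside the region, mirroring the 80-cm
    analysis window.
    """
    inside = np.asarray(geom.in_region(track.x("hindpaw")))
    if not inside.any():
        return []
    first, last = int(np.argmax(inside)), int(len(inside) - 1 - np.argmax(inside[::-1]))
    height = height_above_beam(track, geom, "hindpaw")[first : last + 1]
    return detect_foot_slips(height, params, frame_offset=first)


def compute_endpoints(
    track: TrackingTable,
    geom: BeamGeometry,
    params: DetectionParams = DetectionParams(),
) -> EndpointResult:
    """Both classical endpoints for one trial."""
    entry, exit_, direction = crossing_window(track, geom)
    slips = detect_trial_slips(track, geom, params)
    return EndpointResult(
        video_id=track.video_id,
        time_to_cross=(exit_ - entry) / track.fps,
        direction=direction,
        slips=tuple(slips),
        entry_frame=entry,
        exit_frame=exit_,
    )


# --------------------------------------------------------------------------
# Evaluation against human annotations
# --------------------------------------------------------------------------


def match_events(
    detected: Sequence[int],
    annotated: Sequence[int],
    tolerance: int,
) -> MatchResult:
    """Greedy one-to-one matching of detected vs annotated slip frames.

    Detections are visited in increasing frame order; each matches the
    earliest still-unmatched annotation within ``+/- tolerance`` frames.
    Matched pairs are TP, leftover annotations FN, leftover detections FP.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    det = sorted(int(d) for d in detected)
    ann = sorted(int(a) for a in annotated)
    used = [False] * len(ann)
    tp = 0
    for d in det:
        for j, a in enumerate(ann):
            if not used[j] and abs(d - a) <= tolerance:
                used[j] = True
                tp += 1
                break
    fp = len(det) - tp
    fn = len(ann) - tp
    return MatchResult(
        TP=tp,
        FP=fp,
        FN=fn,
        undefined_precision=(tp + fp == 0),
        undefined_recall=(tp + fn == 0),
    )


def threshold_sweep(
    trials: Sequence[tuple[np.ndarray, Sequence[int]]],
    thresholds: Sequence[float],
    params: DetectionParams = DetectionParams(),
) -> list[tuple[float, MatchResult]]:
    """Pooled precision/recall across trials for each spatial threshold.

    Each trial is a (height series, annotated slip frames) pair; TP/FP/FN
    are pooled over trials per threshold.  Annotations are fixed, so
    TP + FN is constant across thresholds.
    """
    if not trials:
        raise ValueError("threshold_sweep needs at least one trial")
    if not len(thresholds):
        raise ValueError("threshold list must not be empty")
    out = []
    for thr in thresholds:
        p = DetectionParams(
            spatial_threshold=float(thr),
            merge_gap=params.merge_gap,
            match_tolerance=params.match_tolerance,
        )
        tp = fp = fn = 0
        for height, annotated in trials:
            events = detect_foot_slips(np.asarray(height, dtype=float), p)
            m = match_events([e.onset_frame for e in events], annotated, p.match_tolerance)
            tp, fp, fn = tp + m.TP, fp + m.FP, fn + m.FN
        out.append(
            (float(thr), MatchResult(TP=tp, FP=fp, FN=fn,
                                     undefined_precision=(tp + fp == 0),
                                     undefined_recall=(tp + fn == 0)))
        )
    return out


def kappa_per_video(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> tuple[float, bool]:
    """Cohen's kappa between two raters' per-video slip counts.

    Counts are treated as categorical labels.  Returns ``(kappa, flag)``
    where the flag marks the degenerate case of chance agreement p_e = 1
    (both raters constant and equal), reported as kappa 1.0 by convention.
    """
    a = [int(v) for v in counts_a]
    b = [int(v) for v in counts_b]
    if len(a) != len(b):
        raise ValueError(f"count vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("need at least one video")
    if a == b and len(set(a)) == 1:
        return 1.0, True
    kappa = float(cohen_kappa_score(a, b))
    if math.isnan(kappa):  # identical constant raters in sklearn
        return 1.0, True
    return kappa, False
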