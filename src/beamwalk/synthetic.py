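"""Seeded simulators of beam-walk data with full ground truth.

Two generators cover the two testing levels of the pipeline:

* :func:`generate_trial` / :func:`generate_experiment` emit DLC-dialect
  keypoint trajectories of a mouse traversing a 1-m beam -- a monotone
  nose progression through the marked central 80-cm region, a rigid
  posture template with gait-oscillating limbs, planted hindpaw slips of
  controllable depth/duration/spacing, group-level posture offsets and
  variance effects, Gaussian tracking jitter and likelihood dropouts.
  Every planted quantity (slip intervals, entry/exit frames, perturbed
  template parts) is returned as :class:`GroundTruth`.

* :func:`make_feature_experiment` draws per-trial feature matrices
  directly (per-mouse random intercepts plus trial noise, with a mean
  shift on a known informative subset), which is the right granularity
  for calibrating the nested cross-validation.

Defaults are sized to the study rig the thresholds were derived on:
120 fps and 2 px/mm, so the 18-px slip threshold corresponds to 9 mm.
All randomness flows from one seed through ``numpy`` SeedSequence
spawning, so identical seeds give bit-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ExperimentDataset
from .io_keypoints import (
    ALL_KEYPOINTS,
    BODY_PARTS,
    BeamType,
    TrackingTable,
    VideoMetadata,
    write_metadata,
    write_tracking,
)

# --------------------------------------------------------------------------
# Posture template
# --------------------------------------------------------------------------

#: (mm behind the nose, mm above the beam surface) for each body part of a
#: mouse in steady beam-walking posture; body length ~115 mm nose-to-tail,
#: heights ~1-40 mm above the surface.
DEFAULT_TEMPLATE_MM: dict[str, tuple[float, float]] = {
    "nose": (0.0, 15.0),
    "eye": (8.0, 25.0),
    "forepaw": (28.0, 2.0),
    "elbow": (30.0, 20.0),
    "shoulder": (25.0, 35.0),
    "hindpaw": (70.0, 1.0),
    "ankle": (72.0, 8.0),
    "knee": (68.0, 18.0),
    "hip": (62.0, 32.0),
    "iliac_crest": (55.0, 38.0),
    "tail_base": (75.0, 30.0),
    "tail_center": (95.0, 25.0),
    "tail_tip": (115.0, 20.0),
}

#: Vertical gait oscillation per limb keypoint: (amplitude px, period
#: frames, phase rad) at 120 fps (~4 Hz stride).
DEFAULT_GAIT: dict[str, tuple[float, float, float]] = {
    "forepaw": (4.0, 30.0, 0.0),
    "elbow": (2.0, 30.0, 0.3),
    "hindpaw": (4.0, 30.0, np.pi),
    "ankle": (3.0, 30.0, np.pi + 0.3),
    "knee": (2.0, 30.0, np.pi + 0.6),
    "tail_tip": (2.0, 45.0, 1.0),
}


@dataclass(frozen=True)
class GroupEffect:
    """Group-level perturbation of the posture template.

    ``offsets_mm`` shifts named parts by (dx back, dy up) millimetres;
    ``var_mult`` multiplies the vertical oscillation+jitter variance of
    named parts; ``slip_rate_shift`` adds to the expected slip count.
    """

    offsets_mm: dict = field(default_factory=dict)
    var_mult: dict = field(default_factory=dict)
    slip_rate_shift: float = 0.0

    @property
    def informative_parts(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.offsets_mm) | set(self.var_mult)))


@dataclass(frozen=True)
class SimParams:
    """Full parameterisation of one simulated trial."""

    fps: float = 120.0
    x_left: float = 160.0          # region bounds in px; width 1600 px = 80 cm
    x_right: float = 1760.0
    surface_intercept: float = 400.0
    surface_slope: float = 0.0
    beam_type: BeamType = BeamType.BEAM1_16SQ
    direction: str = "left_to_right"
    crossing_frames: int = 480     # nose frames inside the region (4 s at 120 fps)
    lead_frames: int = 60
    trail_frames: int = 100
    template_mm: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_MM)
    )
    gait: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GAIT)
    )
    body_scale: float = 1.0
    slips: tuple[tuple[int, int, float], ...] | None = None  # (onset, duration, depth px)
    n_slips: int = 0               # auto-placed when ``slips`` is None
    slip_depth: float = 30.0
    slip_duration: int = 8
    noise_sd: float = 2.0
    dropout_rate: float = 0.02
    dropout_likelihood: float = 0.1
    likelihood_good: float = 0.99
    group_effect: GroupEffect = field(default_factory=GroupEffect)

    @property
    def px_per_mm(self) -> float:
        return (self.x_right - self.x_left) / 800.0

    @property
    def total_frames(self) -> int:
        return self.lead_frames + self.crossing_frames + self.trail_frames


@dataclass(frozen=True)
class GroundTruth:
    video_id: str
    mouse_id: str
    group: str
    entry_frame: int
    exit_frame: int
    direction: str
    slip_intervals: tuple[tuple[int, int], ...]   # inclusive frame spans
    informative_parts: tuple[str, ...]

    @property
    def crossing_seconds(self) -> float:
        raise AttributeError("use (exit_frame - entry_frame) / fps of the trial")


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------


def _surface_y(params: SimParams, x: np.ndarray) -> np.ndarray:
    return params.surface_intercept + params.surface_slope * x


def _auto_slips(params: SimParams) -> tuple[tuple[int, int, float], ...]:
    """Evenly place ``n_slips`` hindpaw dips inside the span where the
    hindpaw is within the central region."""
    if params.n_slips <= 0:
        return ()
    dx_px = params.template_mm["hindpaw"][0] * params.px_per_mm * params.body_scale
    speed = (params.x_right - params.x_left) / params.crossing_frames
    delay = int(np.ceil(dx_px / speed))
    lo = params.lead_frames + delay + 10
    hi = params.lead_frames + params.crossing_frames + delay - 10 - params.slip_duration
    if hi <= lo:
        raise ValueError("crossing too short to place the requested slips")
    onsets = np.linspace(lo, hi, params.n_slips).round().astype(int)
    if params.n_slips > 1 and np.diff(onsets).min() <= params.slip_duration + 32:
        raise ValueError(
            f"cannot place {params.n_slips} slips with spacing above the merge gap"
        )
    return tuple((int(o), params.slip_duration, params.slip_depth) for o in onsets)


def generate_trial(
    params: SimParams,
    seed: int = 0,
    video_id: str = "sim000",
    mouse_id: str = "m000",
    group: str = "",
) -> tuple[TrackingTable, GroundTruth]:
    """One simulated beam-walk trial with ground truth.

    The nose advances linearly so that it spends exactly
    ``crossing_frames`` frames inside the half-open central region; body
    parts follow the (possibly group-shifted) posture template with gait
    oscillation and Gaussian jitter; the hindpaw is forced
    ``slip_depth`` px below the surface during each planted slip.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    n = params.total_frames
    t = np.arange(n)
    width = params.x_right - params.x_left
    frac = (t - params.lead_frames) / params.crossing_frames
    if params.direction == "left_to_right":
        nose_x = params.x_left + width * frac
        entry = params.lead_frames
        exit_ = params.lead_frames + params.crossing_frames
        sign = 1.0
    elif params.direction == "right_to_left":
        nose_x = params.x_right - width * frac
        entry = params.lead_frames + 1       # x_right itself is outside [l, r)
        exit_ = entry + params.crossing_frames
        sign = -1.0
    else:
        raise ValueError(f"unknown direction {params.direction!r}")

    slips = params.slips if params.slips is not None else _auto_slips(params)
    for onset, duration, depth in slips:
        if onset < 0 or onset + duration > n:
            raise ValueError(f"slip at frame {onset} falls outside the trial")

    eff = params.group_effect
    ppm = params.px_per_mm
    columns: dict[tuple[str, str], np.ndarray] = {}

    for part in BODY_PARTS:
        dx_mm, dy_mm = params.template_mm[part]
        off_dx, off_dy = eff.offsets_mm.get(part, (0.0, 0.0))
        dx_px = (dx_mm + off_dx) * ppm * params.body_scale
        dy_px = (dy_mm + off_dy) * ppm * params.body_scale
        vmult = np.sqrt(eff.var_mult.get(part, 1.0))
        x = nose_x - sign * dx_px
        y = _surface_y(params, x) - dy_px
        if part in params.gait:
            amp, period, phase = params.gait[part]
            y = y + vmult * amp * np.sin(2 * np.pi * t / period + phase)
        if params.noise_sd > 0:
            x = x + rng.normal(0.0, params.noise_sd, n) * (0.0 if part == "nose" else 1.0)
            y = y + rng.normal(0.0, params.noise_sd * vmult, n)
        if part == "hindpaw":
            for onset, duration, depth in slips:
                sl = slice(onset, onset + duration)
                y[sl] = _surface_y(params, x[sl]) + depth
                if params.noise_sd > 0:
                    y[sl] = y[sl] + rng.normal(0.0, params.noise_sd, duration)
        lik = np.full(n, params.likelihood_good)
        if params.dropout_rate > 0:
            drop = rng.random(n) < params.dropout_rate
            lik[drop] = params.dropout_likelihood
            x = np.where(drop, x + rng.normal(0.0, 40.0, n), x)
            y = np.where(drop, y + rng.normal(0.0, 40.0, n), y)
        columns[(part, "x")] = x
        columns[(part, "y")] = y
        columns[(part, "likelihood")] = lik

    marker_sd = min(params.noise_sd, 0.5)
    dot_y = params.surface_intercept - 10.0

    def marker(x0: float, y0: float, good: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if good:
            jit = rng.normal(0.0, marker_sd, (2, n)) if marker_sd > 0 else np.zeros((2, n))
            return x0 + jit[0], y0 + jit[1], np.full(n, params.likelihood_good)
        # an absent marker: the network guesses scattered positions
        return (
            x0 + rng.normal(0.0, 200.0, n),
            y0 + rng.normal(0.0, 100.0, n),
            np.full(n, 0.03),
        )

    dot_right_ok = params.beam_type is BeamType.BEAM1_16SQ
    dot_left_ok = params.beam_type is BeamType.BEAM3_9SQ
    specs = {
        "line_left": marker(params.x_left, float(_surface_y(params, np.array(params.x_left))), True),
        "line_right": marker(params.x_right, float(_surface_y(params, np.array(params.x_right))), True),
        "dot_left": marker(params.x_left - 40.0, dot_y, dot_left_ok),
        "dot_right": marker(params.x_right + 40.0, dot_y, dot_right_ok),
        "aux": marker((params.x_left + params.x_right) / 2, dot_y, True),
    }
    for name, (mx, my, ml) in specs.items():
        columns[(name, "x")] = mx
        columns[(name, "y")] = my
        columns[(name, "likelihood")] = ml

    data = pd.DataFrame(
        {key: columns[key] for key in ((p, c) for p in ALL_KEYPOINTS for c in ("x", "y", "likelihood"))}
    )
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodyparts", "coords"])
    track = TrackingTable(data=data, fps=params.fps, video_id=video_id, mouse_id=mouse_id)
    truth = GroundTruth(
        video_id=video_id,
        mouse_id=mouse_id,
        group=group,
        entry_frame=int(entry),
        exit_frame=int(exit_),
        direction=params.direction,
        slip_intervals=tuple((int(o), int(o + d - 1)) for o, d, _ in slips),
        informative_parts=eff.informative_parts,
    )
    return track, truth


# --------------------------------------------------------------------------
# Experiment generation
# --------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    tracks: list[TrackingTable]
    truths: list[GroundTruth]
    metadata: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        """Emit per-trial DLC CSVs, meta.csv and ground_truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for track in self.tracks:
            write_tracking(track, outdir / f"{track.video_id}.csv")
        write_metadata(self.metadata, outdir / "meta.csv")
        payload = [
            {
                "video_id": g.video_id,
                "mouse_id": g.mouse_id,
                "group": g.group,
                "entry_frame": g.entry_frame,
                "exit_frame": g.exit_frame,
                "direction": g.direction,
                "slip_intervals": [list(iv) for iv in g.slip_intervals],
                "informative_parts": list(g.informative_parts),
            }
            for g in self.truths
        ]
        (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
        return outdir


def generate_experiment(
    n_per_group: int = 8,
    group_effects: Mapping[str, GroupEffect] | None = None,
    trials_per_mouse: int = 2,
    beams: Sequence[BeamType] = (BeamType.BEAM1_16SQ,),
    base_params: SimParams = SimParams(),
    slip_rate: float = 1.5,
    seed: int = 0,
) -> SimulatedExperiment:
    """A full multi-mouse experiment with per-mouse random effects.

    Mice draw log-normal body-size and speed multipliers around the group
    template (positive scales, mild skew) plus a baseline posture offset;
    weight is generated from the scaled elbow-shoulder template length
    (the reference dimension), mirroring its strong correlation with body
    weight.  Each mouse crosses each beam ``trials_per_mouse`` times;
    slip counts per trial are Poisson around ``slip_rate``.
    """
    if group_effects is None:
        group_effects = {"WT": GroupEffect(), "KO": GroupEffect()}
    if n_per_group < 2:
        raise ValueError("need >= 2 mice per group")
    root = np.random.SeedSequence([seed & 0x7FFFFFFF])
    tracks: list[TrackingTable] = []
    truths: list[GroundTruth] = []
    meta_rows: list[dict] = []
    mouse_counter = 0
    for g_i, (group, effect) in enumerate(group_effects.items()):
        for m_i in range(n_per_group):
            mouse_id = f"m{mouse_counter:03d}"
            m_ss = np.random.SeedSequence([seed & 0x7FFFFFFF, g_i, m_i])
            m_rng = np.random.default_rng(m_ss)
            body_scale = float(np.exp(m_rng.normal(0.0, 0.05)))
            speed_mult = float(np.exp(m_rng.normal(0.0, 0.08)))
            posture_dy = float(m_rng.normal(0.0, 1.0))   # mm, whole-body height
            sex = "F" if m_rng.random() < 0.5 else "M"
            # reference dimension of this mouse's template, in mm
            exm, eym = base_params.template_mm["elbow"]
            sxm, sym = base_params.template_mm["shoulder"]
            ref_mm = float(np.hypot(exm - sxm, eym - sym)) * body_scale
            weight = float(1.4 * ref_mm + m_rng.normal(0.0, 0.5))
            template = {
                p: (dx, dy + posture_dy) for p, (dx, dy) in base_params.template_mm.items()
            }
            for b_i, beam in enumerate(beams):
                for trial in range(1, trials_per_mouse + 1):
                    t_rng = np.random.default_rng(
                        np.random.SeedSequence([seed & 0x7FFFFFFF, g_i, m_i, b_i, trial])
                    )
                    lam = max(0.0, slip_rate + effect.slip_rate_shift)
                    n_slips = int(t_rng.poisson(lam))
                    crossing = max(120, int(round(base_params.crossing_frames / speed_mult
                                                  * float(np.exp(t_rng.normal(0.0, 0.05))))))
                    video_id = f"{mouse_id}_{beam.name}_t{trial}"
                    params = replace(
                        base_params,
                        beam_type=beam,
                        crossing_frames=crossing,
                        body_scale=body_scale,
                        template_mm=template,
                        n_slips=n_slips,
                        slips=None,
                        group_effect=effect,
                    )
                    trial_seed = int(t_rng.integers(2**31))
                    track, truth = generate_trial(
                        params, seed=trial_seed, video_id=video_id,
                        mouse_id=mouse_id, group=group,
                    )
                    tracks.append(track)
                    truths.append(truth)
                    meta_rows.append({
                        "video_id": video_id, "mouse_id": mouse_id, "sex": sex,
                        "weight": round(weight, 2), "group": group,
                        "beam": beam.name, "trial": trial, "fps": base_params.fps,
                        "cohort": "",
                    })
            mouse_counter += 1
    return SimulatedExperiment(tracks=tracks, truths=truths,
                               metadata=pd.DataFrame(meta_rows))


# --------------------------------------------------------------------------
# Feature-level experiment generator
# --------------------------------------------------------------------------


def make_feature_experiment(
    n_mice_per_group: int = 8,
    n_trials: int = 2,
    n_features: int = 96,
    n_informative: int = 10,
    effect_size: float = 0.0,
    mouse_sd: float = 0.5,
    groups: tuple[str, str] = ("WT", "KO"),
    seed: int = 0,
    design_seed: int = 0,
) -> tuple[ExperimentDataset, list[str]]:
    """Draw a trials x features matrix with a planted group effect.

    Every feature is a per-mouse random intercept (SD ``mouse_sd``) plus
    unit trial noise; the second group's mean is shifted by
    ``effect_size`` total SDs on ``n_informative`` features chosen at
    random.  ``seed`` drives the sampling noise while ``design_seed``
    fixes *which* features carry the effect, so independent cohorts of
    the same design (same ``design_seed``, different ``seed``) plant the
    effect on the same features.  Returns the dataset and the informative
    feature names.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 77]))
    design_rng = np.random.default_rng(
        np.random.SeedSequence([design_seed & 0x7FFFFFFF, 78])
    )
    names = [f"f{i:03d}" for i in range(n_features)]
    informative = sorted(design_rng.choice(n_features, size=n_informative, replace=False))
    total_sd = float(np.sqrt(1.0 + mouse_sd**2))
    shift = effect_size * total_sd

    rows, y, mice = [], [], []
    for g_i, group in enumerate(groups):
        for m_i in range(n_mice_per_group):
            mouse = f"{group}_m{m_i:02d}"
            intercept = rng.normal(0.0, mouse_sd, n_features)
            for _ in range(n_trials):
                x = intercept + rng.normal(0.0, 1.0, n_features)
                if g_i == 1:
                    x[informative] += shift
                rows.append(x)
                y.append(group)
                mice.append(mouse)
    X = pd.DataFrame(np.array(rows), columns=names)
    dataset = ExperimentDataset(X=X, y=np.array(y), mouse_ids=np.array(mice))
    return dataset, [names[i] for i in informative]
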