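"""Nose-anchored average-skeleton summaries and rendering.

Each animal's posture on the beam is condensed into a standardized
"average skeleton": the nose sits at x = 0, every other body part is
placed at minus its mean euclidean distance from the nose divided by the
reference dimension (so parts trail a rightward-walking nose), the
vertical position is the mean normalized height above the beam surface,
and a vertical bar shows the variance of that height -- the axis along
which balance disturbances express themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .features import reference_length, region_frame_mask
from .io_keypoints import BODY_PARTS, BeamGeometry, TrackingTable, height_above_beam

#: Polyline topology used when rendering (head chain, trunk/hindlimb chain,
#: tail chain) -- a drawing convention, not an analysis quantity.
SKELETON_CHAINS: tuple[tuple[str, ...], ...] = (
    ("nose", "eye", "shoulder", "elbow", "forepaw"),
    ("shoulder", "iliac_crest", "hip", "knee", "ankle", "hindpaw"),
    ("hip", "tail_base", "tail_center", "tail_tip"),
)


@dataclass
class SkeletonSummary:
    """Per-part display coordinates of one animal's (or group's) average
    skeleton.  All quantities are unitless (normalized by the reference
    dimension)."""

    x_display: dict            # part -> x (nose = 0, others negative)
    y_display: dict            # part -> mean normalized height above beam
    y_var: dict                # part -> variance of normalized height
    n_animals: int = 1

    def __post_init__(self) -> None:
        for part in BODY_PARTS:
            if part not in self.x_display:
                raise ValueError(f"skeleton summary missing body part {part!r}")


def skeleton_per_animal(
    tracks: Sequence[TrackingTable],
    geoms: Sequence[BeamGeometry] | BeamGeometry,
) -> SkeletonSummary:
    """Average skeleton of one animal from its trials (frames pooled).

    Per part: x = -(mean nose-part distance)/ref, y = mean height/ref,
    y_var = variance of height/ref.  The reference dimension is the mean
    elbow-shoulder distance, averaged over the pooled trials.
    """
    if not tracks:
        raise ValueError("need at least one trial")
    if isinstance(geoms, BeamGeometry):
        geoms = [geoms] * len(tracks)
    nose_dist: dict[str, list[np.ndarray]] = {p: [] for p in BODY_PARTS}
    heights: dict[str, list[np.ndarray]] = {p: [] for p in BODY_PARTS}
    refs = []
    for track, geom in zip(tracks, geoms):
        mask = region_frame_mask(track, geom)
        ref = reference_length(track, geom, mask)
        refs.append(ref)
        nose = track.xy("nose")
        for part in BODY_PARTS:
            d = np.linalg.norm(track.xy(part) - nose, axis=1)[mask]
            nose_dist[part].append(d / ref)
            heights[part].append(height_above_beam(track, geom, part)[mask] / ref)
    x_display = {}
    y_display = {}
    y_var = {}
    for part in BODY_PARTS:
        d = np.concatenate(nose_dist[part])
        h = np.concatenate(heights[part])
        x_display[part] = 0.0 if part == "nose" else -float(d.mean())
        y_display[part] = float(h.mean())
        y_var[part] = float(h.var(ddof=1)) if h.size > 1 else 0.0
    return SkeletonSummary(x_display=x_display, y_display=y_display, y_var=y_var,
                           n_animals=1)


def skeleton_group_mean(summaries: Sequence[SkeletonSummary]) -> SkeletonSummary:
    """Unweighted mean across animals; variance bars average the
    per-animal variances."""
    if not summaries:
        raise ValueError("need at least one animal summary")
    x_display = {}
    y_display = {}
    y_var = {}
    for part in BODY_PARTS:
        x_display[part] = float(np.mean([s.x_display[part] for s in summaries]))
        y_display[part] = float(np.mean([s.y_display[part] for s in summaries]))
        y_var[part] = float(np.mean([s.y_var[part] for s in summaries]))
    return SkeletonSummary(x_display=x_display, y_display=y_display, y_var=y_var,
                           n_animals=sum(s.n_animals for s in summaries))


def render_skeletons(
    group_summaries: Mapping[str, SkeletonSummary],
    path: str | Path,
    title: str = "Average skeleton",
    colors: Sequence[str] | None = None,
) -> Path:
    """Render overlaid group skeletons with +/- sqrt(variance) bars.

    Output is deterministic for fixed input (no timestamps; fixed SVG
    hash salt), so identical calls produce byte-identical files.
    """
    if not group_summaries:
        raise ValueError("no group summaries to render")
    path = Path(path)
    with matplotlib.rc_context({"svg.hashsalt": "beamwalk"}):
        fig, ax = plt.subplots(figsize=(7, 4))
        palette = colors or [f"C{i}" for i in range(10)]
        for c_i, (group, summ) in enumerate(group_summaries.items()):
            color = palette[c_i % len(palette)]
            xs = {p: summ.x_display[p] for p in BODY_PARTS}
            ys = {p: summ.y_display[p] for p in BODY_PARTS}
            for chain in SKELETON_CHAINS:
                ax.plot([xs[p] for p in chain], [ys[p] for p in chain],
                        "-", color=color, linewidth=1.2, zorder=2)
            ax.errorbar(
                [xs[p] for p in BODY_PARTS],
                [ys[p] for p in BODY_PARTS],
                yerr=[np.sqrt(summ.y_var[p]) for p in BODY_PARTS],
                fmt="o", color=color, markersize=4, capsize=2,
                label=f"{group} (n={summ.n_animals})", zorder=3,
            )
        ax.axhline(0.0, color="0.6", linewidth=0.8, linestyle="--", zorder=1)
        ax.set_xlabel("distance behind nose / reference")
        ax.set_ylabel("height above beam / reference")
        ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path, metadata=_deterministic_metadata(path))
        plt.close(fig)
    return path


def _deterministic_metadata(path: Path) -> dict:
    suffix = path.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    if suffix == ".pdf":
        return {"CreationDate": None}
    return {}


def skeleton_table(group_summaries: Mapping[str, SkeletonSummary]):
    """Long-format table of the rendered quantities (group, part, x, y, var)."""
    import pandas as pd

    rows = []
    for group, summ in group_summaries.items():
        for part in BODY_PARTS:
            rows.append({"group": group, "part": part,
                         "x_display": summ.x_display[part],
                         "y_display": summ.y_display[part],
                         "y_var": summ.y_var[part],
                         "n_animals": summ.n_animals})
    return pd.DataFrame(rows)
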