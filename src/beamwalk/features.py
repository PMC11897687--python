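"""Per-trial posture/balance feature engineering.

Every trial is condensed into one ordered vector governed by an explicit
manifest (:class:`FeatureRegistry`):

* all C(13,2) = 78 pairwise distances between body parts, normalized by
  the reference dimension (mean elbow-shoulder distance, chosen for its
  strong correlation with body weight), each summarised by mean / min /
  max / variance  -> 312 entries;
* the four joint angles (elbow, ankle, knee, hip), in degrees, x4
  statistics -> 16 entries;
* the height of each of the 13 body parts above the beam surface,
  normalized by the same reference, x4 statistics -> 52 entries;
* animal sex (F=0, M=1) and weight in grams -> 2 entries;
* the classical endpoints: number of foot slips and time to cross -> 2.

Total: 384 entries.  Only frames inside the nose-based crossing window
(the 80-cm analysis region) contribute to any series.  All statistics use
the sample (n-1) variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_keypoints import BODY_PARTS, BeamGeometry, BeamwalkError, TrackingTable, \
    VideoMetadata, height_above_beam
from .endpoints import EndpointResult, crossing_window


class FeatureError(BeamwalkError):
    """A feature could not be computed (degenerate geometry, non-finite)."""


STATISTICS = ("mean", "min", "max", "variance")

#: Anatomically adjacent triplets (a, vertex, b) defining each joint angle.
ANGLE_TRIPLETS: dict[str, tuple[str, str, str]] = {
    "elbow": ("shoulder", "elbow", "forepaw"),
    "ankle": ("knee", "ankle", "hindpaw"),
    "knee": ("hip", "knee", "ankle"),
    "hip": ("iliac_crest", "hip", "knee"),
}


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str              # distance | angle | height | meta | endpoint
    statistic: str             # mean | min | max | variance | none
    constituents: tuple[str, ...]


def build_registry() -> list[FeatureDef]:
    """The canonical ordered feature manifest (384 entries)."""
    defs: list[FeatureDef] = []
    for a, b in itertools.combinations(BODY_PARTS, 2):
        for stat in STATISTICS:
            defs.append(FeatureDef(f"dist_{a}_{b}_{stat}", "distance", stat, (a, b)))
    for joint in ANGLE_TRIPLETS:
        for stat in STATISTICS:
            defs.append(FeatureDef(f"angle_{joint}_{stat}", "angle", stat,
                                   ANGLE_TRIPLETS[joint]))
    for part in BODY_PARTS:
        for stat in STATISTICS:
            defs.append(FeatureDef(f"height_{part}_{stat}", "height", stat, (part,)))
    defs.append(FeatureDef("sex", "meta", "none", ()))
    defs.append(FeatureDef("weight", "meta", "none", ()))
    defs.append(FeatureDef("n_slips", "endpoint", "none", ()))
    defs.append(FeatureDef("time_to_cross", "endpoint", "none", ()))
    names = [d.name for d in defs]
    assert len(names) == len(set(names)) == 384
    return defs


def registry_names(registry: Sequence[FeatureDef] | None = None) -> list[str]:
    return [d.name for d in (registry or build_registry())]


def registry_to_manifest(registry: Sequence[FeatureDef]) -> list[dict]:
    """JSON-serialisable manifest of the registry."""
    return [
        {"name": d.name, "category": d.category, "statistic": d.statistic,
         "constituents": list(d.constituents)}
        for d in registry
    ]


@dataclass
class FeatureVector:
    video_id: str
    mouse_id: str
    group: str
    beam: str
    trial: int
    names: tuple[str, ...]
    values: np.ndarray
    reference_length: float    # pixels

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.video_id)


# --------------------------------------------------------------------------
# Series builders
# --------------------------------------------------------------------------


def region_frame_mask(track: TrackingTable, geom: BeamGeometry) -> np.ndarray:
    """Boolean mask of analysis frames: the nose crossing window
    ``entry <= t < exit``."""
    entry, exit_, _ = crossing_window(track, geom)
    mask = np.zeros(track.frames, dtype=bool)
    mask[entry:exit_] = True
    return mask


def reference_length(
    track: TrackingTable, geom: BeamGeometry, mask: np.ndarray | None = None
) -> float:
    """Mean elbow-shoulder distance (pixels) over in-region frames."""
    if mask is None:
        mask = region_frame_mask(track, geom)
    d = np.linalg.norm(track.xy("elbow") - track.xy("shoulder"), axis=1)[mask]
    if d.size == 0:
        raise FeatureError("no in-region frames for the reference length")
    ref = float(d.mean())
    if ref <= 0:
        raise FeatureError("elbow and shoulder coincide throughout; zero reference")
    return ref


def series_distance(
    track: TrackingTable,
    part_a: str,
    part_b: str,
    ref: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame euclidean distance between two parts / reference, over
    in-region frames."""
    if ref <= 0:
        raise FeatureError("reference length must be > 0")
    d = np.linalg.norm(track.xy(part_a) - track.xy(part_b), axis=1)
    if mask is not None:
        d = d[mask]
    return d / ref


def series_angle(
    track: TrackingTable, joint: str, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame interior angle (degrees, in [0, 180]) at a joint vertex.

    Frames with a zero-length limb vector are linearly interpolated from
    neighbouring frames (edge frames copy the nearest valid value).
    """
    if joint not in ANGLE_TRIPLETS:
        raise KeyError(f"unknown joint {joint!r}; expected one of {list(ANGLE_TRIPLETS)}")
    a, vertex, b = ANGLE_TRIPLETS[joint]
    v1 = track.xy(a) - track.xy(vertex)
    v2 = track.xy(b) - track.xy(vertex)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    valid = (n1 > 0) & (n2 > 0)
    angle = np.full(len(v1), np.nan)
    if valid.any():
        cosang = np.einsum("ij,ij->i", v1[valid], v2[valid]) / (n1[valid] * n2[valid])
        angle[valid] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if not valid.all():
        angle = (
            pd.Series(angle).interpolate(method="linear", limit_direction="both").to_numpy()
        )
    if np.isnan(angle).any():
        raise FeatureError(f"angle at {joint!r} undefined in every frame")
    return angle[mask] if mask is not None else angle


def summarize(series: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, min, max, sample variance) of a series of length >= 2."""
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise FeatureError(f"series too short to summarise (length {s.size})")
    return float(s.mean()), float(s.min()), float(s.max()), float(s.var(ddof=1))


# --------------------------------------------------------------------------
# Vector assembly
# --------------------------------------------------------------------------

_SEX_CODE = {"F": 0.0, "M": 1.0}


def build_feature_vector(
    track: TrackingTable,
    geom: BeamGeometry,
    meta: VideoMetadata,
    endpoints: EndpointResult,
    registry: Sequence[FeatureDef] | None = None,
) -> FeatureVector:
    """Compute every registry entry, in manifest order, for one trial."""
    if meta.video_id != track.video_id or meta.video_id != endpoints.video_id:
        raise ValueError(
            f"inconsistent inputs: track={track.video_id!r}, meta={meta.video_id!r}, "
            f"endpoints={endpoints.video_id!r}"
        )
    registry = list(registry or build_registry())
    mask = region_frame_mask(track, geom)
    ref = reference_length(track, geom, mask)

    series_cache: dict[tuple, np.ndarray] = {}

    def get_series(d: FeatureDef) -> np.ndarray:
        key = (d.category, d.constituents)
        if key not in series_cache:
            if d.category == "distance":
                series_cache[key] = series_distance(track, *d.constituents, ref, mask)
            elif d.category == "angle":
                joint = d.name.split("_")[1]
                series_cache[key] = series_angle(track, joint, mask)
            elif d.category == "height":
                series_cache[key] = height_above_beam(track, geom, d.constituents[0])[mask] / ref
            else:  # pragma: no cover
                raise FeatureError(f"no series for category {d.category}")
        return series_cache[key]

    stat_index = {s: i for i, s in enumerate(STATISTICS)}
    values = np.empty(len(registry), dtype=float)
    for i, d in enumerate(registry):
        if d.category in ("distance", "angle", "height"):
            values[i] = summarize(get_series(d))[stat_index[d.statistic]]
        elif d.name == "sex":
            values[i] = _SEX_CODE[meta.sex]
        elif d.name == "weight":
            values[i] = float(meta.weight)
        elif d.name == "n_slips":
            values[i] = float(endpoints.n_slips)
        elif d.name == "time_to_cross":
            values[i] = float(endpoints.time_to_cross)
        else:  # pragma: no cover
            raise FeatureError(f"unhandled registry entry {d.name!r}")
        if not np.isfinite(values[i]):
            raise FeatureError(f"feature {d.name!r} is non-finite")

    return FeatureVector(
        video_id=meta.video_id,
        mouse_id=meta.mouse_id,
        group=meta.group,
        beam=meta.beam,
        trial=meta.trial,
        names=tuple(d.name for d in registry),
        values=values,
        reference_length=ref,
    )


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack per-trial vectors into a trials x features DataFrame with
    identifier columns in front."""
    if not vectors:
        raise ValueError("no feature vectors given")
    rows = []
    for v in vectors:
        row = {"video_id": v.video_id, "mouse_id": v.mouse_id, "group": v.group,
               "beam": v.beam, "trial": v.trial}
        row.update(dict(zip(v.names, v.values)))
        rows.append(row)
    return pd.DataFrame(rows)
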