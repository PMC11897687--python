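"""Keypoint-table IO, beam geometry and confidence-filtered coordinates.

The universal input is a DeepLabCut-dialect CSV: three header rows
(``scorer`` / ``bodyparts`` / ``coords``) above per-frame ``x``, ``y``,
``likelihood`` triplets for 18 keypoints -- 13 mouse body parts and 5
static markers on the beam itself.  Image coordinates are used throughout
(y grows downward); every "height" quantity is converted to up-positive
as ``surface_y - y`` so that a hindpaw *below* the beam surface has a
negative height.

The 5 beam markers encode the rig: two vertical lines delimit the central
80-cm analysis region (hence the pixel scale, width / 800 mm), and the
presence/side of a small dot identifies which of the three beams was used
(16-mm square: dot right; 16-mm round: no dot; 9-mm square: dot left).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Canonical keypoint names
# --------------------------------------------------------------------------

BODY_PARTS: tuple[str, ...] = (
    "nose",
    "eye",
    "forepaw",
    "elbow",
    "shoulder",
    "hindpaw",
    "ankle",
    "knee",
    "hip",
    "iliac_crest",
    "tail_base",
    "tail_center",
    "tail_tip",
)

BEAM_MARKERS: tuple[str, ...] = (
    "line_left",
    "line_right",
    "dot_left",
    "dot_right",
    "aux",
)

ALL_KEYPOINTS: tuple[str, ...] = BODY_PARTS + BEAM_MARKERS

#: Common header spellings mapped onto canonical names.  Users can extend
#: this via the ``aliases`` argument of :func:`load_tracking`.
DEFAULT_ALIASES: dict[str, str] = {
    "Nose": "nose",
    "Eye": "eye",
    "Forepaw": "forepaw",
    "Fore_paw": "forepaw",
    "Elbow": "elbow",
    "Shoulder": "shoulder",
    "Hindpaw": "hindpaw",
    "Hind_paw": "hindpaw",
    "Ankle": "ankle",
    "Knee": "knee",
    "Hip": "hip",
    "Iliac_crest": "iliac_crest",
    "IliacCrest": "iliac_crest",
    "Tail_base": "tail_base",
    "Tail_center": "tail_center",
    "Tail_centre": "tail_center",
    "Tail_middle": "tail_center",
    "Tail_tip": "tail_tip",
    "Line_left": "line_left",
    "Line_right": "line_right",
    "Dot_left": "dot_left",
    "Dot_right": "dot_right",
    "Aux": "aux",
}

#: Default likelihood cut-off for confidence gating and marker detection.
DEFAULT_LIKELIHOOD_FLOOR: float = 0.6

#: Physical width of the central analysis region in mm (80 cm).
REGION_WIDTH_MM: float = 800.0


class BeamwalkError(Exception):
    """Base class for all package errors."""


class FormatError(BeamwalkError):
    """Malformed or incomplete keypoint / metadata file."""


class GeometryError(BeamwalkError):
    """Beam geometry cannot be derived (degenerate markers, ambiguity)."""


class BeamType(enum.Enum):
    BEAM1_16SQ = "BEAM1_16SQ"   # 16-mm square, dot on the right
    BEAM2_16RD = "BEAM2_16RD"   # 16-mm round, no dot
    BEAM3_9SQ = "BEAM3_9SQ"     # 9-mm square, dot on the left


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class TrackingTable:
    """Per-frame (x, y, likelihood) for the 18 keypoints of one video.

    ``data`` holds a frame-indexed DataFrame with a two-level column index
    ``(keypoint, coord)`` where ``coord`` is ``x`` / ``y`` / ``likelihood``.
    Frames are 0-based and follow file row order.
    """

    data: pd.DataFrame
    fps: float
    video_id: str = ""
    mouse_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if len(self.data) < 2:
            raise FormatError("a tracking table needs at least 2 frames")

    @property
    def frames(self) -> int:
        return len(self.data)

    @property
    def keypoints(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def x(self, part: str) -> np.ndarray:
        self._check(part)
        return self.data[(part, "x")].to_numpy(dtype=float)

    def y(self, part: str) -> np.ndarray:
        self._check(part)
        return self.data[(part, "y")].to_numpy(dtype=float)

    def likelihood(self, part: str) -> np.ndarray:
        self._check(part)
        return self.data[(part, "likelihood")].to_numpy(dtype=float)

    def xy(self, part: str) -> np.ndarray:
        """(frames, 2) array of x,y for one keypoint."""
        self._check(part)
        return np.column_stack([self.x(part), self.y(part)])

    def _check(self, part: str) -> None:
        if part not in self.data.columns.get_level_values(0):
            raise KeyError(f"unknown keypoint {part!r}")


@dataclass(frozen=True)
class BeamGeometry:
    """Beam surface line, central-region bounds and pixel scale.

    ``surface_y(x) = intercept + slope * x`` in image coordinates; the
    central region is the half-open pixel interval ``[x_left, x_right)``.
    """

    x_left: float
    x_right: float
    surface_intercept: float
    surface_slope: float = 0.0
    beam_type: BeamType | None = None

    def __post_init__(self) -> None:
        if not self.x_left < self.x_right:
            raise GeometryError(
                f"region width must be positive, got [{self.x_left}, {self.x_right})"
            )

    @property
    def px_per_mm(self) -> float:
        return (self.x_right - self.x_left) / REGION_WIDTH_MM

    def surface_y(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.surface_intercept + self.surface_slope * np.asarray(x, dtype=float)

    def in_region(self, x: np.ndarray | float) -> np.ndarray | bool:
        x = np.asarray(x, dtype=float)
        return (x >= self.x_left) & (x < self.x_right)


@dataclass(frozen=True)
class VideoMetadata:
    video_id: str
    mouse_id: str
    sex: str                   # "F" or "M"
    weight: float              # grams
    group: str                 # dose / genotype label
    beam: str                  # BeamType name
    trial: int
    fps: float = 120.0
    cohort: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.weight <= 0:
            raise ValueError("weight must be > 0 grams")


# --------------------------------------------------------------------------
# DLC-dialect reader / writer
# --------------------------------------------------------------------------


def load_tracking(
    path: str | Path,
    fps: float,
    video_id: str = "",
    mouse_id: str = "",
    aliases: Mapping[str, str] | None = None,
) -> TrackingTable:
    """Read a DLC-dialect keypoint CSV into a :class:`TrackingTable`.

    The file must carry the three standard header rows (scorer /
    bodyparts / coords).  Column names are mapped onto canonical keypoint
    names through :data:`DEFAULT_ALIASES` merged with ``aliases``; all
    18 canonical keypoints must be present after mapping.
    """
    path = Path(path)
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)

    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                          float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"{path}: not a 3-row-header keypoint CSV ({exc})") from exc

    # canonicalise body-part level
    parts = [alias_map.get(p, p) for p in raw.columns.get_level_values(1)]
    coords = list(raw.columns.get_level_values(2))
    bad = sorted(set(coords) - {"x", "y", "likelihood"})
    if bad:
        raise FormatError(f"{path}: unexpected coords row entries {bad}")
    raw.columns = pd.MultiIndex.from_arrays([parts, coords], names=["bodyparts", "coords"])

    missing = [p for p in ALL_KEYPOINTS if p not in set(parts)]
    if missing:
        raise FormatError(f"{path}: missing required keypoint(s): {', '.join(missing)}")

    data = raw[[c for c in raw.columns]].copy()
    # strict numeric conversion with row/column diagnostics
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad_rows = converted.index[converted.isna() & data[col].notna()]
        if len(bad_rows):
            raise FormatError(
                f"{path}: non-numeric value in column {col[0]}/{col[1]} "
                f"at frame {bad_rows[0]}"
            )
        data[col] = converted.astype(float)
    data = data[[(p, c) for p in ALL_KEYPOINTS for c in ("x", "y", "likelihood")]]
    data.index = pd.RangeIndex(len(data))

    lik = data.loc[:, (slice(None), "likelihood")].to_numpy()
    if np.nanmin(lik) < 0 or np.nanmax(lik) > 1:
        raise FormatError(f"{path}: likelihood values outside [0, 1]")

    return TrackingTable(data=data, fps=fps, video_id=video_id or path.stem,
                         mouse_id=mouse_id)


def write_tracking(track: TrackingTable, path: str | Path, scorer: str = "beamwalk") -> Path:
    """Write a :class:`TrackingTable` as a DLC-dialect CSV.

    Floats are serialised with ``repr`` (shortest round-trip form) so
    ``load_tracking(write_tracking(t))`` reproduces every numeric cell
    bit-exactly.
    """
    path = Path(path)
    parts = track.keypoints
    header1 = ["scorer"] + [scorer] * (3 * len(parts))
    header2 = ["bodyparts"] + [p for p in parts for _ in range(3)]
    header3 = ["coords"] + ["x", "y", "likelihood"] * len(parts)
    values = track.data.to_numpy(dtype=float)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header1) + "\n")
        fh.write(",".join(header2) + "\n")
        fh.write(",".join(header3) + "\n")
        for i, row in enumerate(values):
            fh.write(str(i) + "," + ",".join(repr(float(v)) for v in row) + "\n")
    return path


# --------------------------------------------------------------------------
# Metadata and annotation tables
# --------------------------------------------------------------------------

_META_COLUMNS = ["video_id", "mouse_id", "sex", "weight", "group", "beam", "trial"]


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Flat per-video metadata CSV -> DataFrame (one row per trial video)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, dtype={"video_id": str, "mouse_id": str})
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {missing}")
    if "fps" not in meta.columns:
        meta["fps"] = 120.0
    if "cohort" not in meta.columns:
        meta["cohort"] = ""
    dup = meta.duplicated(subset=["mouse_id", "beam", "trial"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (mouse_id, beam, trial) rows")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, index=False)
    return path


def load_annotations(path: str | Path) -> dict[str, list[int]]:
    """Human foot-slip annotations CSV (video_id, frame) -> frames per video."""
    ann = pd.read_csv(path, dtype={"video_id": str})
    for col in ("video_id", "frame"):
        if col not in ann.columns:
            raise FormatError(f"{path}: annotation file missing column {col!r}")
    out: dict[str, list[int]] = {}
    for vid, grp in ann.groupby("video_id"):
        out[str(vid)] = sorted(int(f) for f in grp["frame"])
    return out


# --------------------------------------------------------------------------
# Beam geometry
# --------------------------------------------------------------------------


def detect_beam_type(
    track: TrackingTable, likelihood_floor: float = DEFAULT_LIKELIHOOD_FLOOR
) -> BeamType:
    """Identify the beam from the dot markers.

    A dot is "confidently tracked" when its median likelihood over all
    frames reaches ``likelihood_floor``.  Dot on the right: 16-mm square;
    no dot: 16-mm round; dot on the left: 9-mm square.
    """
    right = float(np.median(track.likelihood("dot_right")))
    left = float(np.median(track.likelihood("dot_left")))
    right_ok = right >= likelihood_floor
    left_ok = left >= likelihood_floor
    if right_ok and left_ok:
        raise GeometryError(
            f"both beam dots confidently tracked (median likelihoods "
            f"left={left:.3f}, right={right:.3f}); cannot identify beam"
        )
    if right_ok:
        return BeamType.BEAM1_16SQ
    if left_ok:
        return BeamType.BEAM3_9SQ
    return BeamType.BEAM2_16RD


def locate_region(track: TrackingTable, beam_type: BeamType | None = None) -> BeamGeometry:
    """Derive the central-region bounds, pixel scale and surface line.

    The two vertical line markers at the region extremities are static, so
    their per-marker median (x, y) positions define the geometry: region
    ``[x_left, x_right)`` from the median x's, the surface as the line
    through the two median points (slope 0 when the x-span degenerates
    below 1 px).
    """
    xl, yl = (float(np.median(track.x("line_left"))),
              float(np.median(track.y("line_left"))))
    xr, yr = (float(np.median(track.x("line_right"))),
              float(np.median(track.y("line_right"))))
    x_left, x_right = min(xl, xr), max(xl, xr)
    if not x_right - x_left > 0:
        raise GeometryError(
            f"degenerate beam-line markers: zero region width at x={x_left}"
        )
    if abs(xr - xl) < 1.0:
        slope = 0.0
        intercept = (yl + yr) / 2.0
    else:
        slope = (yr - yl) / (xr - xl)
        intercept = yl - slope * xl
    return BeamGeometry(
        x_left=x_left,
        x_right=x_right,
        surface_intercept=intercept,
        surface_slope=slope,
        beam_type=beam_type,
    )


# --------------------------------------------------------------------------
# Confidence gating
# --------------------------------------------------------------------------


def clean_track(
    track: TrackingTable, likelihood_floor: float = DEFAULT_LIKELIHOOD_FLOOR
) -> TrackingTable:
    """Interpolate low-confidence body-part coordinates.

    Frames where a body part's likelihood falls below ``likelihood_floor``
    get that part's x and y replaced by linear interpolation between the
    nearest confident frames; runs at either end copy the nearest confident
    frame.  Likelihood columns are left untouched and only the 13 body
    parts are gated (beam markers are static references summarised by
    medians and may legitimately be low-confidence, e.g. an absent dot).
    """
    data = track.data.copy()
    for part in BODY_PARTS:
        lik = data[(part, "likelihood")].to_numpy(dtype=float)
        confident = lik >= likelihood_floor
        if not confident.any():
            raise FormatError(
                f"body part {part!r} has no frame at or above the "
                f"likelihood floor {likelihood_floor}"
            )
        if confident.all():
            continue
        for coord in ("x", "y"):
            s = data[(part, coord)].copy()
            s[~confident] = np.nan
            s = s.interpolate(method="linear", limit_direction="both")
            data[(part, coord)] = s
    return replace(track, data=data)


def height_above_beam(track: TrackingTable, geom: BeamGeometry, part: str) -> np.ndarray:
    """Per-frame height of ``part`` above the beam surface, in pixels.

    Positive above the beam; image-y grows downward so
    ``height = surface_y(x_part) - y_part``.
    """
    x = track.x(part)
    y = track.y(part)
    return np.asarray(geom.surface_y(x), dtype=float) - y
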