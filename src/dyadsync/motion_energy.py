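"""Frame-differencing motion energy extraction.

Motion energy analysis (MEA) quantifies movement in a region of interest
(ROI) of a fixed-camera video as the number of pixels whose gray-scale
intensity changes by more than a threshold between consecutive frames.
One nonnegative count per frame transition and per ROI is produced; the
four canonical ROIs cover the head and upper body of the two interactants
(participant and administrator) in a dyadic interview.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical ROI roles for a patient-administrator dyad.
ROLES = (
    "participant_head",
    "participant_body",
    "administrator_head",
    "administrator_body",
)

#: ITU-R BT.601 luma weights used when collapsing RGB input to gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class FrameSequence:
    """An ordered stack of 8-bit gray-scale frames at a fixed frame rate."""

    frames: np.ndarray  # (n_frames, height, width), uint8
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if frames.shape[0] < 2:
            raise ValueError("a frame sequence needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass(frozen=True)
class RegionOfInterest:
    """A half-open pixel rectangle [x0, x1) x [y0, y1) tagged with its role."""

    role: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"ROI {self.role!r} is empty")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def validate_bounds(self, height: int, width: int) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.x1 > width or self.y1 > height:
            raise ValueError(
                f"ROI {self.role!r} {(self.x0, self.y0, self.x1, self.y1)} "
                f"exceeds frame bounds {width}x{height}"
            )

    def slice(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass(frozen=True)
class MEAConfig:
    """Motion energy settings. ``threshold`` is in gray-level units (0-255)."""

    threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class MotionEnergySeries:
    """Per-frame-transition movement counts for one ROI.

    ``values`` has one entry per frame transition, i.e. length
    ``n_frames - 1`` when extracted from video.
    """

    values: np.ndarray
    role: str
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("motion energy series must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("motion energy counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_sec(self) -> float:
        return len(self.values) / self.fps


def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse an (h, w, 3) RGB frame to 8-bit gray via BT.601 luma weights."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[2] >= 3:
        gray = frame[..., :3].astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError("expected a gray (h, w) or RGB (h, w, 3) frame")


def frame_motion_energy(
    prev: np.ndarray,
    curr: np.ndarray,
    roi: RegionOfInterest,
    cfg: MEAConfig = MEAConfig(),
) -> int:
    """Count pixels in ``roi`` whose absolute intensity change exceeds the threshold.

    The comparison is strict (> threshold): a change equal to the threshold
    does not count as movement.
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError("frames differ in shape")
    roi.validate_bounds(*prev.shape)
    ys, xs = roi.slice()
    # int16 avoids uint8 wrap-around in the subtraction
    diff = np.abs(prev[ys, xs].astype(np.int16) - curr[ys, xs].astype(np.int16))
    return int(np.count_nonzero(diff > cfg.threshold))


def extract_motion_energy(
    video: FrameSequence,
    rois: Iterable[RegionOfInterest],
    cfg: MEAConfig = MEAConfig(),
) -> dict[str, MotionEnergySeries]:
    """Extract one motion energy series per ROI from a frame sequence."""
    rois = list(rois)
    for roi in rois:
        roi.validate_bounds(video.height, video.width)
    frames = video.frames.astype(np.int16)
    diff = np.abs(np.diff(frames, axis=0))
    out: dict[str, MotionEnergySeries] = {}
    for roi in rois:
        ys, xs = roi.slice()
        counts = np.count_nonzero(diff[:, ys, xs] > cfg.threshold, axis=(1, 2))
        out[roi.role] = MotionEnergySeries(counts.astype(np.int64), roi.role, video.fps)
    return out


def movement_quantity(
    series: MotionEnergySeries, denominator: str = "transitions"
) -> float:
    """Fraction of frame transitions with nonzero motion energy.

    The denominator is the length of the transition series by default
    (``"transitions"``, i.e. n_frames - 1); pass ``"frames"`` to divide by
    the frame count instead (the off-by-one alternative reading).
    """
    n = len(series)
    if n == 0:
        raise ValueError("empty motion energy series")
    active = int(np.count_nonzero(series.values))
    if denominator == "transitions":
        return active / n
    if denominator == "frames":
        return active / (n + 1)
    raise ValueError("denominator must be 'transitions' or 'frames'")


# ---------------------------------------------------------------------------
# I/O adapters


def load_frame_sequence(directory: str | Path, fps: float) -> FrameSequence:
    """Load a lexicographically ordered PNG/JPEG image directory as video."""
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if len(paths) < 2:
        raise ValueError(f"{directory} holds fewer than 2 image frames")
    frames = np.stack([rgb_to_gray(iio.imread(p)) for p in paths])
    return FrameSequence(frames, fps)


def load_rois(path: str | Path) -> list[RegionOfInterest]:
    """Read ROI rectangles from a JSON list of {role, x0, y0, x1, y1}."""
    with open(path) as fh:
        spec = json.load(fh)
    return [RegionOfInterest(**entry) for entry in spec]


def write_series_csv(
    series: Mapping[str, MotionEnergySeries],
    path: str | Path,
    sidecar: Mapping | None = None,
) -> None:
    """Write one column per ROI role plus a JSON sidecar with provenance.

    All series must share fps and length; rows are frame transitions.
    """
    path = Path(path)
    fps = {round(s.fps, 6) for s in series.values()}
    if len(fps) != 1:
        raise ValueError("series disagree on fps")
    df = pd.DataFrame({role: s.values for role, s in series.items()})
    df.to_csv(path, index=False)
    meta = {"fps": fps.pop(), "columns": list(df.columns)}
    if sidecar:
        meta.update(sidecar)
    meta["sha256"] = hashlib.sha256(path.read_bytes()).hexdigest()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_series_csv(path: str | Path) -> dict[str, MotionEnergySeries]:
    """Read a motion-energy CSV written by :func:`write_series_csv`."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    return {
        role: MotionEnergySeries(df[role].to_numpy(), role, meta["fps"])
        for role in df.columns
    }
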