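"""World-coordinate path reconstruction and motion classification for
freely moving imaging experiments.

During free-behavior imaging the animal is kept in the field of view by
manually moving the stage, so neither the stage log nor the ROI position
alone gives the animal's trajectory; their combination does:

    world = stage + pixel_size * R @ (roi - frame_center)

with ``R`` an axis-orientation transform (camera vs stage axes).  The
reconstructed path is smoothed with a centered moving average; short gaps
(unresolved tracking) are filled with a cubic spline and long gaps are
excluded: gaps shorter than 30 frames are filled, gaps of 30 frames or
more (and gaps touching the sequence ends, where interpolation would be
extrapolation) are excluded.

Movement is classified per frame from the smoothed path: speed from
central differences; frames slower than 10 um/s are stationary and leave
direction analysis; maximal runs whose successive heading changes stay
within 7.5 degrees are "consistent movement"; consistent runs longer than
90 s are forward automatically, shorter ones need a direction label
(``needs_label``, the stand-in for interactive user input).  Reversals are
maximal backward-labeled runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "StageLog",
    "MotionConfig",
    "ORIENTATIONS",
    "reconstruct_path",
    "fill_gaps",
    "classify_motion",
    "detect_reversals_freely_moving",
]


@dataclass
class StageLog:
    """Logged stage positions (um) with timestamps (s)."""

    xy: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, float)
        self.times = np.asarray(self.times, float)
        if self.xy.shape != (len(self.times), 2):
            raise ValueError("stage log must be (n, 2) with matching times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MotionConfig:
    smooth_window: int = 5  # moving-average frames, centered
    gap_fill_max: int = 30  # gaps of >= this many frames are excluded
    stationary_speed: float = 10.0  # um/s
    consistent_angle: float = 7.5  # degrees per frame
    forward_min_s: float = 90.0
    spline_flank: int = 3  # valid points used on each side of a gap

    def __post_init__(self) -> None:
        if min(
            self.smooth_window,
            self.gap_fill_max,
            self.stationary_speed,
            self.consistent_angle,
            self.forward_min_s,
        ) <= 0:
            raise ValueError("all motion parameters must be positive")


#: Orientation transforms between camera and stage axes: the four rotations
#: and their mirror images, keyed by name.
ORIENTATIONS = {
    "identity": np.array([[1.0, 0.0], [0.0, 1.0]]),
    "rot90": np.array([[0.0, -1.0], [1.0, 0.0]]),
    "rot180": np.array([[-1.0, 0.0], [0.0, -1.0]]),
    "rot270": np.array([[0.0, 1.0], [-1.0, 0.0]]),
    "mirror_x": np.array([[-1.0, 0.0], [0.0, 1.0]]),
    "mirror_y": np.array([[1.0, 0.0], [0.0, -1.0]]),
    "mirror_rot90": np.array([[0.0, 1.0], [1.0, 0.0]]),
    "mirror_rot270": np.array([[0.0, -1.0], [-1.0, 0.0]]),
}


def _moving_average(path: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, window shrinking at edges and around NaNs;
    output length equals input length and NaN frames stay NaN."""
    n = len(path)
    out = np.full_like(path, np.nan)
    half = window // 2
    valid = np.isfinite(path[:, 0])
    for i in range(n):
        if not valid[i]:
            continue
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        sel = valid[lo:hi]
        out[i] = path[lo:hi][sel].mean(axis=0)
    return out


def reconstruct_path(
    stage: StageLog,
    roi,
    pixel_size: float = 1.0,
    frame_shape: tuple[int, int] | None = None,
    orientation: str = "identity",
    smooth_window: int | None = 5,
) -> np.ndarray:
    """Animal world path (um) from stage log plus ROI frame position.

    ``roi`` is a RoiTrack or an (n, 2) pixel array (NaN = unresolved).
    ``frame_shape`` (H, W) defines the frame center; if omitted, the ROI
    coordinates are taken as already center-relative.  The result is
    moving-average smoothed unless ``smooth_window`` is None.
    """
    xy = roi.xy if hasattr(roi, "xy") else np.asarray(roi, float)
    if len(xy) != stage.n_frames:
        raise ValueError("stage log and ROI track must cover the same frames")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    rel = xy.astype(float).copy()
    if frame_shape is not None:
        center = np.array([(frame_shape[1] - 1) / 2.0, (frame_shape[0] - 1) / 2.0])
        rel = rel - center
    world = stage.xy + pixel_size * rel @ ORIENTATIONS[orientation].T
    if smooth_window:
        world = _moving_average(world, smooth_window)
    return world


def fill_gaps(
    path: np.ndarray, config: MotionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short NaN gaps by cubic-spline interpolation.

    Interior gaps strictly shorter than ``gap_fill_max`` frames are filled
    using a natural cubic spline through ``spline_flank`` valid points on
    each side; longer gaps, and gaps touching either end of the sequence,
    are left excluded.  Returns (filled path, excluded mask).
    """
    config = config or MotionConfig()
    path = np.asarray(path, float).copy()
    n = len(path)
    valid = np.isfinite(path[:, 0]) & np.isfinite(path[:, 1])
    excluded = ~valid
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        gap = j - i
        boundary = i == 0 or j == n
        if not boundary and gap < config.gap_fill_max:
            lo = np.flatnonzero(valid[:i])[-config.spline_flank :]
            hi = np.flatnonzero(valid[j:])[: config.spline_flank] + j
            knots = np.concatenate([lo, hi])
            spline = CubicSpline(knots, path[knots], bc_type="natural")
            idx = np.arange(i, j)
            path[idx] = spline(idx)
            excluded[idx] = False
        i = j
    return path, excluded


def _central_diff_velocity(path: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame velocity (um/s) by central differences, one-sided at the
    ends; NaN wherever a needed neighbor is excluded."""
    n = len(path)
    v = np.full_like(path, np.nan)
    if n >= 3:
        v[1:-1] = (path[2:] - path[:-2]) * (fps / 2.0)
    if n >= 2:
        v[0] = (path[1] - path[0]) * fps
        v[-1] = (path[-1] - path[-2]) * fps
    return v


def classify_motion(
    path: np.ndarray,
    fps: float,
    config: MotionConfig | None = None,
    excluded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame motion classes from a reconstructed, gap-processed path.

    Returns a DataFrame (frame, speed_um_s, heading_deg, label, run_id)
    with labels in {stationary, forward, needs_label, excluded}.  Runs of
    consistent movement (successive heading changes <= ``consistent_angle``)
    longer than ``forward_min_s`` are labeled forward; shorter consistent
    runs are ``needs_label`` and carry a run id for later manual labeling.
    """
    config = config or MotionConfig()
    path = np.asarray(path, float)
    n = len(path)
    if excluded is None:
        excluded = ~(np.isfinite(path[:, 0]) & np.isfinite(path[:, 1]))
    v = _central_diff_velocity(path, fps)
    speed = np.linalg.norm(v, axis=1)
    heading = np.degrees(np.arctan2(v[:, 1], v[:, 0]))

    label = np.array(["excluded"] * n, object)
    moving = ~excluded & np.isfinite(speed)
    stationary = moving & (speed < config.stationary_speed)
    label[stationary] = "stationary"
    directed = moving & ~stationary

    run_id = np.full(n, -1)
    rid = 0
    i = 0
    while i < n:
        if not directed[i]:
            i += 1
            continue
        # grow a maximal consistent run
        j = i + 1
        while j < n and directed[j]:
            dh = (heading[j] - heading[j - 1] + 180.0) % 360.0 - 180.0
            if abs(dh) > config.consistent_angle + 1e-9:
                break
            j += 1
        dur = (j - i) / fps
        lab = "forward" if dur > config.forward_min_s else "needs_label"
        label[i:j] = lab
        run_id[i:j] = rid
        rid += 1
        i = j
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "speed_um_s": speed,
            "heading_deg": heading,
            "label": label,
            "run_id": run_id,
        }
    )


def detect_reversals_freely_moving(
    motion: pd.DataFrame, manual_labels: dict[int, str] | None = None
) -> pd.DataFrame:
    """Reversal events (maximal backward runs) from classified motion.

    ``manual_labels`` maps run_id -> "forward" | "backward" for runs the
    automatic 90 s rule could not label; unlabeled ``needs_label`` runs are
    excluded with a warning.  Returns a DataFrame (onset_frame,
    offset_frame) where offset is the first forward frame after the run
    (or the frame past the run's end at the sequence boundary).
    """
    manual_labels = manual_labels or {}
    label = motion["label"].to_numpy().copy()
    run_id = motion["run_id"].to_numpy()
    unlabeled = set()
    for i in range(len(label)):
        if label[i] == "needs_label":
            lab = manual_labels.get(int(run_id[i]))
            if lab in ("forward", "backward"):
                label[i] = lab
            else:
                unlabeled.add(int(run_id[i]))
                label[i] = "excluded"
    if unlabeled:
        warnings.warn(
            f"{len(unlabeled)} consistent runs left unlabeled; excluded",
            stacklevel=2,
        )
    events = []
    n = len(label)
    i = 0
    while i < n:
        if label[i] == "backward":
            j = i
            while j < n and label[j] == "backward":
                j += 1
            k = j
            while k < n and label[k] not in ("forward",):
                k += 1
            events.append({"onset_frame": i, "offset_frame": k if k < n else j})
            i = j
        else:
            i += 1
    return pd.DataFrame(events, columns=["onset_frame", "offset_frame"])
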