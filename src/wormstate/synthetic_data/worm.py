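"""Synthetic crawling-worm movies with a known behavioral-state schedule.

The generator produces, per frame, a binary silhouette plus a centroid
track, with ground-truth state labels, so the whole behavioral pipeline
(shape classification, turn detection, penalty decoding) can be tested
against a known answer.

Body model
----------
The worm is a constant-length, constant-width tube around a midline:

* forward / backward / stationary frames: a sinusoidal midline (one
  undulation wave) oriented along the body heading — an elongated shape
  with high eccentricity and compactness above the omega thresholds;
* omega frames: the midline is a circular arc of ~300 degrees — a nearly
  closed ring whose second-moment ellipse is almost circular (low
  eccentricity) and which fills its convex hull well (high solidity).

Kinematics are deliberately minimal: forward motion follows the heading
with small angular drift, backward motion reverses the direction of travel
(so forward<->backward transitions produce >60 degree direction changes),
stationary frames jitter in place well below the 10 um/s threshold, and an
omega turn ends with a large reorientation of the heading.

The rendered silhouette is a small per-frame crop accompanied by a
floating-point origin; crop + origin always places the mask's foreground
centroid exactly on the stored centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

STATES = ("forward", "backward", "omega", "stationary")

__all__ = [
    "StateSchedule",
    "WormSpeedParams",
    "SyntheticWormMovie",
    "gen_worm_movie",
    "random_schedule",
]


@dataclass(frozen=True)
class StateSchedule:
    """Ordered behavioral-state segments, (state, duration in s), at ``fps``."""

    segments: tuple[tuple[str, float], ...]
    fps: float = 2.0

    def __init__(self, segments, fps: float = 2.0):
        segments = tuple((str(s), float(d)) for s, d in segments)
        if not segments:
            raise ValueError("schedule must contain at least one segment")
        if fps <= 0:
            raise ValueError("fps must be positive")
        for state, dur in segments:
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if state == "omega" and dur > 3.0:
                raise ValueError("omega segments are bounded at 3 s")
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "fps", float(fps))

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.segments)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def expand(self) -> np.ndarray:
        """Per-frame truth labels: frame i carries the state at time i/fps."""
        times = np.arange(self.n_frames) / self.fps
        bounds = np.cumsum([d for _, d in self.segments])
        idx = np.searchsorted(bounds, times, side="right")
        idx = np.minimum(idx, len(self.segments) - 1)
        return np.array([self.segments[i][0] for i in idx], dtype=object)


@dataclass(frozen=True)
class WormSpeedParams:
    """Kinematic defaults of the miniature synthetic worm (um, um/s, deg)."""

    body_length_um: float = 60.0
    body_width_um: float = 8.0
    crawl_amplitude_um: float = 6.0
    forward_speed_um_s: float = 30.0
    backward_speed_um_s: float = 25.0
    omega_drift_um_s: float = 2.0
    stationary_jitter_um: float = 0.2  # per-frame per-axis sd
    heading_drift_deg: float = 6.0
    omega_arc_deg: float = 300.0
    reorient_min_deg: float = 80.0
    reorient_max_deg: float = 160.0


@dataclass
class SyntheticWormMovie:
    """Per-frame silhouette crops with ground truth.

    ``masks[i]`` is a small binary image whose pixel (row r, col c) sits at
    world pixel coordinates ``origins[i] + (c, r)``; ``centroids`` are in um
    (``pixel_size`` um per px) and coincide with the foreground centroid of
    the placed mask.
    """

    masks: list[np.ndarray]
    origins: np.ndarray  # (n, 2) float px, (x, y)
    centroids: np.ndarray  # (n, 2) float um
    truth: np.ndarray  # (n,) state labels
    pixel_size: float
    fps: float
    schedule: StateSchedule

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _crawl_midline(params: WormSpeedParams, heading: float, phase: float) -> np.ndarray:
    """Sinusoidal midline of one undulation wave, rotated to ``heading``."""
    n = 121
    s = np.linspace(-0.5, 0.5, n) * params.body_length_um
    lat = params.crawl_amplitude_um * np.sin(
        2 * math.pi * s / params.body_length_um + phase
    )
    c, si = math.cos(heading), math.sin(heading)
    x = c * s - si * lat
    y = si * s + c * lat
    return np.column_stack([x, y])


def _omega_midline(params: WormSpeedParams, heading: float) -> np.ndarray:
    """Circular-arc midline (~300 degrees) of the same body length."""
    theta = math.radians(params.omega_arc_deg)
    radius = params.body_length_um / theta
    ang = heading + np.linspace(0.0, theta, 121)
    x = radius * np.cos(ang)
    y = radius * np.sin(ang)
    return np.column_stack([x - x.mean(), y - y.mean()])


def _render_mask(
    midline: np.ndarray,
    half_width: float,
    noise_sd: float,
    rng: np.random.Generator,
    crop: int,
) -> np.ndarray:
    """Rasterize a tube of ``2*half_width`` around the midline into a crop.

    Boundary noise perturbs the signed distance field before thresholding;
    speckle is removed by keeping the largest component and filling holes.
    """
    center = crop / 2.0
    pts = midline + center
    yy, xx = np.mgrid[0:crop, 0:crop]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    dist, _ = cKDTree(pts).query(grid, k=1)
    fieldv = half_width - dist
    if noise_sd > 0:
        fieldv = fieldv + rng.normal(0.0, noise_sd, fieldv.shape)
    mask = (fieldv > 0).reshape(crop, crop)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:  # pragma: no cover - only under absurd noise
        mask = (dist.reshape(crop, crop) <= half_width)
    elif n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def gen_worm_movie(
    schedule: StateSchedule,
    speed_params: WormSpeedParams | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> SyntheticWormMovie:
    """Simulate a single-worm movie following ``schedule``.

    ``noise_sd`` sets both the mask boundary roughness (px) and the
    isotropic per-frame centroid jitter (um).  Identical seeds give
    bit-identical movies.
    """
    params = speed_params or WormSpeedParams()
    rng = np.random.default_rng(seed)
    states = schedule.expand()
    n = len(states)
    fps = schedule.fps

    crop = int(math.ceil((params.body_length_um + 4 * params.body_width_um) / pixel_size))
    heading = rng.uniform(0, 2 * math.pi)
    phase = 0.0
    pos = np.zeros(2)

    masks: list[np.ndarray] = []
    origins = np.empty((n, 2))
    centroids = np.empty((n, 2))

    for i, state in enumerate(states):
        # --- kinematics -------------------------------------------------
        if i > 0:
            prev = states[i - 1]
            if prev == "omega" and state != "omega":
                turn = rng.uniform(
                    math.radians(params.reorient_min_deg),
                    math.radians(params.reorient_max_deg),
                ) * rng.choice([-1.0, 1.0])
                heading += turn
            if state == "forward":
                heading += rng.normal(0, math.radians(params.heading_drift_deg))
                step = params.forward_speed_um_s / fps * _unit(heading)
            elif state == "backward":
                heading += rng.normal(0, math.radians(params.heading_drift_deg) / 2)
                step = -params.backward_speed_um_s / fps * _unit(heading)
            elif state == "omega":
                step = params.omega_drift_um_s / fps * _unit(rng.uniform(0, 2 * math.pi))
            else:  # stationary
                step = np.zeros(2)
            jitter = rng.normal(0.0, noise_sd, 2) if state != "stationary" else (
                rng.normal(0.0, params.stationary_jitter_um, 2)
            )
            pos = pos + step + jitter
        if state in ("forward", "backward"):
            phase += (1.0 if state == "forward" else -1.0) * 2 * math.pi * 0.5 / fps

        # --- silhouette -------------------------------------------------
        if state == "omega":
            midline = _omega_midline(params, heading) / pixel_size
        else:
            midline = _crawl_midline(params, heading, phase) / pixel_size
        mask = _render_mask(
            midline, params.body_width_um / 2.0 / pixel_size, noise_sd, rng, crop
        )
        cy, cx = ndimage.center_of_mass(mask)
        masks.append(mask)
        origins[i] = pos / pixel_size - np.array([cx, cy])
        centroids[i] = pos

    return SyntheticWormMovie(
        masks=masks,
        origins=origins,
        centroids=centroids,
        truth=states,
        pixel_size=pixel_size,
        fps=fps,
        schedule=schedule,
    )


def random_schedule(
    rng: np.random.Generator,
    duration_s: float = 90.0,
    fps: float = 2.0,
    p_reversal: float = 0.6,
    p_omega_after_reversal: float = 0.5,
    p_pause: float = 0.15,
) -> StateSchedule:
    """Random mixed schedule resembling plate-assay behavior.

    Long forward runs interleaved with short reversals (1-4 s), omega turns
    after about half the reversals, and occasional pauses; forward time
    dominates, matching the structure the penalty heuristic assumes.
    """
    segments: list[tuple[str, float]] = []
    t = 0.0
    while t < duration_s:
        fwd = float(rng.uniform(6.0, 18.0))
        segments.append(("forward", fwd))
        t += fwd
        if t >= duration_s:
            break
        u = rng.uniform()
        if u < p_reversal:
            rev = float(rng.uniform(1.0, 4.0))
            segments.append(("backward", rev))
            t += rev
            if rng.uniform() < p_omega_after_reversal:
                om = float(rng.uniform(1.0, 2.5))
                segments.append(("omega", om))
                t += om
        elif u < p_reversal + p_pause:
            pause = float(rng.uniform(2.0, 6.0))
            segments.append(("stationary", pause))
            t += pause
    # close on a forward run so no schedule ends mid-reversal/omega
    if segments[-1][0] != "forward":
        segments.append(("forward", float(rng.uniform(4.0, 8.0))))
    return StateSchedule(segments, fps=fps)
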