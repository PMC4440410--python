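"""Synthetic two-channel ratiometric imaging stacks with ground truth.

Emulates a FRET-sensor recording of one neuron in a freely moving animal:
a 2-D Gaussian spot rendered in a donor (CFP-band) and an acceptor
(YFP-band) channel, with programmed acceptor/donor ratio dynamics, a
constant fraction of the donor fluorescence bleeding into the acceptor
channel (crosstalk), additive Gaussian camera noise, optional distractor
spots, and a stage-position log consistent with the neuron's world path.

The world/stage/frame convention matches the trajectory module:

    world_um = stage_um + pixel_size * (frame_px - frame_center)

so ``truth_path`` (frame px), ``stage_log`` (um) and ``truth_world`` (um)
are mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Distractor",
    "SyntheticStack",
    "gen_imaging_stack",
    "smooth_random_path",
    "stage_follow",
]


@dataclass(frozen=True)
class Distractor:
    """A second fluorescent object, e.g. gut autofluorescence or a second
    neuron of the expression pattern.

    ``offset_px`` is relative to the neuron position; ``frames`` limits the
    frames in which the distractor is rendered (None = all frames).
    """

    offset_px: tuple[float, float]
    amplitude: float
    sigma_px: float = 2.0
    ratio: float = 1.0
    frames: tuple[int, int] | None = None  # [start, stop)

    def active(self, i: int) -> bool:
        return self.frames is None or (self.frames[0] <= i < self.frames[1])


@dataclass
class SyntheticStack:
    """Two-channel stack plus every ground-truth quantity a test needs."""

    donor: np.ndarray  # (n, H, W) float32
    acceptor: np.ndarray  # (n, H, W) float32
    truth_path: np.ndarray  # (n, 2) neuron (x, y) in frame px
    truth_ratio: np.ndarray  # (n,) programmed acceptor/donor ratio (pre-crosstalk)
    truth_world: np.ndarray  # (n, 2) neuron world position, um
    stage_log: np.ndarray  # (n, 2) stage position, um
    crosstalk_coeff: float
    noise_sd: float
    pixel_size: float
    fps: float
    amplitude_donor: float
    background: float
    sigma_px: float
    distractors: tuple[Distractor, ...] = field(default_factory=tuple)

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _spot(shape: tuple[int, int], xy: np.ndarray, sigma: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-((xx - xy[0]) ** 2 + (yy - xy[1]) ** 2) / (2.0 * sigma**2))


def gen_imaging_stack(
    path_spec: np.ndarray,
    ratio_profile,
    crosstalk_coeff: float = 0.6,
    noise_sd: float = 2.0,
    distractors: tuple[Distractor, ...] = (),
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    amplitude_donor: float = 100.0,
    background: float = 50.0,
    sigma_px: float = 2.0,
    stage_path: np.ndarray | None = None,
    pixel_size: float = 1.0,
    fps: float = 2.0,
) -> SyntheticStack:
    """Render a two-channel stack for a neuron following ``path_spec``.

    Parameters
    ----------
    path_spec : (n, 2) array
        Neuron (x, y) position per frame, in frame pixels.
    ratio_profile : scalar or (n,) array
        Programmed acceptor/donor amplitude ratio, pre-crosstalk (> 0).
    crosstalk_coeff : float
        Fraction of donor fluorescence added to the acceptor channel.
    stage_path : (n, 2) array, optional
        Stage position log in um (default: stationary stage at origin).

    The acceptor spot amplitude is ``ratio * amplitude_donor`` before the
    crosstalk term ``crosstalk_coeff * amplitude_donor`` is added, so the
    ideal extracted ratio equals ``ratio + crosstalk_coeff``.
    """
    path = np.atleast_2d(np.asarray(path_spec, float))
    n = len(path)
    ratios = np.broadcast_to(np.asarray(ratio_profile, float), (n,)).copy()
    if np.any(ratios <= 0):
        raise ValueError("truth_ratio must be positive")
    if crosstalk_coeff < 0:
        raise ValueError("crosstalk_coeff must be >= 0")
    if amplitude_donor <= 0 or background < 0:
        raise ValueError("intensities must be non-negative")
    stage = (
        np.zeros((n, 2)) if stage_path is None else np.asarray(stage_path, float).copy()
    )
    if stage.shape != (n, 2):
        raise ValueError("stage_path must match path_spec frame count")

    rng = np.random.default_rng(seed)
    donor = np.empty((n, *shape), np.float32)
    acceptor = np.empty((n, *shape), np.float32)
    for i in range(n):
        d_sig = amplitude_donor * _spot(shape, path[i], sigma_px)
        a_sig = ratios[i] * amplitude_donor * _spot(shape, path[i], sigma_px)
        for dis in distractors:
            if dis.active(i):
                pos = path[i] + np.asarray(dis.offset_px, float)
                g = _spot(shape, pos, dis.sigma_px)
                d_sig = d_sig + dis.amplitude * g
                a_sig = a_sig + dis.ratio * dis.amplitude * g
        a_sig = a_sig + crosstalk_coeff * d_sig
        donor[i] = background + d_sig
        acceptor[i] = background + a_sig
        if noise_sd > 0:
            donor[i] += rng.normal(0.0, noise_sd, shape)
            acceptor[i] += rng.normal(0.0, noise_sd, shape)

    center = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
    world = stage + pixel_size * (path - center)
    return SyntheticStack(
        donor=donor,
        acceptor=acceptor,
        truth_path=path,
        truth_ratio=ratios,
        truth_world=world,
        stage_log=stage,
        crosstalk_coeff=crosstalk_coeff,
        noise_sd=noise_sd,
        pixel_size=pixel_size,
        fps=fps,
        amplitude_donor=amplitude_donor,
        background=background,
        sigma_px=sigma_px,
        distractors=tuple(distractors),
    )


def smooth_random_path(
    n: int,
    shape: tuple[int, int] = (128, 128),
    step_px: float = 3.0,
    seed: int = 0,
    margin: float = 20.0,
    turn_sd_deg: float = 10.0,
) -> np.ndarray:
    """Smooth bounded random walk in frame coordinates (px), for tracker tests."""
    rng = np.random.default_rng(seed)
    pos = np.array([shape[1] / 2.0, shape[0] / 2.0])
    heading = rng.uniform(0, 2 * np.pi)
    out = np.empty((n, 2))
    lo = np.array([margin, margin])
    hi = np.array([shape[1] - margin, shape[0] - margin])
    for i in range(n):
        out[i] = pos
        heading += rng.normal(0, np.radians(turn_sd_deg))
        pos = pos + step_px * np.array([np.cos(heading), np.sin(heading)])
        for ax in range(2):
            if pos[ax] < lo[ax] or pos[ax] > hi[ax]:
                pos[ax] = np.clip(pos[ax], lo[ax], hi[ax])
                heading += np.pi / 2  # bounce
    return out


def stage_follow(
    world_path_um: np.ndarray,
    deadband_um: float = 15.0,
    gain: float = 0.5,
) -> np.ndarray:
    """Emulate manual stage re-centering: the stage moves toward the animal
    only once it strays past ``deadband_um`` from the frame center, closing
    ``gain`` of the error per frame.  Returns the stage log (um)."""
    world = np.asarray(world_path_um, float)
    stage = np.empty_like(world)
    s = world[0].copy()
    for i, w in enumerate(world):
        err = w - s
        r = np.linalg.norm(err)
        if r > deadband_um:
            s = s + gain * err
        stage[i] = s
    return stage
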