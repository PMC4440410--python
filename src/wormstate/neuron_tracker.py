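"""ROI tracking of a single neuron across a two-channel image stack.

Three tracking modes mirror how neurons are followed in practice:

* ``brightest`` — when the neuron is the brightest object in the field,
  simply follow the global intensity maximum frame by frame;
* ``heuristic`` — semi-supervised candidate search: a 20-by-20 pixel
  window around the previous ROI centroid is searched for connected bright
  regions whose intensity differs by less than 1/3 from the previous ROI
  and whose centroid lies within a 10-pixel radius; a single candidate is
  accepted, several candidates are resolved by a dominance rule on the
  (intensity difference, centroid distance) match-quality scores, and
  ambiguous frames fall back to a resolver callback (the stand-in for
  interactive user input) or are marked unresolved;
* ``supervised`` — the brightest point inside a user-specified moveable
  region (from a region file, the stand-in for GUI input).

An unresolved run ends at the next frame where the brightest-point track
and the candidate search agree; tracking reseeds there automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

__all__ = [
    "TrackerConfig",
    "Candidate",
    "RoiTrack",
    "track_brightest",
    "find_candidates",
    "resolve_candidates",
    "track_heuristic",
    "track_supervised",
]

AUTO = "auto"
RESOLVED = "resolved_by_callback"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class TrackerConfig:
    """Search-window geometry and match tolerances."""

    window_half: int = 10  # 20-by-20 pixel search square
    radius_max: float = 10.0  # max candidate displacement, px
    intensity_tol: float = 1.0 / 3.0  # relative intensity difference
    region_thresh_frac: float = 0.5  # candidate segmentation threshold
    smooth_sigma_px: float = 1.0  # Gaussian prefilter before segmentation
    snr_min: float = 5.0  # robust peak z-score for low-SNR flagging
    reseed_agree_px: float = 2.0

    def __post_init__(self) -> None:
        if self.window_half <= 0:
            raise ValueError("window_half must be positive")
        if not 0 < self.intensity_tol < 1:
            raise ValueError("intensity_tol must be in (0, 1)")


@dataclass(frozen=True)
class Candidate:
    """A connected bright region proposed as the ROI in the current frame."""

    xy: tuple[float, float]
    intensity: float
    distance: float  # centroid distance to previous ROI, px
    rel_intensity_diff: float  # |I - I_prev| / I_prev

    def scores(self, radius_max: float) -> tuple[float, float]:
        """Match-quality scores (lower is better): intensity and location."""
        return self.rel_intensity_diff, self.distance / radius_max


@dataclass
class RoiTrack:
    """Per-frame ROI centroids with resolution status.

    ``xy`` is (n, 2) float, NaN where unresolved; ``status`` per frame is
    one of auto / resolved_by_callback / unresolved; ``intensity`` is the
    ROI region intensity used for frame-to-frame matching; ``low_snr``
    flags frames whose chosen peak is not clearly above local background.
    """

    xy: np.ndarray
    status: np.ndarray
    intensity: np.ndarray
    low_snr: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "RoiTrack":
        return cls(
            xy=np.full((n, 2), np.nan),
            status=np.array([UNRESOLVED] * n, object),
            intensity=np.full(n, np.nan),
            low_snr=np.zeros(n, bool),
        )

    @property
    def n_frames(self) -> int:
        return len(self.xy)

    def resolved(self) -> np.ndarray:
        return self.status != UNRESOLVED


def _channel(stack, channel: str) -> np.ndarray:
    if isinstance(stack, np.ndarray):
        return stack
    return getattr(stack, channel)


def _prep(img: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """Light Gaussian prefilter: all peak finding, segmentation and
    intensity matching run on the filtered image so that single-pixel noise
    neither fragments candidate regions nor biases their scores."""
    if config.smooth_sigma_px > 0:
        return gaussian_filter(np.asarray(img, float), config.smooth_sigma_px)
    return np.asarray(img, float)


def _region_at_peak(
    img: np.ndarray, peak_rc: tuple[int, int], frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Connected region >= frac * peak value containing the peak."""
    thr = frac * img[peak_rc]
    mask = img >= thr
    labels, _ = ndimage.label(mask)
    return labels == labels[peak_rc], mask


def _weighted_centroid(img: np.ndarray, region: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid with the region's own floor subtracted,
    so the background pedestal does not pull the estimate toward the
    region's geometric center."""
    yy, xx = np.nonzero(region)
    wv = img[yy, xx] - img[yy, xx].min()
    if wv.sum() == 0:
        wv = np.ones_like(wv)
    return float((xx * wv).sum() / wv.sum()), float((yy * wv).sum() / wv.sum())


def _peak_snr(img: np.ndarray, peak_value: float) -> float:
    med = np.median(img)
    mad = np.median(np.abs(img - med)) * 1.4826
    if mad == 0:
        # degenerate flat background: any contrast is infinitely clear,
        # no contrast at all is none
        return math.inf if peak_value > med else 0.0
    return (peak_value - med) / mad


def track_brightest(stack, channel: str = "acceptor", config: TrackerConfig | None = None) -> RoiTrack:
    """Follow the global intensity maximum of one channel.

    Ties between equal maxima resolve deterministically to the lowest
    raster-order pixel (the frame is tie-flagged via ``low_snr``); frames
    with no contrast at all (constant image) are unresolved.
    """
    config = config or TrackerConfig()
    imgs = _channel(stack, channel)
    n = len(imgs)
    track = RoiTrack.empty(n)
    for i in range(n):
        img = _prep(imgs[i], config)
        vmax = img.max()
        if vmax == img.min():
            continue  # unresolved: saturated/empty frame
        flat = int(np.argmax(img))
        peak = np.unravel_index(flat, img.shape)
        n_ties = int((img == vmax).sum())
        region, _ = _region_at_peak(img, peak, config.region_thresh_frac)
        x, y = _weighted_centroid(img, region)
        track.xy[i] = (x, y)
        track.status[i] = AUTO
        track.intensity[i] = float(img[region].mean())
        track.low_snr[i] = (
            n_ties > 1 or _peak_snr(img, vmax) < config.snr_min
        )
    return track


def find_candidates(
    frame: np.ndarray,
    prev_xy: tuple[float, float],
    prev_intensity: float,
    config: TrackerConfig | None = None,
) -> list[Candidate]:
    """Connected bright regions in the search window that match the
    previous ROI in both intensity and location.

    The window is segmented at ``region_thresh_frac`` of the previous ROI
    intensity; each region's intensity is the mean of its pixels above the
    window's Otsu threshold (falling back to the region mean for flat
    windows).  Regions pass if their relative intensity difference is
    strictly below ``intensity_tol`` and their centroid lies within
    ``radius_max`` of the previous ROI.
    """
    config = config or TrackerConfig()
    frame = _prep(frame, config)
    h, w = frame.shape
    cx, cy = prev_xy
    x0 = max(0, int(round(cx)) - config.window_half)
    x1 = min(w, int(round(cx)) + config.window_half)
    y0 = max(0, int(round(cy)) - config.window_half)
    y1 = min(h, int(round(cy)) + config.window_half)
    win = frame[y0:y1, x0:x1]
    if win.size == 0:
        return []
    mask = win >= config.region_thresh_frac * prev_intensity
    if not mask.any():
        return []
    try:
        otsu = threshold_otsu(win)
    except ValueError:  # constant window
        otsu = -math.inf
    labels, n_reg = ndimage.label(mask)
    out: list[Candidate] = []
    for r in range(1, n_reg + 1):
        region = labels == r
        x, y = _weighted_centroid(win, region)
        x += x0
        y += y0
        above = region & (win > otsu)
        intensity = float(win[above].mean() if above.any() else win[region].mean())
        rel = abs(intensity - prev_intensity) / prev_intensity
        dist = math.hypot(x - cx, y - cy)
        if rel < config.intensity_tol and dist <= config.radius_max:
            out.append(
                Candidate(
                    xy=(x, y),
                    intensity=intensity,
                    distance=dist,
                    rel_intensity_diff=rel,
                )
            )
    return out


def resolve_candidates(
    candidates: list[Candidate],
    prev_xy: tuple[float, float],
    resolver=None,
    config: TrackerConfig | None = None,
    frame_index: int | None = None,
) -> tuple[Candidate | None, str]:
    """Choose the ROI among candidates.

    Exactly one candidate is accepted outright.  Among several, a
    candidate strictly better than every other in BOTH match-quality
    scores (intensity difference and centroid distance) wins; otherwise —
    and when there are no candidates — the resolver callback is consulted.
    The default resolver declines, leaving the frame unresolved.
    """
    config = config or TrackerConfig()
    if len(candidates) == 1:
        return candidates[0], AUTO
    if len(candidates) > 1:
        scored = [c.scores(config.radius_max) for c in candidates]
        for i, si in enumerate(scored):
            if all(
                si[0] < sj[0] and si[1] < sj[1]
                for j, sj in enumerate(scored)
                if j != i
            ):
                return candidates[i], AUTO
    if resolver is not None:
        choice = resolver(frame_index, candidates, prev_xy)
        if choice is not None:
            if isinstance(choice, Candidate):
                return choice, RESOLVED
            x, y = choice
            return (
                Candidate(xy=(float(x), float(y)), intensity=math.nan, distance=0.0, rel_intensity_diff=0.0),
                RESOLVED,
            )
    return None, UNRESOLVED


def _roi_near(
    img: np.ndarray, xy: tuple[float, float], config: TrackerConfig
) -> tuple[tuple[float, float], float]:
    """ROI (centroid, intensity) at the brightest point of the window
    around ``xy`` — used for seeding and reseeding."""
    img = _prep(img, config)
    h, w = img.shape
    x0 = max(0, int(round(xy[0])) - config.window_half)
    x1 = min(w, int(round(xy[0])) + config.window_half)
    y0 = max(0, int(round(xy[1])) - config.window_half)
    y1 = min(h, int(round(xy[1])) + config.window_half)
    win = img[y0:y1, x0:x1]
    peak = np.unravel_index(int(np.argmax(win)), win.shape)
    region, _ = _region_at_peak(win, peak, config.region_thresh_frac)
    x, y = _weighted_centroid(win, region)
    return (x + x0, y + y0), float(win[region].mean())


def track_heuristic(
    stack,
    seed_xy: tuple[float, float],
    channel: str = "acceptor",
    config: TrackerConfig | None = None,
    resolver=None,
) -> RoiTrack:
    """Heuristic candidate-search tracking seeded at ``seed_xy``.

    After an unresolved frame the tracker follows the per-frame brightest
    point provisionally and resumes automatic tracking at the first frame
    where the candidate search around the provisional ROI returns exactly
    one candidate that coincides with the frame's brightest point (within
    ``reseed_agree_px``); frames before that point stay unresolved.
    """
    config = config or TrackerConfig()
    imgs = _channel(stack, channel)
    n = len(imgs)
    track = RoiTrack.empty(n)

    prev_xy, prev_int = _roi_near(imgs[0], seed_xy, config)
    track.xy[0] = prev_xy
    track.status[0] = AUTO
    track.intensity[0] = prev_int
    track.low_snr[0] = _peak_snr(imgs[0], imgs[0].max()) < config.snr_min

    lost = False
    for i in range(1, n):
        img = imgs[i]
        cands = find_candidates(img, prev_xy, prev_int, config)
        chosen, status = resolve_candidates(
            cands, prev_xy, resolver, config, frame_index=i
        )
        if not lost and chosen is not None:
            # refine the accepted candidate with the sharper peak-region
            # centroid (the candidate segmentation threshold sits close to
            # the background, so its centroid is comparatively coarse)
            (x, y), intensity = _roi_near(img, chosen.xy, config)
            if math.hypot(x - chosen.xy[0], y - chosen.xy[1]) > config.radius_max:
                x, y = chosen.xy  # refinement jumped to another object
                intensity = chosen.intensity
            track.xy[i] = (x, y)
            track.status[i] = status
            track.intensity[i] = intensity
            prev_xy, prev_int = (x, y), intensity
            continue
        # lost: provisional brightest-point chain, wait for agreement
        lost = True
        sm = _prep(img, config)
        pk = np.unravel_index(int(np.argmax(sm)), sm.shape)
        bright_xy, bright_int = _roi_near(img, (pk[1], pk[0]), config)
        cands = find_candidates(img, prev_xy, prev_int, config)
        agree = (
            len(cands) == 1
            and math.hypot(
                cands[0].xy[0] - bright_xy[0], cands[0].xy[1] - bright_xy[1]
            )
            <= config.reseed_agree_px
        )
        if agree:
            track.xy[i] = cands[0].xy
            track.status[i] = AUTO
            track.intensity[i] = cands[0].intensity
            prev_xy, prev_int = cands[0].xy, cands[0].intensity
            lost = False
        else:
            prev_xy, prev_int = bright_xy, bright_int
    return track


def track_supervised(
    stack,
    region_spec,
    channel: str = "acceptor",
    config: TrackerConfig | None = None,
) -> RoiTrack:
    """Brightest-point tracking restricted to a moveable user region.

    ``region_spec`` maps frame index -> (x0, y0, x1, y1); frames without an
    entry inherit the most recent region.  Frames whose in-region peak is
    not clearly above the region background are flagged ``low_snr``.
    """
    config = config or TrackerConfig()
    imgs = _channel(stack, channel)
    n = len(imgs)
    h, w = imgs[0].shape
    track = RoiTrack.empty(n)
    region = None
    for i in range(n):
        if i in region_spec:
            region = tuple(int(v) for v in region_spec[i])
        if region is None:
            raise ValueError("region_spec must define a region at or before frame 0")
        x0, y0, x1, y1 = region
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"region {region} outside frame bounds {(w, h)}")
        win = _prep(imgs[i], config)[y0:y1, x0:x1]
        peak = np.unravel_index(int(np.argmax(win)), win.shape)
        reg, _ = _region_at_peak(win, peak, config.region_thresh_frac)
        x, y = _weighted_centroid(win, reg)
        track.xy[i] = (x + x0, y + y0)
        track.status[i] = AUTO
        track.intensity[i] = float(win[reg].mean())
        track.low_snr[i] = _peak_snr(win, win[peak]) < config.snr_min
    return track
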