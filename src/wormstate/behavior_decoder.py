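"""Plate-assay behavioral-state decoding by penalty minimization.

The centroid track of a crawling worm does not reveal directly whether the
animal is moving head-first (forward) or tail-first (backward): only the
direction of centroid travel is observed.  The decoder therefore

1. computes instantaneous centroid speed,
2. finds sharp (> 60 degrees) changes in travel direction,
3. splits the track into segments at sharp turns, omega-turn runs (fixed
   by silhouette shape) and stationary runs (speed below threshold), and
4. scores every candidate assignment of {forward, backward} to the mobile
   segments with three penalty terms:

   * a continuous same-direction movement lasting more than 7.5 s that is
     not forward,
   * an omega turn not followed by forward movement,
   * not spending more time moving forward than backward;

   the labeling with the lowest total penalty wins.

Equal-penalty candidates are ordered by a deterministic tie-break:
fewest sharp-turn boundaries without a direction flip (a > 60 degree jump
in travel direction without an omega is kinematic evidence of a
forward/backward switch), then greatest total forward time, then fewest
backward runs.

Segment counts up to ``exhaustive_cap`` are solved by exact enumeration;
longer tracks fall back to an exact dynamic program over (segment, label,
run duration, forward-minus-backward time) with time discretized in
``time_bin_s`` bins (exact whenever frame durations are multiples of the
bin, e.g. at the native 2 frames/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WormTrack",
    "TurnEvent",
    "PenaltyConfig",
    "StateLabels",
    "Segment",
    "instantaneous_speed",
    "detect_sharp_turns",
    "build_segments",
    "enumerate_patterns",
    "pattern_penalty",
    "assign_states",
    "track_summary",
]


@dataclass
class WormTrack:
    """Single-animal centroid track with per-frame flags.

    centroids are (x, y) in um; ``omega_flags`` mark silhouette-classified
    omega frames; ``valid_flags`` encode upstream exclusion (contact with
    another animal, off the lawn, near the border).
    """

    times: np.ndarray
    centroids: np.ndarray
    fps: float
    omega_flags: np.ndarray | None = None
    valid_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.centroids = np.asarray(self.centroids, float)
        n = len(self.times)
        if self.centroids.shape != (n, 2):
            raise ValueError("centroids must be (n, 2) matching times")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.omega_flags is None:
            self.omega_flags = np.zeros(n, bool)
        else:
            self.omega_flags = np.asarray(self.omega_flags, bool)
        if self.valid_flags is None:
            self.valid_flags = np.ones(n, bool)
        else:
            self.valid_flags = np.asarray(self.valid_flags, bool)
        if len(self.omega_flags) != n or len(self.valid_flags) != n:
            raise ValueError("per-frame series must all have equal length")

    @classmethod
    def from_movie(cls, movie, shape_config=None) -> "WormTrack":
        """Build a track from a synthetic (or segmented) mask movie,
        classifying omega frames from the silhouettes."""
        from wormstate.shape_features import omega_flags_for_movie

        flags = omega_flags_for_movie(movie.masks, shape_config)
        return cls(
            times=movie.times,
            centroids=movie.centroids,
            fps=movie.fps,
            omega_flags=flags,
        )

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TurnEvent:
    frame: int
    angle_change: float  # degrees, absolute


@dataclass(frozen=True)
class PenaltyConfig:
    """Decoder thresholds and penalty weights."""

    turn_angle_min: float = 60.0  # degrees, strict
    long_run_s: float = 7.5  # strict ("more than 7.5 s")
    w_long_nonforward: float = 1.0
    w_omega_not_forward: float = 1.0
    w_time_balance: float = 1.0
    stationary_speed_um_s: float = 10.0
    min_heading_disp_um: float = 1.0  # below this, heading is undefined
    merge_omega_gap_frames: int = 2  # omega runs closer than this merge
    exhaustive_cap: int = 20
    time_bin_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.w_long_nonforward, self.w_omega_not_forward, self.w_time_balance) < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.long_run_s <= 0:
            raise ValueError("long_run_s must be positive")


@dataclass(frozen=True)
class Segment:
    """A maximal run of mobile frames between decoding boundaries."""

    start: int  # first frame (inclusive)
    stop: int  # last frame (exclusive)
    duration_s: float
    after_turn: bool  # contiguous with previous segment, split by a turn


@dataclass
class StateLabels:
    """Winning labeling: per-frame states and the decoder's bookkeeping."""

    states: np.ndarray  # per-frame {forward, backward, omega, stationary, excluded}
    penalty: float
    segments: list[Segment]
    segment_labels: tuple[str, ...]
    turns: list[TurnEvent]
    reversals: list[tuple[int, int]] = field(default_factory=list)  # (onset, offset)


def instantaneous_speed(track: WormTrack, rel_tol: float = 1e-3) -> np.ndarray:
    """Centroid displacement between successive frames times fps (um/s).

    ``speed[0]`` is NaN (no preceding frame).  Rejects tracks whose
    timestamps deviate from uniform sampling beyond ``rel_tol``.
    """
    if track.n_frames < 2:
        raise ValueError("need at least two frames for speed")
    dt = np.diff(track.times)
    if np.any(np.abs(dt - 1.0 / track.fps) > rel_tol / track.fps):
        raise ValueError("non-uniform timestamps; resample before decoding")
    disp = np.linalg.norm(np.diff(track.centroids, axis=0), axis=1)
    speed = np.empty(track.n_frames)
    speed[0] = np.nan
    speed[1:] = disp * track.fps
    return speed


def _merged_omega(track: WormTrack, config: PenaltyConfig) -> np.ndarray:
    """Omega flags with sub-threshold gaps (raster flicker) merged."""
    flags = track.omega_flags.copy()
    gap = config.merge_omega_gap_frames
    if gap <= 0:
        return flags
    idx = np.flatnonzero(flags)
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= gap:
            flags[a:b] = True
    return flags


def _frame_classes(track: WormTrack, config: PenaltyConfig) -> np.ndarray:
    """Per-frame coarse class: omega / stationary / mobile."""
    speed = instantaneous_speed(track)
    if track.n_frames > 1:
        speed[0] = speed[1]  # frame 0 inherits its successor's speed
    omega = _merged_omega(track, config)
    cls = np.where(
        omega, "omega", np.where(speed < config.stationary_speed_um_s, "stationary", "mobile")
    )
    return cls.astype(object)


def _headings(track: WormTrack, config: PenaltyConfig) -> np.ndarray:
    """Per-frame travel direction (radians); NaN where undefined."""
    d = np.diff(track.centroids, axis=0)
    h = np.full(track.n_frames, np.nan)
    norms = np.linalg.norm(d, axis=1)
    ok = norms >= config.min_heading_disp_um
    h[1:][ok] = np.arctan2(d[ok, 1], d[ok, 0])
    return h


def _wrap_deg(a: float) -> float:
    return abs((a + 180.0) % 360.0 - 180.0)


def detect_sharp_turns(
    track: WormTrack, config: PenaltyConfig | None = None
) -> list[TurnEvent]:
    """Frames where travel direction changes by more than ``turn_angle_min``.

    Headings are compared between successive defined headings within a
    single mobile span; omega and stationary frames never carry events, and
    direction is never compared across them.
    """
    config = config or PenaltyConfig()
    cls = _frame_classes(track, config)
    h = _headings(track, config)
    events: list[TurnEvent] = []
    prev_heading = None
    for i in range(track.n_frames):
        if cls[i] != "mobile":
            prev_heading = None
            continue
        if math.isnan(h[i]):
            continue
        if i >= 1 and cls[i - 1] != "mobile":
            # first displacement of a span crosses the boundary; use it only
            # as the span's reference direction
            prev_heading = h[i]
            continue
        if prev_heading is not None:
            change = _wrap_deg(math.degrees(h[i] - prev_heading))
            if change > config.turn_angle_min:
                events.append(TurnEvent(frame=i, angle_change=change))
        prev_heading = h[i]
    return events


def build_segments(
    track: WormTrack, config: PenaltyConfig | None = None
) -> tuple[list[Segment], list[tuple[int, int, int | None]], np.ndarray, list[TurnEvent]]:
    """Segment the track for decoding.

    Returns (segments, omega_runs, frame_classes, turns) where omega_runs
    are (start, stop, index of next mobile segment or None).
    """
    config = config or PenaltyConfig()
    cls = _frame_classes(track, config)
    turns = detect_sharp_turns(track, config)
    turn_frames = {t.frame for t in turns}

    segments: list[Segment] = []
    i = 0
    n = track.n_frames
    while i < n:
        if cls[i] != "mobile":
            i += 1
            continue
        j = i
        while j < n and cls[j] == "mobile" and not (j > i and j in turn_frames):
            j += 1
        after = i in turn_frames and i > 0 and cls[i - 1] == "mobile"
        segments.append(
            Segment(start=i, stop=j, duration_s=(j - i) / track.fps, after_turn=after)
        )
        i = j

    omega_runs: list[tuple[int, int, int | None]] = []
    i = 0
    while i < n:
        if cls[i] == "omega":
            j = i
            while j < n and cls[j] == "omega":
                j += 1
            nxt = next((k for k, s in enumerate(segments) if s.start >= j), None)
            omega_runs.append((i, j, nxt))
            i = j
        else:
            i += 1
    return segments, omega_runs, cls, turns


def enumerate_patterns(n_segments: int, cap: int = 20):
    """All 2**k assignments of {forward, backward} to k segments.

    Raises ``ValueError`` above ``cap``; :func:`assign_states` switches to
    the dynamic program instead of enumerating there.
    """
    if n_segments > cap:
        raise ValueError(f"{n_segments} segments exceeds the exhaustive cap {cap}")
    for bits in range(2**n_segments):
        yield tuple(
            "backward" if (bits >> (n_segments - 1 - j)) & 1 else "forward"
            for j in range(n_segments)
        )


def _penalty_terms(
    labels,
    segments: list[Segment],
    omega_runs,
    config: PenaltyConfig,
) -> tuple[float, int, float, int, int]:
    """(penalty, n_long_nonforward, fwd_time, noflip, n_back_runs)."""
    k = len(segments)
    long_runs = 0
    n_back_runs = 0
    noflip = 0
    fwd = 0.0
    bwd = 0.0
    run_label = None
    run_dur = 0.0

    def close_run():
        nonlocal long_runs
        if run_label == "backward" and run_dur > config.long_run_s:
            long_runs += 1

    for j in range(k):
        lab = labels[j]
        dur = segments[j].duration_s
        if lab == "forward":
            fwd += dur
        else:
            bwd += dur
        chained = segments[j].after_turn and j > 0
        if chained and lab == labels[j - 1]:
            noflip += 1
        if run_label == lab and chained:
            run_dur += dur
        else:
            close_run()
            run_label, run_dur = lab, dur
            if lab == "backward":
                n_back_runs += 1
    close_run()

    omega_pen = sum(
        1
        for (_, _, nxt) in omega_runs
        if nxt is not None and labels[nxt] != "forward"
    )
    balance = 1 if fwd <= bwd else 0
    penalty = (
        config.w_long_nonforward * long_runs
        + config.w_omega_not_forward * omega_pen
        + config.w_time_balance * balance
    )
    return penalty, long_runs, fwd, noflip, n_back_runs


def pattern_penalty(
    labels,
    track: WormTrack,
    config: PenaltyConfig | None = None,
    _prebuilt=None,
) -> float:
    """Penalty score of one candidate labeling of the track's segments."""
    config = config or PenaltyConfig()
    if _prebuilt is None:
        segments, omega_runs, _, _ = build_segments(track, config)
    else:
        segments, omega_runs = _prebuilt
    if len(labels) != len(segments):
        raise ValueError("labeling must cover all segments")
    return _penalty_terms(tuple(labels), segments, omega_runs, config)[0]


def _tie_key(labels, segments, omega_runs, config):
    pen, _, fwd, noflip, nback = _penalty_terms(labels, segments, omega_runs, config)
    return (pen, noflip, -fwd, nback)


def _exhaustive_best(segments, omega_runs, config) -> tuple[tuple[str, ...], float]:
    """Vectorized scan over all 2**k labelings (k <= exhaustive_cap)."""
    k = len(segments)
    if k == 0:
        pen, *_ = _penalty_terms((), segments, omega_runs, config)
        return (), pen
    P = 1 << k
    bits = (np.arange(P)[:, None] >> np.arange(k - 1, -1, -1)) & 1
    back = bits.astype(bool)  # True = backward
    dur = np.array([s.duration_s for s in segments])
    chained = np.array([s.after_turn for s in segments], bool)
    chained[0] = False

    fwd = (~back) @ dur
    bwd = back @ dur
    balance = (fwd <= bwd).astype(float)

    same_as_prev = np.zeros((P, k), bool)
    same_as_prev[:, 1:] = back[:, 1:] == back[:, :-1]
    noflip = (same_as_prev & chained[None, :]).sum(axis=1)

    cont = same_as_prev & chained[None, :]
    run_start = back & ~(cont & np.roll(back, 1, axis=1))
    run_start[:, 0] = back[:, 0]
    nback = run_start.sum(axis=1)

    # backward-run durations, charged when a run closes with > long_run_s
    long_runs = np.zeros(P)
    acc = np.zeros(P)
    for j in range(k):
        cont_j = cont[:, j] & back[:, j] if j > 0 else np.zeros(P, bool)
        closing = (acc > config.long_run_s) & ~cont_j
        long_runs += closing
        acc = np.where(cont_j, acc + back[:, j] * dur[j], back[:, j] * dur[j])
    long_runs += acc > config.long_run_s

    omega_pen = np.zeros(P)
    for _, _, nxt in omega_runs:
        if nxt is not None:
            omega_pen += back[:, nxt]

    pen = (
        config.w_long_nonforward * long_runs
        + config.w_omega_not_forward * omega_pen
        + config.w_time_balance * balance
    )
    order = np.lexsort((np.arange(P), nback, -fwd, noflip, pen))
    best = order[0]
    labels = tuple("backward" if b else "forward" for b in back[best])
    return labels, float(pen[best])


def _dp_best(segments, omega_runs, config) -> tuple[tuple[str, ...], float]:
    """Exact DP over (label, backward-run bins, forward-minus-backward bins).

    Time is discretized in ``time_bin_s`` bins; exact when segment
    durations are bin multiples (always true at the native frame rate).
    Per-step state tables are kept for backtracking.
    """
    k = len(segments)
    binw = config.time_bin_s
    dbins = [int(round(s.duration_s / binw)) for s in segments]
    long_bins = int(math.floor(config.long_run_s / binw))  # run > 7.5 s <=> bins > long_bins
    cap_bins = long_bins + 1
    omega_next: dict[int, int] = {}
    for _, _, nxt in omega_runs:
        if nxt is not None:
            omega_next[nxt] = omega_next.get(nxt, 0) + 1

    def better(a, b):
        return a if a[:3] <= b[:3] else b

    # state key: (label, capped backward-run bins, forward-minus-backward bins)
    # value: (penalty, noflip, n_back_runs, backpointer to previous state key)
    tables: list[dict] = []
    states: dict[tuple, tuple] = {}
    for j in range(k):
        d = dbins[j]
        new: dict[tuple, tuple] = {}
        for lab in ("forward", "backward"):
            om_pen = (
                config.w_omega_not_forward * omega_next.get(j, 0)
                if lab != "forward"
                else 0.0
            )
            if j == 0:
                if lab == "backward":
                    run = min(d, cap_bins)
                    pen = om_pen + (
                        config.w_long_nonforward if d > long_bins else 0.0
                    )
                    key = (lab, run, -d)
                    cand = (pen, 0, 1, None)
                else:
                    key = (lab, 0, d)
                    cand = (om_pen, 0, 0, None)
                cur = new.get(key)
                new[key] = cand if cur is None else better(cand, cur)
                continue
            for pkey, (pen, noflip, nback, _) in states.items():
                plab, prun, pfmb = pkey
                chain = segments[j].after_turn and plab == lab
                noflip_inc = 1 if chain else 0
                if lab == "backward":
                    base = prun if chain else 0
                    run = min(base + d, cap_bins)
                    crossing = base <= long_bins and base + d > long_bins
                    pen_inc = om_pen + (
                        config.w_long_nonforward if crossing else 0.0
                    )
                    nback_inc = 0 if (chain and plab == "backward") else 1
                    nfmb = pfmb - d
                else:
                    run = 0
                    pen_inc = om_pen
                    nback_inc = 0
                    nfmb = pfmb + d
                key = (lab, run, nfmb)
                cand = (pen + pen_inc, noflip + noflip_inc, nback + nback_inc, pkey)
                cur = new.get(key)
                new[key] = cand if cur is None else better(cand, cur)
        tables.append(new)
        states = new

    best_key = None
    best_state = None
    for (lab, run, fmb), (pen, noflip, nback, _) in states.items():
        total = pen + config.w_time_balance * (1 if fmb <= 0 else 0)
        keyt = (total, noflip, -fmb, nback, lab == "backward")
        if best_key is None or keyt < best_key:
            best_key = keyt
            best_state = (lab, run, fmb)

    labels = []
    key = best_state
    for j in range(k - 1, -1, -1):
        labels.append(key[0])
        key = tables[j][key][3]
    labels.reverse()
    return tuple(labels), float(best_key[0])


def assign_states(
    track: WormTrack, config: PenaltyConfig | None = None
) -> StateLabels:
    """Decode per-frame states by lowest-penalty pattern assignment."""
    config = config or PenaltyConfig()
    segments, omega_runs, cls, turns = build_segments(track, config)
    k = len(segments)
    if k <= config.exhaustive_cap:
        labels, penalty = _exhaustive_best(segments, omega_runs, config)
    else:
        labels, penalty = _dp_best(segments, omega_runs, config)

    states = np.empty(track.n_frames, object)
    states[:] = None
    for i in range(track.n_frames):
        if cls[i] == "omega":
            states[i] = "omega"
        elif cls[i] == "stationary":
            states[i] = "stationary"
    for seg, lab in zip(segments, labels):
        states[seg.start : seg.stop] = lab
    # any frame not covered (possible only at degenerate ends) inherits its
    # nearest labeled neighbor
    for i in range(track.n_frames):
        if states[i] is None:  # pragma: no cover - defensive
            j = i + 1
            while j < track.n_frames and states[j] is None:
                j += 1
            states[i] = states[j] if j < track.n_frames else "stationary"
    states[~track.valid_flags] = "excluded"

    reversals = []
    i = 0
    n = track.n_frames
    while i < n:
        if states[i] == "backward":
            j = i
            while j < n and states[j] == "backward":
                j += 1
            reversals.append((i, j))
            i = j
        else:
            i += 1

    return StateLabels(
        states=states,
        penalty=penalty,
        segments=segments,
        segment_labels=labels,
        turns=turns,
        reversals=reversals,
    )


def track_summary(track: WormTrack, labels: StateLabels) -> dict:
    """Per-track summary: mean speed over valid mobile frames, reversal
    rate per second of valid time, and state occupancy fractions."""
    speed = instantaneous_speed(track)
    valid = track.valid_flags
    mobile = np.isin(labels.states, ("forward", "backward")) & valid
    mean_speed = float(np.nanmean(speed[mobile])) if mobile.any() else float("nan")
    valid_time = valid.sum() / track.fps
    n_rev = sum(1 for (a, b) in labels.reversals if valid[a])
    occ = {
        s: float(np.mean(labels.states == s))
        for s in ("forward", "backward", "omega", "stationary", "excluded")
    }
    return {
        "mean_speed_um_s": mean_speed,
        "reversal_rate_per_s": n_rev / valid_time if valid_time > 0 else float("nan"),
        "occupancy": occ,
        "penalty": labels.penalty,
    }
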