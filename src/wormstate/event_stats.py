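"""Event-triggered averaging, validity filtering, per-subject means and
nonparametric comparison — the statistics layer of the pipeline.

Conventions:

* Event-triggered panels align trace snippets at relative time 0 (event
  onset) and report the mean with its standard error across events; the
  reported n is the number of events (each animal is imaged once but may
  contribute several events).
* Steady-state comparisons use intervals that begin a fixed lag after each
  stimulus transition, so the compared quantities have plateaued.
* Behavioral comparisons draw one mean per animal per interval, and only
  from animals continuously valid for at least 10 s within the interval;
  the reported n of a two-interval comparison is the smaller per-interval
  sample count.
* Group comparisons use the two-sided Mann-Whitney U test: exact by full
  enumeration of group assignments for small samples, the tie-corrected
  normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidityConfig",
    "EventAlignedMatrix",
    "ComparisonResult",
    "align_events",
    "valid_subject_means",
    "mann_whitney",
    "steady_state_intervals",
    "significance_stars",
]


@dataclass(frozen=True)
class ValidityConfig:
    """An animal enters an interval's sample only if it has at least one
    continuously-valid run of ``min_continuous_valid_s`` inside it."""

    min_continuous_valid_s: float = 10.0

    def __post_init__(self) -> None:
        if self.min_continuous_valid_s <= 0:
            raise ValueError("minimum valid duration must be positive")


@dataclass
class EventAlignedMatrix:
    """Event-aligned trace snippets on a common relative-time grid."""

    matrix: np.ndarray  # (n_events, n_timepoints)
    rel_times: np.ndarray  # (n_timepoints,), 0 at the alignment frame
    animals: np.ndarray  # per-event animal id
    clipped: np.ndarray  # per-event flag: window extended past the trace

    @property
    def n(self) -> int:
        """Number of events (the n reported in event-triggered panels)."""
        return len(self.matrix)

    def mean(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0) if self.n else np.array([])

    def sem(self) -> np.ndarray:
        if not self.n:
            return np.array([])
        m = self.matrix
        k = np.sum(np.isfinite(m), axis=0)
        return np.nanstd(m, axis=0, ddof=1) / np.sqrt(np.maximum(k, 1))


def align_events(
    traces: dict,
    events,
    window_s: tuple[float, float],
    fps: float,
    baseline_subtract: bool = True,
    range_scale: bool = True,
) -> EventAlignedMatrix:
    """Align per-animal traces to event frames.

    Parameters
    ----------
    traces : dict
        animal id -> 1-D trace sampled at ``fps``.
    events : sequence of (animal, frame) or DataFrame with those columns.
    window_s : (pre, post)
        Window extent in seconds around the event (pre is positive).
    baseline_subtract, range_scale
        Per-event normalization: subtract the pre-window baseline mean,
        then scale by the within-window range.  Both default on for
        normalized panels; turn both off to keep physical units.

    Rows where the window extends past the trace are clipped (NaN padded)
    and flagged.  Zero events yield an empty matrix, not an error.
    """
    if isinstance(events, pd.DataFrame):
        events = list(zip(events["animal"], events["frame"]))
    pre = int(round(window_s[0] * fps))
    post = int(round(window_s[1] * fps))
    rel = np.arange(-pre, post + 1) / fps
    rows, animals, clipped = [], [], []
    for animal, frame in events:
        trace = np.asarray(traces[animal], float)
        idx = np.arange(frame - pre, frame + post + 1)
        row = np.full(len(idx), np.nan)
        ok = (idx >= 0) & (idx < len(trace))
        row[ok] = trace[idx[ok]]
        clipped.append(not ok.all())
        if baseline_subtract:
            base = np.nanmean(row[: pre + 1][rel[: pre + 1] < 0]) if pre else 0.0
            if np.isfinite(base):
                row = row - base
        if range_scale:
            rng = np.nanmax(row) - np.nanmin(row)
            if rng > 0:
                row = row / rng
        rows.append(row)
        animals.append(animal)
    matrix = np.array(rows) if rows else np.empty((0, len(rel)))
    return EventAlignedMatrix(
        matrix=matrix,
        rel_times=rel,
        animals=np.array(animals, object),
        clipped=np.array(clipped, bool),
    )


def _has_long_valid_run(valid: np.ndarray, min_frames: int) -> bool:
    run = 0
    for v in valid:
        run = run + 1 if v else 0
        if run >= min_frames:
            return True
    return False


def valid_subject_means(
    data: pd.DataFrame,
    interval: tuple[float, float],
    fps: float,
    config: ValidityConfig | None = None,
    value_col: str = "value",
) -> pd.Series:
    """One mean per qualifying animal over its valid frames in an interval.

    ``data`` has columns animal, time_s, valid and ``value_col``.  An
    animal qualifies if it has a continuously-valid run of at least
    ``min_continuous_valid_s`` within the interval; its contribution is
    the mean of ``value_col`` over its valid frames there — one number per
    animal per interval, never more.
    """
    config = config or ValidityConfig()
    t0, t1 = interval
    min_frames = int(np.ceil(config.min_continuous_valid_s * fps))
    sel = data[(data["time_s"] >= t0) & (data["time_s"] < t1)]
    out = {}
    for animal, grp in sel.groupby("animal", sort=True):
        valid = grp["valid"].to_numpy(bool)
        if _has_long_valid_run(valid, min_frames):
            out[animal] = float(grp.loc[grp["valid"].astype(bool), value_col].mean())
    return pd.Series(out, dtype=float, name=value_col)


@dataclass(frozen=True)
class ComparisonResult:
    """Mann-Whitney comparison summary; U is counted from group A."""

    U: float
    p: float
    n1: int
    n2: int
    method: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _u_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(
    group_a,
    group_b,
    exact_max_n: int = 16,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact mode (combined n <= ``exact_max_n``) enumerates all
    C(n1+n2, n1) assignments of the pooled values (midranks handle ties)
    and computes P(|U - n1*n2/2| >= |U_obs - n1*n2/2|).  Larger samples use
    the tie-corrected normal approximation with continuity correction.
    Groups with all values tied give p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(U=n1 * n2 / 2.0, p=1.0, n1=n1, n2=n2, method="degenerate")
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1], n1)
    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = comb(n1 + n2, n1)
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(idx)], n1)
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return ComparisonResult(
            U=u_obs, p=hits / total, n1=n1, n2=n2, method="exact"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonResult(
        U=float(res.statistic), p=float(res.pvalue), n1=n1, n2=n2, method="asymptotic"
    )


def steady_state_intervals(
    protocol, lag_s: float = 120.0
) -> pd.DataFrame:
    """Comparison intervals from a stimulus protocol.

    ``protocol`` is a sequence of (level, duration_s) segments (or a
    DataFrame with those columns).  Each interval starts ``lag_s`` after
    the segment's onset transition — allowing responses to plateau — and
    ends at the next transition.  Intervals whose lag exceeds the segment
    are flagged empty.
    """
    if isinstance(protocol, pd.DataFrame):
        protocol = list(zip(protocol["level"], protocol["duration_s"]))
    rows = []
    t = 0.0
    for i, (level, dur) in enumerate(protocol):
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        start = t + lag_s
        end = t + dur
        rows.append(
            {
                "segment": i,
                "level": level,
                "t0": min(start, end),
                "t1": end,
                "empty": start >= end,
            }
        )
        t = end
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Figure-legend significance tiers: *** <0.001, ** <0.01, * <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"
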