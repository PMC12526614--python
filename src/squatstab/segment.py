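"""Squat-cycle detection, window extraction, time and amplitude normalization.

A squat cycle is detected from the torso depth signal (standing baseline minus
torso height). The standing baseline is estimated iteratively as the median of
the non-squat samples; candidate cycles are maximal runs of depth above a
detection level of 20% of the candidate's own peak depth (spurious-detection
rejection), with boundaries then extended outward to a small onset floor so
the reported onset/end sit at the true start/end of the movement. Candidates
shallower than ``min_depth`` or with out-of-range durations are rejected and
logged.

Each retained cycle is sliced from all five channels, linearly resampled onto
a fixed number of time points (20 by default) so squats of different duration
become comparable, and feature channels are min-max scaled per subject (or
globally) with the scaling recorded for exact inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .preprocess import SyncedSession

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH_M = 0.15
DEFAULT_DURATION_BOUNDS_S = (1.0, 10.0)
DEFAULT_ONSET_FLOOR_M = 0.005
DEFAULT_N_SAMPLES = 20


@dataclass
class CycleBoundary:
    """Index bounds of one detected squat on the session grid."""

    onset: int
    hold_start: int
    hold_end: int
    end: int
    peak_depth: float
    y_t1: float  # standing torso baseline, meters

    def __post_init__(self) -> None:
        if not (self.onset < self.hold_start <= self.hold_end < self.end):
            raise ParameterError(
                f"inconsistent boundary: onset={self.onset} hold=[{self.hold_start},"
                f"{self.hold_end}] end={self.end}")


@dataclass
class SquatCycle:
    """One segmented squat: channel windows in physical units."""

    subject: int
    index: int
    t: np.ndarray
    dt: float
    channels: dict[str, np.ndarray]
    y_t1: float

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def estimate_baseline(y_torso: np.ndarray, n_iter: int = 3) -> float:
    """Standing torso height: median over non-squat samples, found iteratively
    (samples whose depth is below 25% of the depth signal's 95th percentile)."""
    y = np.asarray(y_torso, dtype=float)
    y_t1 = float(np.median(y))
    for _ in range(n_iter):
        depth = y_t1 - y
        p95 = np.percentile(depth, 95)
        mask = depth < 0.25 * p95
        if not mask.any():
            break
        y_t1 = float(np.median(y[mask]))
    return y_t1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop] (inclusive) runs of True."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def detect_squats(session: SyncedSession,
                  min_depth: float = DEFAULT_MIN_DEPTH_M,
                  dur_bounds: tuple[float, float] = DEFAULT_DURATION_BOUNDS_S,
                  onset_floor: float = DEFAULT_ONSET_FLOOR_M) -> list[CycleBoundary]:
    """Detect squat cycles on the torso channel; returns accepted boundaries.

    Rejections (too shallow, too short/long) are logged, not raised. A flat
    torso trace yields an empty list.
    """
    y = session.data["y_torso"]
    y_t1 = estimate_baseline(y)
    depth = y_t1 - y
    if np.ptp(depth) < onset_floor:
        return []

    accepted: list[CycleBoundary] = []
    prev_end = -1
    for lo, hi in _runs(depth > onset_floor):
        seg = depth[lo:hi + 1]
        peak = float(seg.max())
        if peak < min_depth:
            logger.info("rejected candidate [%d, %d]: peak depth %.3f m < %.3f m",
                        lo, hi, peak, min_depth)
            continue
        # spurious rejection: keep the sub-run above 20% of peak that contains
        # the peak, then extend outward to the onset floor crossings
        level = max(onset_floor, 0.2 * peak)
        peak_idx = lo + int(np.argmax(seg))
        core = None
        for clo, chi in _runs(depth[lo:hi + 1] > level):
            if clo + lo <= peak_idx <= chi + lo:
                core = (clo + lo, chi + lo)
                break
        if core is None:  # numerically impossible, defensive
            continue
        onset, end = core
        while onset > lo and depth[onset - 1] > onset_floor:
            onset -= 1
        while end < hi and depth[end + 1] > onset_floor:
            end += 1
        if onset <= prev_end:  # earlier run keeps a shared boundary sample
            onset = prev_end + 1
        duration = (end - onset) * session.dt
        if not dur_bounds[0] <= duration <= dur_bounds[1]:
            logger.info("rejected candidate [%d, %d]: duration %.2f s outside %s",
                        onset, end, duration, dur_bounds)
            continue
        hold = np.flatnonzero(depth[onset:end + 1] >= 0.9 * peak) + onset
        hold_start, hold_end = int(hold[0]), int(hold[-1])
        if not (onset < hold_start and hold_end < end):
            logger.info("rejected candidate [%d, %d]: degenerate hold span", onset, end)
            continue
        accepted.append(CycleBoundary(onset=int(onset), hold_start=hold_start,
                                      hold_end=hold_end, end=int(end),
                                      peak_depth=peak, y_t1=y_t1))
        prev_end = end
    return accepted


def extract_window(session: SyncedSession, boundary: CycleBoundary,
                   index: int = 0) -> SquatCycle:
    """Slice all channels onset..end inclusive into one :class:`SquatCycle`."""
    if boundary.onset < 0 or boundary.end >= session.n:
        raise IndexError(
            f"boundary [{boundary.onset}, {boundary.end}] outside grid of {session.n}")
    sl = slice(boundary.onset, boundary.end + 1)
    return SquatCycle(
        subject=session.subject, index=index, t=session.t[sl].copy(), dt=session.dt,
        channels={name: arr[sl].copy() for name, arr in session.data.items()},
        y_t1=boundary.y_t1)


def resample_series(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation of one series onto n equally spaced points
    spanning [t[0], t[-1]] inclusive."""
    if t.size < 2:
        raise ParameterError("window shorter than 2 samples cannot be resampled")
    grid = np.linspace(t[0], t[-1], n)
    return np.interp(grid, t, y)


def time_normalize(cycle: SquatCycle, n: int = DEFAULT_N_SAMPLES) -> SquatCycle:
    """Resample every channel onto n equally spaced points from onset to end;
    dt becomes duration/(n-1) for later time-step-dependent features."""
    if cycle.n < 2:
        raise ParameterError("cycle shorter than 2 samples cannot be time-normalized")
    grid = np.linspace(cycle.t[0], cycle.t[-1], n)
    channels = {name: np.interp(grid, cycle.t, y) for name, y in cycle.channels.items()}
    return replace(cycle, t=grid, dt=cycle.duration / (n - 1), channels=channels)


@dataclass
class NormalizationRecord:
    """Per-group, per-channel (min, max) used by min-max scaling; supports
    exact inversion back to physical units."""

    scope: str  # 'per_subject' | 'global'
    channel_names: tuple[str, ...]
    bounds: dict  # group key -> ndarray (C, 2) of [min, max]

    def invert(self, values: np.ndarray, subject) -> np.ndarray:
        key = subject if self.scope == "per_subject" else "__global__"
        b = self.bounds[key]
        lo, hi = b[:, 0], b[:, 1]
        return values * (hi - lo) + lo


def minmax_normalize(matrices: list[np.ndarray], subjects: list,
                     channel_names: tuple[str, ...],
                     scope: str = "per_subject") -> tuple[list[np.ndarray], NormalizationRecord]:
    """Scale each channel to [0, 1] using min/max pooled across all cycles of
    the scope group (per subject by default, preserving subject-specific
    biomechanics; 'global' pools all subjects).

    A constant channel maps to all zeros with a logged warning.
    """
    if scope not in ("per_subject", "global"):
        raise ParameterError(f"unknown scope {scope!r}")
    if not matrices:
        raise ParameterError("minmax_normalize requires at least one cycle")
    subjects = list(subjects)
    keys = subjects if scope == "per_subject" else ["__global__"] * len(matrices)
    bounds: dict = {}
    for key in set(keys):
        stack = np.concatenate([m for m, k in zip(matrices, keys) if k == key], axis=0)
        bounds[key] = np.stack([stack.min(axis=0), stack.max(axis=0)], axis=1)
    out = []
    warned = set()
    for m, key in zip(matrices, keys):
        b = bounds[key]
        lo, hi = b[:, 0], b[:, 1]
        span = hi - lo
        degenerate = span <= 0
        safe = np.where(degenerate, 1.0, span)
        scaled = (m - lo) / safe
        scaled[:, degenerate] = 0.0
        for ci in np.flatnonzero(degenerate):
            if (key, ci) not in warned:
                logger.warning("channel %r constant in group %r: set to 0",
                               channel_names[ci], key)
                warned.add((key, ci))
        out.append(scaled)
    return out, NormalizationRecord(scope=scope, channel_names=tuple(channel_names),
                                    bounds=bounds)
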