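"""Time-, pressure- and smoothness-related features of one test block.

Completion time is the elapsed time of the block; it splits into execution
time (total pen-down time, the pen actually drawing) and preparation or
"thinking" time (total pen-up time — the tablet still tracks the hovering
pen, but pressure reads zero).  Writing-pressure summaries are taken over
pen-down samples only.  The smoothness index is based on jerk, the third
time-derivative of position: tremulous or ataxic movement raises it, while
smooth point-to-point reaching keeps it low.

Undefined features (e.g. pressure statistics of an all-pen-up trajectory)
are returned as NaN and propagate as missing values downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .core import Trajectory, segment_strokes

#: minimum resampled points a stroke needs for third central differences
_MIN_JERK_POINTS = 5


def completion_time(traj: Trajectory) -> float:
    """Elapsed time of the block: last timestamp minus first, in seconds."""
    return float(traj.t[-1] - traj.t[0])


def pen_state_durations(traj: Trajectory) -> tuple[float, float]:
    """(preparation, execution) times in seconds.

    The interval between consecutive samples counts as pen-down iff the
    earlier sample has pressure > 0.  Execution is the pen-down total;
    preparation is the remainder of the completion time.
    """
    dt = np.diff(traj.t)
    execution = float(dt[traj.pressure[:-1] > 0].sum())
    preparation = completion_time(traj) - execution
    return preparation, execution


def time_difference(t_a2: float, t_b2: float) -> float:
    """Completion-time difference A2 − B2 (negative when B2 takes longer)."""
    return t_a2 - t_b2


def time_ratio(t_a2: float, t_b2: float) -> float:
    """Completion-time ratio A2 / B2.

    A zero denominator (a block recorded as not completed) is replaced by
    −1, yielding −A2 — a sentinel convention that keeps the feature finite.
    """
    if t_b2 == 0:
        return t_a2 / -1.0
    return t_a2 / t_b2


def pressure_summary(traj: Trajectory) -> tuple[float, float, float]:
    """(mean, min, max) writing pressure over pen-down samples.

    Pen-up zeros are excluded: they encode pen state, not writing force.
    All-NaN triple if the pen never touched the paper.
    """
    p = traj.pressure[traj.pen_down]
    if len(p) == 0:
        return (np.nan, np.nan, np.nan)
    return (float(p.mean()), float(p.min()), float(p.max()))


def _stroke_jerk_rms(sx, sy, st, h):
    """RMS jerk magnitude of one stroke resampled to step ``h``.

    Returns None when the stroke is too short to support the five-point
    central stencil for the third derivative.
    """
    duration = st[-1] - st[0]
    # small slack keeps the grid length stable under fp noise in t
    n = int(np.floor(duration / h + 1e-9)) + 1
    if n < _MIN_JERK_POINTS:
        return None
    grid = st[0] + h * np.arange(n)
    gx = np.interp(grid, st, sx)
    gy = np.interp(grid, st, sy)
    # f''' ~ (f[i+2] - 2 f[i+1] + 2 f[i-1] - f[i-2]) / (2 h^3)
    stencil = np.array([1.0, -2.0, 0.0, 2.0, -1.0])
    jx = np.convolve(gx, stencil[::-1], mode="valid") / (2.0 * h**3)
    jy = np.convolve(gy, stencil[::-1], mode="valid") / (2.0 * h**3)
    mag2 = jx**2 + jy**2
    return float(np.sqrt(mag2.mean())), duration


def jerk_metric(traj: Trajectory) -> float:
    """Duration-weighted RMS jerk magnitude over the trajectory's strokes.

    Each stroke is resampled (linear interpolation) to a uniform grid at the
    trajectory's median sampling interval, differentiated three times with a
    central stencil, and summarized by the RMS of the jerk-vector magnitude;
    strokes shorter than five resampled points are skipped.  NaN when no
    stroke is long enough.
    """
    h = float(np.median(np.diff(traj.t)))
    vals, weights = [], []
    for s in segment_strokes(traj):
        out = _stroke_jerk_rms(s.x, s.y, s.t, h)
        if out is None:
            continue
        rms, duration = out
        vals.append(rms)
        weights.append(duration)
    if not vals:
        return np.nan
    return float(np.average(vals, weights=weights))


@dataclass
class BlockFeatures:
    """The per-block feature bundle (NaN marks an undefined feature)."""

    completion_time: float
    preparation_time: float
    execution_time: float
    pressure_mean: float
    pressure_min: float
    pressure_max: float
    jerk: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def block_features(traj: Trajectory) -> BlockFeatures:
    """Compute the full per-block bundle for one trajectory."""
    prep, execu = pen_state_durations(traj)
    pmean, pmin, pmax = pressure_summary(traj)
    return BlockFeatures(
        completion_time=completion_time(traj),
        preparation_time=prep,
        execution_time=execu,
        pressure_mean=pmean,
        pressure_min=pmin,
        pressure_max=pmax,
        jerk=jerk_metric(traj),
    )
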