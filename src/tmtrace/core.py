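"""Canonical data model for digitized pen trajectories.

An electromagnetic tablet under an A4 sheet reports ordered samples of
``(x, y, pressure, t)``: ``x`` in device units 0–21000, ``y`` in 0–29700
(210 x 297 mm at 100 units/mm), pen force ``pressure >= 0`` where zero means
the pen is lifted off the paper, and a timestamp in seconds.  A
:class:`Trajectory` is one subject drawing one test block; a :class:`Stroke`
is a maximal pen-down run within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

X_MAX = 21000.0
Y_MAX = 29700.0

PARTS = ("A", "B")
BLOCKS = (1, 2)
#: the four (part, block) keys of a complete assessment
BLOCK_KEYS = tuple((p, b) for p in PARTS for b in BLOCKS)

GROUPS = ("HC", "MCI", "AD")

#: examiner-interaction count fields accepted as metadata (never computed here)
INTERACTION_FIELDS = (
    "errors_A2",
    "errors_B2",
    "penup_warnings_A2",
    "penup_warnings_B2",
    "prompts_A2",
    "prompts_B2",
)


def block_key_str(part: str, block: int) -> str:
    return f"{part}{block}"


@dataclass
class Trajectory:
    """Ordered tablet samples for one subject x one test block.

    Arrays are parallel and share length ``n >= 2``; timestamps are strictly
    increasing (duplicate timestamps are collapsed at read time).
    """

    subject_id: str
    part: str
    block: int
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.pressure) == n):
            raise ValueError("sample arrays must have equal length")
        if n < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if self.part not in PARTS:
            raise ValueError(f"part must be one of {PARTS}, got {self.part!r}")
        if self.block not in BLOCKS:
            raise ValueError(f"block must be one of {BLOCKS}, got {self.block!r}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be nonnegative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def key(self) -> tuple[str, int]:
        return (self.part, self.block)

    @property
    def pen_down(self) -> np.ndarray:
        """Boolean mask of pen-down samples (pressure > 0)."""
        return self.pressure > 0

    def xy(self) -> np.ndarray:
        """Samples as an (n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def replace(self, **kwargs) -> "Trajectory":
        data = dict(
            subject_id=self.subject_id, part=self.part, block=self.block,
            x=self.x, y=self.y, pressure=self.pressure, t=self.t,
        )
        data.update(kwargs)
        return Trajectory(**data)

    def validate_bounds(self, strict: bool = True) -> "Trajectory":
        """Check tablet coordinate bounds.

        Strict mode raises; lenient mode returns a copy with coordinates
        clamped into the device range.
        """
        in_x = (self.x >= 0) & (self.x <= X_MAX)
        in_y = (self.y >= 0) & (self.y <= Y_MAX)
        if bool(np.all(in_x)) and bool(np.all(in_y)):
            return self
        if strict:
            i = int(np.flatnonzero(~(in_x & in_y))[0])
            raise ValueError(
                f"sample {i} of {self.subject_id}/{self.part}{self.block} "
                f"out of tablet bounds: ({self.x[i]}, {self.y[i]})"
            )
        return self.replace(x=np.clip(self.x, 0, X_MAX), y=np.clip(self.y, 0, Y_MAX))


@dataclass
class Stroke:
    """Maximal pen-down run: contiguous samples with pressure > 0."""

    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    t: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @property
    def start_t(self) -> float:
        return float(self.t[0])

    @property
    def end_t(self) -> float:
        return float(self.t[-1])

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def segment_strokes(traj: Trajectory) -> list[Stroke]:
    """Split a trajectory into maximal pen-down runs, ordered by time.

    Every pressure>0 sample belongs to exactly one stroke; pen-up samples
    (pressure == 0) belong to none.  A trajectory drawn entirely in the air
    yields an empty list.
    """
    down = traj.pen_down.astype(np.int8)
    edges = np.diff(np.concatenate([[0], down, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        Stroke(traj.x[s:e], traj.y[s:e], traj.pressure[s:e], traj.t[s:e])
        for s, e in zip(starts, ends)
    ]


@dataclass
class SubjectRecord:
    """One participant: trajectories per (part, block) plus metadata.

    ``group`` is the screening class (HC, MCI or AD) when known; sex is coded
    0 = female, 1 = male; age and education are in years.  Interaction counts
    are examiner-recorded (errors, prompts, pen-up warnings in blocks A2/B2)
    and accepted as input, never computed.
    """

    subject_id: str
    group: str | None = None
    sex: float | None = None
    age: float | None = None
    education: float | None = None
    trajectories: dict[tuple[str, int], Trajectory] = field(default_factory=dict)
    interaction_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for k in self.interaction_counts:
            if k not in INTERACTION_FIELDS:
                raise ValueError(f"unknown interaction count field {k!r}")
        for key, traj in self.trajectories.items():
            if key != traj.key:
                raise ValueError(f"trajectory under key {key} has key {traj.key}")

    def add_trajectory(self, traj: Trajectory) -> None:
        if traj.key in self.trajectories:
            raise ValueError(
                f"subject {self.subject_id} already has a trajectory for {traj.key}"
            )
        self.trajectories[traj.key] = traj


def records_equal(a: SubjectRecord, b: SubjectRecord, rtol: float = 0.0) -> bool:
    """Field-by-field equality of two records (exact by default)."""
    def _num_eq(u, v):
        if u is None and v is None:
            return True
        if u is None or v is None:
            return False
        if rtol == 0.0:
            return u == v or (math.isnan(u) and math.isnan(v))
        return math.isclose(u, v, rel_tol=rtol)

    if a.subject_id != b.subject_id or a.group != b.group:
        return False
    if not all(_num_eq(getattr(a, f), getattr(b, f)) for f in ("sex", "age", "education")):
        return False
    if a.interaction_counts != b.interaction_counts:
        return False
    if set(a.trajectories) != set(b.trajectories):
        return False
    for key, ta in a.trajectories.items():
        tb = b.trajectories[key]
        for arr in ("x", "y", "pressure", "t"):
            u, v = getattr(ta, arr), getattr(tb, arr)
            if len(u) != len(v):
                return False
            if rtol == 0.0:
                if not np.array_equal(u, v):
                    return False
            elif not np.allclose(u, v, rtol=rtol):
                return False
    return True
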