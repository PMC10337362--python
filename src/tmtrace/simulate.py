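"""Synthetic Shape Trail Test cohorts with known ground truth.

No public tablet-trajectory cohort exists for this task, so the simulator
generates the study's raw material: sheet layouts (numbered circle/square
targets on the tablet plane) and group-conditioned pen trajectories.  A
drawn segment between consecutive targets follows a minimum-jerk position
profile (the smoothness-optimal point-to-point reach, which has a closed
form and zero endpoint jerk cost), optionally corrupted by sinusoidal
tremor; before each target the pen may hover (pressure zero) for a
"thinking" pause.  Pen force is truncated-normal per sample.  Group
profiles (healthy control / mild cognitive impairment / Alzheimer disease)
differ in speed, pause length, pressure level, tremor and lapse rate, in
the directions clinical cohorts show: impairment slows drawing, lengthens
pauses, lowers pressure and adds tremor.

All timing is laid on an exact uniform sample grid, so the ground-truth
bookkeeping (total duration, total pause time) is exact to the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BLOCK_KEYS, X_MAX, Y_MAX, SubjectRecord, Trajectory


@dataclass
class SheetTarget:
    """One numbered target printed on the sheet."""

    label: int
    shape: str  # 'circle' | 'square'
    cx: float
    cy: float
    radius: float


@dataclass
class SheetLayout:
    """Targets of one (part, block) sheet plus the correct visiting order."""

    part: str
    block: int
    targets: list[SheetTarget]
    visiting_order: list[int]  # indices into targets

    def ordered_centers(self) -> np.ndarray:
        return np.array(
            [[self.targets[i].cx, self.targets[i].cy] for i in self.visiting_order]
        )


@dataclass
class GroupProfile:
    """Generative parameters of one screening group.

    Units: speeds in device units/s (100 units = 1 mm), times in seconds,
    pressure in device units, tremor amplitude in device units, frequency
    in Hz.  ``lapse_prob`` is the chance of an extra long hesitation before
    a target.
    """

    move_speed_mean: float = 9000.0
    pause_mean: float = 0.15
    pause_sd: float = 0.05
    pressure_mean: float = 1650.0
    pressure_sd: float = 120.0
    tremor_amplitude: float = 15.0
    tremor_freq: float = 5.0
    sample_rate: float = 50.0
    lapse_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.move_speed_mean <= 0:
            raise ValueError("move_speed_mean must be positive")
        for f in ("pause_mean", "pause_sd", "pressure_mean", "pressure_sd",
                  "tremor_amplitude", "tremor_freq", "lapse_prob"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


#: shipped group profiles: ordered HC < MCI < AD in completion time and
#: AD < MCI < HC in writing pressure, mirroring the direction of clinical
#: group differences; magnitudes are the simulator's own choices.
DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "HC": GroupProfile(),
    "MCI": GroupProfile(
        move_speed_mean=6200.0, pause_mean=0.55, pause_sd=0.20,
        pressure_mean=1380.0, pressure_sd=150.0,
        tremor_amplitude=30.0, tremor_freq=5.5, lapse_prob=0.08,
    ),
    "AD": GroupProfile(
        move_speed_mean=4200.0, pause_mean=1.10, pause_sd=0.40,
        pressure_mean=900.0, pressure_sd=180.0,
        tremor_amplitude=45.0, tremor_freq=6.0, lapse_prob=0.20,
    ),
}


@dataclass
class GroundTruth:
    """Programmed quantities of one simulated trajectory."""

    subject_id: str
    part: str
    block: int
    total_duration: float
    total_pause_time: float
    pressure_mean_programmed: float
    pressure_sd_programmed: float
    n_pen_down: int
    clean_x: np.ndarray = field(repr=False, default=None)
    clean_y: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# sheet layout
# ---------------------------------------------------------------------------

def _block_labels(block: int) -> int:
    return 8 if block == 1 else 25


def make_sheet_layout(part: str, block: int, seed: int = 0,
                      radius: float = 600.0, margin: float = 2000.0) -> SheetLayout:
    """Rejection-sample a non-overlapping target layout.

    Block 1 uses labels 1–8, block 2 labels 1–25.  Part A shows each label
    once (circles).  Part B shows every label twice — once circled, once in
    a square — except label 1, which appears only in a square; the correct
    visiting order alternates shapes anchored at that square (odd labels in
    squares, even labels in circles), the unvisited duplicates acting as
    distractors.  If placement fails, the target radius shrinks and
    placement restarts.
    """
    if part not in ("A", "B"):
        raise ValueError("part must be 'A' or 'B'")
    if block not in (1, 2):
        raise ValueError("block must be 1 or 2")
    n_labels = _block_labels(block)
    want: list[tuple[int, str]] = []
    if part == "A":
        want = [(lab, "circle") for lab in range(1, n_labels + 1)]
    else:
        want.append((1, "square"))
        for lab in range(2, n_labels + 1):
            want.append((lab, "circle"))
            want.append((lab, "square"))
    rng = np.random.default_rng(seed)
    r = radius
    for _shrink in range(6):
        placed: list[SheetTarget] = []
        ok = True
        for lab, shape in want:
            for _ in range(2000):
                cx = rng.uniform(margin, X_MAX - margin)
                cy = rng.uniform(margin, Y_MAX - margin)
                if all((cx - p.cx) ** 2 + (cy - p.cy) ** 2 > (2.2 * r) ** 2
                       for p in placed):
                    placed.append(SheetTarget(lab, shape, cx, cy, r))
                    break
            else:
                ok = False
                break
        if ok:
            break
        r *= 0.8
    else:
        raise RuntimeError("could not place targets without overlap")

    if part == "A":
        order_spec = [(lab, "circle") for lab in range(1, n_labels + 1)]
    else:
        order_spec = [
            (lab, "square" if lab % 2 == 1 else "circle")
            for lab in range(1, n_labels + 1)
        ]
    index = {(tg.label, tg.shape): i for i, tg in enumerate(placed)}
    visiting = [index[key] for key in order_spec]
    return SheetLayout(part=part, block=block, targets=placed, visiting_order=visiting)


def make_sheet_layouts(seed: int = 0, **kwargs) -> dict[tuple[str, int], SheetLayout]:
    """One layout per (part, block), each with its own derived seed."""
    return {
        (part, block): make_sheet_layout(part, block, seed=seed * 4 + i, **kwargs)
        for i, (part, block) in enumerate(BLOCK_KEYS)
    }


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

def _min_jerk_profile(n: int) -> np.ndarray:
    """Normalized minimum-jerk position profile at n interior grid points
    (tau in (0, 1]): s = 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _trunc_normal(rng, mean, sd, low, size=None):
    v = rng.normal(mean, sd, size=size)
    return np.maximum(v, low)


def simulate_trajectory(layout: SheetLayout, profile: GroupProfile, seed: int = 0,
                        subject_id: str = "sim") -> tuple[Trajectory, GroundTruth]:
    """Draw one block: hover-pause then minimum-jerk reach per target pair.

    Pauses are rounded to whole sample intervals and drawn with pressure 0
    at the hover position, so total pause time is exact in the ground
    truth; tremor adds a fixed-frequency sinusoid (random phase per axis)
    to the drawn path only.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / profile.sample_rate
    centers = layout.ordered_centers()
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=2)

    xs = [centers[0, 0]]
    ys = [centers[0, 1]]
    press = [_trunc_normal(rng, profile.pressure_mean, profile.pressure_sd, 1.0)]
    clean_x = [centers[0, 0]]
    clean_y = [centers[0, 1]]
    n_pause_samples = 0

    for a, b in zip(centers[:-1], centers[1:]):
        # hover pause before heading to the next target
        pause = _trunc_normal(rng, profile.pause_mean, profile.pause_sd, 0.0)
        if rng.uniform() < profile.lapse_prob:
            pause += 5.0 * max(profile.pause_mean, 0.2)
        k = int(round(pause / dt))
        if k > 0:
            xs.extend([xs[-1]] * k)
            ys.extend([ys[-1]] * k)
            clean_x.extend([clean_x[-1]] * k)
            clean_y.extend([clean_y[-1]] * k)
            press.extend([0.0] * k)
            n_pause_samples += k
        # minimum-jerk reach
        dist = float(np.hypot(*(b - a)))
        duration = max(dist / profile.move_speed_mean, 4 * dt)
        m = max(int(round(duration / dt)), 2)
        s = _min_jerk_profile(m)
        seg_x = a[0] + (b[0] - a[0]) * s
        seg_y = a[1] + (b[1] - a[1]) * s
        clean_x.extend(seg_x)
        clean_y.extend(seg_y)
        t_seg = dt * np.arange(len(xs), len(xs) + m)
        if profile.tremor_amplitude > 0:
            w = 2 * np.pi * profile.tremor_freq
            seg_x = seg_x + profile.tremor_amplitude * np.sin(w * t_seg + phase_x)
            seg_y = seg_y + profile.tremor_amplitude * np.sin(w * t_seg + phase_y)
        xs.extend(seg_x)
        ys.extend(seg_y)
        press.extend(_trunc_normal(rng, profile.pressure_mean, profile.pressure_sd,
                                   1.0, size=m))

    n = len(xs)
    traj = Trajectory(
        subject_id=subject_id,
        part=layout.part,
        block=layout.block,
        x=np.clip(xs, 0, X_MAX),
        y=np.clip(ys, 0, Y_MAX),
        pressure=np.asarray(press),
        t=dt * np.arange(n),
    )
    gt = GroundTruth(
        subject_id=subject_id,
        part=layout.part,
        block=layout.block,
        total_duration=dt * (n - 1),
        total_pause_time=dt * n_pause_samples,
        pressure_mean_programmed=profile.pressure_mean,
        pressure_sd_programmed=profile.pressure_sd,
        n_pen_down=int(np.sum(np.asarray(press) > 0)),
        clean_x=np.asarray(clean_x),
        clean_y=np.asarray(clean_y),
    )
    return traj, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: demographic sampling per group: (age mean, age sd, education mean, education sd)
_DEMOGRAPHICS = {
    "HC": (70.0, 7.0, 12.5, 3.5),
    "MCI": (72.5, 7.5, 10.0, 4.0),
    "AD": (72.5, 8.5, 8.3, 5.0),
}

#: Poisson rates for optional examiner-interaction counts, per group
_INTERACTION_RATES = {
    "HC": {"errors_A2": 0.05, "errors_B2": 0.4, "penup_warnings_A2": 0.7,
           "penup_warnings_B2": 1.0, "prompts_A2": 0.05, "prompts_B2": 1.4},
    "MCI": {"errors_A2": 0.15, "errors_B2": 1.1, "penup_warnings_A2": 1.2,
            "penup_warnings_B2": 1.6, "prompts_A2": 0.3, "prompts_B2": 3.0},
    "AD": {"errors_A2": 0.25, "errors_B2": 0.55, "penup_warnings_A2": 2.6,
           "penup_warnings_B2": 1.5, "prompts_A2": 1.5, "prompts_B2": 2.7},
}


def _jitter_profile(profile: GroupProfile, rng) -> GroupProfile:
    """Subject-level random effects: lognormal multipliers on speed, pause
    and pressure so subjects within a group differ but stay ordered."""
    return replace(
        profile,
        move_speed_mean=profile.move_speed_mean * rng.lognormal(0.0, 0.10),
        pause_mean=profile.pause_mean * rng.lognormal(0.0, 0.15),
        pressure_mean=profile.pressure_mean * rng.lognormal(0.0, 0.06),
        tremor_amplitude=profile.tremor_amplitude * rng.lognormal(0.0, 0.15),
    )


def simulate_cohort(
    n_per_group: dict[str, int],
    profiles: dict[str, GroupProfile] | None = None,
    seed: int = 0,
    layouts: dict[tuple[str, int], SheetLayout] | None = None,
    simulate_errors: bool = False,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a labelled cohort: four blocks (A1, A2, B1, B2) per subject.

    All subjects draw the same sheets (as in a real administration).  Each
    subject gets a jittered copy of the group profile.  Returns the records
    plus a ground-truth table (one row per subject x block).  Deterministic
    for a fixed seed.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    for g in n_per_group:
        if g not in profiles:
            raise ValueError(f"no profile for group {g!r}")
    if layouts is None:
        layouts = make_sheet_layouts(seed=seed)
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    gt_rows = []
    for group in sorted(n_per_group):
        for i in range(n_per_group[group]):
            sid = f"{group}{i:03d}"
            sub_rng = np.random.default_rng(
                int(rng.integers(0, 2**31 - 1))
            )
            prof = _jitter_profile(profiles[group], sub_rng)
            age_m, age_s, edu_m, edu_s = _DEMOGRAPHICS.get(group, (71.0, 8.0, 10.0, 4.0))
            rec = SubjectRecord(
                subject_id=sid,
                group=group,
                sex=float(sub_rng.integers(0, 2)),
                age=float(np.round(sub_rng.normal(age_m, age_s), 1)),
                education=float(np.clip(np.round(sub_rng.normal(edu_m, edu_s)), 0, 22)),
            )
            if simulate_errors:
                rates = _INTERACTION_RATES.get(group, _INTERACTION_RATES["HC"])
                rec.interaction_counts = {
                    k: int(sub_rng.poisson(lam)) for k, lam in rates.items()
                }
            else:
                rec.interaction_counts = {k: 0 for k in _INTERACTION_RATES["HC"]}
            for key in BLOCK_KEYS:
                traj, gt = simulate_trajectory(
                    layouts[key], prof,
                    seed=int(sub_rng.integers(0, 2**31 - 1)),
                    subject_id=sid,
                )
                rec.add_trajectory(traj)
                gt_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "part": gt.part,
                        "block": gt.block,
                        "total_duration": gt.total_duration,
                        "total_pause_time": gt.total_pause_time,
                        "pressure_mean_programmed": gt.pressure_mean_programmed,
                        "pressure_sd_programmed": gt.pressure_sd_programmed,
                        "n_pen_down": gt.n_pen_down,
                    }
                )
            records.append(rec)
    return records, pd.DataFrame(gt_rows)
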