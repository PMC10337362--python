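"""Per-block kinematic features of a single simulated trajectory.

Completion time splits exactly into execution (pen-down) and preparation
(pen-up) time; pressure statistics cover pen-down samples only; the jerk
metric is the duration-weighted RMS magnitude of the third derivative of
pen position — near zero for smooth motion, rising with tremor.
"""

from tmtrace import block_features, segment_strokes, simulate_cohort

records, _ = simulate_cohort({"HC": 1, "AD": 1}, seed=7)

for rec in records:
    traj = rec.trajectories[("A", 2)]
    bf = block_features(traj)
    strokes = segment_strokes(traj)
    print(f"\n{rec.group} subject, part A block 2 "
          f"({len(traj)} samples, {len(strokes)} strokes):")
    print(f"  completion {bf.completion_time:7.2f} s = "
          f"execution {bf.execution_time:.2f} s + preparation {bf.preparation_time:.2f} s")
    print(f"  pressure mean/min/max: {bf.pressure_mean:7.1f} / "
          f"{bf.pressure_min:6.1f} / {bf.pressure_max:6.1f} device units")
    print(f"  jerk smoothness index: {bf.jerk:11.0f} units/s^3")

print(
    "\nThe impaired subject takes longer, pauses more, and presses more"
    "\nlightly.  Jerk mixes two effects — faster strokes raise the smooth"
    "\nbaseline, tremor raises it further — so its group separation is much"
    "\nweaker than the time and pressure families."
)
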