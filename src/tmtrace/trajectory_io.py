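"""Reading and writing tablet trajectory streams.

Two on-disk dialects are supported:

``delimited-samples``
    A flat CSV with header ``subject_id,part,block,x,y,pressure,t``, one
    tablet sample per row.  Subject metadata (group label, demographics,
    examiner-interaction counts) travels in an optional companion CSV keyed
    by ``subject_id``.

``structured-records``
    One JSON document holding a list of subjects, each with metadata plus
    per-block sample arrays.  This dialect is self-contained.

Raw device timestamps are normalized to seconds at read time via
``time_unit`` (seconds per raw unit, default 1.0).  Duplicate timestamps are
collapsed keeping the first sample; a timestamp that *decreases* is a
validation error in strict mode and is dropped (with a log message) in
lenient mode.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    INTERACTION_FIELDS,
    SubjectRecord,
    Trajectory,
)

logger = logging.getLogger(__name__)

DIALECTS = ("delimited-samples", "structured-records")

SAMPLE_COLUMNS = ["subject_id", "part", "block", "x", "y", "pressure", "t"]
METADATA_COLUMNS = ["subject_id", "group", "sex", "age", "education", *INTERACTION_FIELDS]


class TrajectoryParseError(ValueError):
    """Malformed input file; the message names the offending row."""


def _clean_time_series(sub: pd.DataFrame, strict: bool, label: str) -> pd.DataFrame:
    """Collapse duplicate timestamps (keep first); reject/drop decreasing ones."""
    t = sub["t"].to_numpy()
    keep = np.ones(len(t), dtype=bool)
    t_max = -np.inf
    for i, ti in enumerate(t):
        if ti > t_max:
            t_max = ti
        elif ti == t_max:
            keep[i] = False  # duplicate: keep first occurrence
        else:
            if strict:
                row = sub.index[i]
                raise TrajectoryParseError(
                    f"{label}: non-monotone timestamp at input row {row} (t={ti})"
                )
            keep[i] = False
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d duplicate/out-of-order samples", label, n_dropped)
    return sub.loc[keep]


def _finish_record(rec: SubjectRecord, strict: bool) -> SubjectRecord:
    rec.trajectories = {
        k: traj.validate_bounds(strict=strict) for k, traj in rec.trajectories.items()
    }
    return rec


def read_trajectories(
    path: str | Path,
    dialect: str = "delimited-samples",
    strict: bool = True,
    metadata: str | Path | None = None,
    time_unit: float = 1.0,
) -> list[SubjectRecord]:
    """Read subject records from *path*.

    Parameters
    ----------
    dialect:
        ``delimited-samples`` or ``structured-records``.
    strict:
        Strict mode raises on out-of-bounds coordinates and decreasing
        timestamps; lenient mode clamps/drops and logs.
    metadata:
        Optional companion metadata CSV (delimited dialect only).
    time_unit:
        Seconds per raw device time unit.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "delimited-samples":
        return _read_delimited(path, strict, metadata, time_unit)
    return _read_structured(path, strict, time_unit)


def _read_delimited(path, strict, metadata, time_unit):
    # round_trip parsing keeps write -> read bit-identical on float fields
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing required column(s) {missing}")
    meta = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata)
        if "subject_id" not in mdf.columns:
            raise TrajectoryParseError(f"{metadata}: missing required column subject_id")
        meta = {str(r["subject_id"]): r for _, r in mdf.iterrows()}

    records: dict[str, SubjectRecord] = {}
    for (sid, part, block), sub in df.groupby(
        ["subject_id", "part", "block"], sort=False
    ):
        sid = str(sid)
        label = f"{path.name}:{sid}/{part}{block}"
        sub = _clean_time_series(sub, strict, label)
        if len(sub) < 2:
            raise TrajectoryParseError(f"{label}: fewer than 2 valid samples")
        traj = Trajectory(
            subject_id=sid,
            part=str(part),
            block=int(block),
            x=sub["x"].to_numpy(float),
            y=sub["y"].to_numpy(float),
            pressure=sub["pressure"].to_numpy(float),
            t=sub["t"].to_numpy(float) * time_unit,
        )
        rec = records.setdefault(sid, SubjectRecord(subject_id=sid))
        rec.add_trajectory(traj)

    for sid, rec in records.items():
        if sid in meta:
            row = meta[sid]
            for attr in ("group",):
                v = row.get(attr)
                if isinstance(v, str) and v:
                    rec.group = v
            for attr in ("sex", "age", "education"):
                v = row.get(attr)
                if v is not None and pd.notna(v):
                    setattr(rec, attr, float(v))
            counts = {
                f: int(row[f])
                for f in INTERACTION_FIELDS
                if f in row and pd.notna(row[f])
            }
            rec.interaction_counts = counts
    return [_finish_record(r, strict) for r in records.values()]


def _read_structured(path, strict, time_unit):
    with open(path) as fh:
        doc = json.load(fh)
    records = []
    for entry in doc["subjects"]:
        rec = SubjectRecord(
            subject_id=str(entry["subject_id"]),
            group=entry.get("group"),
            sex=entry.get("sex"),
            age=entry.get("age"),
            education=entry.get("education"),
            interaction_counts={
                k: int(v) for k, v in entry.get("interaction_counts", {}).items()
            },
        )
        for blk in entry.get("blocks", []):
            label = f"{path.name}:{rec.subject_id}/{blk['part']}{blk['block']}"
            sub = pd.DataFrame(
                {
                    "x": blk["x"],
                    "y": blk["y"],
                    "pressure": blk["pressure"],
                    "t": blk["t"],
                }
            )
            sub = _clean_time_series(sub, strict, label)
            if len(sub) < 2:
                raise TrajectoryParseError(f"{label}: fewer than 2 valid samples")
            rec.add_trajectory(
                Trajectory(
                    subject_id=rec.subject_id,
                    part=str(blk["part"]),
                    block=int(blk["block"]),
                    x=sub["x"].to_numpy(float),
                    y=sub["y"].to_numpy(float),
                    pressure=sub["pressure"].to_numpy(float),
                    t=sub["t"].to_numpy(float) * time_unit,
                )
            )
        records.append(_finish_record(rec, strict))
    return records


def write_trajectories(
    records: list[SubjectRecord],
    path: str | Path,
    dialect: str = "delimited-samples",
    metadata: str | Path | None = None,
) -> None:
    """Write records so that :func:`read_trajectories` reproduces them
    with bit-identical numeric fields."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "delimited-samples":
        _write_delimited(records, path, metadata)
    else:
        _write_structured(records, path)


def _fmt(v: float) -> str:
    return repr(float(v))


def _write_delimited(records, path, metadata):
    with open(path, "w") as fh:
        fh.write(",".join(SAMPLE_COLUMNS) + "\n")
        for rec in records:
            for (part, block), traj in sorted(rec.trajectories.items()):
                for xi, yi, pi, ti in zip(traj.x, traj.y, traj.pressure, traj.t):
                    fh.write(
                        f"{rec.subject_id},{part},{block},"
                        f"{_fmt(xi)},{_fmt(yi)},{_fmt(pi)},{_fmt(ti)}\n"
                    )
    if metadata is not None:
        rows = []
        for rec in records:
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "sex": rec.sex,
                "age": rec.age,
                "education": rec.education,
            }
            row.update({f: rec.interaction_counts.get(f) for f in INTERACTION_FIELDS})
            rows.append(row)
        pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata, index=False)


def _write_structured(records, path):
    doc = {"subjects": []}
    for rec in records:
        entry = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "sex": rec.sex,
            "age": rec.age,
            "education": rec.education,
            "interaction_counts": rec.interaction_counts,
            "blocks": [],
        }
        for (part, block), traj in sorted(rec.trajectories.items()):
            entry["blocks"].append(
                {
                    "part": part,
                    "block": block,
                    "x": traj.x.tolist(),
                    "y": traj.y.tolist(),
                    "pressure": traj.pressure.tolist(),
                    "t": traj.t.tolist(),
                }
            )
        doc["subjects"].append(entry)
    with open(path, "w") as fh:
        json.dump(doc, fh)
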