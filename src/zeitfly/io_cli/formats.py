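"""Plain-text file formats: trajectory CSV, Trikinetics-style monitor TXT.

Trajectory dialect: header ``fly_id,chamber_id,t_s,x_mm,y_mm,detected``;
``t_s`` integer seconds with unit step; undetected samples leave x/y empty
with detected=0; UTF-8, LF line endings.  Floats are written with shortest
round-trip repr so write -> read -> write is byte-identical.

Monitor files follow the DAM2 layout: one tab-delimited line per minute with
record index, date (``d mon yy``), time (``HH:MM:SS``), a status column and
six auxiliary zero fields, then 32 integer channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from ..dam_emulation import BeamCountSeries
from ..tracking import Trajectory

__all__ = [
    "MonitorFile",
    "TrajectoryFormatError",
    "monitor_from_series",
    "read_monitor",
    "read_trajectory",
    "series_from_monitor",
    "write_monitor",
    "write_trajectory",
]

TRAJ_HEADER = "fly_id,chamber_id,t_s,x_mm,y_mm,detected"
_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; message carries the offending line number."""


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    lines = [TRAJ_HEADER]
    for i in range(len(traj)):
        if traj.detected[i]:
            x = repr(float(traj.x_mm[i]))
            y = repr(float(traj.y_mm[i]))
            det = "1"
        else:
            x = y = ""
            det = "0"
        lines.append(f"{traj.fly_id},{traj.chamber_id},{int(traj.t[i])},{x},{y},{det}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_trajectory(
    path: Union[str, Path], body_length_mm: float = 2.5
) -> Trajectory:
    """Parse one single-fly trajectory file; report malformed rows by line.

    The dialect carries no body length; callers supply it (default 2.5 mm).
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0] != TRAJ_HEADER:
        raise TrajectoryFormatError(
            f"{path}:1: expected header {TRAJ_HEADER!r}, got {lines[0] if lines else ''!r}"
        )
    fly_id = chamber_id = None
    ts: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    det: list[bool] = []
    prev_t: Optional[int] = None
    for ln, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise TrajectoryFormatError(f"{path}:{ln}: expected 6 fields, got {len(parts)}")
        fid, cid, t_s, x_s, y_s, d_s = parts
        if fly_id is None:
            fly_id, chamber_id = fid, cid
        elif fid != fly_id:
            raise TrajectoryFormatError(
                f"{path}:{ln}: multiple fly_ids in one file ({fly_id!r}, {fid!r})"
            )
        try:
            t = int(t_s)
        except ValueError:
            raise TrajectoryFormatError(f"{path}:{ln}: bad t_s {t_s!r}") from None
        if prev_t is not None and t != prev_t + 1:
            kind = "duplicated" if t == prev_t else "non-monotone"
            raise TrajectoryFormatError(f"{path}:{ln}: {kind} t_s {t}")
        prev_t = t
        ts.append(t)
        if d_s == "1":
            try:
                xs.append(float(x_s))
                ys.append(float(y_s))
            except ValueError:
                raise TrajectoryFormatError(f"{path}:{ln}: bad coordinates") from None
            det.append(True)
        elif d_s == "0":
            xs.append(np.nan)
            ys.append(np.nan)
            det.append(False)
        else:
            raise TrajectoryFormatError(f"{path}:{ln}: detected must be 0 or 1")
    if fly_id is None:
        raise TrajectoryFormatError(f"{path}: no data rows")
    return Trajectory(
        fly_id,
        chamber_id,
        np.asarray(ts),
        np.asarray(xs),
        np.asarray(ys),
        np.asarray(det),
        body_length_mm=body_length_mm,
    )


@dataclass
class MonitorFile:
    """In-memory DAM monitor: per-minute counts for 32 channels."""

    counts: np.ndarray  # (n_minutes, 32)
    start: datetime

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 32:
            raise ValueError("counts must be (n_minutes, 32)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


def monitor_from_series(
    series: Sequence[BeamCountSeries],
    start: Optional[datetime] = None,
) -> MonitorFile:
    """Pack emulated flies into channels 1..n; unused channels stay zero."""
    if not (1 <= len(series) <= 32):
        raise ValueError("need between 1 and 32 channels")
    n_min = max(len(s) for s in series)
    counts = np.zeros((n_min, 32), dtype=np.int64)
    for ch, s in enumerate(series):
        counts[: len(s), ch] = s.counts
    return MonitorFile(counts, start or datetime(2022, 1, 1, 0, 0, 0))


def series_from_monitor(monitor: MonitorFile, channel: int) -> BeamCountSeries:
    col = monitor.counts[:, channel]
    return BeamCountSeries(col, np.ones(len(col), dtype=bool))


def write_monitor(monitor: MonitorFile, path: Union[str, Path]) -> None:
    lines = []
    for i, row in enumerate(monitor.counts):
        ts = monitor.start + timedelta(minutes=i)
        date = f"{ts.day} {_MONTHS[ts.month - 1]} {ts.strftime('%y')}"
        fields = [str(i + 1), date, ts.strftime("%H:%M:%S"), "1"] + ["0"] * 6
        fields += [str(int(c)) for c in row]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_monitor(path: Union[str, Path]) -> MonitorFile:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = []
    start: Optional[datetime] = None
    for ln, line in enumerate(lines, start=1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 42:
            raise ValueError(f"{path}:{ln}: ragged line ({len(parts)} fields, expected 42)")
        if start is None:
            day_s, mon_s, yy_s = parts[1].split(" ")
            hh, mm, ss = parts[2].split(":")
            start = datetime(
                2000 + int(yy_s),
                _MONTHS.index(mon_s) + 1,
                int(day_s),
                int(hh),
                int(mm),
                int(ss),
            )
        rows.append([int(v) for v in parts[10:]])
    if start is None:
        raise ValueError(f"{path}: empty monitor file")
    return MonitorFile(np.asarray(rows, dtype=np.int64), start)
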