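"""Virtual single-infrared-beam (DAM-style) monitor.

A crossing is counted at second t when the fly's x position changes side of
the beam between consecutive detected samples; counts aggregate per minute.
DAM sleep is the standard monitor convention: maximal runs of zero-count
minutes lasting >= 5 minutes.  Because a stationary fly never crosses, any
supra-threshold movement that stays on one side of the beam is invisible to
the monitor — the sleep-overestimation bias this module exists to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as zstats
from .metrics import (
    LDSchedule,
    SleepRecord,
    displacement_series,
    morning_anticipation_index,
    score_sleep,
)
from .tracking import ChamberGeometry, Trajectory

__all__ = [
    "BeamCountSeries",
    "beam_counts",
    "compare_systems",
    "dam_mai",
    "dam_sleep",
]

GAP_BREAK_S = 5  # undetected gaps longer than this break DAM zero-runs


@dataclass
class BeamCountSeries:
    """Per-minute nonnegative integer crossing counts aligned to experiment t=0.

    Minute m covers steps landing at seconds (60m, 60(m+1)].  ``valid`` is
    False where a detection gap longer than :data:`GAP_BREAK_S` touches the
    minute; such minutes never extend a DAM sleep run.
    """

    counts: np.ndarray
    valid: np.ndarray
    t0_s: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.counts) != len(self.valid):
            raise ValueError("counts and valid must share one length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.counts)


def beam_counts(
    traj: Trajectory, geometry: ChamberGeometry, dead_band_mm: float = 0.0
) -> BeamCountSeries:
    """Count beam crossings per minute from a 1 Hz trajectory.

    A crossing at step t requires both samples detected and the x coordinate
    on strictly opposite sides of the beam (outside the optional dead band).
    """
    beam = geometry.beam_x()
    s = traj.x_mm - beam
    both = traj.detected[1:] & traj.detected[:-1]
    prev, curr = s[:-1], s[1:]
    crossing = both & (
        ((prev < -dead_band_mm) & (curr > dead_band_mm))
        | ((prev > dead_band_mm) & (curr < -dead_band_mm))
    )
    n_steps = len(traj) - 1
    n_minutes = int(np.ceil(n_steps / 60.0))
    step_minute = (traj.t[1:] - traj.t[0] - 1) // 60
    counts = np.bincount(step_minute[crossing], minlength=n_minutes)

    valid = np.ones(n_minutes, dtype=bool)
    und = ~traj.detected
    if und.any():
        edges = np.diff(np.concatenate(([0], und.astype(np.int8), [0])))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        for i0, i1 in zip(starts, ends):
            if i1 - i0 > GAP_BREAK_S:
                m0 = max(0, (i0 - 1) // 60)
                m1 = min(n_minutes, (i1 - 1) // 60 + 1)
                valid[m0:m1] = False
    return BeamCountSeries(counts, valid, t0_s=int(traj.t[0]))


def dam_sleep(counts: BeamCountSeries) -> SleepRecord:
    """Maximal runs of zero-count valid minutes, >= 5 min, become bouts."""
    quiet = (counts.counts == 0) & counts.valid
    if not quiet.any():
        return SleepRecord([])
    q = quiet.astype(np.int8)
    edges = np.diff(np.concatenate(([0], q, [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    bouts = []
    for m0, m1 in zip(starts, ends):
        if m1 - m0 >= 5:
            bouts.append((counts.t0_s + 60 * int(m0), counts.t0_s + 60 * int(m1)))
    return SleepRecord(bouts)


def dam_mai(
    counts: BeamCountSeries, schedule: LDSchedule, day: int
) -> Optional[float]:
    """MAI computed from beam counts: ZT21-24 crossings over ZT18-24 crossings."""
    w18, w24 = schedule.window(day, 18.0, 24.0)
    w21, _ = schedule.window(day, 21.0, 24.0)
    minute_start = counts.t0_s + 60 * np.arange(len(counts))
    in18 = (minute_start >= w18) & (minute_start < w24)
    in21 = (minute_start >= w21) & (minute_start < w24)
    denom = counts.counts[in18].sum()
    if denom == 0:
        return None
    return float(counts.counts[in21].sum() / denom)


def compare_systems(
    trajectories: Sequence[Trajectory],
    geometry: ChamberGeometry,
    schedule: Optional[LDSchedule] = None,
    n_days: Optional[int] = None,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Paired video-vs-beam metrics per fly per day, plus the test battery.

    Both metric sets come from the same trajectories.  Returns a long-format
    table (fly_id, day, video/dam sleep minutes and MAI) and a dict with the
    Scheirer-Ray-Hare system x day test on sleep and per-day paired Wilcoxon
    p-values BH-corrected over days.
    """
    if len(trajectories) < 2:
        raise ValueError("need >= 2 flies for a system comparison")
    schedule = schedule or LDSchedule()
    if n_days is None:
        n_days = max(
            int(schedule.day_index(traj.t[-1] - 1)) + 1 for traj in trajectories
        )
        n_days = max(n_days, 1)

    rows = []
    for traj in trajectories:
        series = displacement_series(traj)
        video_rec = score_sleep(series, traj.body_length_mm)
        counts = beam_counts(traj, geometry)
        dam_rec = dam_sleep(counts)
        for day in range(n_days):
            d0, d1 = schedule.window(day, 0.0, schedule.period_h)
            v_sleep = sum(
                max(0, min(e, d1) - max(s, d0)) for s, e in video_rec.bouts
            )
            b_sleep = sum(
                max(0, min(e, d1) - max(s, d0)) for s, e in dam_rec.bouts
            )
            v_mai, _ = morning_anticipation_index(series, schedule, day)
            rows.append(
                {
                    "fly_id": traj.fly_id,
                    "day": day,
                    "video_sleep_min": v_sleep / 60.0,
                    "dam_sleep_min": b_sleep / 60.0,
                    "video_mai": v_mai,
                    "dam_mai": dam_mai(counts, schedule, day),
                }
            )
    table = pd.DataFrame(rows)

    srh = None
    if n_days >= 2:  # the system x day test needs >= 2 day levels
        long_vals = np.concatenate([table["video_sleep_min"], table["dam_sleep_min"]])
        long_sys = np.array(["video"] * len(table) + ["dam"] * len(table))
        long_day = np.concatenate([table["day"], table["day"]])
        srh = zstats.scheirer_ray_hare(long_vals, long_sys, long_day)

    by_day = [
        (
            table.loc[table["day"] == day, "dam_sleep_min"].to_numpy(),
            table.loc[table["day"] == day, "video_sleep_min"].to_numpy(),
        )
        for day in range(n_days)
    ]
    wilcoxon = zstats.wilcoxon_bh(by_day, paired=True)
    return table, {"scheirer_ray_hare": srh, "wilcoxon_bh_by_day": wilcoxon}
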