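"""Behavioral readouts: displacement activity, sleep, and morning anticipation.

Conventions
-----------
* A displacement sample at time ``t`` measures movement over ``(t-1, t]``;
  the series therefore starts one second after the trajectory does.
* Sleep: a maximal run of seconds whose displacement stays below one body
  length per second, lasting at least 300 s.  Invalid (undetected) seconds
  break runs — tracking dropouts never manufacture sleep.
* Zeitgeber time (ZT): hours since lights-on; ZT0 = lights-on, daytime is
  ZT0-12 in a 12:12 LD cycle.
* MAI: summed activity in ZT21-24 divided by summed activity in ZT18-24;
  0.5 under time-uniform activity, undefined when the denominator is zero or
  the day is incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tracking import Trajectory

__all__ = [
    "ActivitySeries",
    "BinnedProfile",
    "LDSchedule",
    "MAIResult",
    "SleepRecord",
    "SleepSummary",
    "average_activity_profile",
    "displacement_series",
    "mai_mean",
    "mai_result",
    "morning_anticipation_index",
    "score_sleep",
    "sleep_summary",
]

SLEEP_MIN_S = 300  # five consecutive minutes of quiescence


@dataclass(frozen=True)
class LDSchedule:
    """Maps experiment seconds to Zeitgeber time and day index.

    ``lights_on_offset_s`` is the experiment time of the first lights-on;
    samples before it fall on day -1.
    """

    lights_on_offset_s: int = 0
    photoperiod_h: float = 12.0
    period_h: float = 24.0

    def __post_init__(self) -> None:
        if not (0.0 < self.photoperiod_h < self.period_h):
            raise ValueError("need 0 < photoperiod_h < period_h")

    @property
    def period_s(self) -> int:
        return int(round(self.period_h * 3600))

    def zt_hours(self, t_s):
        t = np.asarray(t_s, dtype=float)
        return ((t - self.lights_on_offset_s) / 3600.0) % self.period_h

    def day_index(self, t_s):
        t = np.asarray(t_s, dtype=float)
        return np.floor((t - self.lights_on_offset_s) / self.period_s).astype(int)

    def is_light(self, t_s):
        return self.zt_hours(t_s) < self.photoperiod_h

    def window(self, day: int, zt_start: float, zt_end: float) -> tuple[int, int]:
        """Absolute-second half-open window [start, end) for a ZT interval."""
        base = self.lights_on_offset_s + day * self.period_s
        return base + int(round(zt_start * 3600)), base + int(round(zt_end * 3600))


@dataclass
class ActivitySeries:
    """Per-second displacement (mm/s); sample at t covers movement in (t-1, t]."""

    t: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.values) == len(self.valid)):
            raise ValueError("t, values, valid must share one length")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("activity values must be nonnegative")

    def __len__(self) -> int:
        return len(self.t)

    def total_distance(self) -> float:
        return float(self.values[self.valid].sum())


@dataclass
class SleepRecord:
    """Non-overlapping quiescence bouts ``(start_s, end_s)``, each >= 300 s."""

    bouts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.bouts:
            if end - start < SLEEP_MIN_S:
                raise ValueError(f"bout ({start}, {end}) shorter than {SLEEP_MIN_S}s")
            if prev_end is not None and start < prev_end:
                raise ValueError("bouts must be sorted and non-overlapping")
            prev_end = end

    def total_s(self) -> int:
        return sum(end - start for start, end in self.bouts)

    def __len__(self) -> int:
        return len(self.bouts)


@dataclass
class SleepSummary:
    daytime_min: float
    nighttime_min: float
    bout_count: int
    mean_bout_min: float
    binned_min: np.ndarray  # (n_days, n_bins) minutes asleep per ZT bin
    bin_width_min: int


@dataclass
class MAIResult:
    per_day: list[Optional[float]]
    mean3: Optional[float]
    reasons: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.per_day:
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("defined MAI values must lie in [0, 1]")


@dataclass
class BinnedProfile:
    """Cross-fly mean +/- SEM of per-fly day-averaged binned totals."""

    bin_width_min: int
    zt_bin_edges_h: np.ndarray
    per_fly: np.ndarray  # (n_flies, n_bins)
    mean: np.ndarray
    sem: np.ndarray


def displacement_series(traj: Trajectory) -> ActivitySeries:
    """Euclidean distance between consecutive detected positions, at 1 Hz."""
    if len(traj) < 2:
        raise ValueError("need at least 2 samples for a displacement series")
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    valid = traj.detected[1:] & traj.detected[:-1]
    values = np.hypot(dx, dy)
    values[~valid] = 0.0
    return ActivitySeries(traj.t[1:], values, valid)


def score_sleep(series: ActivitySeries, body_length_mm: float) -> SleepRecord:
    """Maximal runs of sub-threshold seconds lasting >= 300 s become bouts.

    Threshold: displacement strictly below one body length per second counts
    as quiescent.  A bout spanning samples t=a..b covers (a-1, b], i.e.
    ``(a-1, b)`` with duration ``b - (a-1)``.
    """
    if body_length_mm <= 0:
        raise ValueError("body_length_mm must be positive")
    quiescent = series.valid & (series.values < body_length_mm)
    if not quiescent.any():
        return SleepRecord([])
    q = quiescent.astype(np.int8)
    edges = np.diff(np.concatenate(([0], q, [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive sample index
    bouts = []
    for i0, i1 in zip(starts, ends):
        duration = i1 - i0  # number of quiescent seconds
        if duration >= SLEEP_MIN_S:
            bouts.append((int(series.t[i0] - 1), int(series.t[i1 - 1])))
    return SleepRecord(bouts)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def sleep_summary(
    record: SleepRecord,
    schedule: LDSchedule,
    n_days: Optional[int] = None,
    bin_width_min: int = 30,
) -> SleepSummary:
    """Daytime/nighttime totals (minutes), bout stats, and binned sleep.

    Bouts are split at ZT window boundaries before summation.
    """
    if n_days is None:
        n_days = 0
        if record.bouts:
            last = record.bouts[-1][1]
            n_days = int(schedule.day_index(last - 1)) + 1
        n_days = max(n_days, 1)
    day_s = night_s = 0
    n_bins = int(round(schedule.period_h * 60)) // bin_width_min
    binned = np.zeros((n_days, n_bins))
    bin_s = bin_width_min * 60
    for start, end in record.bouts:
        for day in range(n_days):
            l0, l1 = schedule.window(day, 0.0, schedule.photoperiod_h)
            d0, d1 = schedule.window(day, schedule.photoperiod_h, schedule.period_h)
            day_s += _overlap(start, end, l0, l1)
            night_s += _overlap(start, end, d0, d1)
            base = schedule.lights_on_offset_s + day * schedule.period_s
            for b in range(n_bins):
                binned[day, b] += _overlap(
                    start, end, base + b * bin_s, base + (b + 1) * bin_s
                )
    count = len(record.bouts)
    mean_bout = record.total_s() / count / 60.0 if count else 0.0
    return SleepSummary(
        daytime_min=day_s / 60.0,
        nighttime_min=night_s / 60.0,
        bout_count=count,
        mean_bout_min=mean_bout,
        binned_min=binned / 60.0,
        bin_width_min=bin_width_min,
    )


def _window_slice(series: ActivitySeries, start: int, end: int) -> np.ndarray:
    # sample at t covers (t-1, t]; include samples with start < t <= end
    return (series.t > start) & (series.t <= end)


def morning_anticipation_index(
    series: ActivitySeries,
    schedule: LDSchedule,
    day: int,
    completeness: float = 0.95,
) -> tuple[Optional[float], Optional[str]]:
    """MAI = sum of activity over ZT21-24 / sum over ZT18-24 for one day.

    Returns ``(value, None)`` or ``(None, reason)`` when the day is
    incomplete (valid coverage of ZT18-24 below ``completeness``) or the
    denominator is zero.
    """
    w18, w24 = schedule.window(day, 18.0, 24.0)
    w21, _ = schedule.window(day, 21.0, 24.0)
    sel = _window_slice(series, w18, w24)
    expected = w24 - w18
    n_valid = int((series.valid & sel).sum())
    if sel.sum() < expected or n_valid < completeness * expected:
        return None, f"incomplete day {day}: {n_valid}/{expected} valid seconds"
    use = sel & series.valid
    denom = float(series.values[use].sum())
    if denom == 0.0:
        return None, f"zero activity in ZT18-24 of day {day}"
    num = float(series.values[use & (series.t > w21)].sum())
    return num / denom, None


def mai_mean(per_day: Sequence[Optional[float]]) -> float:
    """Mean of the first three defined complete-day MAI values."""
    defined = [v for v in per_day if v is not None]
    if len(defined) < 3:
        usable = [i for i, v in enumerate(per_day) if v is not None]
        raise ValueError(
            f"need 3 complete days with defined MAI, have {len(defined)} "
            f"(usable days: {usable})"
        )
    return float(np.mean(defined[:3]))


def mai_result(
    series: ActivitySeries,
    schedule: LDSchedule,
    n_days: int,
    completeness: float = 0.95,
) -> MAIResult:
    per_day: list[Optional[float]] = []
    reasons: list[Optional[str]] = []
    for day in range(n_days):
        v, reason = morning_anticipation_index(series, schedule, day, completeness)
        per_day.append(v)
        reasons.append(reason)
    try:
        mean3: Optional[float] = mai_mean(per_day)
    except ValueError:
        mean3 = None
    return MAIResult(per_day=per_day, mean3=mean3, reasons=reasons)


def average_activity_profile(
    cohort: Sequence[ActivitySeries],
    schedule: LDSchedule,
    bin_width_min: int = 30,
    n_days: Optional[int] = None,
) -> BinnedProfile:
    """Per-fly per-day binned activity totals -> cross-fly mean and SEM.

    Each fly's complete days are binned by ZT and averaged within the fly;
    the profile is the cross-fly mean with SEM per bin.
    """
    if not cohort:
        raise ValueError("need at least one fly")
    n_bins = int(round(schedule.period_h * 60)) // bin_width_min
    bin_s = bin_width_min * 60
    per_fly = []
    for series in cohort:
        days = (
            n_days
            if n_days is not None
            else int(schedule.day_index(series.t[-1] - 1)) + 1
        )
        day_rows = []
        for day in range(max(days, 1)):
            w0, w1 = schedule.window(day, 0.0, schedule.period_h)
            sel = _window_slice(series, w0, w1) & series.valid
            if not sel.any():
                continue
            offs = series.t[sel] - 1 - w0  # second-start offset within the day
            bins = offs // bin_s
            day_rows.append(np.bincount(bins, weights=series.values[sel], minlength=n_bins))
        if not day_rows:
            day_rows = [np.zeros(n_bins)]
        per_fly.append(np.mean(day_rows, axis=0))
    per_fly_arr = np.asarray(per_fly)
    mean = per_fly_arr.mean(axis=0)
    if len(per_fly_arr) > 1:
        sem = per_fly_arr.std(axis=0, ddof=1) / np.sqrt(len(per_fly_arr))
    else:
        sem = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * (bin_width_min / 60.0)
    return BinnedProfile(bin_width_min, edges, per_fly_arr, mean, sem)
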