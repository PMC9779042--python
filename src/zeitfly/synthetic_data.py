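"""Ground-truth generators: trajectories, rendered frames, confocal-like stacks.

The activity model is deliberately simple and fully parameterized: a baseline
expected displacement per ZT phase, a linear pre-dawn anticipation ramp ending
at lights-on, a lights-on startle plateau, a linear evening rise ending at
lights-off, and a per-phase two-state (wake/sleep) chain.  Awake steps draw an
exponential length with the configured mean and a uniform heading; asleep steps
stay below ``micro_move_mm``.  Walls reflect (triangle-wave fold of the
unconstrained walk), so positions never leave the chamber.

Everything is driven by one seed; per-fly seeds are ``master + fly_index``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional, Sequence, Union

import numpy as np

from .metrics import LDSchedule
from .tracking import ChamberGeometry, FrameSequence, Trajectory

__all__ = [
    "ConfigurationError",
    "PRESETS",
    "Ramp",
    "RenderParams",
    "SimConfig",
    "SleepDynamics",
    "StackTruth",
    "Startle",
    "calibrated_geometry",
    "config_hash",
    "iter_rendered_frames",
    "preset_config",
    "render_frames",
    "simulate_cohort",
    "simulate_intensity",
    "simulate_stack",
    "simulate_trajectory",
]

DAY_S = 86400


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configuration (e.g. phase overlap)."""


@dataclass(frozen=True)
class Ramp:
    """Linear rise from zero at ``onset_zt`` to ``amplitude`` at the phase end
    (lights-on for the anticipation ramp, lights-off for the evening peak)."""

    onset_zt: float
    amplitude: float


@dataclass(frozen=True)
class Startle:
    amplitude: float
    duration_s: int = 60  # the paper reports a lights-on startle without a duration


@dataclass(frozen=True)
class SleepDynamics:
    p_fall_asleep: float
    p_wake: float

    def __post_init__(self) -> None:
        for p in (self.p_fall_asleep, self.p_wake):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("transition probabilities must lie in [0,1]")


PhaseMap = dict[tuple[float, float], float]
DynamicsMap = dict[tuple[float, float], SleepDynamics]


def _check_phases(phases: Sequence[tuple[float, float]]) -> None:
    spans = sorted(phases)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ConfigurationError(f"overlapping phase definitions: {(a0, a1)} and {(b0, b1)}")
    for z0, z1 in spans:
        if not (0.0 <= z0 < z1 <= 24.0):
            raise ConfigurationError(f"phase {(z0, z1)} outside [0, 24]")


@dataclass(frozen=True)
class SimConfig:
    """Full per-fly behavioral simulation recipe (see module docstring)."""

    seed: int = 0
    n_days: int = 3
    body_length_mm: float = 2.5
    phase_rates: PhaseMap = field(default_factory=lambda: {(0.0, 24.0): 1.0})
    anticipation_ramp: Optional[Ramp] = None
    startle: Optional[Startle] = None
    evening_peak: Optional[Ramp] = None
    sleep_dynamics: DynamicsMap = field(
        default_factory=lambda: {(0.0, 24.0): SleepDynamics(0.002, 0.01)}
    )
    micro_move_mm: float = 0.1
    x_range: Optional[tuple[float, float]] = None  # confinement along the long axis

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.body_length_mm <= 0:
            raise ConfigurationError("body_length_mm must be positive")
        if any(r < 0 for r in self.phase_rates.values()):
            raise ConfigurationError("phase rates must be nonnegative")
        _check_phases(list(self.phase_rates))
        _check_phases(list(self.sleep_dynamics))
        for ramp in (self.anticipation_ramp, self.evening_peak):
            if ramp is not None:
                if not (0.0 <= ramp.onset_zt < 24.0):
                    raise ConfigurationError("ramp onset_zt must lie in [0, 24)")
                if ramp.amplitude < 0:
                    raise ConfigurationError("ramp amplitude must be nonnegative")
        if self.micro_move_mm < 0:
            raise ConfigurationError("micro_move_mm must be nonnegative")

    def sleep_prob_arrays(self, schedule: LDSchedule) -> tuple[np.ndarray, np.ndarray]:
        """Per-second (p_fall_asleep, p_wake) arrays over the full run."""
        n = DAY_S * self.n_days
        zt = schedule.zt_hours(np.arange(n))
        p_fall = np.zeros(n)
        p_wake = np.ones(n)  # uncovered ZT defaults to "always awake"
        for (z0, z1), dyn in self.sleep_dynamics.items():
            m = (zt >= z0) & (zt < z1)
            p_fall[m] = dyn.p_fall_asleep
            p_wake[m] = dyn.p_wake
        return p_fall, p_wake


def config_hash(config: SimConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]


def simulate_intensity(config: SimConfig, schedule: LDSchedule) -> np.ndarray:
    """Per-second expected displacement (mm/s), length ``86400 * n_days``.

    Baseline rates are piecewise-constant over ZT phases; the anticipation
    ramp rises linearly from its onset to full amplitude exactly at lights-on
    (ZT24 == ZT0); the startle adds its amplitude for ``duration_s`` seconds
    after lights-on; the evening peak rises linearly to lights-off.
    """
    n = DAY_S * config.n_days
    t = np.arange(n)
    zt = schedule.zt_hours(t)
    out = np.zeros(n)
    for (z0, z1), rate in config.phase_rates.items():
        out[(zt >= z0) & (zt < z1)] += rate
    ramp = config.anticipation_ramp
    if ramp is not None and ramp.amplitude > 0:
        m = zt >= ramp.onset_zt
        out[m] += ramp.amplitude * (zt[m] - ramp.onset_zt) / (24.0 - ramp.onset_zt)
    if config.startle is not None:
        out[zt * 3600.0 < config.startle.duration_s] += config.startle.amplitude
    ev = config.evening_peak
    if ev is not None and ev.amplitude > 0:
        off = schedule.photoperiod_h
        if ev.onset_zt < off:
            m = (zt >= ev.onset_zt) & (zt < off)
            out[m] += ev.amplitude * (zt[m] - ev.onset_zt) / (off - ev.onset_zt)
    return out


def _fold(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflecting-boundary (triangle wave) fold of an unconstrained walk."""
    span = hi - lo
    if span <= 0:
        raise ConfigurationError("empty folding interval")
    y = np.mod(s - lo, 2.0 * span)
    return lo + np.where(y <= span, y, 2.0 * span - y)


def _simulate_states(
    p_fall: np.ndarray, p_wake: np.ndarray, u: np.ndarray, start_asleep: bool = False
) -> np.ndarray:
    n = len(u)
    states = np.empty(n, dtype=bool)  # True = asleep
    asleep = start_asleep
    pf = p_fall.tolist()
    pw = p_wake.tolist()
    ul = u.tolist()
    out = states.tolist()
    for i in range(n):
        if asleep:
            if ul[i] < pw[i]:
                asleep = False
        else:
            if ul[i] < pf[i]:
                asleep = True
        out[i] = asleep
    return np.asarray(out, dtype=bool)


def simulate_trajectory(
    intensity: np.ndarray,
    sleep_dynamics: Union[SleepDynamics, tuple[np.ndarray, np.ndarray]],
    geometry: ChamberGeometry,
    seed: int,
    micro_move_mm: float = 0.1,
    x_range: Optional[tuple[float, float]] = None,
    fly_id: str = "fly",
    chamber_id: str = "c0",
    body_length_mm: float = 2.5,
) -> Trajectory:
    """Bounded reflecting random walk driven by the intensity series.

    Awake seconds draw an exponential step length with mean equal to the
    intensity value; asleep seconds draw uniform lengths in
    ``[0, micro_move_mm)``.  The wake/sleep state follows the two-state chain
    (constant probabilities, or per-second arrays from
    :meth:`SimConfig.sleep_prob_arrays`).  The sleep-state sequence is stored
    in ``meta['asleep']`` as generator ground truth.
    """
    intensity = np.asarray(intensity, dtype=float)
    n = len(intensity)
    rng = np.random.default_rng(seed)
    if isinstance(sleep_dynamics, SleepDynamics):
        p_fall = np.full(n, sleep_dynamics.p_fall_asleep)
        p_wake = np.full(n, sleep_dynamics.p_wake)
    else:
        p_fall, p_wake = (np.asarray(a, dtype=float) for a in sleep_dynamics)
        if len(p_fall) != n or len(p_wake) != n:
            raise ConfigurationError("probability arrays must match intensity length")

    u_state = rng.random(n)
    exp_draw = rng.exponential(size=n)
    micro_draw = rng.random(n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)

    asleep = _simulate_states(p_fall, p_wake, u_state)
    lengths = np.where(asleep, micro_draw * micro_move_mm, exp_draw * intensity)

    lo_x, hi_x = x_range if x_range is not None else (0.0, geometry.length_mm)
    if not (0.0 <= lo_x < hi_x <= geometry.length_mm):
        raise ConfigurationError("x_range must lie within the chamber")
    x0 = 0.5 * (lo_x + hi_x)
    y0 = 0.5 * geometry.width_mm
    x = _fold(x0 + np.concatenate(([0.0], np.cumsum(lengths * np.cos(theta)))), lo_x, hi_x)
    y = _fold(y0 + np.concatenate(([0.0], np.cumsum(lengths * np.sin(theta)))), 0.0, geometry.width_mm)

    t = np.arange(n + 1, dtype=np.int64)
    traj = Trajectory(
        fly_id,
        chamber_id,
        t,
        x,
        y,
        np.ones(n + 1, dtype=bool),
        body_length_mm=body_length_mm,
        meta={"seed": seed},
    )
    traj.meta["asleep"] = asleep
    return traj


def simulate_fly(
    config: SimConfig,
    schedule: Optional[LDSchedule] = None,
    geometry: Optional[ChamberGeometry] = None,
    seed: Optional[int] = None,
    fly_id: str = "fly",
    chamber_id: str = "c0",
) -> Trajectory:
    """Convenience wrapper: intensity + state chain + walk from one config."""
    schedule = schedule or LDSchedule()
    geometry = geometry or ChamberGeometry()
    intensity = simulate_intensity(config, schedule)
    traj = simulate_trajectory(
        intensity,
        config.sleep_prob_arrays(schedule),
        geometry,
        seed if seed is not None else config.seed,
        micro_move_mm=config.micro_move_mm,
        x_range=config.x_range,
        fly_id=fly_id,
        chamber_id=chamber_id,
        body_length_mm=config.body_length_mm,
    )
    traj.meta["config_hash"] = config_hash(config)
    return traj


def simulate_cohort(
    group_configs: dict[str, SimConfig],
    n_flies_per_group: Union[int, dict[str, int]],
    seed: int,
    schedule: Optional[LDSchedule] = None,
    geometry: Optional[ChamberGeometry] = None,
) -> list[Trajectory]:
    """Independent flies with deterministic per-fly seeds (master + index)."""
    if not group_configs:
        raise ConfigurationError("empty group list")
    schedule = schedule or LDSchedule()
    geometry = geometry or ChamberGeometry()
    flies: list[Trajectory] = []
    idx = 0
    for group, config in group_configs.items():
        n = (
            n_flies_per_group[group]
            if isinstance(n_flies_per_group, dict)
            else n_flies_per_group
        )
        if n < 1:
            raise ConfigurationError(f"group {group!r} needs n >= 1")
        for k in range(n):
            fly = simulate_fly(
                config,
                schedule,
                geometry,
                seed=seed + idx,
                fly_id=f"{group}_{k:03d}",
                chamber_id=f"c{idx:02d}",
            )
            fly.meta["group"] = group
            flies.append(fly)
            idx += 1
    return flies


# ---------------------------------------------------------------------------
# frame rendering


@dataclass(frozen=True)
class RenderParams:
    """Dark fly disc on a light background; anti-aliased edges, optional noise."""

    px_per_mm: float = 4.0
    frame_height_px: Optional[int] = None  # default: derived from geometry
    frame_width_px: Optional[int] = None
    background_gray: int = 200
    fly_gray: int = 50
    noise_sd: float = 0.0
    fly_radius_px: float = 5.0
    margin_px: int = 8  # must exceed fly_radius_px so wall contact stays in frame

    def __post_init__(self) -> None:
        if self.margin_px <= self.fly_radius_px:
            raise ConfigurationError("margin_px must exceed fly_radius_px")
        if self.fly_gray >= self.background_gray:
            raise ConfigurationError("fly_gray must be darker than background_gray")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


def calibrated_geometry(geometry: ChamberGeometry, params: RenderParams) -> ChamberGeometry:
    """Attach px_per_mm and a frame ROI consistent with the render scale."""
    w = int(round(geometry.length_mm * params.px_per_mm))
    h = int(round(geometry.width_mm * params.px_per_mm))
    roi = (params.margin_px, params.margin_px, w, h)
    return replace(geometry, px_per_mm=params.px_per_mm, roi_px=roi)


def _frame_dims(geometry: ChamberGeometry, params: RenderParams) -> tuple[int, int]:
    if params.frame_height_px is not None and params.frame_width_px is not None:
        return params.frame_height_px, params.frame_width_px
    _, (x0, y0, w, h) = geometry.require_calibration()
    return y0 + h + params.margin_px, x0 + w + params.margin_px


def _render_one(
    x_mm: float,
    y_mm: float,
    params: RenderParams,
    geometry: ChamberGeometry,
    dims: tuple[int, int],
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    ppm, (rx0, ry0, _, _) = geometry.require_calibration()
    h, w = dims
    cx = rx0 + x_mm * ppm
    cy = ry0 + y_mm * ppm
    r = params.fly_radius_px
    if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
        raise ValueError(f"fly at ({x_mm}, {y_mm}) mm maps outside the frame")
    frame = np.full(dims, float(params.background_gray))
    # draw only the local patch around the disc
    px0, px1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 2))
    py0, py1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 2))
    yy, xx = np.mgrid[py0:py1, px0:px1]
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
    frame[py0:py1, px0:px1] -= (params.background_gray - params.fly_gray) * coverage
    if params.noise_sd > 0 and rng is not None:
        frame += rng.normal(0.0, params.noise_sd, size=dims)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def iter_rendered_frames(
    traj: Trajectory,
    params: RenderParams,
    geometry: ChamberGeometry,
    seed: int = 0,
) -> Iterator[tuple[float, np.ndarray]]:
    """Lazy frame generator: one frame per trajectory sample."""
    dims = _frame_dims(geometry, params)
    rng = np.random.default_rng(seed) if params.noise_sd > 0 else None
    for i in range(len(traj)):
        if not traj.detected[i]:
            frame = np.full(dims, float(params.background_gray))
            if rng is not None:
                frame += rng.normal(0.0, params.noise_sd, size=dims)
            yield float(traj.t[i]), np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        else:
            yield float(traj.t[i]), _render_one(
                traj.x_mm[i], traj.y_mm[i], params, geometry, dims, rng
            )


def render_frames(
    traj: Trajectory,
    params: RenderParams,
    geometry: ChamberGeometry,
    seed: int = 0,
) -> FrameSequence:
    """Materialized :class:`FrameSequence`; use :func:`iter_rendered_frames`
    for day-scale sequences."""
    ts, frames = zip(*iter_rendered_frames(traj, params, geometry, seed))
    return FrameSequence(np.stack(frames), np.asarray(ts))


# ---------------------------------------------------------------------------
# confocal-like stacks


@dataclass(frozen=True)
class StackTruth:
    """Known-intensity axonal-terminal blob in an n-slice stack (a.u.)."""

    n_slices: int = 10
    shape: tuple[int, int] = (64, 64)
    blob_center_px: Optional[tuple[float, float]] = (32.0, 32.0)  # (row, col); None = background only
    blob_radius_px: float = 8.0
    blob_mean_intensity: float = 500.0
    background_intensity: float = 100.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.blob_center_px is not None and not (
            self.blob_mean_intensity > self.background_intensity
        ):
            raise ValueError("blob must be brighter than background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def blob_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        if self.blob_center_px is None:
            return mask
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        r0, c0 = self.blob_center_px
        mask[np.hypot(rr - r0, cc - c0) <= self.blob_radius_px] = True
        return mask


def simulate_stack(truth: StackTruth, seed: int = 0) -> np.ndarray:
    """Stack whose max-projection blob mean equals ``blob_mean_intensity``
    exactly before noise: the centre slice carries the full contrast and the
    depth profile falls off steeply on either side."""
    rng = np.random.default_rng(seed)
    stack = np.full((truth.n_slices, *truth.shape), truth.background_intensity)
    mask = truth.blob_mask()
    if mask.any():
        k0 = truth.n_slices // 2
        contrast = truth.blob_mean_intensity - truth.background_intensity
        for k in range(truth.n_slices):
            d = abs(k - k0)
            w = 1.0 if d == 0 else (0.45 if d == 1 else 0.1)
            stack[k][mask] += w * contrast
    if truth.noise_sd > 0:
        stack = stack + rng.normal(0.0, truth.noise_sd, size=stack.shape)
    return stack


# ---------------------------------------------------------------------------
# presets


def _base_dynamics() -> DynamicsMap:
    return {
        (0.0, 4.0): SleepDynamics(0.0008, 0.05),   # morning activity
        (4.0, 10.0): SleepDynamics(0.004, 0.004),  # siesta
        (10.0, 12.0): SleepDynamics(0.0008, 0.05), # evening activity
        (12.0, 18.0): SleepDynamics(0.006, 0.002), # consolidated night rest
        (18.0, 24.0): SleepDynamics(0.002, 0.006), # late night, waking up
    }


def _male(seed: int, n_days: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_days=n_days,
        phase_rates={
            (0.0, 1.0): 1.2,
            (1.0, 4.0): 0.8,
            (4.0, 10.0): 0.3,
            (10.0, 12.0): 1.0,
            (12.0, 18.0): 0.2,
            (18.0, 24.0): 0.3,
        },
        anticipation_ramp=Ramp(onset_zt=21.0, amplitude=1.5),
        startle=Startle(amplitude=2.0, duration_s=60),
        evening_peak=Ramp(onset_zt=10.0, amplitude=1.5),
        sleep_dynamics=_base_dynamics(),
    )


def _virgin_female(seed: int, n_days: int) -> SimConfig:
    cfg = _male(seed, n_days)
    rates = dict(cfg.phase_rates)
    rates[(4.0, 10.0)] = 0.6  # shallower siesta, more daytime activity
    return replace(cfg, phase_rates=rates, anticipation_ramp=Ramp(21.0, 0.8))


def _mated_female(seed: int, n_days: int) -> SimConfig:
    cfg = _male(seed, n_days)
    rates = dict(cfg.phase_rates)
    rates[(4.0, 10.0)] = 1.0  # siesta suppressed: sustained daytime activity
    dyn = dict(_base_dynamics())
    dyn[(4.0, 10.0)] = SleepDynamics(0.0008, 0.05)
    return replace(
        cfg,
        phase_rates=rates,
        sleep_dynamics=dyn,
        anticipation_ramp=None,  # morning anticipation virtually suppressed
        startle=Startle(amplitude=3.0, duration_s=60),
    )


def _mated_female_declining(seed: int, n_days: int) -> SimConfig:
    # alternative reading of "virtually suppressed": pre-dawn activity declines
    cfg = _mated_female(seed, n_days)
    rates = dict(cfg.phase_rates)
    rates[(18.0, 21.0)] = 0.45
    rates[(21.0, 24.0)] = 0.25
    del rates[(18.0, 24.0)]
    return replace(cfg, phase_rates=rates)


def _flat(seed: int, n_days: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_days=n_days,
        phase_rates={(0.0, 24.0): 1.0},
        sleep_dynamics={(0.0, 24.0): SleepDynamics(0.002, 0.01)},
    )


def _anticipating(seed: int, n_days: int) -> SimConfig:
    # flat baseline plus a ramp at >= 2x baseline amplitude over ZT21-24
    return replace(_flat(seed, n_days), anticipation_ramp=Ramp(21.0, 2.5))


def _confined(seed: int, n_days: int) -> SimConfig:
    # half-chamber micro-foraging: vigorous movement that never crosses the
    # midline beam, the DAM sleep-overestimation regime
    return replace(_flat(seed, n_days), x_range=(1.0, 38.0))


PRESETS: dict[str, Callable[[int, int], SimConfig]] = {
    "male": _male,
    "virgin_female": _virgin_female,
    "mated_female": _mated_female,
    "mated_female_declining": _mated_female_declining,
    "flat": _flat,
    "anticipating": _anticipating,
    "confined": _confined,
}


def preset_config(name: str, seed: int = 0, n_days: int = 3) -> SimConfig:
    try:
        return PRESETS[name](seed, n_days)
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
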