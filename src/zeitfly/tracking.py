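"""Recover 1 Hz per-fly trajectories from grayscale frame sequences.

A frame sequence of a single-fly chamber is segmented against a temporal-median
background; the fly is the largest above-threshold connected component of the
absolute difference image inside the chamber ROI.  Detections are decimated to
exactly 1 Hz and converted from pixels to chamber millimetres.  Short detection
gaps are bridged by linear interpolation; long gaps stay undetected.

All downstream maths works in millimetres; pixels never leave this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "CalibrationError",
    "ChamberGeometry",
    "Detection",
    "FrameSequence",
    "TrackConfig",
    "Trajectory",
    "detect_fly",
    "estimate_background",
    "track",
]


class CalibrationError(ValueError):
    """Raised when pixel-to-mm calibration is missing or invalid."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Physical chamber and its mapping into frame coordinates.

    The chamber long axis (``length_mm``) maps onto the ROI x axis with the
    origin at the food end.  ``beam_x_mm`` locates the virtual infrared beam
    used by :mod:`zeitfly.dam_emulation`; it defaults to the midpoint.
    """

    length_mm: float = 80.0
    width_mm: float = 8.0
    height_mm: float = 8.0
    px_per_mm: Optional[float] = None
    roi_px: Optional[tuple[int, int, int, int]] = None  # (x0, y0, w, h)
    beam_x_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.px_per_mm is not None and self.px_per_mm <= 0:
            raise CalibrationError("px_per_mm must be positive")
        beam = self.beam_x()
        if not (0.0 < beam < self.length_mm):
            raise ValueError("beam_x_mm must lie strictly inside the chamber")

    def beam_x(self) -> float:
        return self.length_mm / 2.0 if self.beam_x_mm is None else self.beam_x_mm

    def require_calibration(self) -> tuple[float, tuple[int, int, int, int]]:
        if self.px_per_mm is None or self.roi_px is None:
            raise CalibrationError("geometry lacks px_per_mm / roi_px calibration")
        return self.px_per_mm, self.roi_px

    def contains(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        return (
            (x_mm >= 0.0)
            & (x_mm <= self.length_mm)
            & (y_mm >= 0.0)
            & (y_mm <= self.width_mm)
        )


@dataclass
class FrameSequence:
    """Ordered grayscale frames with strictly increasing timestamps."""

    frames: np.ndarray  # (n, h, w)
    timestamps: np.ndarray  # seconds since experiment start

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[float, np.ndarray]]:
        return zip(self.timestamps.tolist(), self.frames)

    @property
    def dims(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class Trajectory:
    """Per-fly 1 Hz positions in chamber coordinates (mm).

    ``t`` is integer seconds from experiment start with unit step; where
    ``detected`` is False the position is NaN.  ``meta`` carries provenance
    (group label, seed, config hash) and is never interpreted here.
    """

    fly_id: str
    chamber_id: str
    t: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    detected: np.ndarray
    body_length_mm: float = 2.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n = len(self.t)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.detected) == n):
            raise ValueError("all trajectory columns must share one length")
        if n > 1 and not np.all(np.diff(self.t) == 1):
            raise ValueError("t must be strictly increasing with unit step")
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be positive")
        if np.any(~np.isfinite(self.x_mm[self.detected])) or np.any(
            ~np.isfinite(self.y_mm[self.detected])
        ):
            raise ValueError("detected samples must have finite positions")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Detection:
    x_px: float
    y_px: float
    area_px: int
    major_axis_px: float


@dataclass
class TrackConfig:
    """Knobs for :func:`track`.

    ``threshold=None`` selects per-frame Otsu on the difference image.
    ``body_length_mm`` overrides the median-major-axis estimate.
    ``background`` short-circuits background estimation (required when frames
    arrive as a one-shot iterator).
    """

    threshold: Optional[float] = None
    min_area_px: int = 4
    max_gap_s: int = 5
    body_length_mm: Optional[float] = None
    background: Optional[np.ndarray] = None
    background_samples: int = 50


def estimate_background(
    frames: Union[FrameSequence, np.ndarray, Sequence[np.ndarray]],
    method: str = "median",
    max_samples: int = 100,
) -> np.ndarray:
    """Per-pixel temporal median (default) over an even subsample of frames."""
    arr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    if arr.ndim != 3 or len(arr) < 3:
        raise ValueError("need at least 3 frames to estimate a background")
    idx = np.linspace(0, len(arr) - 1, min(max_samples, len(arr))).astype(int)
    sample = arr[idx].astype(float)
    if method == "median":
        bg = np.median(sample, axis=0)
    elif method == "mean":
        bg = sample.mean(axis=0)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return bg


def _otsu(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def detect_fly(
    frame: np.ndarray,
    background: np.ndarray,
    geometry: Optional[ChamberGeometry] = None,
    min_area_px: int = 4,
    threshold: Optional[float] = None,
    roi_pad_px: int = 8,
) -> Optional[Detection]:
    """Locate the fly in one frame, or return ``None`` if nothing plausible.

    The absolute difference to the background, restricted to the chamber ROI
    (padded by ``roi_pad_px`` so a fly touching the wall is not clipped), is
    binarized (Otsu by default) and the largest connected component with
    area >= ``min_area_px`` yields an intensity-weighted centroid in *frame*
    pixel coordinates.
    """
    if frame.shape != background.shape:
        raise ValueError("frame and background dims differ")
    if geometry is not None and geometry.roi_px is not None:
        x0, y0, w, h = geometry.roi_px
        x1 = min(frame.shape[1], x0 + w + roi_pad_px)
        y1 = min(frame.shape[0], y0 + h + roi_pad_px)
        x0 = max(0, x0 - roi_pad_px)
        y0 = max(0, y0 - roi_pad_px)
        w, h = x1 - x0, y1 - y0
    else:
        x0 = y0 = 0
        h, w = frame.shape
    diff = np.abs(frame[y0 : y0 + h, x0 : x0 + w].astype(float) - background[y0 : y0 + h, x0 : x0 + w].astype(float))
    if diff.max() <= 1.0:  # indistinguishable from the background
        return None
    thr = _otsu(diff) if threshold is None else float(threshold)
    mask = diff >= max(thr, 1.0)
    if not mask.any():
        return None
    labels, n_comp = ndimage.label(mask)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = int(areas.argmax())
    if areas[best] < min_area_px:
        return None
    comp = labels == best
    wts = diff * comp
    total = wts.sum()
    ys, xs = np.nonzero(comp)
    cx = float((wts[ys, xs] * xs).sum() / total)
    cy = float((wts[ys, xs] * ys).sum() / total)
    # second central moments -> regionprops-style major axis length
    dx = xs - (wts[ys, xs] * xs).sum() / total
    dy = ys - (wts[ys, xs] * ys).sum() / total
    wn = wts[ys, xs] / total
    cxx = float((wn * dx * dx).sum()) + 1.0 / 12.0
    cyy = float((wn * dy * dy).sum()) + 1.0 / 12.0
    cxy = float((wn * dx * dy).sum())
    lam = 0.5 * (cxx + cyy) + 0.5 * np.hypot(cxx - cyy, 2.0 * cxy)
    major = 4.0 * float(np.sqrt(max(lam, 0.0)))
    return Detection(cx + x0, cy + y0, int(areas[best]), major)


def _interpolate_gaps(
    x: np.ndarray, y: np.ndarray, detected: np.ndarray, max_gap_s: int
) -> np.ndarray:
    """Linearly fill interior undetected runs of length <= max_gap_s.

    Returns the updated detected mask; x/y are modified in place.
    """
    out = detected.copy()
    n = len(detected)
    i = 0
    while i < n:
        if detected[i]:
            i += 1
            continue
        j = i
        while j < n and not detected[j]:
            j += 1
        gap = j - i
        if i > 0 and j < n and gap <= max_gap_s:
            f = (np.arange(i, j) - (i - 1)) / (j - (i - 1))
            x[i:j] = x[i - 1] + f * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + f * (y[j] - y[i - 1])
            out[i:j] = True
        i = j
    return out


def track(
    frames: Union[FrameSequence, Iterable[tuple[float, np.ndarray]]],
    geometry: ChamberGeometry,
    config: Optional[TrackConfig] = None,
    fly_id: str = "fly",
    chamber_id: str = "c0",
) -> Trajectory:
    """Detect, decimate to 1 Hz, convert to mm, and apply the gap policy.

    ``frames`` is a :class:`FrameSequence` or a lazy iterable of
    ``(timestamp_s, frame)`` pairs; the latter requires
    ``config.background``.
    """
    config = config or TrackConfig()
    px_per_mm, (rx0, ry0, _, _) = geometry.require_calibration()

    if config.background is not None:
        background = np.asarray(config.background, dtype=float)
    elif isinstance(frames, FrameSequence):
        background = estimate_background(frames, max_samples=config.background_samples)
    else:
        raise ValueError("iterator input requires config.background")

    seconds: list[int] = []
    dets: list[Optional[Detection]] = []
    last_second: Optional[int] = None
    for ts, frame in frames:
        sec = int(np.floor(ts))
        if sec == last_second:
            continue  # decimate: first frame of each second wins
        last_second = sec
        seconds.append(sec)
        dets.append(
            detect_fly(
                frame,
                background,
                geometry,
                min_area_px=config.min_area_px,
                threshold=config.threshold,
            )
        )
    if not seconds:
        raise ValueError("no frames to track")

    t = np.arange(seconds[0], seconds[-1] + 1, dtype=np.int64)
    x = np.full(len(t), np.nan)
    y = np.full(len(t), np.nan)
    detected = np.zeros(len(t), dtype=bool)
    majors: list[float] = []
    for sec, det in zip(seconds, dets):
        if det is None:
            continue
        k = sec - seconds[0]
        x[k] = (det.x_px - rx0) / px_per_mm
        y[k] = (det.y_px - ry0) / px_per_mm
        detected[k] = True
        majors.append(det.major_axis_px)

    detected = _interpolate_gaps(x, y, detected, config.max_gap_s)
    x[~detected] = np.nan
    y[~detected] = np.nan

    if config.body_length_mm is not None:
        body = config.body_length_mm
    elif majors:
        body = float(np.median(majors)) / px_per_mm
    else:
        body = 2.5
    return Trajectory(fly_id, chamber_id, t, x, y, detected, body_length_mm=body)
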