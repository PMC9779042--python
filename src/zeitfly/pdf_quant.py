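"""Fluorescence quantification: max z-projection -> threshold ROI -> mean.

Mirrors the standard ImageJ workflow: per-brain maximum-intensity projection
of the slice stack, an Otsu (default) threshold image defining the ROI, and
the arithmetic mean of the projection over the ROI as the reported
immunoreactivity.  Batch quantification dispatches group x timepoint tables to
the two-way ANOVA in :mod:`zeitfly.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as zstats
from .stats import TestResult

__all__ = [
    "ImageStack",
    "QuantRecord",
    "ROIMask",
    "max_projection",
    "quantify_batch",
    "quantify_stack",
    "roi_mean",
    "threshold_roi",
]


@dataclass
class ImageStack:
    """Ordered 2D intensity slices (a.u.), uniform dims."""

    slices: np.ndarray  # (k, h, w)
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3 or len(self.slices) < 1:
            raise ValueError("need a (k, h, w) stack with >= 1 slice")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class ROIMask:
    mask: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask must be non-empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantRecord:
    brain_id: str
    group: str
    timepoint: str  # e.g. ZT02 / ZT14
    roi_mean_intensity: float
    roi_area_px: int

    def __post_init__(self) -> None:
        if self.roi_mean_intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if self.roi_area_px <= 0:
            raise ValueError("ROI area must be positive")


def _as_stack(stack: Union[ImageStack, np.ndarray]) -> np.ndarray:
    arr = stack.slices if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ValueError("stack must be (k, h, w)")
    return arr


def max_projection(stack: Union[ImageStack, np.ndarray]) -> np.ndarray:
    """Per-pixel maximum across slices."""
    return _as_stack(stack).max(axis=0)


def threshold_roi(
    projection: np.ndarray,
    method: Union[str, float, tuple] = "otsu",
    largest_only: bool = True,
) -> ROIMask:
    """Threshold the projection into an ROI.

    ``method``: ``"otsu"`` (default), a fixed threshold value, or
    ``("percentile", q)``.  With ``largest_only`` the mask keeps only the
    largest connected component (the projection's dominant signal).
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2:
        raise ValueError("projection must be 2D")
    if np.ptp(proj) == 0:
        raise ValueError("constant projection: cannot threshold")
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(proj))
        name = "otsu"
    elif isinstance(method, tuple) and method[0] == "percentile":
        thr = float(np.percentile(proj, method[1]))
        name = f"percentile{method[1]}"
    elif isinstance(method, (int, float)):
        thr = float(method)
        name = "fixed"
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = proj >= thr
    if not mask.any():
        raise ValueError("no signal above threshold")
    if largest_only:
        labels, _ = ndimage.label(mask)
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        mask = labels == int(areas.argmax())
    return ROIMask(mask, name, thr)


def roi_mean(projection: np.ndarray, mask: Union[ROIMask, np.ndarray]) -> float:
    """Arithmetic mean of the projection over ROI pixels."""
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if m.shape != np.shape(projection):
        raise ValueError("mask and projection dims differ")
    if not m.any():
        raise ValueError("empty mask")
    return float(np.asarray(projection, dtype=float)[m].mean())


def quantify_stack(
    stack: Union[ImageStack, np.ndarray],
    method: Union[str, float, tuple] = "otsu",
) -> tuple[float, ROIMask]:
    proj = max_projection(stack)
    mask = threshold_roi(proj, method)
    return roi_mean(proj, mask), mask


def quantify_batch(
    stacks: Mapping[str, Union[ImageStack, np.ndarray]],
    metadata: pd.DataFrame,
    method: Union[str, float, tuple] = "otsu",
) -> tuple[pd.DataFrame, TestResult]:
    """One QuantRecord per brain + two-way ANOVA (timepoint x group).

    ``metadata`` needs columns brain_id, group, timepoint; a stack without a
    metadata row is an error.
    """
    meta = metadata.set_index("brain_id")
    records = []
    for brain_id, stack in stacks.items():
        if brain_id not in meta.index:
            raise KeyError(f"missing metadata row for brain {brain_id!r}")
        mean, mask = quantify_stack(stack, method)
        row = meta.loc[brain_id]
        records.append(
            QuantRecord(
                brain_id=str(brain_id),
                group=str(row["group"]),
                timepoint=str(row["timepoint"]),
                roi_mean_intensity=mean,
                roi_area_px=mask.area_px,
            )
        )
    table = pd.DataFrame([r.__dict__ for r in records])
    result = zstats.two_way_anova(
        table["roi_mean_intensity"], table["timepoint"], table["group"]
    )
    return table, result
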