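"""Wound-healing gap quantification.

A wound mask is binary (1 = cell-covered).  The gap length of one frame is
the mean, over scanlines perpendicular to the wound, of the longest
cell-free run on each scanline; the longest run (rather than the total zero
count) keeps interior holes in the sheet from inflating the gap.  A series
of gap lengths over time is compared between conditions as a ratio to a
reference condition at a fixed evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default evaluation time (min) for gap ratios: 8 h.
DEFAULT_GAP_EVAL_MIN = 480.0


@dataclass
class WoundSeries:
    """Gap length over time for one condition."""

    times: np.ndarray  # min, strictly increasing
    gap_um: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gap_um = np.asarray(self.gap_um, dtype=float)
        if len(self.times) != len(self.gap_um):
            raise ValueError("times and gap_um must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.gap_um < 0).any():
            raise ValueError("gap lengths must be >= 0")

    def gap_at(self, t_eval: float) -> float:
        """Gap at the frame time nearest t_eval (ties toward earlier)."""
        k = int(np.abs(self.times - t_eval).argmin())
        return float(self.gap_um[k])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.times, "gap_um": self.gap_um}).to_csv(
            path, index=False
        )


def _longest_zero_run(line: np.ndarray) -> int:
    """Length of the longest run of zeros in a 1-D 0/1 array."""
    padded = np.concatenate([[1], line, [1]])
    starts = np.nonzero(np.diff(padded) == -1)[0]
    ends = np.nonzero(np.diff(padded) == 1)[0]
    if starts.size == 0:
        return 0
    return int((ends - starts).max())


def gap_length(mask: np.ndarray, axis: str = "vertical",
               pixel_size: float = 1.0) -> float:
    """Mean wound-gap length of one binary mask, in µm.

    Parameters
    ----------
    mask
        2-D array of {0, 1}; 1 = cell-covered.
    axis
        Orientation of the wound band: ``vertical`` (scanlines are rows) or
        ``horizontal`` (scanlines are columns).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    if axis not in ("vertical", "horizontal"):
        raise ValueError("axis must be 'vertical' or 'horizontal'")
    lines = mask if axis == "vertical" else mask.T
    runs = np.array([_longest_zero_run(line) for line in lines], dtype=float)
    return float(runs.mean() * pixel_size)


def measure_series(
    masks: list[np.ndarray],
    times: np.ndarray,
    axis: str = "vertical",
    pixel_size: float = 1.0,
    condition: str = "",
) -> WoundSeries:
    """Gap length of every frame in a mask series."""
    if len(masks) != len(times):
        raise ValueError("one time per mask required")
    gaps = [gap_length(m, axis=axis, pixel_size=pixel_size) for m in masks]
    return WoundSeries(times=np.asarray(times, dtype=float),
                       gap_um=np.asarray(gaps), condition=condition)


def gap_ratio(series: WoundSeries, reference: WoundSeries,
              t_eval: float = DEFAULT_GAP_EVAL_MIN) -> float:
    """Gap length of a condition relative to the reference at t_eval.

    Both series are evaluated at their frame nearest ``t_eval``; a closed
    (zero) reference gap makes the ratio undefined and is an error.
    """
    ref_gap = reference.gap_at(t_eval)
    if ref_gap <= 0:
        raise ValueError(
            f"reference gap is {ref_gap} at t={t_eval}; ratio undefined"
        )
    return series.gap_at(t_eval) / ref_gap
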