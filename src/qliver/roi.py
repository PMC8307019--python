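"""Elliptical regions of interest and their signal statistics.

The measurement protocol places elliptical ROIs on a single slice: three
in the liver (Couinaud segments IV, VIII and VII), one in each
paravertebral muscle, one in the spleen, one in abdominal fat and one in
the image background (noise).  ROIs are user input — there is no
automatic placement or vessel exclusion — and should avoid vessels and
artifacts.

A pixel belongs to an ellipse when its centre satisfies
``((r - r0)/a)**2 + ((c - c0)/b)**2 <= 1`` (boundary included), with
0-based row/column coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .images import ImageFrame

__all__ = [
    "ROILabel",
    "EllipseROI",
    "ROIStats",
    "roi_stats",
    "liver_summary",
    "RegionSummary",
    "load_rois",
    "save_rois",
    "stats_table",
]

LIVER_LABELS = ("LIVER_IV", "LIVER_VIII", "LIVER_VII")
MUSCLE_LABELS = ("MUSCLE_L", "MUSCLE_R")


class ROILabel(str, Enum):
    LIVER_IV = "LIVER_IV"
    LIVER_VIII = "LIVER_VIII"
    LIVER_VII = "LIVER_VII"
    MUSCLE_L = "MUSCLE_L"
    MUSCLE_R = "MUSCLE_R"
    SPLEEN = "SPLEEN"
    ABDOMINAL_FAT = "ABDOMINAL_FAT"
    NOISE = "NOISE"


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical ROI: centre (row, col) and semi-axes (a, b) in pixels."""

    label: ROILabel
    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ROILabel(self.label))
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean inclusion mask on an image of the given shape."""
        r0, c0 = self.center
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ValueError(f"ROI centre {self.center} outside image {shape}")
        a, b = self.semi_axes
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class ROIStats:
    """Mean, sample SD and pixel count of a signal inside one ROI."""

    label: ROILabel
    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ROILabel(self.label))


def roi_stats(frame: ImageFrame, roi: EllipseROI) -> ROIStats:
    """Mean and sample standard deviation of the frame inside the ROI.

    The SD uses the n−1 denominator and is 0 for a single-pixel ROI.

    Raises
    ------
    ValueError
        If the ellipse encloses no pixel centres.
    """
    mask = roi.mask(frame.shape)
    values = frame.pixels[mask]
    if values.size == 0:
        raise ValueError(f"ROI {roi.label.value} encloses no pixels")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ROIStats(label=roi.label, mean=float(values.mean()), sd=sd,
                    n_pixels=int(values.size))


@dataclass(frozen=True)
class RegionSummary:
    """Across-ROI summary: mean of ROI means, sample SD across means."""

    mean: float
    sd_across: float
    per_roi: tuple[ROIStats, ...]


def liver_summary(stats: Sequence[ROIStats]) -> RegionSummary:
    """Summarise the three-ROI liver protocol.

    Returns the unweighted arithmetic mean of the three ROI means and the
    sample SD across those means.  Note that the across-ROI SD computed
    this way is a dispersion of regional means, not a within-ROI noise
    estimate; see the methods note for a caveat on reported dispersions.

    Raises
    ------
    ValueError
        If not exactly three ROI statistics are supplied.
    """
    if len(stats) != 3:
        raise ValueError(f"liver protocol requires exactly 3 ROIs, got {len(stats)}")
    means = np.array([s.mean for s in stats], dtype=float)
    return RegionSummary(mean=float(means.mean()),
                         sd_across=float(np.std(means, ddof=1)),
                         per_roi=tuple(stats))


# ---------------------------------------------------------------------------
# I/O: ROI definitions as JSON, statistics as a tidy table / CSV.
# ---------------------------------------------------------------------------


def load_rois(path: str | Path) -> list[EllipseROI]:
    """Load ROI definitions from JSON: [{label, center, semi_axes}, ...]."""
    entries = json.loads(Path(path).read_text())
    return [
        EllipseROI(label=e["label"], center=tuple(e["center"]),
                   semi_axes=tuple(e["semi_axes"]))
        for e in entries
    ]


def save_rois(rois: Iterable[EllipseROI], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"label": r.label.value, "center": list(r.center),
         "semi_axes": list(r.semi_axes)}
        for r in rois
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def stats_table(stats: Iterable[ROIStats]) -> pd.DataFrame:
    """Tabulate ROI statistics (label, mean, sd, n_pixels)."""
    return pd.DataFrame(
        [{"label": s.label.value, "mean": s.mean, "sd": s.sd,
          "n_pixels": s.n_pixels} for s in stats]
    )
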