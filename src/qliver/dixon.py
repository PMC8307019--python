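"""Steatosis arm: two-point Dixon fat–water separation and grading.

Water and fat protons precess at slightly different frequencies, so at
suitable echo times their transverse magnetisations add (in-phase, IP)
or subtract (opposed-phase, OOP).  Half-sum and half-difference of the
two magnitude images recover water-only and fat-only images:

    fat   = (IP - OOP) / 2        water = (IP + OOP) / 2

The fat fraction FF = S_F / (S_F + S_W) x 100 measured over the liver
ROIs grades steatosis, and the liver-to-paravertebral-muscle signal
intensity ratio (SIR) provides a reference-tissue check: muscle signal
is unaffected by steatosis, so the liver turns hyperintense relative to
muscle on fat-only images as FF grows.

Magnitude-only two-point Dixon cannot distinguish a fat fraction above
50 % from its mirror below (fat–water dominance swap); estimates are
reported in [0, 50] with an ambiguity flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .config import DEFAULT_THRESHOLDS, Thresholds
from .images import ImageFrame, Role
from .roi import ROIStats

__all__ = [
    "DixonPair",
    "SteatosisGrade",
    "SteatosisResult",
    "reconstruct_fat_water",
    "fat_water_arrays",
    "fat_fraction",
    "grade_steatosis",
    "signal_intensity_ratio",
    "steatosis_from_stats",
]


class SteatosisGrade(str, Enum):
    NONE = "NONE"
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"


@dataclass
class DixonPair:
    """Matched in-phase / opposed-phase magnitude frames."""

    ip: ImageFrame
    oop: ImageFrame

    def __post_init__(self) -> None:
        if self.ip.role is not Role.IN_PHASE:
            raise ValueError("ip frame must have role IN_PHASE")
        if self.oop.role is not Role.OPPOSED_PHASE:
            raise ValueError("oop frame must have role OPPOSED_PHASE")
        if self.ip.shape != self.oop.shape:
            raise ValueError(
                f"IP/OOP dimension mismatch: {self.ip.shape} vs {self.oop.shape}")
        if self.ip.field_t != self.oop.field_t:
            raise ValueError("IP and OOP frames must share field strength")


def fat_water_arrays(ip: np.ndarray, oop: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Half-difference / half-sum Dixon arithmetic on raw arrays.

    Returns ``((ip - oop)/2, (ip + oop)/2)`` without clipping, so the
    conservation identity ``fat + water == ip`` holds exactly; the fat
    component may dip below zero where noise dominates.
    """
    ip = np.asarray(ip, dtype=float)
    oop = np.asarray(oop, dtype=float)
    if ip.shape != oop.shape:
        raise ValueError(f"IP/OOP dimension mismatch: {ip.shape} vs {oop.shape}")
    return (ip - oop) / 2.0, (ip + oop) / 2.0


def reconstruct_fat_water(pair: DixonPair) -> tuple[ImageFrame, ImageFrame]:
    """Fat-only and water-only images from an IP/OOP pair.

    Uses the standard half-sum/half-difference convention so that
    ``fat + water == ip`` holds exactly before clipping; negative
    fat-only pixels (noise) are then clipped to 0 to keep a valid
    magnitude image.  The factor 1/2 is a pure rescaling: the fat
    fraction is invariant to it.
    """
    fat, water = fat_water_arrays(pair.ip.pixels, pair.oop.pixels)
    fat = np.clip(fat, 0.0, None)
    common = dict(field_t=pair.ip.field_t, te_ms=None,
                  pixel_spacing_mm=pair.ip.pixel_spacing_mm)
    return (
        ImageFrame(fat, role=Role.FAT_ONLY, **common),
        ImageFrame(water, role=Role.WATER_ONLY, **common),
    )


def fat_fraction(s_fat: float, s_water: float) -> float:
    """Fat fraction in percent: ``100 * s_fat / (s_fat + s_water)``.

    Scale-invariant in its two arguments; both signals must be
    non-negative with a positive total.
    """
    if s_fat < 0 or s_water < 0:
        raise ValueError("signals must be non-negative")
    total = s_fat + s_water
    if total <= 0:
        raise ZeroDivisionError("zero total fat+water signal")
    return 100.0 * s_fat / total


def grade_steatosis(ff_percent: float,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> SteatosisGrade:
    """Four-grade steatosis classification of a fat fraction.

    None below 6.4 %, mild in [6.4, 17.4), moderate in [17.4, 22.1],
    severe strictly above 22.1 % (default thresholds).
    """
    if not 0 <= ff_percent <= 100:
        raise ValueError("fat fraction must lie in [0, 100] %")
    if ff_percent < thresholds.ff_mild:
        return SteatosisGrade.NONE
    if ff_percent < thresholds.ff_moderate:
        return SteatosisGrade.MILD
    if ff_percent <= thresholds.ff_severe:
        return SteatosisGrade.MODERATE
    return SteatosisGrade.SEVERE


def signal_intensity_ratio(liver: Sequence[ROIStats],
                           muscles: Sequence[ROIStats]) -> float:
    """Liver-to-muscle signal intensity ratio on a common frame.

    Mean of the three liver ROI means divided by the mean of the two
    paravertebral muscle ROI means.
    """
    if len(liver) != 3:
        raise ValueError("SIR needs the 3-ROI liver protocol")
    if len(muscles) != 2:
        raise ValueError("SIR needs both paravertebral muscle ROIs")
    muscle_mean = float(np.mean([m.mean for m in muscles]))
    if muscle_mean <= 0:
        raise ZeroDivisionError("non-positive muscle reference signal")
    liver_mean = float(np.mean([l.mean for l in liver]))
    return liver_mean / muscle_mean


@dataclass(frozen=True)
class SteatosisResult:
    """Liver fat quantification for one subject."""

    ff_percent: float
    ff_sd: float
    sir: float
    grade: SteatosisGrade
    dominance_ambiguous: bool = False

    def to_dict(self) -> dict:
        return {
            "ff_percent": self.ff_percent,
            "ff_sd": self.ff_sd,
            "sir": self.sir,
            "grade": self.grade.value,
            "dominance_ambiguous": self.dominance_ambiguous,
        }


def steatosis_from_stats(liver_fat: Sequence[ROIStats],
                         liver_water: Sequence[ROIStats],
                         liver_ref: Sequence[ROIStats],
                         muscles_ref: Sequence[ROIStats],
                         thresholds: Thresholds = DEFAULT_THRESHOLDS
                         ) -> SteatosisResult:
    """Subject-level steatosis result from per-ROI fat/water statistics.

    ``liver_fat``/``liver_water`` are the three liver ROI statistics on
    the fat-only and water-only images (same ROI order);
    ``liver_ref``/``muscles_ref`` are liver and muscle statistics on the
    reference frame used for the SIR (fat-only by convention).  The
    fat fraction is computed per ROI and averaged across the three liver
    ROIs; a per-ROI FF above 50 % raises the dominance-ambiguity flag
    and is reported at 50 %.
    """
    if len(liver_fat) != 3 or len(liver_water) != 3:
        raise ValueError("need fat and water statistics for the 3 liver ROIs")
    ffs, ambiguous = [], False
    for f, w in zip(liver_fat, liver_water):
        ff = fat_fraction(f.mean, w.mean)
        if ff > 50.0:
            ff, ambiguous = 50.0, True
        ffs.append(ff)
    ffs = np.array(ffs)
    ff = float(ffs.mean())
    return SteatosisResult(
        ff_percent=ff,
        ff_sd=float(np.std(ffs, ddof=1)),
        sir=signal_intensity_ratio(liver_ref, muscles_ref),
        grade=grade_steatosis(ff, thresholds),
        dominance_ambiguous=ambiguous,
    )
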