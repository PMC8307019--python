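"""Fibrosis arm: linear calibration of T1 against HSA concentration.

Human serum albumin (HSA) is synthesised exclusively by the liver and its
concentration falls in advanced fibrosis, while the longitudinal
relaxation time T1 of albumin solutions falls as concentration rises.
Calibrating T1 maps against HSA phantoms of known concentration therefore
gives an inverse linear relation T1(HSA%) whose fitted line can be
solved backwards to express a measured liver T1 as an equivalent HSA
concentration — an exploratory biomarker, not a validated staging rule.

The calibration regresses T1 (ms, response) on concentration
(%, regressor) by ordinary least squares; inverse prediction solves the
fitted line rather than regressing concentration on T1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import RegionSummary

__all__ = [
    "PhantomMeasurement",
    "T1Calibration",
    "T1CalibrationResults",
    "HSAEstimate",
    "fit_calibration",
    "compare_t1",
    "T1Comparison",
]

HSA_RANGE_PERCENT = (0.0, 20.0)


class DegenerateDesignError(ValueError):
    """Calibration design cannot identify a line."""


@dataclass(frozen=True)
class PhantomMeasurement:
    """T1 measured on one HSA phantom of known concentration."""

    hsa_percent: float
    t1_ms: float
    sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (HSA_RANGE_PERCENT[0] <= self.hsa_percent <= HSA_RANGE_PERCENT[1]):
            raise ValueError("HSA concentration must lie in [0, 20] %")
        if self.t1_ms <= 0:
            raise ValueError("T1 must be positive")


@dataclass(frozen=True)
class HSAEstimate:
    """Inverse-predicted HSA concentration with an out-of-range flag."""

    hsa_percent: float
    out_of_range: bool


class T1Calibration:
    """OLS model of phantom T1 (ms) on HSA concentration (%).

    Parameters
    ----------
    hsa_percent, t1_ms : array-like
        Paired phantom observations; at least three distinct
        concentrations are required.

    Examples
    --------
    >>> model = T1Calibration([0, 10, 20], [1500, 1200, 900])
    >>> res = model.fit()
    >>> res.slope, res.intercept
    (-30.0, 1500.0)
    """

    def __init__(self, hsa_percent, t1_ms):
        x = np.asarray(hsa_percent, dtype=float)
        y = np.asarray(t1_ms, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("hsa_percent and t1_ms must be 1-D and paired")
        if x.size < 3:
            raise DegenerateDesignError(
                f"need at least 3 phantom measurements, got {x.size}")
        if np.unique(x).size < 3:
            raise DegenerateDesignError(
                "need at least 3 distinct HSA concentrations")
        self.hsa_percent = x
        self.t1_ms = y

    @classmethod
    def from_measurements(cls, points: Sequence[PhantomMeasurement]) -> "T1Calibration":
        return cls([p.hsa_percent for p in points], [p.t1_ms for p in points])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "hsa_percent",
                       y: str = "t1_ms") -> "T1Calibration":
        return cls(df[x].to_numpy(), df[y].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "T1Calibration":
        return cls.from_dataframe(pd.read_csv(path))

    def fit(self) -> "T1CalibrationResults":
        """Fit the line by ordinary least squares."""
        lr = sps.linregress(self.hsa_percent, self.t1_ms)
        return T1CalibrationResults(
            slope=float(lr.slope),
            intercept=float(lr.intercept),
            r_pearson=float(lr.rvalue),
            stderr_slope=float(lr.stderr),
            stderr_intercept=float(lr.intercept_stderr),
            nobs=int(self.hsa_percent.size),
            model=self,
        )


@dataclass
class T1CalibrationResults:
    """Fitted T1-vs-HSA calibration line.

    ``r_pearson`` carries the sign of the slope; ``r_squared`` is its
    square.  For a valid HSA calibration the slope is negative (T1 falls
    as protein concentration rises).
    """

    slope: float
    intercept: float
    r_pearson: float
    stderr_slope: float
    stderr_intercept: float
    nobs: int
    model: T1Calibration | None = None

    @property
    def r_squared(self) -> float:
        return self.r_pearson ** 2

    def predict_t1(self, hsa_percent) -> np.ndarray:
        """Evaluate the fitted line at the given concentration(s)."""
        return self.intercept + self.slope * np.asarray(hsa_percent, dtype=float)

    def predict_hsa(self, t1_ms: float) -> HSAEstimate:
        """Invert the fitted line: concentration matching a liver T1.

        Values outside the calibrated 0–20 % range are returned as-is
        with ``out_of_range=True``.
        """
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a calibration with zero slope")
        hsa = (t1_ms - self.intercept) / self.slope
        lo, hi = HSA_RANGE_PERCENT
        return HSAEstimate(hsa_percent=float(hsa), out_of_range=not lo <= hsa <= hi)

    def summary(self) -> str:
        lines = [
            "T1 vs HSA calibration (OLS)",
            "---------------------------",
            f"n phantoms        {self.nobs:>10d}",
            f"slope [ms/%]      {self.slope:>10.3f}  (SE {self.stderr_slope:.3f})",
            f"intercept [ms]    {self.intercept:>10.2f}  (SE {self.stderr_intercept:.2f})",
            f"Pearson r         {self.r_pearson:>10.4f}",
            f"R-squared         {self.r_squared:>10.4f}",
        ]
        if self.slope >= 0:
            lines.append("warning: non-negative slope — not a valid HSA calibration")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "slope_ms_per_percent": self.slope,
            "intercept_ms": self.intercept,
            "r_pearson": self.r_pearson,
            "r_squared": self.r_squared,
            "stderr_slope": self.stderr_slope,
            "stderr_intercept": self.stderr_intercept,
            "nobs": self.nobs,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "T1CalibrationResults":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(slope=d["slope_ms_per_percent"], intercept=d["intercept_ms"],
                   r_pearson=d["r_pearson"], stderr_slope=d.get("stderr_slope", np.nan),
                   stderr_intercept=d.get("stderr_intercept", np.nan),
                   nobs=d.get("nobs", 0))


def fit_calibration(points: Sequence[PhantomMeasurement]) -> T1CalibrationResults:
    """Convenience wrapper: fit the calibration from phantom measurements."""
    return T1Calibration.from_measurements(points).fit()


@dataclass(frozen=True)
class T1Comparison:
    """Ordered comparison of two subjects' mean liver T1."""

    higher: str  # "a", "b" or "equal"
    difference_ms: float  # |mean_a - mean_b|
    mean_a_ms: float
    mean_b_ms: float


def compare_t1(subject_a: RegionSummary, subject_b: RegionSummary) -> T1Comparison:
    """Compare the 3-ROI mean liver T1 of two subjects.

    Higher liver T1 is the direction expected with more fibrosis (fat and
    iron also shift T1; see the cross-contamination warnings in the
    report layer).
    """
    diff = subject_a.mean - subject_b.mean
    higher = "equal" if diff == 0 else ("a" if diff > 0 else "b")
    return T1Comparison(higher=higher, difference_ms=abs(float(diff)),
                        mean_a_ms=subject_a.mean, mean_b_ms=subject_b.mean)
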