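"""Synthetic phantom generator for every acquisition the pipeline reads.

Three generators mirror the three biomarker arms:

* :func:`make_hsa_phantom_t1map` — a T1 parameter map of circular vials
  at prescribed HSA concentrations, with T1 following a (negative-slope)
  line plus Gaussian noise, emulating a 7-vial albumin calibration
  phantom.
* :func:`make_dixon_pair` — an in-phase / opposed-phase magnitude pair
  of an abdominal phantom (liver segments, two paravertebral muscles,
  spleen, abdominal fat) with prescribed per-region fat fraction,
  proton density and T2*.
* :func:`make_multiecho_series` — a multi-echo gradient-echo series
  (alternating OOP/IP echoes, e.g. 10 x 2.4 ms at 1.5 T or
  12 x 1.2 ms at 3 T) with prescribed per-region T2* and a background
  noise floor.

The signal model is the two-point Dixon dichotomy: per region with
proton density ``pd`` and fat fraction ``ff``, water ``W = pd(1-ff/100)``
and fat ``F = pd·ff/100`` give ``|W+F|·exp(-TE/T2*)`` on in-phase and
``|W-F|·exp(-TE/T2*)`` on opposed-phase echoes.  Noise is Gaussian added
to the magnitude then clipped at 0 (adequate above SNR ~10), or exact
Rician on request; an optional constant baseline emulates a background
offset.  Every generator returns its ground truth, and a fixed seed
gives bit-identical output.

These phantoms are piecewise-constant ellipses — no anatomy, motion,
B1 inhomogeneity or continuous fat chemical-shift evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .images import EchoSeries, ImageFrame, Role, classify_phase
from .roi import LIVER_LABELS, EllipseROI, ROILabel

__all__ = [
    "PhantomRegion",
    "PhantomSpec",
    "default_phantom_spec",
    "default_rois",
    "make_hsa_phantom_t1map",
    "make_dixon_pair",
    "make_multiecho_series",
    "simulate_calibration_points",
    "HSA_CONCENTRATIONS_PERCENT",
]

#: Vial concentrations of the 7-phantom HSA calibration set (%).
HSA_CONCENTRATIONS_PERCENT = (0.0, 2.5, 5.0, 8.0, 11.0, 16.0, 20.0)


@dataclass(frozen=True)
class PhantomRegion:
    """One elliptical tissue region with its true MR parameters."""

    label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    proton_density: float = 1000.0  # a.u.
    t1_ms: float = 800.0
    t2star_ms: float = 30.0         # np.inf = no decay
    ff_percent: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff_percent <= 100.0:
            raise ValueError("fat fraction must lie in [0, 100] %")
        if self.proton_density < 0:
            raise ValueError("proton density cannot be negative")
        if self.t2star_ms <= 0:
            raise ValueError("T2* must be positive")

    def ellipse(self) -> EllipseROI:
        return EllipseROI(label=ROILabel(self.label), center=self.center,
                          semi_axes=self.semi_axes)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        r0, c0 = self.center
        a, b = self.semi_axes
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and acquisition conditions of a synthetic abdominal phantom."""

    layout: tuple[PhantomRegion, ...]
    field_t: float = 1.5
    shape: tuple[int, int] = (128, 128)
    noise_sd: float = 0.0       # a.u., on the magnitude
    baseline: float = 0.0       # constant background offset, a.u.
    noise_model: str = "gaussian"  # "gaussian" (clipped) or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("noise_sd and baseline cannot be negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        taken = np.zeros(self.shape, dtype=bool)
        for region in self.layout:
            m = region.mask(self.shape)
            if (taken & m).any():
                raise ValueError(f"region {region.label} overlaps another region")
            taken |= m

    def region(self, label: str) -> PhantomRegion:
        for r in self.layout:
            if r.label == label:
                return r
        raise KeyError(label)

    def with_liver(self, **updates) -> "PhantomSpec":
        """Copy of the spec with all liver regions' parameters updated."""
        layout = tuple(
            replace(r, **updates) if r.label in LIVER_LABELS else r
            for r in self.layout
        )
        return replace(self, layout=layout)


def default_phantom_spec(field_t: float = 1.5, *, liver_ff: float = 0.0,
                         liver_t2star: float = 30.0, noise_sd: float = 0.0,
                         baseline: float = 0.0, noise_model: str = "gaussian",
                         seed: int = 0) -> PhantomSpec:
    """Abdominal phantom on a 128 x 128 matrix.

    Three liver regions (stand-ins for Couinaud segments IV, VIII, VII)
    share the liver parameters; the paravertebral muscles, spleen and
    abdominal fat carry typical relative proton densities and T2*
    values (muscle ~25 ms, spleen ~60 ms, fat nearly pure fat signal).
    """
    liver = dict(proton_density=1000.0, t2star_ms=liver_t2star,
                 ff_percent=liver_ff, t1_ms=800.0)
    layout = (
        PhantomRegion("LIVER_IV", (40.0, 40.0), (12.0, 14.0), **liver),
        PhantomRegion("LIVER_VIII", (42.0, 75.0), (12.0, 14.0), **liver),
        PhantomRegion("LIVER_VII", (70.0, 58.0), (12.0, 14.0), **liver),
        PhantomRegion("MUSCLE_L", (104.0, 44.0), (8.0, 10.0),
                      proton_density=700.0, t2star_ms=25.0, t1_ms=1000.0),
        PhantomRegion("MUSCLE_R", (104.0, 84.0), (8.0, 10.0),
                      proton_density=700.0, t2star_ms=25.0, t1_ms=1000.0),
        PhantomRegion("SPLEEN", (44.0, 108.0), (10.0, 8.0),
                      proton_density=900.0, t2star_ms=60.0, t1_ms=1200.0),
        PhantomRegion("ABDOMINAL_FAT", (14.0, 64.0), (7.0, 30.0),
                      proton_density=800.0, t2star_ms=40.0, ff_percent=95.0,
                      t1_ms=350.0),
    )
    return PhantomSpec(layout=layout, field_t=field_t, noise_sd=noise_sd,
                       baseline=baseline, noise_model=noise_model, seed=seed)


def default_rois(spec: PhantomSpec, shrink: float = 0.6,
                 noise_center: tuple[float, float] | None = None,
                 noise_axes: tuple[float, float] = (8.0, 8.0)
                 ) -> list[EllipseROI]:
    """Measurement ROIs matching a phantom layout.

    One concentric ellipse per region with semi-axes scaled by
    ``shrink`` (stays clear of region edges), plus a background NOISE
    ROI near the image corner.
    """
    rois = [
        EllipseROI(label=ROILabel(r.label), center=r.center,
                   semi_axes=(r.semi_axes[0] * shrink, r.semi_axes[1] * shrink))
        for r in spec.layout
    ]
    if noise_center is None:
        noise_center = (spec.shape[0] - 12.0, 12.0)
    rois.append(EllipseROI(label=ROILabel.NOISE, center=noise_center,
                           semi_axes=noise_axes))
    return rois


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def _add_noise(clean: np.ndarray, sd: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return clean.copy()
    if model == "rician":
        re = clean + rng.normal(0.0, sd, clean.shape)
        im = rng.normal(0.0, sd, clean.shape)
        return np.hypot(re, im)
    return np.clip(clean + rng.normal(0.0, sd, clean.shape), 0.0, None)


# ---------------------------------------------------------------------------
# HSA calibration phantom
# ---------------------------------------------------------------------------


def make_hsa_phantom_t1map(
    concentrations: Sequence[float] = HSA_CONCENTRATIONS_PERCENT,
    true_slope: float = -30.0,
    true_intercept: float = 1500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    field_t: float = 3.0,
    shape: tuple[int, int] = (96, 224),
    radius: float = 12.0,
) -> tuple[ImageFrame, pd.DataFrame]:
    """T1 map of circular HSA vials plus its ground-truth table.

    Vials are laid out on a horizontal line; each vial's pixels are the
    true line ``t1 = true_intercept + true_slope * concentration`` plus
    Gaussian noise of SD ``noise_sd`` (ms).  The ground truth table has
    one row per vial: ``hsa_percent, true_t1_ms, row, col, radius``.

    The slope must be negative: T1 falls as protein concentration rises.

    Raises
    ------
    ValueError
        Concentrations outside [0, 20] %, non-negative slope, or vials
        that would overlap at the requested radius.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any((conc < 0) | (conc > 20)):
        raise ValueError("HSA concentrations must lie in [0, 20] %")
    if true_slope >= 0:
        raise ValueError("the HSA calibration slope must be negative")
    n = conc.size
    gap = shape[1] / n
    if gap < 2 * radius + 2:
        raise ValueError(
            f"{n} vials of radius {radius} px overlap on a {shape[1]}-px-wide image")
    rng = np.random.default_rng(seed)
    pixels = np.zeros(shape)
    rows = []
    r0 = shape[0] / 2
    for i, c in enumerate(conc):
        c0 = gap * (i + 0.5)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        true_t1 = true_intercept + true_slope * c
        if true_t1 <= 0:
            raise ValueError(f"true T1 non-positive at {c}% HSA")
        values = true_t1 + rng.normal(0.0, noise_sd, int(mask.sum()))
        pixels[mask] = np.clip(values, 0.0, None)
        rows.append({"hsa_percent": float(c), "true_t1_ms": float(true_t1),
                     "row": float(r0), "col": float(c0), "radius": float(radius)})
    frame = ImageFrame(pixels, field_t=field_t, role=Role.T1_MAP)
    return frame, pd.DataFrame(rows)


def simulate_calibration_points(
    concentrations: Sequence[float] = HSA_CONCENTRATIONS_PERCENT,
    true_slope: float = -30.0,
    true_intercept: float = 1500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Measurement-level calibration points (no image rendering).

    One noisy T1 observation per concentration; columns
    ``hsa_percent, t1_ms, true_t1_ms``.  Lighter than rendering a full
    phantom image when only the regression is under test.
    """
    if true_slope >= 0:
        raise ValueError("the HSA calibration slope must be negative")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    true_t1 = true_intercept + true_slope * conc
    t1 = true_t1 + rng.normal(0.0, noise_sd, conc.size)
    return pd.DataFrame({"hsa_percent": conc, "t1_ms": t1, "true_t1_ms": true_t1})


# ---------------------------------------------------------------------------
# Dixon pair and multi-echo series
# ---------------------------------------------------------------------------


def _clean_image(spec: PhantomSpec, te_ms: float, role: Role) -> np.ndarray:
    """Noise-free magnitude image of the phantom at one echo."""
    img = np.zeros(spec.shape)
    for region in spec.layout:
        w = region.proton_density * (1.0 - region.ff_percent / 100.0)
        f = region.proton_density * region.ff_percent / 100.0
        amplitude = abs(w + f) if role is Role.IN_PHASE else abs(w - f)
        decay = np.exp(-te_ms / region.t2star_ms) if np.isfinite(region.t2star_ms) else 1.0
        img[region.mask(spec.shape)] = amplitude * decay
    return img + spec.baseline


def make_dixon_pair(spec: PhantomSpec, te_ip: float, te_oop: float):
    """Synthetic IP/OOP magnitude pair plus per-region ground truth.

    Echo times must classify to the stated phase at the spec's field
    strength.  Returns ``(DixonPair, DataFrame)`` where the table lists
    per region the true fat fraction, water/fat amplitudes and T2*.
    """
    from .dixon import DixonPair  # local import to avoid a cycle

    if classify_phase(te_ip, spec.field_t) is not Role.IN_PHASE:
        raise ValueError(f"TE={te_ip} ms is not an in-phase echo at {spec.field_t} T")
    if classify_phase(te_oop, spec.field_t) is not Role.OPPOSED_PHASE:
        raise ValueError(f"TE={te_oop} ms is not an opposed-phase echo at {spec.field_t} T")
    rng = np.random.default_rng(spec.seed)
    ip = _add_noise(_clean_image(spec, te_ip, Role.IN_PHASE),
                    spec.noise_sd, spec.noise_model, rng)
    oop = _add_noise(_clean_image(spec, te_oop, Role.OPPOSED_PHASE),
                     spec.noise_sd, spec.noise_model, rng)
    pair = DixonPair(
        ip=ImageFrame(ip, field_t=spec.field_t, role=Role.IN_PHASE, te_ms=te_ip),
        oop=ImageFrame(oop, field_t=spec.field_t, role=Role.OPPOSED_PHASE, te_ms=te_oop),
    )
    truth = pd.DataFrame([
        {"label": r.label, "ff_true_percent": r.ff_percent,
         "proton_density": r.proton_density, "t2star_ms": r.t2star_ms,
         "water": r.proton_density * (1 - r.ff_percent / 100.0),
         "fat": r.proton_density * r.ff_percent / 100.0}
        for r in spec.layout
    ])
    return pair, truth


def make_multiecho_series(spec: PhantomSpec, n_echoes: int = 10,
                          echo_spacing_ms: float | None = None):
    """Synthetic multi-echo gradient-echo series plus ground truth.

    Echoes sit at ``TE = k * spacing`` for ``k = 1..n_echoes`` with the
    field's base spacing by default (2.4 ms at 1.5 T, 1.2 ms at 3 T), so
    phases alternate OOP/IP starting opposed-phase.  Per-region signal
    follows the two-point Dixon model with exponential T2* decay; the
    spec's baseline and noise supply the background floor.

    Returns ``(EchoSeries, DataFrame)`` with the same per-region truth
    table as :func:`make_dixon_pair`.
    """
    from .config import BASE_ECHO_SPACING_MS

    if n_echoes < 4:
        raise ValueError("a decay series needs at least 4 echoes")
    if echo_spacing_ms is None:
        echo_spacing_ms = BASE_ECHO_SPACING_MS[spec.field_t]
    rng = np.random.default_rng(spec.seed)
    frames = []
    for k in range(1, n_echoes + 1):
        te = k * echo_spacing_ms
        role = classify_phase(te, spec.field_t)
        clean = _clean_image(spec, te, role)
        noisy = _add_noise(clean, spec.noise_sd, spec.noise_model, rng)
        frames.append(ImageFrame(noisy, field_t=spec.field_t, role=role, te_ms=te))
    series = EchoSeries(frames, field_t=spec.field_t,
                        echo_spacing_ms=float(echo_spacing_ms))
    truth = pd.DataFrame([
        {"label": r.label, "ff_true_percent": r.ff_percent,
         "proton_density": r.proton_density, "t2star_ms": r.t2star_ms,
         "water": r.proton_density * (1 - r.ff_percent / 100.0),
         "fat": r.proton_density * r.ff_percent / 100.0}
        for r in spec.layout
    ])
    return series, truth
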