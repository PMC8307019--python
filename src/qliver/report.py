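"""Subject-level reporting: tie the three biomarker arms together.

A :class:`BiomarkerReport` collects whatever arms were measured for one
subject — liver T1 (with an optional HSA-equivalent estimate from a
calibration), Dixon fat fraction with steatosis grade, and T2*/LIC with
iron grade — plus the cross-contamination warnings that fat and iron
raise against each other's estimates (and against T1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .config import DEFAULT_THRESHOLDS, Thresholds
from .dixon import (DixonPair, SteatosisResult, reconstruct_fat_water,
                    steatosis_from_stats)
from .images import EchoSeries, ImageFrame, Role
from .roi import (LIVER_LABELS, MUSCLE_LABELS, EllipseROI, ROILabel,
                  RegionSummary, liver_summary, roi_stats, stats_table)
from .t1 import HSAEstimate, T1CalibrationResults
from .t2star import (DecayFitError, IronResult, T2StarDecay, T2StarDecayResults)

__all__ = [
    "Warning_",
    "cross_contamination_warnings",
    "BiomarkerReport",
    "t1_arm",
    "steatosis_arm",
    "iron_arm",
    "build_report",
    "run_pipeline",
    "PipelineInputs",
]


class Warning_(str, Enum):
    """Reproducible warning flags derived from the numeric fields."""

    FAT_AFFECTS_T2STAR = "FAT_AFFECTS_T2STAR"
    IRON_AFFECTS_FF = "IRON_AFFECTS_FF"
    OMIT_FF = "OMIT_FF"
    T1_AFFECTED_BY_FAT_IRON = "T1_AFFECTED_BY_FAT_IRON"
    CALIBRATION_OUT_OF_RANGE = "CALIBRATION_OUT_OF_RANGE"
    LIC_1P5T_APPROXIMATE = "LIC_1P5T_APPROXIMATE"


def cross_contamination_warnings(ff_percent: float, lic_umol_g: float,
                                 thresholds: Thresholds = DEFAULT_THRESHOLDS
                                 ) -> set[Warning_]:
    """Mutual-interference warnings between the fat and iron arms.

    Fat above the steatosis threshold corrupts the mono-exponential T2*
    decay (fat–water oscillation); iron above the overload threshold
    depresses in-phase signal and hence the fat estimate; with severe
    iron overload the fat calculation is unreliable enough to omit.
    """
    warnings: set[Warning_] = set()
    if ff_percent >= thresholds.ff_mild:
        warnings.add(Warning_.FAT_AFFECTS_T2STAR)
    if lic_umol_g >= thresholds.lic_mild:
        warnings.add(Warning_.IRON_AFFECTS_FF)
    if lic_umol_g > thresholds.lic_severe:
        warnings.add(Warning_.OMIT_FF)
    return warnings


@dataclass
class BiomarkerReport:
    """Per-subject non-invasive liver biomarker panel."""

    subject_id: str
    field_t: float
    t1_liver_ms: float | None = None
    t1_sd_ms: float | None = None
    hsa_percent: float | None = None
    hsa_out_of_range: bool = False
    steatosis: SteatosisResult | None = None
    iron: IronResult | None = None
    warnings: set[Warning_] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "field_t": self.field_t,
            "t1_liver_ms": self.t1_liver_ms,
            "t1_sd_ms": self.t1_sd_ms,
            "hsa_percent": self.hsa_percent,
            "hsa_out_of_range": self.hsa_out_of_range,
            "steatosis": None if self.steatosis is None else self.steatosis.to_dict(),
            "iron": None if self.iron is None else self.iron.to_dict(),
            "warnings": sorted(w.value for w in self.warnings),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BiomarkerReport":
        from .dixon import SteatosisGrade
        from .t2star import IronGrade

        p = Path(source)
        d = json.loads(p.read_text()) if p.exists() else json.loads(str(source))
        steat = d.get("steatosis")
        iron = d.get("iron")
        return cls(
            subject_id=d["subject_id"], field_t=d["field_t"],
            t1_liver_ms=d.get("t1_liver_ms"), t1_sd_ms=d.get("t1_sd_ms"),
            hsa_percent=d.get("hsa_percent"),
            hsa_out_of_range=d.get("hsa_out_of_range", False),
            steatosis=None if steat is None else SteatosisResult(
                ff_percent=steat["ff_percent"], ff_sd=steat["ff_sd"],
                sir=steat["sir"], grade=SteatosisGrade(steat["grade"]),
                dominance_ambiguous=steat["dominance_ambiguous"]),
            iron=None if iron is None else IronResult(
                t2star_ms=iron["t2star_ms"], r2star_s=iron["r2star_s"],
                lic_umol_g=iron["lic_umol_g"], lic_rounded=iron["lic_rounded"],
                grade=IronGrade(iron["grade"]), field_t=iron["field_t"],
                approximate=iron["approximate"], clamped=iron["clamped"]),
            warnings={Warning_(w) for w in d.get("warnings", [])},
        )

    def summary(self) -> str:
        lines = [f"Subject {self.subject_id}  ({self.field_t} T)",
                 "-" * 40]
        if self.t1_liver_ms is not None:
            lines.append(f"liver T1        {self.t1_liver_ms:8.2f} ms "
                         f"(SD across ROIs {self.t1_sd_ms:.2f})")
            if self.hsa_percent is not None:
                flag = "  [outside 0-20% calibration]" if self.hsa_out_of_range else ""
                lines.append(f"HSA equivalent  {self.hsa_percent:8.2f} %{flag}")
        if self.steatosis is not None:
            s = self.steatosis
            lines.append(f"fat fraction    {s.ff_percent:8.2f} %  "
                         f"(SD {s.ff_sd:.2f}) -> {s.grade.value}")
            lines.append(f"SIR             {s.sir:8.3f}")
        if self.iron is not None:
            i = self.iron
            lines.append(f"T2*             {i.t2star_ms:8.2f} ms  "
                         f"(R2* {i.r2star_s:.1f} 1/s)")
            lines.append(f"LIC             {i.lic_umol_g:8.1f} µmol/g "
                         f"(~{i.lic_rounded}) -> {i.grade.value}")
        if self.warnings:
            lines.append("warnings: " + ", ".join(sorted(w.value for w in self.warnings)))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Per-arm drivers working on frames + ROI lists
# ---------------------------------------------------------------------------


def _pick(rois: list[EllipseROI], labels) -> list[EllipseROI]:
    by_label = {r.label.value: r for r in rois}
    missing = [l for l in labels if l not in by_label]
    if missing:
        raise ValueError(f"missing ROI labels for this arm: {missing}")
    return [by_label[l] for l in labels]


def t1_arm(t1_map: ImageFrame, rois: list[EllipseROI],
           calibration: T1CalibrationResults | None = None
           ) -> tuple[RegionSummary, HSAEstimate | None]:
    """Liver T1 summary (3-ROI protocol) and optional HSA estimate."""
    if t1_map.role is not Role.T1_MAP:
        raise ValueError("t1_arm requires a T1_MAP frame")
    liver = [roi_stats(t1_map, r) for r in _pick(rois, LIVER_LABELS)]
    summary = liver_summary(liver)
    hsa = calibration.predict_hsa(summary.mean) if calibration is not None else None
    return summary, hsa


def steatosis_arm(pair: DixonPair, rois: list[EllipseROI],
                  thresholds: Thresholds = DEFAULT_THRESHOLDS) -> SteatosisResult:
    """Fat fraction and SIR from an IP/OOP pair and the ROI protocol."""
    fat, water = reconstruct_fat_water(pair)
    liver_rois = _pick(rois, LIVER_LABELS)
    muscle_rois = _pick(rois, MUSCLE_LABELS)
    # SIR reference frame: fat-only by convention; muscle carries no fat,
    # so if its fat-only signal is entirely noise-clipped fall back to IP.
    ref_frame = fat
    if all(roi_stats(fat, r).mean <= 0 for r in muscle_rois):
        ref_frame = pair.ip
    return steatosis_from_stats(
        liver_fat=[roi_stats(fat, r) for r in liver_rois],
        liver_water=[roi_stats(water, r) for r in liver_rois],
        liver_ref=[roi_stats(ref_frame, r) for r in liver_rois],
        muscles_ref=[roi_stats(ref_frame, r) for r in muscle_rois],
        thresholds=thresholds,
    )


def iron_arm(series: EchoSeries, rois: list[EllipseROI],
             thresholds: Thresholds = DEFAULT_THRESHOLDS,
             ip_only: bool = False) -> tuple[IronResult, T2StarDecayResults]:
    """T2* fit of the liver decay and LIC conversion.

    The liver signal per echo is the mean of the three liver ROI means;
    the noise floor is the mean NOISE-ROI signal across echoes.
    """
    liver_rois = _pick(rois, LIVER_LABELS)
    noise_roi = _pick(rois, ("NOISE",))[0]
    liver_signal = [
        float(np.mean([roi_stats(f, r).mean for r in liver_rois]))
        for f in series.frames
    ]
    noise_floor = float(np.mean([roi_stats(f, noise_roi).mean
                                 for f in series.frames]))
    model = T2StarDecay(series.te_ms, liver_signal, noise_floor=noise_floor,
                        phases=series.roles)
    results = model.fit(ip_only=ip_only)
    return results.lic(series.field_t, thresholds), results


def echo_table(series: EchoSeries, rois: list[EllipseROI]):
    """Per-echo ROI means (te_ms, phase, liver, spleen, muscle, noise)."""
    import pandas as pd

    liver_rois = _pick(rois, LIVER_LABELS)
    by_label = {r.label.value: r for r in rois}
    rows = []
    for f in series.frames:
        row = {"te_ms": f.te_ms, "phase": f.role.value,
               "liver_mean": float(np.mean([roi_stats(f, r).mean
                                            for r in liver_rois]))}
        for lbl, col in (("SPLEEN", "spleen_mean"), ("MUSCLE_L", "muscle_l_mean"),
                         ("MUSCLE_R", "muscle_r_mean"), ("NOISE", "noise_mean")):
            if lbl in by_label:
                row[col] = roi_stats(f, by_label[lbl]).mean
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-subject pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    """In-memory inputs for one subject; any arm may be absent."""

    subject_id: str
    field_t: float
    rois: list[EllipseROI]
    t1_map: ImageFrame | None = None
    dixon: DixonPair | None = None
    multiecho: EchoSeries | None = None
    calibration: T1CalibrationResults | None = None
    thresholds: Thresholds = DEFAULT_THRESHOLDS


def build_report(inputs: PipelineInputs) -> BiomarkerReport:
    """Execute every arm whose inputs are present and assemble the report."""
    if inputs.t1_map is None and inputs.dixon is None and inputs.multiecho is None:
        raise ValueError("at least one arm's inputs must be present")
    report = BiomarkerReport(subject_id=inputs.subject_id, field_t=inputs.field_t)

    if inputs.dixon is not None:
        report.steatosis = steatosis_arm(inputs.dixon, inputs.rois,
                                         inputs.thresholds)
    if inputs.multiecho is not None:
        ip_only = (report.steatosis is not None
                   and report.steatosis.ff_percent >= inputs.thresholds.ff_mild)
        try:
            report.iron, _ = iron_arm(inputs.multiecho, inputs.rois,
                                      inputs.thresholds, ip_only=ip_only)
        except DecayFitError:
            if not ip_only:
                raise
            # too few in-phase echoes above the floor: fall back to all echoes
            report.iron, _ = iron_arm(inputs.multiecho, inputs.rois,
                                      inputs.thresholds, ip_only=False)
    if inputs.t1_map is not None:
        summary, hsa = t1_arm(inputs.t1_map, inputs.rois, inputs.calibration)
        report.t1_liver_ms = summary.mean
        report.t1_sd_ms = summary.sd_across
        if hsa is not None:
            report.hsa_percent = hsa.hsa_percent
            report.hsa_out_of_range = hsa.out_of_range
            if hsa.out_of_range:
                report.warnings.add(Warning_.CALIBRATION_OUT_OF_RANGE)

    ff = report.steatosis.ff_percent if report.steatosis is not None else 0.0
    lic = report.iron.lic_umol_g if report.iron is not None else 0.0
    report.warnings |= cross_contamination_warnings(ff, lic, inputs.thresholds)
    if report.t1_liver_ms is not None and (
            ff >= inputs.thresholds.ff_mild or lic >= inputs.thresholds.lic_mild):
        report.warnings.add(Warning_.T1_AFFECTED_BY_FAT_IRON)
    if report.iron is not None and report.iron.approximate:
        report.warnings.add(Warning_.LIC_1P5T_APPROXIMATE)
    return report


def run_pipeline(inputs: PipelineInputs, out_dir: str | Path | None = None
                 ) -> BiomarkerReport:
    """Build the subject report and, if requested, write its artifacts.

    Writes ``report.json``, per-ROI statistics CSVs, the per-echo signal
    CSV and the decay-curve plot into ``out_dir``.
    """
    report = build_report(inputs)
    if out_dir is None:
        return report
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / "report.json")
    if inputs.t1_map is not None:
        t1_stats = [roi_stats(inputs.t1_map, r)
                    for r in _pick(inputs.rois, LIVER_LABELS)]
        stats_table(t1_stats).to_csv(out / "t1_roi_stats.csv", index=False)
    if inputs.dixon is not None:
        fat, water = reconstruct_fat_water(inputs.dixon)
        usable = [r for r in inputs.rois if r.label is not ROILabel.NOISE]
        stats_table([roi_stats(fat, r) for r in usable]
                    ).to_csv(out / "fat_only_roi_stats.csv", index=False)
        stats_table([roi_stats(water, r) for r in usable]
                    ).to_csv(out / "water_only_roi_stats.csv", index=False)
    if inputs.multiecho is not None:
        echo_table(inputs.multiecho, inputs.rois).to_csv(
            out / "echo_signals.csv", index=False)
        try:
            _, decay = iron_arm(inputs.multiecho, inputs.rois, inputs.thresholds)
            import matplotlib
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            ax = decay.plot()
            ax.figure.savefig(out / "decay_fit.svg", bbox_inches="tight")
            plt.close(ax.figure)
        except DecayFitError:
            pass
    return report
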