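"""Subject-level reports, cross-contamination warnings, pipeline and CLI."""

import json

import numpy as np
import pytest

from qliver import (BiomarkerReport, PipelineInputs, Warning_, build_report,
                    cross_contamination_warnings, run_pipeline)
from qliver import synth


@pytest.mark.parametrize(
    "ff, lic, expected",
    [
        (3.1, 19.0, set()),  # no-disease subject values
        (17.5, 95.0, {Warning_.FAT_AFFECTS_T2STAR, Warning_.IRON_AFFECTS_FF,
                      Warning_.OMIT_FF}),  # moderate steatosis + severe iron
        (6.4, 36.0, {Warning_.FAT_AFFECTS_T2STAR, Warning_.IRON_AFFECTS_FF}),
        (24.8, 0.0, {Warning_.FAT_AFFECTS_T2STAR}),
        (0.0, 80.0, {Warning_.IRON_AFFECTS_FF}),
        (0.0, 80.1, {Warning_.IRON_AFFECTS_FF, Warning_.OMIT_FF}),
    ],
)
def test_cross_contamination_warning_table(ff, lic, expected):
    assert cross_contamination_warnings(ff, lic) == expected


def _subject_inputs(liver_ff=0.0, liver_t2star=30.0, field=1.5, seed=0,
                    noise_sd=10.0, dixon_t2star=None):
    spec = synth.default_phantom_spec(field, liver_ff=liver_ff,
                                      liver_t2star=liver_t2star,
                                      noise_sd=noise_sd, noise_model="rician",
                                      seed=seed)
    n_echoes = 10 if field == 1.5 else 12
    series, _ = synth.make_multiecho_series(spec, n_echoes=n_echoes)
    dixon_spec = spec.with_liver(
        t2star_ms=np.inf if dixon_t2star is None else dixon_t2star)
    spacing = 2.4 if field == 1.5 else 1.2
    pair, _ = synth.make_dixon_pair(dixon_spec, te_ip=2 * spacing, te_oop=spacing)
    return PipelineInputs(subject_id="synthetic", field_t=field,
                          rois=synth.default_rois(spec), dixon=pair,
                          multiecho=series)


def test_no_disease_subject_reports_clean():
    report = build_report(_subject_inputs())
    assert report.steatosis.grade.value == "NONE"
    assert report.iron.grade.value == "NONE"
    # the 1.5 T LIC path is always flagged approximate; nothing else
    assert report.warnings <= {Warning_.LIC_1P5T_APPROXIMATE}


def test_severe_steatosis_without_iron():
    report = build_report(_subject_inputs(liver_ff=24.8, liver_t2star=40.0))
    assert report.steatosis.grade.value == "SEVERE"
    assert report.iron.grade.value == "NONE"
    assert Warning_.FAT_AFFECTS_T2STAR in report.warnings
    assert Warning_.OMIT_FF not in report.warnings


def test_moderate_steatosis_with_severe_iron_mirrors_worked_case():
    """FF 17.5 % with T2* 6.2 ms at 1.5 T: moderate steatosis, severe
    iron overload, and mutual-interference warnings both ways."""
    report = build_report(_subject_inputs(liver_ff=17.5, liver_t2star=6.2,
                                          noise_sd=5.0))
    assert report.steatosis.grade.value == "MODERATE"
    assert report.iron.grade.value == "SEVERE"
    assert {Warning_.FAT_AFFECTS_T2STAR, Warning_.IRON_AFFECTS_FF,
            Warning_.OMIT_FF} <= report.warnings


def test_report_json_roundtrip_and_determinism(tmp_path):
    report = build_report(_subject_inputs(liver_ff=16.8, seed=3))
    p = tmp_path / "report.json"
    report.to_json(p)
    back = BiomarkerReport.from_json(p)
    assert back.to_dict() == report.to_dict()
    # identical inputs give a bit-identical report
    again = build_report(_subject_inputs(liver_ff=16.8, seed=3))
    assert again.to_json() == report.to_json()


def test_missing_roi_labels_are_listed():
    inputs = _subject_inputs()
    inputs.rois = [r for r in inputs.rois if not r.label.value.startswith("MUSCLE")]
    with pytest.raises(ValueError, match="MUSCLE_L"):
        build_report(inputs)


def test_at_least_one_arm_required():
    with pytest.raises(ValueError):
        build_report(PipelineInputs(subject_id="x", field_t=1.5, rois=[]))


def test_t1_arm_with_calibration_flags_fat_iron_influence():
    from qliver import ImageFrame, Role, T1Calibration
    from qliver.synth import HSA_CONCENTRATIONS_PERCENT

    x = np.array(HSA_CONCENTRATIONS_PERCENT)
    calibration = T1Calibration(x, -30.0 * x + 1500.0).fit()
    inputs = _subject_inputs(liver_ff=24.8, liver_t2star=40.0)
    # synthetic T1 map: constant liver-like 900 ms everywhere
    inputs.t1_map = ImageFrame(np.full((128, 128), 900.0), field_t=1.5,
                               role=Role.T1_MAP)
    inputs.calibration = calibration
    report = build_report(inputs)
    assert report.t1_liver_ms == pytest.approx(900.0)
    assert report.hsa_percent == pytest.approx((900.0 - 1500.0) / -30.0)
    assert Warning_.T1_AFFECTED_BY_FAT_IRON in report.warnings


def test_run_pipeline_writes_artifacts(tmp_path):
    report = run_pipeline(_subject_inputs(seed=5), out_dir=tmp_path)
    assert (tmp_path / "report.json").exists()
    assert (tmp_path / "echo_signals.csv").exists()
    assert (tmp_path / "decay_fit.svg").exists()
    assert (tmp_path / "fat_only_roi_stats.csv").exists()
    loaded = json.loads((tmp_path / "report.json").read_text())
    assert loaded["subject_id"] == "synthetic"
    assert loaded["iron"]["grade"] == report.iron.grade.value


def test_cli_end_to_end(tmp_path):
    from click.testing import CliRunner

    from qliver.cli import main

    runner = CliRunner()
    sim_dir = tmp_path / "subject"
    result = runner.invoke(main, ["simulate", "--out", str(sim_dir),
                                  "--field", "1.5", "--seed", "2"])
    assert result.exit_code == 0, result.output
    out_dir = tmp_path / "out"
    result = runner.invoke(main, [
        "report", "--multiecho", str(sim_dir / "multiecho.nii"),
        "--ip", str(sim_dir / "dixon_ip.nii"),
        "--oop", str(sim_dir / "dixon_oop.nii"),
        "--rois", str(sim_dir / "rois.json"),
        "--field", "1.5", "--out", str(out_dir)])
    assert result.exit_code == 0, result.output
    assert (out_dir / "report.json").exists()
    result = runner.invoke(main, ["calibrate-t1", "--points",
                                  str(_write_points_csv(tmp_path))])
    assert result.exit_code == 0, result.output
    assert json.loads(result.stdout)["slope_ms_per_percent"] < 0


def _write_points_csv(tmp_path):
    df = synth.simulate_calibration_points(noise_sd=10.0, seed=1)
    path = tmp_path / "points.csv"
    df.to_csv(path, index=False)
    return path
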