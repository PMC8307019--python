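"""Synthetic phantom generators: determinism, ground truth, invariants."""

import numpy as np
import pytest

from qliver import Role, fit_calibration, PhantomMeasurement
from qliver.roi import roi_stats
from qliver import synth
from qliver.synth import (PhantomRegion, PhantomSpec, default_phantom_spec,
                          default_rois, make_dixon_pair, make_hsa_phantom_t1map,
                          make_multiecho_series, simulate_calibration_points)


def test_fixed_seed_gives_bit_identical_output():
    spec = default_phantom_spec(1.5, noise_sd=12.0, seed=99)
    s1, _ = make_multiecho_series(spec, n_echoes=10)
    s2, _ = make_multiecho_series(spec, n_echoes=10)
    for a, b in zip(s1.frames, s2.frames):
        assert np.array_equal(a.pixels, b.pixels)
    f1, _ = make_hsa_phantom_t1map(noise_sd=15.0, seed=5)
    f2, _ = make_hsa_phantom_t1map(noise_sd=15.0, seed=5)
    assert np.array_equal(f1.pixels, f2.pixels)


def test_overlapping_regions_are_rejected():
    with pytest.raises(ValueError, match="overlap"):
        PhantomSpec(layout=(
            PhantomRegion("LIVER_IV", (20.0, 20.0), (10.0, 10.0)),
            PhantomRegion("SPLEEN", (25.0, 25.0), (10.0, 10.0)),
        ), shape=(64, 64))


def test_overlapping_vials_are_rejected():
    with pytest.raises(ValueError, match="overlap"):
        make_hsa_phantom_t1map(shape=(64, 64), radius=12.0)


def test_ip_at_least_oop_before_noise():
    """|W+F| >= |W-F|: on a decay-free phantom the in-phase image
    dominates the opposed-phase image pixelwise (pre-noise).  With T2*
    decay the comparison also involves the different echo times, so the
    amplitude invariant is checked decay-free."""
    for ff in (0.0, 16.8, 50.0, 95.0):
        spec = default_phantom_spec(1.5, liver_ff=ff, liver_t2star=np.inf)
        spec = PhantomSpec(
            layout=tuple(synth.PhantomRegion(
                r.label, r.center, r.semi_axes, r.proton_density, r.t1_ms,
                np.inf, r.ff_percent) for r in spec.layout),
            field_t=1.5)
        pair, truth = make_dixon_pair(spec, te_ip=4.8, te_oop=2.4)
        assert np.all(pair.ip.pixels >= pair.oop.pixels - 1e-12)
        assert np.all(abs(truth.water + truth.fat) >= abs(truth.water - truth.fat))


def test_dixon_pair_validates_phase_te_consistency():
    spec = default_phantom_spec(1.5)
    with pytest.raises(ValueError):
        make_dixon_pair(spec, te_ip=2.4, te_oop=4.8)  # phases swapped


def test_multiecho_alternates_phases_and_spaces_echoes():
    spec = default_phantom_spec(3.0)
    series, _ = make_multiecho_series(spec, n_echoes=12)
    assert len(series) == 12
    np.testing.assert_allclose(series.te_ms, np.arange(1, 13) * 1.2)
    assert series.roles[0] is Role.OPPOSED_PHASE
    assert series.roles[1] is Role.IN_PHASE
    assert all(a is not b for a, b in zip(series.roles, series.roles[1:]))


def test_noise_free_zero_fat_series_fits_exactly():
    spec = default_phantom_spec(1.5, liver_t2star=10.0)
    series, truth = make_multiecho_series(spec, n_echoes=10)
    from qliver import report
    res, _ = report.iron_arm(series, default_rois(spec))
    assert res.t2star_ms == pytest.approx(10.0, rel=1e-4)


def test_noiseless_t1_phantom_calibrates_to_exact_line():
    frame, gt = make_hsa_phantom_t1map(noise_sd=0.0, seed=0)
    assert frame.role is Role.T1_MAP
    points = []
    for _, row in gt.iterrows():
        rr, cc = np.ogrid[: frame.shape[0], : frame.shape[1]]
        mask = (rr - row.row) ** 2 + (cc - row.col) ** 2 <= (row.radius * 0.7) ** 2
        points.append(PhantomMeasurement(row.hsa_percent,
                                         float(frame.pixels[mask].mean())))
    res = fit_calibration(points)
    assert res.slope == pytest.approx(-30.0, abs=1e-9)
    assert res.intercept == pytest.approx(1500.0, abs=1e-7)
    assert res.r_pearson == pytest.approx(-1.0, abs=1e-12)


def test_noisy_t1_phantom_keeps_inverse_relation():
    frame, gt = make_hsa_phantom_t1map(noise_sd=40.0, seed=8)
    means = []
    for _, row in gt.iterrows():
        rr, cc = np.ogrid[: frame.shape[0], : frame.shape[1]]
        mask = (rr - row.row) ** 2 + (cc - row.col) ** 2 <= (row.radius * 0.7) ** 2
        means.append(float(frame.pixels[mask].mean()))
    res = fit_calibration([PhantomMeasurement(c, m)
                           for c, m in zip(gt.hsa_percent, means)])
    assert res.r_pearson < 0


def test_single_concentration_fails_downstream_fit():
    from qliver.t1 import DegenerateDesignError

    df = simulate_calibration_points(concentrations=[10.0, 10.0, 10.0],
                                     noise_sd=1.0, seed=0)
    from qliver import T1Calibration
    with pytest.raises(DegenerateDesignError):
        T1Calibration.from_dataframe(df)


def test_generator_slope_must_be_negative():
    with pytest.raises(ValueError):
        simulate_calibration_points(true_slope=5.0)
    with pytest.raises(ValueError):
        make_hsa_phantom_t1map(true_slope=0.0)


def test_rician_background_has_positive_floor():
    spec = default_phantom_spec(1.5, noise_sd=20.0, noise_model="rician", seed=1)
    series, _ = make_multiecho_series(spec, n_echoes=4)
    noise_roi = default_rois(spec)[-1]
    floor = roi_stats(series.frames[0], noise_roi).mean
    # Rayleigh mean of the signal-free background = sd * sqrt(pi/2)
    assert floor == pytest.approx(20.0 * np.sqrt(np.pi / 2), rel=0.15)


def test_with_liver_updates_all_three_segments():
    spec = default_phantom_spec(1.5).with_liver(t2star_ms=6.2, ff_percent=17.5)
    for label in ("LIVER_IV", "LIVER_VIII", "LIVER_VII"):
        region = spec.region(label)
        assert region.t2star_ms == 6.2 and region.ff_percent == 17.5
    assert spec.region("SPLEEN").t2star_ms == 60.0
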