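"""Polynomial surface: basis construction, least-squares fit, prediction."""

import json

import numpy as np
import pytest

from oysterfresh.surface import (
    CalibrationPoint,
    CalibrationSet,
    RankDeficientError,
    SurfaceError,
    SurfaceModel,
    UnderdeterminedFitError,
    build_design_matrix,
    evaluate_surface,
    fit_surface,
    load_calibration,
)


@pytest.mark.parametrize(
    "x, y, row",
    [
        (1.0, 1.0, [1, 1, 1, 1, 1, 1, 1]),
        (0.0, 5.0, [0, 0, 0, 0, 0, 5, 1]),
        (2.0, 3.0, [8, 12, 4, 6, 2, 3, 1]),  # hand-expanded monomials
    ],
)
def test_design_matrix_rows(x, y, row):
    assert np.allclose(build_design_matrix([x], [y])[0], row)


def test_design_matrix_empty_errors():
    with pytest.raises(SurfaceError):
        build_design_matrix([], [])


def test_calibration_point_validation():
    with pytest.raises(SurfaceError):
        CalibrationPoint(-1.0, 5.0, 0.0)
    with pytest.raises(SurfaceError):
        CalibrationPoint(1.0, 0.0, 0.0)
    with pytest.raises(SurfaceError):
        CalibrationPoint(1.0, 5.0, -2.0)


def test_calibration_set_rejects_duplicate_predictor_pairs():
    pts = [CalibrationPoint(1.0, 2.0, 0.0), CalibrationPoint(1.0, 2.0, 4.0)]
    with pytest.raises(SurfaceError):
        CalibrationSet(tuple(pts))


def test_packaged_calibration_loads_eight_batches():
    cal = load_calibration()
    assert len(cal) == 8
    assert np.all(np.diff(cal.mda) > 0)  # MDA rises with storage
    assert np.all(np.diff(cal.sh) < 0)  # SH falls with storage
    assert cal.day.tolist() == [0, 2, 4, 6, 8, 10, 12, 14]


def test_fit_on_calibration_reaches_published_goodness():
    model = fit_surface(load_calibration())
    assert model.r_squared == pytest.approx(0.9946, abs=1e-3)


def test_exact_span_recovery():
    # z lies in the basis span -> perfect fit, zero residuals
    rng = np.random.default_rng(3)
    x = rng.uniform(1, 5, 10)
    y = rng.uniform(50, 150, 10)
    z = 2 * x + 3 * y + 1
    model = fit_surface(CalibrationSet.from_arrays(x, y, z))
    assert model.r_squared == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(model.predict(x, y), z, atol=1e-6)


def test_coefficient_recovery_matches_normal_equations_oracle():
    rng = np.random.default_rng(7)
    x = rng.uniform(1, 8, 12)
    y = rng.uniform(60, 160, 12)
    truth = np.array([0.01, -0.002, 0.5, 0.01, -3.0, -0.05, 20.0])
    z = build_design_matrix(x, y) @ truth
    model = fit_surface(CalibrationSet.from_arrays(x, y, z))
    assert np.allclose(model.coefficients, truth, rtol=1e-6)
    # independent normal-equations solve
    a = build_design_matrix(x, y)
    oracle = np.linalg.solve(a.T @ a, a.T @ z)
    assert np.allclose(model.coefficients, oracle, rtol=1e-5)


def test_centering_invariance_on_calibration_data():
    cal = load_calibration()
    raw = fit_surface(cal, center_scale=False)
    centered = fit_surface(cal, center_scale=True)
    assert np.allclose(
        raw.predict(cal.mda, cal.sh), centered.predict(cal.mda, cal.sh), atol=1e-6
    )
    assert centered.r_squared == pytest.approx(raw.r_squared, abs=1e-9)


def test_seven_points_interpolate_exactly():
    rng = np.random.default_rng(11)
    x = rng.uniform(1, 8, 7)
    y = rng.uniform(60, 160, 7)
    z = rng.uniform(0, 14, 7)
    model = fit_surface(CalibrationSet.from_arrays(x, y, z))
    assert model.r_squared == pytest.approx(1.0, abs=1e-7)
    assert np.allclose(model.predict(x, y), z, atol=1e-5)


def test_residuals_orthogonal_to_design_columns():
    cal = load_calibration()
    model = fit_surface(cal)
    a = build_design_matrix(cal)
    resid = cal.day - model.predict(cal.mda, cal.sh)
    # relative to column scale
    proj = a.T @ resid / np.linalg.norm(a, axis=0) / max(np.linalg.norm(resid), 1e-30)
    assert np.all(np.abs(proj) < 1e-8)


def test_underdetermined_fit_errors():
    rng = np.random.default_rng(0)
    x, y, z = rng.uniform(1, 5, 6), rng.uniform(50, 150, 6), rng.uniform(0, 14, 6)
    with pytest.raises(UnderdeterminedFitError):
        fit_surface(CalibrationSet.from_arrays(x, y, z))


def test_rank_deficiency_names_collinear_columns():
    # constant MDA makes x^3, x^2, x and 1 proportional
    y = np.linspace(50, 150, 8)
    with pytest.raises(RankDeficientError) as err:
        fit_surface(CalibrationSet.from_arrays(np.full(8, 2.0), y, np.arange(8.0)))
    assert "x" in str(err.value)


def test_prediction_contracts(surface_model):
    # fresh Level-2 medians lie near day 4-5 on the fitted surface
    assert surface_model.predict(5.15, 119.19) == pytest.approx(4.77, abs=0.1)
    assert surface_model.predict(5.15, 106.42) == pytest.approx(8.19, abs=0.1)
    # extrapolating to the freshest SH median gives a negative day,
    # reported unclamped
    assert surface_model.predict(5.15, 163.98) < 0
    with pytest.raises(SurfaceError):
        surface_model.predict(np.nan, 100.0)


def test_constant_surface_returns_intercept():
    model = SurfaceModel(coefficients=[0, 0, 0, 0, 0, 0, 3.5], r_squared=0.0)
    assert evaluate_surface(model, 1.0, 1.0) == pytest.approx(3.5)
    assert evaluate_surface(model, 9.9, 170.0) == pytest.approx(3.5)


def test_json_roundtrip_preserves_predictions(surface_model):
    clone = SurfaceModel.from_json(surface_model.to_json())
    grid_m = np.linspace(3, 11, 5)
    grid_s = np.linspace(60, 170, 5)
    assert np.allclose(
        clone.predict(grid_m, grid_s), surface_model.predict(grid_m, grid_s)
    )
    doc = json.loads(surface_model.to_json())
    assert len(doc["coefficients"]) == 7
    assert doc["terms"][0] == "x^3"
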