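"""Staged transform fitting: per-stage behaviour, stack properties, inversion, LOO."""

import numpy as np
import pytest

from coregmatch import synth
from coregmatch.errors import (
    BinningError,
    DegenerateGeometryError,
    ExtrapolationWarning,
    InsufficientDataError,
)
from coregmatch.transforms import (
    FiducialSet,
    TransformStack,
    apply_transform,
    fit_exact_tps_stage,
    fit_grid_tps_stage,
    fit_polynomial_stage,
    fit_transform_stack,
    fit_z_binned_stage,
    invert_transform,
    loo_residuals,
    residual_report,
)
from conftest import REDUCED_SCHEDULE

rng = np.random.default_rng(42)


def _random_points(n, box=(400, 300, 250), seed=0):
    return np.random.default_rng(seed).uniform(0, 1, size=(n, 3)) * np.asarray(box)


# ---------------------------------------------------------------------------
# polynomial stage
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mapping",
    [
        lambda x: x @ np.array([[1.02, 0.03, 0], [-0.02, 0.98, 0.01], [0, 0.04, 1.05]]) + [5, -3, 2],
        lambda x: x + 0.001 * x**2,
    ],
    ids=["affine", "quadratic"],
)
def test_polynomial_reproduces_exact_family_members(mapping):
    src = _random_points(200, seed=1)
    dst = mapping(src)
    stage = fit_polynomial_stage(src, dst)
    resid = np.linalg.norm(stage.apply(src) - dst, axis=1)
    assert resid.max() <= 1e-9


def test_polynomial_noise_floor_matches_lstsq_oracle():
    """With 2-um iid noise the fit recovers the quadratic map to the noise floor,
    and agrees with an independent normal-equations oracle."""
    src = _random_points(500, seed=2)
    g = np.random.default_rng(3)
    dst = src + 0.001 * src**2 + g.normal(0, 2.0, size=src.shape)
    stage = fit_polynomial_stage(src, dst)
    err = stage.apply(src) - dst
    # per-axis RMS recovers the 2-um noise scale; the 3D Euclidean mean sits at
    # the chi(3) mean, sigma * 2 * sqrt(2/pi) ~= 3.19 um
    assert 1.5 <= np.sqrt((err**2).mean()) <= 2.5
    assert 1.5 <= np.linalg.norm(err, axis=1).mean() <= 2.0 * np.sqrt(2 / np.pi) * 2.5

    # independent oracle: raw-monomial normal equations
    x, y, z = src.T
    design = np.column_stack([np.ones(len(src)), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z])
    coef = np.linalg.solve(design.T @ design, design.T @ dst)
    pred_oracle = design @ coef
    pred = stage.apply(src)
    scale = np.abs(pred_oracle).max()
    assert np.max(np.abs(pred - pred_oracle)) <= 1e-8 * scale


def test_polynomial_error_conditions():
    src = _random_points(9, seed=4)
    with pytest.raises(InsufficientDataError):
        fit_polynomial_stage(src, src)
    flat = _random_points(50, seed=5)
    flat[:, 2] = 7.0  # coplanar
    with pytest.raises(DegenerateGeometryError):
        fit_polynomial_stage(flat, flat)


# ---------------------------------------------------------------------------
# z-binned stage
# ---------------------------------------------------------------------------


def test_single_bin_reduces_to_global_polynomial():
    src = _random_points(100, seed=6)
    dst = src + 0.0005 * src**2
    one = fit_z_binned_stage(src, dst, n_bins=1)
    poly = fit_polynomial_stage(src, dst)
    q = _random_points(50, seed=7)
    assert np.allclose(one.apply(q), poly.apply(q), atol=1e-9)


def test_piecewise_z_offset_recovered_away_from_blend_zone():
    g = np.random.default_rng(8)
    src = g.uniform(0, 1, size=(300, 3)) * [200, 200, 200]
    offset = np.where(src[:, 2:3] < 100, 5.0, -5.0)
    dst = src + offset * [1, 0, 0]
    stage = fit_z_binned_stage(src, dst, n_bins=2, blend_halfwidth=5.0)
    far = np.abs(src[:, 2] - 100) > 5.0
    resid = np.linalg.norm(stage.apply(src[far]) - dst[far], axis=1)
    assert resid.max() <= 1e-6


def test_zero_halfwidth_gives_piecewise_jump():
    g = np.random.default_rng(9)
    src = g.uniform(0, 1, size=(300, 3)) * [200, 200, 200]
    dst = src + np.where(src[:, 2:3] < 100, 5.0, -5.0) * [1, 0, 0]
    stage = fit_z_binned_stage(src, dst, n_bins=2, blend_halfwidth=0.0)
    edge = stage.bin_edges[1]
    below = np.array([[50.0, 50.0, edge - 1e-6]])
    above = np.array([[50.0, 50.0, edge + 1e-6]])
    jump = stage.apply(above) - stage.apply(below)
    model_diff = stage.per_bin[1].apply(below) - stage.per_bin[0].apply(below)
    assert np.allclose(jump, model_diff, atol=1e-4)


def test_binning_error_when_too_few_points():
    src = _random_points(5, seed=10)
    with pytest.raises(BinningError):
        fit_z_binned_stage(src, src, n_bins=2)


# ---------------------------------------------------------------------------
# grid TPS stage
# ---------------------------------------------------------------------------


def test_grid_tps_zero_residual_field_means_zero_motion():
    src = _random_points(80, seed=11)
    stage = fit_grid_tps_stage(src, src, n=3)
    assert stage.mean_motion <= 1e-8
    assert np.allclose(stage.apply(src), src, atol=1e-7)


def test_grid_tps_recovers_global_translation_exactly():
    """A constant displacement lies in the TPS affine span, so with zero
    regularization any interior point is shifted by exactly the same vector."""
    src = _random_points(150, seed=12)
    dst = src + [3.0, 0.0, 0.0]
    stage = fit_grid_tps_stage(src, dst, n=3, regularization_weight=0.0)
    interior = src.mean(axis=0) + np.array([[10.0, -5.0, 3.0], [0, 0, 0]])
    moved = stage.apply(interior)
    assert np.allclose(moved - interior, [3.0, 0.0, 0.0], atol=1e-6)


def test_finer_grid_does_not_increase_in_sample_residual(smooth_warp):
    fids = synth.make_fiducials(smooth_warp, 300, noise_sd_um=0.5, seed=13)
    src, dst = fids.source, fids.target
    resid = []
    for n in (3, 12):
        stage = fit_grid_tps_stage(src, dst, n=n)
        resid.append(np.linalg.norm(stage.apply(src) - dst, axis=1).mean())
    assert resid[1] <= resid[0] + 1e-9


# ---------------------------------------------------------------------------
# exact TPS stage
# ---------------------------------------------------------------------------


def test_exact_tps_interpolates_every_control_point():
    src = _random_points(120, seed=14)
    dst = src + np.random.default_rng(15).normal(0, 5, size=src.shape)
    stage = fit_exact_tps_stage(src, dst)
    resid = np.linalg.norm(stage.apply(src) - dst, axis=1)
    assert resid.max() <= 1e-6


def test_exact_tps_affine_input_gives_zero_kernel_weights():
    src = np.array([[0.0, 0, 0], [100, 0, 0], [0, 100, 0], [0, 0, 100]])
    A = np.array([[1.1, 0.02, 0], [0, 0.95, 0.01], [0.03, 0, 1.02]])
    dst = src @ A.T + [4, -2, 1]
    stage = fit_exact_tps_stage(src, dst)
    kernel_w = stage.weights[: len(src)]
    assert np.abs(kernel_w).max() <= 1e-8
    # affine part of the displacement reproduces (A - I)x + b
    q = _random_points(20, box=(100, 100, 100), seed=16)
    assert np.allclose(stage.apply(q), q @ A.T + [4, -2, 1], atol=1e-6)


def test_exact_tps_symmetric_displacements_cancel_at_midpoint():
    src = np.array(
        [[50.0, 0, 0], [-50.0, 0, 0], [0, 50.0, 0], [0, -50.0, 0], [0, 0, 50.0], [0, 0, -50.0]]
    )
    disp = np.array([[0, 2.0, 0], [0, -2.0, 0], [1.0, 0, 0], [-1.0, 0, 0], [0, 0, 3.0], [0, 0, -3.0]])
    stage = fit_exact_tps_stage(src, src + disp)
    mid = np.zeros((1, 3))
    assert np.abs(stage.apply(mid) - mid).max() <= 1e-8


def test_exact_tps_rejects_duplicate_control_points():
    src = _random_points(30, seed=17)
    src[5] = src[9]
    with pytest.raises(DegenerateGeometryError):
        fit_exact_tps_stage(src, src)


# ---------------------------------------------------------------------------
# the full stack
# ---------------------------------------------------------------------------


def test_identity_fiducials_give_identity_stack():
    pts = _random_points(80, seed=18)
    fids = FiducialSet.from_arrays(pts, pts)
    stack = fit_transform_stack(fids, schedule=REDUCED_SCHEDULE)
    for d in stack.diagnostics:
        assert d.mean_residual_um <= 1e-9
    q = _random_points(40, seed=19)
    assert np.allclose(apply_transform(stack, q, warn_extrapolation=False), q, atol=1e-7)


def test_stage_residuals_non_increasing_and_final_exact(canonical_stack, noisy_fiducials):
    resid = [d.mean_residual_um for d in canonical_stack.diagnostics]
    assert all(resid[k + 1] <= resid[k] + 1e-9 for k in range(len(resid) - 1))
    assert resid[-1] <= 1e-6
    report = residual_report(canonical_stack, noisy_fiducials)
    assert report.summary()["mean_um"] <= 1e-6


def test_up_to_stage_equals_first_stage_alone(canonical_stack):
    q = _random_points(30, box=(1300, 870, 820), seed=20)
    first = canonical_stack.stages[0].apply(q)
    trunc = apply_transform(canonical_stack, q, up_to_stage=1, warn_extrapolation=False)
    assert np.allclose(first, trunc)


def test_translation_equivariance_of_diagnostics(smooth_warp):
    fids = synth.make_fiducials(smooth_warp, 120, noise_sd_um=2.0, seed=21)
    shift = np.array([123.0, -45.0, 67.0])
    shifted = FiducialSet.from_arrays(fids.source + shift, fids.target + shift)
    a = fit_transform_stack(fids, schedule=REDUCED_SCHEDULE)
    b = fit_transform_stack(shifted, schedule=REDUCED_SCHEDULE)
    for da, db in zip(a.diagnostics, b.diagnostics):
        assert abs(da.mean_residual_um - db.mean_residual_um) <= 1e-9


def test_extrapolation_warns_but_does_not_fail(canonical_stack):
    far = np.array([[5000.0, 5000.0, 5000.0]])
    with pytest.warns(ExtrapolationWarning):
        apply_transform(canonical_stack, far)


def test_too_few_fiducials_rejected():
    pts = _random_points(10, seed=22)
    with pytest.raises(InsufficientDataError):
        fit_transform_stack(FiducialSet.from_arrays(pts, pts))


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def test_inversion_round_trip_within_tolerance(canonical_stack):
    g = np.random.default_rng(23)
    pts = g.uniform(0.2, 0.8, size=(100, 3)) * [1300, 870, 820]
    fwd = apply_transform(canonical_stack, pts, warn_extrapolation=False)
    back = invert_transform(canonical_stack, fwd, tol=1e-3)
    round_trip = apply_transform(canonical_stack, back, warn_extrapolation=False)
    assert np.linalg.norm(round_trip - fwd, axis=1).max() <= 1e-3


def test_pure_translation_stack_inverts_exactly():
    src = _random_points(100, seed=24)
    fids = FiducialSet.from_arrays(src, src + [7.0, -4.0, 2.0])
    stack = fit_transform_stack(fids, schedule=[{"type": "polynomial"}])
    q = _random_points(20, seed=25)
    back = invert_transform(stack, q + [7.0, -4.0, 2.0], tol=1e-9)
    assert np.allclose(back, q, atol=1e-6)


def test_identity_stack_inverts_to_identity():
    src = _random_points(60, seed=26)
    stack = fit_transform_stack(FiducialSet.from_arrays(src, src), schedule=REDUCED_SCHEDULE)
    q = _random_points(20, seed=27)
    assert np.allclose(invert_transform(stack, q, tol=1e-9), q, atol=1e-6)


# ---------------------------------------------------------------------------
# residual reports and leave-one-out
# ---------------------------------------------------------------------------


def test_residual_report_single_offset_fiducial():
    src = _random_points(50, seed=28)
    stack = fit_transform_stack(FiducialSet.from_arrays(src, src), schedule=REDUCED_SCHEDULE)
    dst = src.copy()
    dst[7, 0] += 5.0
    report = residual_report(stack, FiducialSet.from_arrays(src, dst))
    assert report.summary()["mean_um"] == pytest.approx(5.0 / 50, abs=1e-7)
    # summaries consistent with per-fiducial values
    assert report.summary()["median_um"] == pytest.approx(np.median(report.residuals))


def test_loo_exact_for_affine_truth_and_minimal_count():
    src = _random_points(21, seed=29)
    A = np.array([[1.05, 0.01, 0], [0, 0.97, 0.02], [0.01, 0, 1.03]])
    fids = FiducialSet.from_arrays(src, src @ A.T + [3, 1, -2])
    report = loo_residuals(fids, schedule=[{"type": "polynomial"}, {"type": "exact_tps"}])
    assert len(report.ids) == 21
    assert np.nanmax(report.residuals) <= 1e-6
    assert report.mode == "leave_one_out"


def test_loo_mean_at_least_in_sample_pre_exact_mean(smooth_warp):
    """Generalization gap: held-out residuals exceed the in-sample residual of
    the pre-exact-TPS fit (the exact stage's own in-sample residual is ~0)."""
    fids = synth.make_fiducials(smooth_warp, 60, noise_sd_um=2.0, seed=30)
    stack = fit_transform_stack(fids, schedule=REDUCED_SCHEDULE)
    pre_exact = stack.diagnostics[-2].mean_residual_um
    loo = loo_residuals(fids, schedule=REDUCED_SCHEDULE)
    assert np.nanmean(loo.residuals) >= pre_exact


def test_loo_within_factor_three_of_annotation_noise(noisy_fiducials):
    """Warp recovery at n = 500: held-out residuals stay within a factor of 3 of
    the 2-um annotation noise (estimated on a held-out subsample).

    The grid schedule is capacity-matched to the fiducial count (lattice
    nodes well below n); grids with more nodes than fiducials interpolate
    the annotation noise and cannot generalize, regardless of the warp.
    """
    schedule = [
        {"type": "polynomial"},
        {"type": "z_binned", "n_bins": 5},
        {"type": "z_binned", "n_bins": 21},
        {"type": "grid_tps", "n": 3},
        {"type": "grid_tps", "n": 5},
        {"type": "exact_tps"},
    ]
    loo = loo_residuals(noisy_fiducials, schedule=schedule, subset=range(0, 500, 25))
    assert len(loo.ids) == 20
    assert np.nanmean(loo.residuals) <= 3 * 2.0


def test_stack_serialization_round_trip(canonical_stack, tmp_path):
    from coregmatch.io import load_stack, save_stack

    path = tmp_path / "stack.json"
    save_stack(path, canonical_stack)
    loaded = load_stack(path)
    q = _random_points(25, box=(1300, 870, 820), seed=31)
    a = apply_transform(canonical_stack, q, warn_extrapolation=False)
    b = apply_transform(loaded, q, warn_extrapolation=False)
    assert np.allclose(a, b, atol=1e-9)
    assert isinstance(loaded, TransformStack)
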