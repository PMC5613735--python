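"""Rigid landmark fit, nearest-neighbour warping and stack alignment."""

import math

import numpy as np
import pytest
from conftest import grid_search_rigid
from hypothesis import given, settings
from hypothesis import strategies as st

from histovol import (
    LandmarkPairSet,
    RigidTransform2D,
    align_stack,
    apply_rigid,
    estimate_rigid,
    warp_nearest,
)
from histovol.errors import RegistrationError
from histovol.preprocess import GraySlice


# ------------------------------------------------------------ estimate_rigid


def test_identity_fit():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    fit, rms = estimate_rigid(LandmarkPairSet(pts, pts))
    assert fit.theta == pytest.approx(0.0, abs=1e-12)
    assert fit.tx == pytest.approx(0.0, abs=1e-12)
    assert fit.ty == pytest.approx(0.0, abs=1e-12)
    assert rms == pytest.approx(0.0, abs=1e-12)


def test_pure_translation_fit():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    fit, rms = estimate_rigid(LandmarkPairSet(pts, pts + [3.0, -2.0]))
    assert fit.theta == pytest.approx(0.0, abs=1e-12)
    assert (fit.tx, fit.ty) == (pytest.approx(3.0), pytest.approx(-2.0))
    assert rms < 1e-12


def test_quarter_turn_about_origin():
    moving = np.array([[1.0, 0.0], [0.0, 1.0]])
    fixed = np.array([[0.0, 1.0], [-1.0, 0.0]])
    fit, rms = estimate_rigid(LandmarkPairSet(moving, fixed))
    assert fit.theta == pytest.approx(math.pi / 2)
    assert abs(fit.tx) < 1e-12 and abs(fit.ty) < 1e-12
    assert rms < 1e-12


def test_degenerate_landmarks_rejected():
    with pytest.raises(RegistrationError, match=">= 2"):
        LandmarkPairSet(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
    same = np.array([[2.0, 2.0], [2.0, 2.0]])
    other = np.array([[0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(RegistrationError, match="coincide"):
        LandmarkPairSet(same, other)


def test_noisy_fit_beats_grid_search_oracle():
    rng = np.random.default_rng(20)
    for _ in range(10):
        n = 10
        moving = rng.uniform(0, 100, (n, 2))
        true = RigidTransform2D(rng.uniform(-1, 1), *rng.uniform(-20, 20, 2))
        fixed = true.apply(moving) + rng.normal(0, 0.5, (n, 2))
        fit, rms = estimate_rigid(LandmarkPairSet(moving, fixed))
        _, _, rms_grid = grid_search_rigid(moving, fixed, step=1e-3)
        assert rms <= rms_grid + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_fit_invariant_to_point_relabelling(seed):
    rng = np.random.default_rng(seed)
    n = 7
    moving = rng.uniform(0, 50, (n, 2))
    fixed = rng.uniform(0, 50, (n, 2))
    perm = rng.permutation(n)
    fit_a, rms_a = estimate_rigid(LandmarkPairSet(moving, fixed))
    fit_b, rms_b = estimate_rigid(LandmarkPairSet(moving[perm], fixed[perm]))
    assert fit_a.theta == pytest.approx(fit_b.theta, abs=1e-9)
    assert fit_a.tx == pytest.approx(fit_b.tx, abs=1e-9)
    assert fit_a.ty == pytest.approx(fit_b.ty, abs=1e-9)
    assert rms_a == pytest.approx(rms_b, abs=1e-9)


def test_noise_free_recovery_over_many_random_slices():
    rng = np.random.default_rng(31)
    worst = 0.0
    for _ in range(50):
        pts = rng.uniform(0, 200, (8, 2))
        true = RigidTransform2D(rng.uniform(-0.1, 0.1), *rng.uniform(-10, 10, 2))
        fit, _ = estimate_rigid(LandmarkPairSet(pts, true.apply(pts)))
        worst = max(worst, abs(fit.theta - true.theta))
    assert worst < 1e-6


def test_angular_error_shrinks_with_more_landmarks():
    rng = np.random.default_rng(8)
    sigma = 1.0
    errors = []
    for n in (4, 16, 64):
        errs = []
        for _ in range(200):
            pts = rng.uniform(0, 100, (n, 2))
            true = RigidTransform2D(rng.uniform(-0.08, 0.08), *rng.uniform(-10, 10, 2))
            fixed = true.apply(pts) + rng.normal(0, sigma, (n, 2))
            fit, _ = estimate_rigid(LandmarkPairSet(pts, fixed))
            errs.append(abs(fit.theta - true.theta))
        errors.append(np.mean(errs))
    assert errors[0] > errors[1] > errors[2]


# -------------------------------------------------------- transform algebra


def test_compose_with_inverse_is_identity():
    t = RigidTransform2D(0.3, 5.0, -7.0)
    ident = t.compose(t.inverse())
    assert abs(ident.theta) < 1e-9
    assert abs(ident.tx) < 1e-9 and abs(ident.ty) < 1e-9


def test_transform_preserves_pairwise_distances():
    rng = np.random.default_rng(2)
    pts = rng.uniform(-50, 50, (12, 2))
    t = RigidTransform2D(1.1, 4.0, -3.0)
    mapped = t.apply(pts)
    d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d1 = np.linalg.norm(mapped[:, None] - mapped[None, :], axis=-1)
    np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)


# --------------------------------------------------------------- resampling


def test_identity_warp_is_a_pixel_copy():
    rng = np.random.default_rng(4)
    px = rng.integers(0, 255, (20, 30), dtype=np.uint8)
    out = warp_nearest(px, RigidTransform2D.identity(), (20, 30))
    np.testing.assert_array_equal(out, px)


def test_translation_moves_single_pixel():
    px = np.zeros((10, 10), dtype=np.uint8)
    px[3, 5] = 200  # (x=5, y=3)
    out = warp_nearest(px, RigidTransform2D(0.0, 1.0, 0.0), (10, 10))
    assert out[3, 6] == 200
    assert out.sum() == 200


def test_half_turn_on_point_symmetric_image():
    rng = np.random.default_rng(5)
    n = 21
    half = rng.integers(0, 255, (n * n // 2 + 1,), dtype=np.uint8)
    px = np.empty(n * n, dtype=np.uint8)
    px[: half.size] = half
    px[half.size :] = half[: n * n - half.size][::-1]  # point symmetry
    px = px.reshape(n, n)
    assert np.array_equal(px, px[::-1, ::-1])
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    t = RigidTransform2D.about_center(math.pi, (0.0, 0.0), center)
    out = warp_nearest(px, t, (n, n))
    np.testing.assert_array_equal(out, px)


def test_out_of_frame_samples_become_background():
    px = np.full((8, 8), 50, dtype=np.uint8)
    out = warp_nearest(px, RigidTransform2D(0.0, 4.0, 0.0), (8, 8))
    assert (out[:, :4] == 0).all()
    assert (out[:, 4:] == 50).all()


# -------------------------------------------------------------- align_stack


def _gray_stack(truth_sections):
    return [
        GraySlice(np.asarray(s.pixels[:, :, 1]), s.slice_index, s.damaged, True)
        for s in truth_sections
    ]


@pytest.mark.parametrize("mode", ["chain", "direct"])
def test_alignment_recovers_relative_transforms(small_stack, mode):
    """With exact landmarks the recovered transform for slice k equals
    T_ref o T_k^{-1} (alignment into the reference slice's frame)."""
    _, sections, truth = small_stack
    grays = _gray_stack(sections)
    landmarks = [lm["misaligned"] for lm in truth.landmark_sets]
    ref = len(grays) // 2
    _, transforms, report = align_stack(grays, landmarks, ref, mode=mode)
    t_ref = truth.applied_transforms[ref]
    for k, got in enumerate(transforms):
        expected = t_ref.compose(truth.applied_transforms[k].inverse())
        assert got.theta == pytest.approx(expected.theta, abs=1e-6)
        assert got.tx == pytest.approx(expected.tx, abs=1e-6)
        assert got.ty == pytest.approx(expected.ty, abs=1e-6)
    assert transforms[ref].is_identity()
    assert len(report.rows) == len(grays)


def test_single_slice_stack_is_trivially_aligned():
    gray = GraySlice(np.zeros((8, 8), dtype=np.uint8), 0)
    aligned, transforms, _ = align_stack([gray], [np.array([[0.0, 0.0], [1.0, 1.0]])], 0)
    assert transforms[0].is_identity()
    np.testing.assert_array_equal(aligned[0].pixels, gray.pixels)


def test_reference_index_out_of_range():
    gray = GraySlice(np.zeros((8, 8), dtype=np.uint8), 0)
    with pytest.raises(RegistrationError, match="out of range"):
        align_stack([gray], [np.array([[0.0, 0.0], [1.0, 1.0]])], 5)


def test_missing_landmarks_on_intact_slice_is_an_error():
    grays = [GraySlice(np.zeros((8, 8), dtype=np.uint8), k) for k in range(3)]
    lm = np.array([[0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(RegistrationError, match="slice 2"):
        align_stack(grays, [lm, lm, None], 1)


def test_damaged_slice_without_landmarks_passes_with_identity():
    grays = [GraySlice(np.zeros((8, 8), dtype=np.uint8), k) for k in range(3)]
    grays[2].damaged = True
    lm = np.array([[0.0, 0.0], [1.0, 1.0]])
    _, transforms, _ = align_stack(grays, [lm, lm, None], 1)
    assert transforms[2].is_identity()


def test_report_tsv_has_one_row_per_slice(small_stack):
    _, sections, truth = small_stack
    grays = _gray_stack(sections)
    landmarks = [lm["misaligned"] for lm in truth.landmark_sets]
    _, _, report = align_stack(grays, landmarks, 3)
    lines = report.to_tsv().strip().splitlines()
    assert lines[0].split("\t") == ["slice", "theta_deg", "tx", "ty", "rms"]
    assert len(lines) == len(grays) + 1
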