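"""Tests for rigid registration, deformation fields and warp estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amypipe.errors import ParameterError, UsageError
from amypipe.image_model import RigidTransform, VolumetricImage, resample_into
from amypipe.normalization import (
    AMOUNT_PRESERVING,
    CONCENTRATION_PRESERVING,
    NATIVE_TO_STANDARD,
    STANDARD_TO_NATIVE,
    DeformationField,
    RigidRegParams,
    WarpParams,
    _nmi,
    apply_warp,
    estimate_map_warp,
    estimate_usm_warp,
    invert_warp,
    jacobian_determinant,
    register_rigid,
    warp_validity_mask,
)


def _grid_img(shape=(24, 24, 24), spacing=2.0, seed=0):
    rng = np.random.default_rng(seed)
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing
    return VolumetricImage(rng.normal(1.0, 0.3, shape), aff)


def _scaling_field(ref: VolumetricImage, s: float, direction=NATIVE_TO_STANDARD):
    """Analytic pull-back field of a uniform scaling about the origin:
    destination x samples source at s*x, i.e. d(x) = (s-1) x."""
    w = ref.world_coords()
    return DeformationField((s - 1.0) * w, ref.affine.copy(), direction)


# ---------------------------------------------------------------------------
# DeformationField basics


def test_field_validation():
    ref = _grid_img()
    with pytest.raises(ParameterError):
        DeformationField(np.zeros((2,) + ref.shape), ref.affine,
                         NATIVE_TO_STANDARD)
    with pytest.raises(ParameterError):
        DeformationField(np.zeros((3,) + ref.shape), ref.affine, "sideways")


def test_identity_field_roundtrips_image():
    img = _grid_img(seed=1)
    fld = DeformationField.identity(img, NATIVE_TO_STANDARD)
    out = apply_warp(img, fld, CONCENTRATION_PRESERVING)
    assert np.allclose(out.data, img.data)


def test_checksum_is_stable_and_discriminates():
    img = _grid_img()
    a = DeformationField.identity(img, NATIVE_TO_STANDARD)
    b = DeformationField.identity(img, NATIVE_TO_STANDARD)
    assert a.checksum() == b.checksum()
    c = DeformationField(a.displacement + 1e-9, img.affine, NATIVE_TO_STANDARD)
    assert c.checksum() != a.checksum()


def test_direction_assertion():
    img = _grid_img()
    fld = DeformationField.identity(img, STANDARD_TO_NATIVE)
    with pytest.raises(UsageError):
        apply_warp(img, fld, CONCENTRATION_PRESERVING,
                   direction=NATIVE_TO_STANDARD)


# ---------------------------------------------------------------------------
# Jacobian and modulation oracles


@given(st.floats(0.7, 1.4))
def test_jacobian_of_uniform_scaling_is_s_cubed(s):
    ref = _grid_img(shape=(16, 16, 16))
    fld = _scaling_field(ref, s)
    j = jacobian_determinant(fld)
    assert np.allclose(j.data, s**3, rtol=1e-6)


def test_constant_image_fixed_by_concentration_warp():
    ref = _grid_img(shape=(20, 20, 20))
    fld = _scaling_field(ref, 0.9)
    const = VolumetricImage(np.full(ref.shape, 3.7), ref.affine)
    out = apply_warp(const, fld, CONCENTRATION_PRESERVING)
    inside = warp_validity_mask(const, fld)
    assert np.allclose(out.data[inside], 3.7, atol=1e-9)


def test_amount_modulation_conserves_integral():
    ref = _grid_img(shape=(32, 32, 32), seed=5)
    # compact blob so no signal leaves the FOV under mild contraction
    w = ref.world_coords()
    r2 = (w**2).sum(axis=0)
    blob = np.exp(-r2 / (2 * 8.0**2))
    img = VolumetricImage(blob, ref.affine)
    fld = _scaling_field(ref, 1.1)  # destination samples expanded source
    out = apply_warp(img, fld, AMOUNT_PRESERVING)
    assert out.semantics == "amount"
    # sum_x src(s x) |J| dx = sum_u src(u) du: the modulated pull-back
    # conserves the integral directly (equal voxel volumes on both grids)
    rel = abs(out.data.sum() / blob.sum() - 1.0)
    assert rel < 0.01


def test_amount_vs_concentration_differ_by_jacobian():
    ref = _grid_img(shape=(16, 16, 16), seed=6)
    fld = _scaling_field(ref, 1.2)
    img = _grid_img(shape=(16, 16, 16), seed=7)
    conc = apply_warp(img, fld, CONCENTRATION_PRESERVING)
    amt = apply_warp(img, fld, AMOUNT_PRESERVING)
    j = jacobian_determinant(fld)
    assert np.allclose(amt.data, conc.data * j.data)


def test_apply_warp_rejects_unknown_modulation():
    img = _grid_img()
    fld = DeformationField.identity(img, NATIVE_TO_STANDARD)
    with pytest.raises(ParameterError):
        apply_warp(img, fld, "magic")


def test_warp_validity_mask_flags_outside_points():
    img = _grid_img(shape=(16, 16, 16))
    d = np.zeros((3,) + img.shape)
    d[0] = 1000.0  # everything pulls from far outside
    fld = DeformationField(d, img.affine, NATIVE_TO_STANDARD)
    assert not warp_validity_mask(img, fld).any()


# ---------------------------------------------------------------------------
# inversion


def test_invert_scaling_field_matches_analytic():
    ref = _grid_img(shape=(20, 20, 20))
    s = 1.15
    fld = _scaling_field(ref, s)
    inv = invert_warp(fld)
    assert inv.direction == STANDARD_TO_NATIVE
    # inverse of d(x) = (s-1)x is d_inv(y) = (1/s - 1) y
    expect = (1.0 / s - 1.0) * ref.world_coords()
    err = np.abs(inv.displacement - expect).max()
    assert err < 0.25  # mm, on a 2 mm grid


def test_invert_warp_composition_is_identity():
    ref = _grid_img(shape=(20, 20, 20))
    w = ref.world_coords()
    d = 1.5 * np.stack([
        np.sin(w[0] / 12.0), np.cos(w[1] / 15.0), np.sin(w[2] / 10.0)
    ])
    fld = DeformationField(d, ref.affine, NATIVE_TO_STANDARD)
    inv = invert_warp(fld)
    # a smooth test image: round-trip error is then dominated by the
    # inversion residual, not by interpolation of high-frequency content
    smooth = 1.0 + 0.5 * np.sin(w[0] / 9.0) * np.cos(w[1] / 11.0) \
        + 0.3 * np.sin(w[2] / 8.0)
    img = VolumetricImage(smooth, ref.affine)
    there = apply_warp(img, fld, CONCENTRATION_PRESERVING)
    back = apply_warp(there, inv, CONCENTRATION_PRESERVING)
    inside = warp_validity_mask(img, fld) & warp_validity_mask(there, inv)
    # interior voxels (exclude the boundary shell where fill leaks in)
    core = np.zeros(ref.shape, bool)
    core[3:-3, 3:-3, 3:-3] = True
    sel = inside & core
    assert np.abs(back.data[sel] - img.data[sel]).mean() < 0.08


# ---------------------------------------------------------------------------
# NMI and rigid registration


def test_nmi_higher_for_aligned_samples():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 20000)
    dependent = 2.0 * a + rng.normal(0, 0.05, a.size)
    shuffled = rng.permutation(dependent)
    assert _nmi(a, dependent) > _nmi(a, shuffled) + 0.05


def test_register_rigid_self_is_identity(template48):
    t1 = template48.template_t1
    T = register_rigid(t1, t1)
    ang = np.degrees(
        np.arccos(np.clip((np.trace(T.rotation) - 1) / 2, -1, 1))
    )
    assert ang < 0.2
    assert np.linalg.norm(T.translation) < 0.2


def test_register_rigid_recovers_known_offset(template48):
    t1 = template48.template_t1
    n = np.array(t1.shape)
    center = t1.affine[:3, :3] @ ((n - 1) / 2.0) + t1.affine[:3, 3]
    true = RigidTransform.from_params([2.0, -1.5, 1.0], [3.0, -2.0, 1.5],
                                      center=center)
    moved = resample_into(t1, true, t1)  # moved(x) = t1(true(x))
    # registering t1 onto `moved` must recover `true`
    T = register_rigid(t1, moved)
    R_err = T.rotation @ true.rotation.T
    ang = np.degrees(np.arccos(np.clip((np.trace(R_err) - 1) / 2, -1, 1)))
    t_err = np.linalg.norm(
        T.apply(center.reshape(3, 1)) - true.apply(center.reshape(3, 1))
    )
    assert ang < 0.5
    assert t_err < 1.0  # mm (half a voxel at 2 mm)


# ---------------------------------------------------------------------------
# warp estimation (small-scale sanity; full-scale checks are acceptance)


def test_map_warp_degenerate_subject_is_near_identity(template48):
    t1 = template48.template_t1
    fld = estimate_map_warp(t1, t1)
    assert fld.direction == NATIVE_TO_STANDARD
    assert fld.provenance == "MAP"
    assert fld.shape == t1.shape
    mag = np.linalg.norm(fld.displacement, axis=0)
    assert float(np.median(mag)) < 0.75  # well under half a voxel


def test_usm_degenerate_subject_near_identity_and_monotone(template48):
    t1 = template48.template_t1
    fld, post = estimate_usm_warp(t1, template48.tpm_images(),
                                  bias_correction=False)
    assert fld.direction == STANDARD_TO_NATIVE
    assert fld.provenance == "USM"
    trace = post["_nll"]
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
    gm = post["GM"].data >= 0.5
    true_gm = template48.tpm_gm.prob >= 0.5
    dice = 2 * np.sum(gm & true_gm) / (gm.sum() + true_gm.sum())
    assert dice > 0.93


def test_map_warp_recovers_uniform_scaling(template48):
    t1 = template48.template_t1
    s = 1.06
    truth = _scaling_field(t1, s)  # standard x samples subject at s*x
    subject = apply_warp(t1, truth, CONCENTRATION_PRESERVING)
    subject = VolumetricImage(subject.data, t1.affine)
    fld = estimate_map_warp(subject, t1)
    j = jacobian_determinant(fld)
    core = np.zeros(t1.shape, bool)
    core[10:-10, 10:-10, 10:-10] = True
    # subject(x) = t1(s x) is the template contracted by 1/s, so the
    # estimated pull-back maps x -> x/s with Jacobian s^-3 in the core
    assert abs(float(np.median(j.data[core])) - s**-3) < 0.05
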