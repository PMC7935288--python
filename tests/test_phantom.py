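"""Tests for the synthetic phantom generator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amypipe.errors import GeometryError, ParameterError
from amypipe.phantom import (
    PhantomParams,
    make_template,
    synthesize_cohort,
    synthesize_subject,
)
from amypipe.quantification import compute_metrics, suvr_image


# ---------------------------------------------------------------------------
# template


def test_template_probabilities_partition(template48):
    s = (
        template48.tpm_gm.prob + template48.tpm_wm.prob
        + template48.tpm_csf.prob
    )
    assert s.max() <= 1.0 + 1e-9
    assert s.min() >= 0.0
    # bulk tissues (WM, CSF) have pure cores; the cortical ribbon is thin
    # relative to the 2 mm test voxels, so GM only approaches purity
    assert template48.tpm_wm.prob.max() > 0.95
    assert template48.tpm_csf.prob.max() > 0.95
    assert template48.tpm_gm.prob.max() > 0.8


def test_template_gm_core_near_pure_at_fine_resolution(template96):
    assert template96.tpm_gm.prob.max() > 0.95


def test_template_cerebellum_volume_matches_analytic(template96):
    # the VOI is the q >= 0.5 region of a sigmoid ellipsoid: its volume
    # approximates the analytic ellipsoid volume to sub-percent accuracy
    vol = template96.cerebellum_voi.volume_ml
    a, b, c = template96.cerebellum_radii_mm
    analytic = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
    assert vol == pytest.approx(analytic, rel=0.02)


def test_template_cerebellum_disjoint_from_cerebrum(template48):
    cb = template48.cerebellum_voi.mask
    # cerebellar voxels are far outside the cerebral ellipsoid
    assert template48.rho[cb].min() > 1.1


def test_template_deterministic():
    a = make_template((36, 36, 36), 2.0)
    b = make_template((36, 36, 36), 2.0)
    assert np.array_equal(a.template_t1.data, b.template_t1.data)
    assert np.array_equal(a.tpm_gm.prob, b.tpm_gm.prob)


def test_template_rejects_tiny_grids():
    with pytest.raises(GeometryError):
        make_template((16, 16, 16), 2.0)
    with pytest.raises(GeometryError):
        make_template((32, 32, 32), 0.5)  # FOV too small


# ---------------------------------------------------------------------------
# parameter validation


def test_params_reject_lesions_below_threshold():
    with pytest.raises(ParameterError):
        PhantomParams(ad_lesion_suvr_range=(1.3, 1.6))


def test_params_reject_hc_above_threshold():
    with pytest.raises(ParameterError):
        PhantomParams(hc_gm_suvr_range=(0.9, 1.6))


def test_params_reject_negative_noise():
    with pytest.raises(ParameterError):
        PhantomParams(pet_noise_sd=-0.1)


def test_defaults_are_study_conditions():
    p = PhantomParams()
    assert (p.n_ad, p.n_hc) == (12, 16)
    assert p.grid_shape == (96, 96, 96)
    assert p.psf_fwhm_mm == 4.0
    assert p.abeta_threshold == 1.5


# ---------------------------------------------------------------------------
# subjects


def test_subject_deterministic(template48, params48):
    a = synthesize_subject(template48, "AD", 7, params48)
    b = synthesize_subject(template48, "AD", 7, params48)
    assert np.array_equal(a.mri.data, b.mri.data)
    assert np.array_equal(a.pet.data, b.pet.data)
    assert a.truth.true_metrics.suvr_mean == b.truth.true_metrics.suvr_mean


def test_subject_seeds_differ(template48, params48):
    a = synthesize_subject(template48, "AD", 7, params48)
    b = synthesize_subject(template48, "AD", 8, params48)
    assert not np.array_equal(a.pet.data, b.pet.data)


def test_subject_rejects_unknown_diagnosis(template48, params48):
    with pytest.raises(ParameterError):
        synthesize_subject(template48, "MCI", 7, params48)


def test_hc_has_no_positive_voxels(pair48):
    _, hc = pair48
    t = hc.truth
    assert t.true_metrics.abeta_volume_ml == 0.0
    assert np.isnan(t.true_metrics.tab_ml)
    # stays below even the 1.2 sensitivity threshold inside GM
    gm_vals = t.true_suvr_field.data[t.true_gm_mask.mask]
    assert gm_vals.max() < 1.2


def test_ad_has_substantial_lesion_load(pair48):
    ad, _ = pair48
    t = ad.truth
    assert t.true_metrics.abeta_volume_ml > 1.0
    assert t.true_metrics.suvr_mean_abeta_pos >= 1.5
    assert t.atrophy_factor < 1.0


def test_cerebellum_suvr_pinned_to_one(pair48):
    for sub in pair48:
        t = sub.truth
        vals = t.true_suvr_field.data[t.true_cerebellum.mask]
        assert np.all(vals == 1.0)


def test_true_warp_is_invertible(pair48):
    from amypipe.normalization import jacobian_determinant

    for sub in pair48:
        j = jacobian_determinant(sub.truth.true_warp)
        assert float(j.data.min()) > 0.05


def test_true_metrics_consistent_with_field(pair48):
    """true_metrics is exactly compute_metrics(true field, true GM)."""
    for sub in pair48:
        t = sub.truth
        ms = compute_metrics(t.true_suvr_field, t.true_gm_mask, 1.5)
        assert ms.suvr_mean == t.true_metrics.suvr_mean
        assert ms.abeta_volume_ml == t.true_metrics.abeta_volume_ml


def test_clean_pet_is_scaled_truth(clean_pair48):
    """With zero PSF, noise and misalignment the PET equals
    pet_scale x true SUVR, so true masks recover true metrics exactly."""
    for sub in clean_pair48:
        t = sub.truth
        assert np.allclose(sub.pet.data, 2.0 * t.true_suvr_field.data)
        suvr = suvr_image(sub.pet, t.true_cerebellum)
        ms = compute_metrics(suvr, t.true_gm_mask, 1.5)
        assert ms.suvr_mean == pytest.approx(t.true_metrics.suvr_mean,
                                             abs=1e-12)


def test_atrophy_shrinks_gm(template48, params48):
    ad = synthesize_subject(template48, "AD", 31, params48)
    # rebuild the same subject as HC (same seed => same warp)
    hc_like = synthesize_subject(template48, "HC", 31, params48)
    assert ad.truth.true_gm_mask.n_voxels < hc_like.truth.true_gm_mask.n_voxels


# ---------------------------------------------------------------------------
# cohort


def test_cohort_composition_and_manifest(template48):
    p = PhantomParams(grid_shape=(48, 48, 48), spacing_mm=2.0, n_ad=2, n_hc=3)
    subs, manifest = synthesize_cohort(template48, p)
    assert len(subs) == 5
    assert [s.diagnosis for s in subs] == ["AD", "AD", "HC", "HC", "HC"]
    assert list(manifest.columns) == [
        "subject_id", "diagnosis", "seed", "atrophy_factor"
    ]
    assert manifest["subject_id"].is_unique
    assert all(0 <= s.seed < 2**31 for s in subs)


def test_cohort_deterministic(template48):
    p = PhantomParams(grid_shape=(48, 48, 48), spacing_mm=2.0, n_ad=1, n_hc=1)
    a, _ = synthesize_cohort(template48, p)
    b, _ = synthesize_cohort(template48, p)
    assert np.array_equal(a[0].pet.data, b[0].pet.data)
    assert np.array_equal(a[1].mri.data, b[1].mri.data)


def test_cohort_rejects_empty_group(template48):
    with pytest.raises(ParameterError):
        synthesize_cohort(
            template48,
            PhantomParams(grid_shape=(48, 48, 48), spacing_mm=2.0, n_ad=0),
        )


@given(st.integers(0, 2**31 - 1))
def test_subject_truth_invariants(seed):
    """For any seed: SUVR field positive, cerebellar GM pinned to the
    reference value (so it can never count as amyloid-positive), HC
    subjects threshold-free.  Run at a tiny grid for speed."""
    tpl = test_subject_truth_invariants.tpl
    p = test_subject_truth_invariants.params
    sub = synthesize_subject(tpl, "HC", seed, p)
    t = sub.truth
    both = t.true_gm_mask.mask & t.true_cerebellum.mask
    assert np.all(t.true_suvr_field.data[both] == 1.0)
    assert t.true_suvr_field.data.min() >= 0.0
    assert t.true_metrics.abeta_volume_ml == 0.0


test_subject_truth_invariants.tpl = make_template((32, 32, 32), 2.0)
test_subject_truth_invariants.params = PhantomParams(
    grid_shape=(32, 32, 32), spacing_mm=2.0
)
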