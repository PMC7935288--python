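"""Synthetic T1/PET brain phantoms with full ground truth.

The generator emulates a [11C]PiB amyloid study cohort (default 12 AD +
16 HC) without any external data: a deterministic analytic template
(ellipsoidal cortical grey-matter ribbon, interior white matter, CSF shell,
a separate inferior-posterior cerebellum) is deformed by a smooth random
invertible warp per subject.  AD subjects additionally get grey-matter
atrophy and amyloid-positive cortical lesion patches.  The MRI channel adds
a multiplicative low-order bias field and Gaussian noise; the PET channel
applies Gaussian point-spread blurring and Gaussian noise whose SD is a
fraction of the cerebellum mean.

All ground truth (warp, masks, the noise-free pre-blur SUVR field and the
metrics computed from it) is recorded, so every downstream pipeline can be
validated against a known answer.  The cerebellum SUVR is pinned to exactly
1 inside the cerebellum VOI, making true SUVR analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EstimationError, GeometryError, ParameterError
from .image_model import CONCENTRATION, RigidTransform, VolumetricImage, resample_into
from .normalization import (
    STANDARD_TO_NATIVE,
    DeformationField,
    jacobian_determinant,
)
from .quantification import MetricSet, compute_metrics
from .segmentation import NATIVE, STANDARD, TissueProbabilityMap, VOIMask

AD, HC = "AD", "HC"

# T1-like tissue mean intensities (arbitrary units)
T1_MEANS = {"GM": 80.0, "WM": 110.0, "CSF": 30.0}
# SUVR of non-lesion tissue relative to cerebellum
BASE_SUVR = {"WM": 1.1, "CSF": 0.35}


@dataclass
class TemplateAnatomy:
    """Analytic standard-space anatomy: TPMs, cerebellum VOI and a T1.

    The smooth radial coordinate fields (``rho`` for the cerebrum,
    ``rho_cb`` cerebellum, ``rho_v`` ventricles) are kept so that subject
    anatomies can be built analytically after warping them: tissue
    probabilities in native space are then exact, not interpolated.
    """

    tpm_gm: TissueProbabilityMap
    tpm_wm: TissueProbabilityMap
    tpm_csf: TissueProbabilityMap
    cerebellum_voi: VOIMask
    template_t1: VolumetricImage
    cerebellum_radii_mm: np.ndarray
    cerebellum_prob: np.ndarray  # smooth [0,1] field behind the VOI
    rho: np.ndarray
    rho_cb: np.ndarray
    rho_v: np.ndarray
    scales: tuple                # sigmoid edge scales (cerebrum, cb, ventricle)

    @property
    def affine(self):
        return self.template_t1.affine

    @property
    def shape(self):
        return self.template_t1.shape

    def tpms(self) -> dict:
        return {"GM": self.tpm_gm, "WM": self.tpm_wm, "CSF": self.tpm_csf}

    def tpm_images(self) -> dict:
        return {k: v.as_image() for k, v in self.tpms().items()}


@dataclass
class PhantomParams:
    """Study conditions for the synthetic cohort.

    Defaults emulate the cohort structure of the study this package
    reproduces: 12 AD and 16 HC subjects, a 4 mm FWHM PET point-spread
    function, 5% Gaussian PET noise relative to the cerebellum mean, and
    AD lesion SUVR drawn above the 1.5 positivity threshold while HC grey
    matter stays below it (and below the 1.2 sensitivity threshold).
    """

    n_ad: int = 12
    n_hc: int = 16
    seed: int = 1
    grid_shape: tuple = (96, 96, 96)
    spacing_mm: float = 1.5
    psf_fwhm_mm: float = 4.0
    pet_noise_sd: float = 0.05           # fraction of cerebellum mean
    mri_noise_sd: float = 4.0            # absolute, T1 units
    bias_field_amplitude: float = 0.10
    warp_amplitude_mm: float = 3.0
    rot_max_deg: float = 3.0
    trans_max_mm: float = 3.0
    scale_jitter: float = 0.04
    ad_lesion_suvr_range: tuple = (1.9, 2.6)
    hc_gm_suvr_range: tuple = (0.90, 1.15)
    atrophy_range_ad: tuple = (0.75, 0.90)
    n_lesions: int = 4
    lesion_radius_range_mm: tuple = (9.0, 14.0)
    pet_scale: float = 2.0               # cerebellum mean SUV (pinned)
    pet_rigid_max_mm: float = 2.0
    pet_rigid_max_deg: float = 2.0
    abeta_threshold: float = 1.5
    max_warp_retries: int = 10

    def __post_init__(self):
        for name in ("psf_fwhm_mm", "pet_noise_sd", "mri_noise_sd",
                     "bias_field_amplitude", "warp_amplitude_mm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.ad_lesion_suvr_range[0] <= self.abeta_threshold:
            raise ParameterError(
                "AD lesion SUVR range must lie above the positivity threshold"
            )
        if self.hc_gm_suvr_range[1] >= self.abeta_threshold:
            raise ParameterError(
                "HC grey-matter SUVR range must lie below the positivity threshold"
            )


@dataclass
class PhantomGroundTruth:
    true_warp: DeformationField          # template -> subject (pull-back on native grid)
    true_gm_mask: VOIMask
    true_cerebellum: VOIMask
    true_suvr_field: VolumetricImage     # noise-free, pre-blur
    true_metrics: MetricSet
    diagnosis: str
    atrophy_factor: float
    gm_base_suvr: float
    pet_rigid: RigidTransform
    seed: int


@dataclass
class Subject:
    subject_id: str
    diagnosis: str
    mri: VolumetricImage
    pet: VolumetricImage
    truth: PhantomGroundTruth
    seed: int


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# relative radii of the cortical ribbon and brain envelope
RIBBON_INNER = 0.70
RIBBON_OUTER = 0.90
BRAIN_OUTER = 1.00


def _tissue_probs(rho, rho_cb, rho_v, scales, atrophy=1.0):
    """Analytic tissue probabilities from the radial coordinate fields.

    ``atrophy`` < 1 thins the cortical ribbon geometrically (the outer GM
    boundary moves inward and CSF takes the vacated space), leaving GM
    voxel composition -- hence MRI contrast -- unchanged.  Cerebellum and
    ventricles are unaffected.
    """
    scale, cb_scale, v_scale = scales
    gm_outer = RIBBON_INNER + atrophy * (RIBBON_OUTER - RIBBON_INNER)
    t_wm = _sigmoid((RIBBON_INNER - rho) * scale)
    t_gmwm = _sigmoid((gm_outer - rho) * scale)
    t_brain = _sigmoid((BRAIN_OUTER - rho) * scale)
    p_wm = t_wm
    p_gm = t_gmwm - t_wm
    p_csf = t_brain - t_gmwm

    # cerebellum: mostly GM with a WM core share
    q = _sigmoid((1.0 - rho_cb) * cb_scale)
    p_gm = np.clip(p_gm + 0.85 * q, 0.0, 1.0)
    p_wm = np.clip(p_wm + 0.15 * q, 0.0, 1.0)

    # lateral-ventricle-like CSF cavity carved out of the white matter:
    # anchors the CSF intensity class (cortical CSF is mostly partial volume)
    v = _sigmoid((1.0 - rho_v) * v_scale)
    p_csf = np.clip(p_csf + v * p_wm, 0.0, 1.0)
    p_wm = np.clip(p_wm * (1.0 - v), 0.0, 1.0)

    total = p_gm + p_wm + p_csf
    over = total > 1.0
    if over.any():  # safety net; the geometry is built to stay disjoint
        p_gm[over] /= total[over]
        p_wm[over] /= total[over]
        p_csf[over] /= total[over]
    return p_gm, p_wm, p_csf, q


def _centered_affine(grid_shape, spacing):
    n = np.asarray(grid_shape)
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = -(n - 1) / 2.0 * spacing
    return aff


def make_template(grid_shape=(96, 96, 96), spacing_mm=1.5) -> TemplateAnatomy:
    """Build the deterministic analytic template anatomy.

    Geometry scales with the field of view: a cerebral ellipsoid with a
    cortical ribbon (WM core at relative radius <= 0.78, GM ribbon to 0.92,
    CSF shell to 1.0) plus a disjoint cerebellar ellipsoid placed
    inferior-posteriorly.  Edges are smoothed with ~2 mm sigmoids so the
    probability maps are soft but sum to <= 1 by construction.
    """
    n = np.asarray(grid_shape, dtype=int)
    if np.any(n < 32):
        raise GeometryError("grid too small for a closed cortical ribbon")
    fov = (n - 1) * float(spacing_mm)
    if np.any(fov < 45.0):
        raise GeometryError("field of view too small to contain the anatomy")
    h = fov / 2.0
    affine = _centered_affine(n, float(spacing_mm))
    idx = np.indices(tuple(n), dtype=float)
    x = idx[0] * spacing_mm + affine[0, 3]
    y = idx[1] * spacing_mm + affine[1, 3]
    z = idx[2] * spacing_mm + affine[2, 3]

    # cerebrum: ellipsoid with a cortical ribbon; 1.0 mm sigmoid edges keep
    # mid-ribbon GM probability near 1 so pure-tissue cores exist
    c_ctr = np.array([0.0, 0.0, 0.17 * h[2]])
    c_rad = np.array([0.70 * h[0], 0.82 * h[1], 0.60 * h[2]])
    rho = np.sqrt(
        ((x - c_ctr[0]) / c_rad[0]) ** 2
        + ((y - c_ctr[1]) / c_rad[1]) ** 2
        + ((z - c_ctr[2]) / c_rad[2]) ** 2
    )
    w_mm = 1.0
    # ventricles: central cavity at 30% of the cerebral radii
    v_rad = 0.30 * c_rad
    rho_v = np.sqrt(
        ((x - c_ctr[0]) / v_rad[0]) ** 2
        + ((y - c_ctr[1]) / v_rad[1]) ** 2
        + ((z - c_ctr[2]) / v_rad[2]) ** 2
    )
    # cerebellum: disjoint inferior-posterior ellipsoid
    cb_ctr = np.array([0.0, -0.50 * h[1], -0.62 * h[2]])
    cb_rad = np.array([0.33 * h[0], 0.25 * h[1], 0.19 * h[2]])
    rho_cb = np.sqrt(
        ((x - cb_ctr[0]) / cb_rad[0]) ** 2
        + ((y - cb_ctr[1]) / cb_rad[1]) ** 2
        + ((z - cb_ctr[2]) / cb_rad[2]) ** 2
    )
    scales = (c_rad.min() / w_mm, cb_rad.min() / w_mm, v_rad.min() / w_mm)
    p_gm, p_wm, p_csf, q = _tissue_probs(rho, rho_cb, rho_v, scales)

    t1 = T1_MEANS["GM"] * p_gm + T1_MEANS["WM"] * p_wm + T1_MEANS["CSF"] * p_csf
    return TemplateAnatomy(
        tpm_gm=TissueProbabilityMap(p_gm, affine, "GM", STANDARD),
        tpm_wm=TissueProbabilityMap(p_wm, affine, "WM", STANDARD),
        tpm_csf=TissueProbabilityMap(p_csf, affine, "CSF", STANDARD),
        cerebellum_voi=VOIMask(q >= 0.5, affine, STANDARD, "cerebellum"),
        template_t1=VolumetricImage(t1, affine),
        cerebellum_radii_mm=cb_rad,
        cerebellum_prob=q,
        rho=rho,
        rho_cb=rho_cb,
        rho_v=rho_v,
        scales=scales,
    )


def _random_true_warp(template: TemplateAnatomy, rng, params: PhantomParams):
    """Smooth random invertible template->subject warp on the native grid."""
    shape = template.shape
    affine = template.affine
    img = template.template_t1
    world = img.world_coords()
    span = np.array([(s - 1) for s in shape]) * img.spacing
    u = [(world[i] - world[i].min()) / span[i] for i in range(3)]

    for attempt in range(params.max_warp_retries):
        ang = rng.uniform(-params.rot_max_deg, params.rot_max_deg, 3)
        tr = rng.uniform(-params.trans_max_mm, params.trans_max_mm, 3)
        sc = 1.0 + rng.uniform(-params.scale_jitter, params.scale_jitter, 3)
        R = RigidTransform.from_params(ang, (0, 0, 0)).rotation
        A = R @ np.diag(sc)

        disp = np.zeros((3,) + tuple(shape))
        K = 3
        for i in range(3):
            comp = np.zeros(shape)
            for p in range(K):
                for q_ in range(K):
                    for r in range(K):
                        if p == q_ == r == 0:
                            continue
                        amp = params.warp_amplitude_mm / (1.0 + p * p + q_ * q_ + r * r)
                        comp += rng.normal(0.0, amp) * (
                            np.cos(np.pi * p * u[0])
                            * np.cos(np.pi * q_ * u[1])
                            * np.cos(np.pi * r * u[2])
                        )
            disp[i] = comp

        # pull-back mapping y -> A (y - c) + c + t + disp(y); c = FOV centre
        c = world.reshape(3, -1).mean(axis=1)
        aff_part = np.einsum(
            "ij,j...->i...", A, world - c[:, None, None, None]
        ) + (c + tr)[:, None, None, None]
        total = aff_part + disp - world
        fld = DeformationField(total, affine.copy(), STANDARD_TO_NATIVE, "truth")
        if float(jacobian_determinant(fld).data.min()) > 0.05:
            return fld
    raise EstimationError("could not sample an invertible warp")


def _warp_template_field(vol: np.ndarray, template, fld: DeformationField,
                         order=1, fill=0.0):
    img = VolumetricImage(vol, template.affine)
    from .normalization import apply_warp  # local import avoids cycle at import time

    return apply_warp(img, fld, "concentration_preserving",
                      "linear" if order == 1 else "nearest", fill=fill).data


def _poly_bias(shape, rng, amplitude):
    if amplitude <= 0:
        return np.ones(shape)
    axes = [np.linspace(-1, 1, s) for s in shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    terms = [u, v, w, u * v, u * w, v * w, u * u, v * v, w * w]
    coefs = rng.normal(0.0, 1.0, len(terms))
    fieldv = sum(c * t for c, t in zip(coefs, terms))
    fieldv = fieldv - fieldv.mean()
    peak = max(np.abs(fieldv).max(), 1e-9)
    return 1.0 + amplitude * fieldv / peak


def synthesize_subject(
    template: TemplateAnatomy,
    diagnosis: str,
    seed: int,
    params: PhantomParams,
    subject_id: str | None = None,
) -> Subject:
    """Generate one subject (MRI, PET, ground truth) from the template.

    Deterministic given ``(seed, params)``.  Ground-truth masks and the
    SUVR field are recorded *before* PET blurring and noise; the Abeta+
    ground truth is therefore a property of the phantom, not of the
    simulated scanner resolution.
    """
    if diagnosis not in (AD, HC):
        raise ParameterError(f"diagnosis must be AD or HC, got {diagnosis!r}")
    rng = np.random.default_rng(seed)
    fld = _random_true_warp(template, rng, params)
    affine = template.affine.copy()
    shape = template.shape

    # warp the smooth radial coordinate fields, then rebuild the tissue
    # probabilities analytically: native-space anatomy is exact, and AD
    # atrophy thins the cortical ribbon geometrically (outer GM boundary
    # moves inward, CSF takes the vacated space)
    far = 10.0  # "far outside the head" fill for out-of-field samples
    rho_n = _warp_template_field(template.rho, template, fld, fill=far)
    rho_cb_n = _warp_template_field(template.rho_cb, template, fld, fill=far)
    rho_v_n = _warp_template_field(template.rho_v, template, fld, fill=far)
    atrophy = 1.0
    if diagnosis == AD:
        atrophy = float(rng.uniform(*params.atrophy_range_ad))
    p_gm, p_wm, p_csf, q_cb = _tissue_probs(
        rho_n, rho_cb_n, rho_v_n, template.scales, atrophy=atrophy
    )

    true_gm = VOIMask(p_gm >= 0.5, affine, NATIVE, "GM")
    true_cb = VOIMask(q_cb >= 0.5, affine, NATIVE, "cerebellum")

    # ---- MRI channel
    t1 = (
        T1_MEANS["GM"] * p_gm + T1_MEANS["WM"] * p_wm + T1_MEANS["CSF"] * p_csf
    )
    bias = _poly_bias(shape, rng, params.bias_field_amplitude)
    mri = t1 * bias
    if params.mri_noise_sd > 0:
        mri = mri + rng.normal(0.0, params.mri_noise_sd, shape)
    mri_img = VolumetricImage(mri, affine.copy())

    # ---- PET channel: noise-free SUVR truth first
    gm_base = float(rng.uniform(*params.hc_gm_suvr_range))
    lesion_field = np.zeros(shape)
    if diagnosis == AD:
        ribbon = (p_gm >= 0.5) & (q_cb < 0.5)
        coords = np.argwhere(ribbon)
        world = mri_img.world_coords()
        for _ in range(params.n_lesions):
            if coords.shape[0] == 0:
                break
            ci = coords[rng.integers(0, coords.shape[0])]
            centre = affine[:3, :3] @ ci + affine[:3, 3]
            radius = float(rng.uniform(*params.lesion_radius_range_mm))
            lesion_suvr = float(rng.uniform(*params.ad_lesion_suvr_range))
            dist2 = (
                (world[0] - centre[0]) ** 2
                + (world[1] - centre[1]) ** 2
                + (world[2] - centre[2]) ** 2
            )
            inside = dist2 <= radius**2
            lesion_field = np.where(
                inside, np.maximum(lesion_field, lesion_suvr), lesion_field
            )
    base = gm_base * p_gm + BASE_SUVR["WM"] * p_wm + BASE_SUVR["CSF"] * p_csf
    suvr = q_cb * 1.0 + (1.0 - q_cb) * base
    # solid amyloid plaques: lesion SUVR replaces the mixture inside the
    # grey-matter ribbon (plaque load dominates the voxel signal there)
    lesion_mask = (lesion_field > 0) & (p_gm >= 0.5) & (q_cb < 0.5)
    suvr[lesion_mask] = lesion_field[lesion_mask]
    suvr[q_cb >= 0.5] = 1.0  # pin the reference region exactly
    true_suvr = VolumetricImage(suvr, affine.copy())

    true_metrics = compute_metrics(true_suvr, true_gm,
                                   threshold=params.abeta_threshold)

    suv = params.pet_scale * suvr
    if params.psf_fwhm_mm > 0:
        sigma_vox = (params.psf_fwhm_mm / 2.3548) / mri_img.spacing
        suv = ndimage.gaussian_filter(suv, sigma=sigma_vox)
    if params.pet_noise_sd > 0:
        suv = suv + rng.normal(0.0, params.pet_noise_sd * params.pet_scale,
                               shape)
    suv_img = VolumetricImage(suv, affine.copy())

    # acquire PET on a slightly mis-aligned grid (exercises rigid coreg)
    if params.pet_rigid_max_mm > 0 or params.pet_rigid_max_deg > 0:
        ang = rng.uniform(-params.pet_rigid_max_deg, params.pet_rigid_max_deg, 3)
        tr = rng.uniform(-params.pet_rigid_max_mm, params.pet_rigid_max_mm, 3)
        centre = affine[:3, :3] @ ((np.asarray(shape) - 1) / 2.0) + affine[:3, 3]
        pet_rigid = RigidTransform.from_params(ang, tr, center=centre)
        pet_img = resample_into(suv_img, pet_rigid, mri_img, "linear")
    else:
        pet_rigid = RigidTransform.identity()
        pet_img = suv_img

    truth = PhantomGroundTruth(
        true_warp=fld,
        true_gm_mask=true_gm,
        true_cerebellum=true_cb,
        true_suvr_field=true_suvr,
        true_metrics=true_metrics,
        diagnosis=diagnosis,
        atrophy_factor=atrophy,
        gm_base_suvr=gm_base,
        pet_rigid=pet_rigid,
        seed=seed,
    )
    sid = subject_id or f"{diagnosis}-{seed}"
    return Subject(sid, diagnosis, mri_img, pet_img, truth, seed)


def synthesize_cohort(template: TemplateAnatomy, params: PhantomParams):
    """Generate the full cohort plus a manifest.

    Per-subject seeds are derived deterministically from ``params.seed``
    via a NumPy SeedSequence, so two cohorts built with the same master
    seed are identical.

    Returns
    -------
    subjects : list of Subject
    manifest : pandas.DataFrame
        Columns: subject_id, diagnosis, seed, atrophy_factor.
    """
    if params.n_ad < 1 or params.n_hc < 1:
        raise ParameterError("need at least one subject per group")
    n = params.n_ad + params.n_hc
    seeds = np.random.SeedSequence(params.seed).generate_state(n) % (2**31)
    subjects = []
    rows = []
    for i in range(n):
        diagnosis = AD if i < params.n_ad else HC
        sid = f"{diagnosis}{i + 1:02d}" if diagnosis == AD else \
            f"{diagnosis}{i - params.n_ad + 1:02d}"
        subj = synthesize_subject(template, diagnosis, int(seeds[i]), params,
                                  subject_id=sid)
        subjects.append(subj)
        rows.append({
            "subject_id": sid,
            "diagnosis": diagnosis,
            "seed": int(seeds[i]),
            "atrophy_factor": subj.truth.atrophy_factor,
        })
    return subjects, pd.DataFrame(rows)
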