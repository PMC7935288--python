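"""Grey-matter definition, tissue probability maps and VOI provisioning.

Three GM definitions are supported, following common amyloid-PET practice:

* **MRn** -- segment the subject's MRI in native space; the GM map can then
  be warped to standard space (thresholded *after* warping).
* **MRs** -- warp the MRI to standard space first, segment there (standard
  space only).
* **TEs** -- use the population template's GM probability map directly
  (inverse-warped into native space when needed).

Binary masks come from a 50% threshold of the GM probability map; the
inclusive ``>=`` convention is used at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._gmm import fit_gmm_with_priors
from .errors import ParameterError, UsageError, VOIError
from .image_model import VolumetricImage
from .normalization import (
    CONCENTRATION_PRESERVING,
    DeformationField,
    apply_warp,
)

NATIVE = "native"
STANDARD = "standard"

MRN, MRS, TES = "MRn", "MRs", "TEs"
GM_DEFINITIONS = (MRN, MRS, TES)


@dataclass
class TissueProbabilityMap:
    """Per-voxel tissue probability in [0, 1] on a named grid."""

    prob: np.ndarray
    affine: np.ndarray
    tissue: str           # "GM", "WM", "CSF"
    space: str            # "native" or "standard"

    def __post_init__(self):
        self.prob = np.clip(np.asarray(self.prob, dtype=float), 0.0, 1.0)
        self.affine = np.asarray(self.affine, dtype=float)

    def as_image(self) -> VolumetricImage:
        return VolumetricImage(self.prob, self.affine)

    @property
    def voxel_volume_ml(self) -> float:
        return abs(np.linalg.det(self.affine[:3, :3])) / 1000.0


@dataclass
class VOIMask:
    """Binary volume of interest."""

    mask: np.ndarray
    affine: np.ndarray
    space: str
    label: str            # "GM", "cerebellum", "abeta_pos"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return abs(np.linalg.det(self.affine[:3, :3])) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml


def _head_mask(data: np.ndarray) -> np.ndarray:
    """Otsu-threshold head mask with closing and hole filling."""
    lo, hi = float(data.min()), float(data.max())
    hist, edges = np.histogram(data, bins=128, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu0 = np.cumsum(p * centers) / np.maximum(w0, 1e-12)
    mu_t = (p * centers).sum()
    mu1 = (mu_t - np.cumsum(p * centers)) / np.maximum(w1, 1e-12)
    between = w0 * w1 * (mu0 - mu1) ** 2
    thr = centers[int(np.argmax(between))]
    mask = data > thr
    mask = ndimage.binary_dilation(mask, iterations=2)  # pull in the CSF rim
    mask = ndimage.binary_closing(mask, iterations=3)
    return ndimage.binary_fill_holes(mask)


def segment_tissues(
    mri: VolumetricImage,
    priors: dict | None = None,
    bias_correction: bool = True,
    space: str = NATIVE,
    n_em: int = 12,
) -> dict:
    """Gaussian-mixture tissue classification of a T1-like MRI.

    Parameters
    ----------
    mri : VolumetricImage
    priors : dict or None
        Optional spatial priors ``{"GM", "WM", "CSF"}`` as
        :class:`TissueProbabilityMap` (or VolumetricImage) on the MRI grid.
        Without priors a flat-prior mixture is fitted and the three
        foreground classes are labelled by intensity order
        (CSF < GM < WM for T1 contrast).
    bias_correction : bool
        Estimate a multiplicative degree-2 polynomial bias field.

    Returns
    -------
    dict of TissueProbabilityMap for GM, WM and CSF (posteriors; their sum
    is <= 1, the remainder being background).
    """
    data = np.asarray(mri.data, dtype=float)
    if priors is None:
        # prior-free route: head/background split first (Otsu threshold,
        # morphological closing and hole filling pull in the CSF shell and
        # ventricles), then a flat-prior mixture inside the head mask
        brain = _head_mask(data)
        fg = np.where(brain, 0.32, 1e-3)
        fg_priors = [fg, fg, fg]
        bg_prior = np.where(brain, 0.04, 1.0 - 3e-3)
        order_by_intensity = True
        init_quantiles = True
    else:
        def arr(p):
            return p.prob if isinstance(p, TissueProbabilityMap) else np.asarray(
                p.data if hasattr(p, "data") else p, dtype=float
            )

        fg_priors = [arr(priors[k]) for k in ("GM", "WM", "CSF")]
        s = np.clip(np.stack(fg_priors).sum(axis=0), 0.0, 1.0)
        bg_prior = np.clip(1.0 - s, 1e-4, 1.0)
        order_by_intensity = False
        init_quantiles = False
    state = fit_gmm_with_priors(
        data, fg_priors, bg_prior, bias_correction=bias_correction, n_em=n_em,
        order_by_intensity=order_by_intensity, init_quantiles=init_quantiles,
    )
    out = {}
    for i, k in enumerate(("GM", "WM", "CSF")):
        out[k] = TissueProbabilityMap(state.posteriors[i], mri.affine.copy(),
                                      k, space)
    return out


def gm_mask_from_tpm(tpm: TissueProbabilityMap, threshold: float = 0.50) -> VOIMask:
    """Binary GM mask: probability >= threshold (inclusive boundary)."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("GM threshold must lie strictly inside (0, 1)")
    return VOIMask(tpm.prob >= threshold, tpm.affine.copy(), tpm.space, "GM")


def warp_tpm(
    tpm: TissueProbabilityMap,
    fld: DeformationField,
    to_space: str,
    interpolation: str = "linear",
) -> TissueProbabilityMap:
    """Move a probability map through a warp (concentration semantics,
    values clamped back into [0, 1] after interpolation)."""
    img = apply_warp(
        tpm.as_image(), fld, CONCENTRATION_PRESERVING, interpolation
    )
    return TissueProbabilityMap(np.clip(img.data, 0.0, 1.0), img.affine,
                                tpm.tissue, to_space)


def provide_gm(
    gm_def: str,
    analysis_space: str,
    *,
    native_gm_tpm: TissueProbabilityMap | None = None,
    template_gm_tpm: TissueProbabilityMap | None = None,
    mri_native: VolumetricImage | None = None,
    forward: DeformationField | None = None,
    inverse: DeformationField | None = None,
    threshold: float = 0.50,
    bias_correction: bool = True,
) -> VOIMask:
    """Produce the GM VOI for one pipeline cell.

    The five valid (definition, space) combinations are: MRn in native and
    standard space, TEs in native and standard space, and MRs in standard
    space only.  Probability maps are always thresholded *after* warping.

    ``forward`` is the subject's native->standard field, ``inverse`` the
    standard->native field; only the ones a combination needs must be given.
    """
    if gm_def not in GM_DEFINITIONS:
        raise ParameterError(f"unknown GM definition {gm_def!r}")
    if gm_def == MRS and analysis_space == NATIVE:
        raise UsageError("MRs GM is only defined for standard-space analyses")

    if gm_def == MRN:
        if native_gm_tpm is None:
            raise ParameterError("MRn requires the native GM TPM")
        tpm = native_gm_tpm
        if analysis_space == STANDARD:
            tpm = warp_tpm(tpm, forward, STANDARD)
    elif gm_def == TES:
        if template_gm_tpm is None:
            raise ParameterError("TEs requires the template GM TPM")
        tpm = template_gm_tpm
        if analysis_space == NATIVE:
            tpm = warp_tpm(tpm, inverse, NATIVE)
    else:  # MRs
        if mri_native is None or forward is None:
            raise ParameterError("MRs requires the native MRI and forward warp")
        mri_std = apply_warp(mri_native, forward, CONCENTRATION_PRESERVING)
        tpm = segment_tissues(
            mri_std, priors=None, bias_correction=bias_correction,
            space=STANDARD,
        )["GM"]
    mask = gm_mask_from_tpm(tpm, threshold)
    return VOIMask(mask.mask, mask.affine, analysis_space, "GM")


def provide_cerebellum(
    analysis_space: str,
    template_cerebellum: VOIMask,
    inverse: DeformationField | None = None,
) -> VOIMask:
    """Cerebellum reference VOI in the requested analysis space.

    In standard space the template VOI is used unchanged; for native-space
    analyses it is inverse-warped (linear interpolation of the soft mask,
    then a 0.5 threshold, so the result stays binary).
    """
    if analysis_space == STANDARD:
        return template_cerebellum
    if inverse is None:
        raise ParameterError("native cerebellum requires the inverse warp")
    soft = apply_warp(
        VolumetricImage(template_cerebellum.mask.astype(float),
                        template_cerebellum.affine),
        inverse,
        CONCENTRATION_PRESERVING,
        "linear",
    )
    mask = soft.data >= 0.5
    if not mask.any():
        raise VOIError("warped cerebellum VOI is empty")
    return VOIMask(mask, soft.affine, NATIVE, "cerebellum")
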