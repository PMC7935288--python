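"""SUVR image construction and the five amyloid-burden metrics.

All metrics are extracted from the grey-matter VOI of a SUVR image
(PET voxel values divided by the mean uptake in the whole-cerebellum VOI):

* ``suvr_mean`` -- mean SUVR over all GM voxels (intensity metric)
* ``suvr_mean_abeta_pos`` -- mean SUVR over amyloid-positive GM voxels
* ``abeta_volume_ml`` -- volume of GM voxels with SUVR >= threshold (mL)
* ``afv`` -- amyloid fractional volume, Abeta+ volume / GM volume
* ``tab_ml`` -- total amyloid burden, ``suvr_mean_abeta_pos * abeta_volume``

The positivity threshold defaults to SUVR >= 1.5 (inclusive); 1.2 is the
conventional higher-sensitivity option.  When a subject has no positive
voxel, ``suvr_mean_abeta_pos`` and ``tab_ml`` are reported as missing (NaN),
not zero, and ``abeta_volume_ml``/``afv`` are 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ReferenceError_, VOIError
from .image_model import CONCENTRATION, VolumetricImage
from .segmentation import VOIMask


@dataclass
class MetricSet:
    suvr_mean: float
    suvr_mean_abeta_pos: float   # NaN when no Abeta+ voxel
    abeta_volume_ml: float
    afv: float
    tab_ml: float                # NaN when no Abeta+ voxel
    n_gm_voxels: int
    n_abeta_voxels: int
    threshold: float

    def as_dict(self) -> dict:
        return {
            "suvr_mean": self.suvr_mean,
            "suvr_mean_abeta_pos": self.suvr_mean_abeta_pos,
            "abeta_volume_ml": self.abeta_volume_ml,
            "afv": self.afv,
            "tab_ml": self.tab_ml,
            "n_gm_voxels": self.n_gm_voxels,
            "n_abeta_voxels": self.n_abeta_voxels,
            "threshold": self.threshold,
        }


METRIC_COLUMNS = ("suvr_mean", "suvr_mean_abeta_pos", "abeta_volume_ml",
                  "afv", "tab_ml")


def suvr_image(pet: VolumetricImage, cerebellum: VOIMask,
               valid: np.ndarray | None = None) -> VolumetricImage:
    """Divide the PET image by its mean over the cerebellum VOI.

    ``valid`` optionally restricts the reference statistic to in-field
    voxels (out-of-field fill values would bias the reference mean).
    """
    sel = cerebellum.mask
    if valid is not None:
        sel = sel & valid
    if not sel.any():
        raise VOIError("cerebellum VOI is empty")
    ref = float(np.asarray(pet.data)[sel].mean())
    if ref <= 0:
        raise ReferenceError_(f"cerebellum mean is non-positive ({ref:g})")
    return VolumetricImage(np.asarray(pet.data, dtype=float) / ref,
                           pet.affine.copy(), CONCENTRATION)


def abeta_mask(suvr: VolumetricImage, gm: VOIMask,
               threshold: float = 1.5) -> VOIMask:
    """Amyloid-positive voxels: SUVR >= threshold inside the GM VOI."""
    if threshold <= 0:
        raise ParameterError("SUVR threshold must be positive")
    mask = (np.asarray(suvr.data) >= threshold) & gm.mask
    return VOIMask(mask, gm.affine.copy(), gm.space, "abeta_pos")


def compute_metrics(
    suvr: VolumetricImage,
    gm: VOIMask,
    threshold: float = 1.5,
    valid: np.ndarray | None = None,
) -> MetricSet:
    """Extract the five amyloid-burden metrics from a SUVR image.

    Volumes are binary-mask volumes on the analysis grid (voxel count times
    voxel volume; no partial-volume weighting).
    """
    gm_sel = gm.mask if valid is None else (gm.mask & valid)
    n_gm = int(gm_sel.sum())
    if n_gm == 0:
        raise VOIError("GM VOI is empty")
    vals = np.asarray(suvr.data)[gm_sel]
    voxvol = gm.voxel_volume_ml
    pos = vals >= threshold
    n_pos = int(pos.sum())
    suvr_mean = float(vals.mean())
    abeta_volume = n_pos * voxvol
    afv = abeta_volume / (n_gm * voxvol)
    if n_pos:
        suvr_pos = float(vals[pos].mean())
        tab = suvr_pos * abeta_volume
    else:
        suvr_pos = math.nan
        tab = math.nan
    return MetricSet(
        suvr_mean=suvr_mean,
        suvr_mean_abeta_pos=suvr_pos,
        abeta_volume_ml=abeta_volume,
        afv=afv,
        tab_ml=tab,
        n_gm_voxels=n_gm,
        n_abeta_voxels=n_pos,
        threshold=threshold,
    )
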