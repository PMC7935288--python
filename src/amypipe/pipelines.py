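"""Factorial pipeline engine: reference space x transform x GM definition.

Fifteen valid pipelines exist at one positivity threshold: in native space
the GM definition can be MRn or TEs (2 x 3 transforms = 6), in standard
space MRn, TEs or MRs (3 x 3 = 9).  MAPa and MAPc share one estimated warp
per subject and differ only in how voxel values are treated when the PET is
moved to standard space (Jacobian-modulated vs not); in native space the
PET is never warped non-rigidly, so MAPa and MAPc native rows are
identical by construction.

The two *main* pipelines are (native, USM, MRn) and (standard, USM, MRn).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AmypipeError, ParameterError
from .image_model import (
    VolumetricImage,
    resample_into,
    validity_mask,
)
from .normalization import (
    AMOUNT_PRESERVING,
    CONCENTRATION_PRESERVING,
    NATIVE_TO_STANDARD,
    STANDARD_TO_NATIVE,
    RigidRegParams,
    WarpParams,
    apply_warp,
    estimate_map_warp,
    estimate_usm_warp,
    invert_warp,
    register_rigid,
    warp_validity_mask,
)
from .quantification import METRIC_COLUMNS, MetricSet, compute_metrics, suvr_image
from .segmentation import (
    GM_DEFINITIONS,
    MRN,
    MRS,
    NATIVE,
    STANDARD,
    TES,
    provide_cerebellum,
    provide_gm,
    segment_tissues,
)

log = logging.getLogger("amypipe.pipelines")

MAPA, MAPC, USM = "MAPa", "MAPc", "USM"
TRANSFORMS = (MAPA, MAPC, USM)
SPACES = (NATIVE, STANDARD)


@dataclass(frozen=True)
class PipelineSpec:
    space: str
    transform: str
    gm_def: str
    threshold: float = 1.5

    def __post_init__(self):
        if self.space not in SPACES:
            raise ParameterError(f"unknown space {self.space!r}")
        if self.transform not in TRANSFORMS:
            raise ParameterError(f"unknown transform {self.transform!r}")
        if self.gm_def not in GM_DEFINITIONS:
            raise ParameterError(f"unknown GM definition {self.gm_def!r}")
        if self.space == NATIVE and self.gm_def == MRS:
            raise ParameterError("MRs GM cannot be used in native space")

    @property
    def label(self) -> str:
        return f"{self.space}+{self.gm_def}+{self.transform}"


MAIN_PIPELINES = (
    PipelineSpec(NATIVE, USM, MRN),
    PipelineSpec(STANDARD, USM, MRN),
)


def enumerate_pipelines(threshold: float = 1.5) -> list:
    """All 15 valid pipeline specs in deterministic order
    (native first; transforms MAPa, MAPc, USM; GM MRn, TEs, MRs)."""
    specs = []
    for space in SPACES:
        for transform in TRANSFORMS:
            for gm_def in (MRN, TES, MRS):
                if space == NATIVE and gm_def == MRS:
                    continue
                specs.append(PipelineSpec(space, transform, gm_def, threshold))
    return specs


def _family(transform: str) -> str:
    return "MAP" if transform in (MAPA, MAPC) else "USM"


class PipelineRunner:
    """Executes pipelines for a cohort, caching per-subject transforms.

    Warps are estimated once per (subject, transform family) and reused by
    every spec, which both saves time and realises the MAPa/MAPc
    shared-parameter contract.  The native tissue segmentation (MRn) is
    likewise computed once per subject.
    """

    def __init__(
        self,
        template,
        warp_params: WarpParams | None = None,
        reg_params: RigidRegParams | None = None,
        bias_correction: bool = True,
    ):
        self.template = template
        self.warp_params = warp_params or WarpParams()
        self.reg_params = reg_params or RigidRegParams()
        self.bias_correction = bias_correction
        self._cache = {}

    # ---- cached per-subject resources -----------------------------------
    def _get(self, subject, key, builder):
        ck = (subject.subject_id, key)
        if ck not in self._cache:
            self._cache[ck] = builder()
        return self._cache[ck]

    def pet_native(self, subject):
        """PET rigidly aligned onto the subject's MRI grid + validity mask."""

        def build():
            T = register_rigid(subject.pet, subject.mri, self.reg_params)
            pet = resample_into(subject.pet, T, subject.mri, "linear")
            valid = validity_mask(subject.pet, T, subject.mri)
            return pet, valid

        return self._get(subject, "pet_native", build)

    def native_segmentation(self, subject):
        def build():
            return segment_tissues(
                subject.mri, priors=None, bias_correction=self.bias_correction
            )

        return self._get(subject, "native_seg", build)

    def warps(self, subject, transform):
        """(forward, inverse) deformation fields for a transform family."""
        family = _family(transform)

        def build():
            if family == "MAP":
                fwd = estimate_map_warp(
                    subject.mri, self.template.template_t1, self.warp_params
                )
                inv = invert_warp(fwd, reference=subject.mri)
            else:
                inv, posteriors = estimate_usm_warp(
                    subject.mri, self.template.tpm_images(), self.warp_params,
                    bias_correction=self.bias_correction,
                )
                fwd = invert_warp(inv, reference=self.template.template_t1)
                self._cache[(subject.subject_id, "usm_posteriors")] = posteriors
            return fwd, inv

        return self._get(subject, f"warp_{family}", build)

    # ---- execution -------------------------------------------------------
    def _gm_voi(self, subject, spec: PipelineSpec):
        """GM VOI for a spec (cached; threshold-independent, and MAPa/MAPc
        share it through the family warp)."""
        fwd, inv = self.warps(subject, spec.transform)

        def build():
            return provide_gm(
                spec.gm_def, spec.space,
                native_gm_tpm=self.native_segmentation(subject)["GM"],
                template_gm_tpm=self.template.tpm_gm,
                mri_native=subject.mri,
                forward=fwd,
                inverse=inv,
                bias_correction=self.bias_correction,
            )

        key = ("gm", spec.space, _family(spec.transform), spec.gm_def)
        return self._get(subject, key, build)

    def _suvr_and_valid(self, subject, spec: PipelineSpec):
        """SUVR image + validity for a spec (cached; GM- and
        threshold-independent)."""
        pet, pet_valid = self.pet_native(subject)
        fwd, inv = self.warps(subject, spec.transform)

        def build():
            if spec.space == NATIVE:
                cereb = provide_cerebellum(
                    NATIVE, self.template.cerebellum_voi, inverse=inv
                )
                return suvr_image(pet, cereb, valid=pet_valid), pet_valid
            modulation = (
                AMOUNT_PRESERVING if spec.transform == MAPA
                else CONCENTRATION_PRESERVING
            )
            pet_std = apply_warp(pet, fwd, modulation, "linear",
                                 direction=NATIVE_TO_STANDARD)
            in_fov = warp_validity_mask(pet, fwd)
            valid_native = apply_warp(
                VolumetricImage(pet_valid.astype(float), pet.affine),
                fwd, CONCENTRATION_PRESERVING, "nearest",
            ).data >= 0.5
            valid = in_fov & valid_native
            cereb = provide_cerebellum(STANDARD, self.template.cerebellum_voi)
            return suvr_image(pet_std, cereb, valid=valid), valid

        key = (
            "suvr",
            spec.space,
            _family(spec.transform) if spec.space == NATIVE else spec.transform,
        )
        return self._get(subject, key, build)

    def run_pipeline(self, subject, spec: PipelineSpec) -> MetricSet:
        """Execute one pipeline for one subject and return its metrics."""
        suvr, valid = self._suvr_and_valid(subject, spec)
        gm = self._gm_voi(subject, spec)
        return compute_metrics(suvr, gm, threshold=spec.threshold, valid=valid)

    def drop_subject_cache(self, subject_id: str):
        """Release all cached resources for one subject."""
        for ck in [k for k in self._cache if k[0] == subject_id]:
            del self._cache[ck]

    def run_cohort(self, subjects, specs=None, keep_cache=False) -> pd.DataFrame:
        """Run the full subject x spec cross product into a long table.

        Individual failures are quarantined as rows with NaN metrics and a
        recorded reason; the run aborts only if more than half of all rows
        fail.  Per-subject caches are released after each subject unless
        ``keep_cache`` is set (memory stays bounded on large cohorts).
        """
        specs = list(specs) if specs is not None else enumerate_pipelines()
        if not subjects or not specs:
            raise ParameterError("cohort and spec list must be nonempty")
        rows = []
        n_fail = 0
        for subject in subjects:
            for spec in specs:
                row = {
                    "subject_id": subject.subject_id,
                    "diagnosis": subject.diagnosis,
                    "space": spec.space,
                    "transform": spec.transform,
                    "gm_def": spec.gm_def,
                    "threshold": spec.threshold,
                }
                try:
                    ms = self.run_pipeline(subject, spec)
                    row.update(ms.as_dict())
                    row["gm_volume_ml"] = ms.n_gm_voxels * _voxvol(
                        self.template if spec.space == STANDARD else subject.mri
                    )
                    fwd, _ = self.warps(subject, spec.transform)
                    row["warp_checksum"] = fwd.checksum()
                    row["status"] = "ok"
                    row["error"] = ""
                except AmypipeError as exc:  # quarantine, keep going
                    n_fail += 1
                    for col in METRIC_COLUMNS:
                        row[col] = math.nan
                    row.update(
                        n_gm_voxels=0, n_abeta_voxels=0,
                        gm_volume_ml=math.nan, warp_checksum="",
                        status="failed", error=f"{type(exc).__name__}: {exc}",
                    )
                    log.warning("pipeline %s failed for %s: %s",
                                spec.label, subject.subject_id, exc)
                rows.append(row)
            if not keep_cache:
                self.drop_subject_cache(subject.subject_id)
            log.info("subject %s done (%d specs)", subject.subject_id,
                     len(specs))
        table = pd.DataFrame(rows)
        if n_fail > 0.5 * len(table):
            raise AmypipeError(
                f"{n_fail}/{len(table)} pipeline rows failed; aborting"
            )
        return table


def _voxvol(obj) -> float:
    aff = obj.affine if hasattr(obj, "affine") else obj.template_t1.affine
    return abs(np.linalg.det(aff[:3, :3])) / 1000.0
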