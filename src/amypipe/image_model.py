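"""Core volumetric data types and resampling primitives.

Volumes are plain 3-D scalar grids with a NIfTI-style 4x4 affine mapping
0-based voxel indices to world millimetres (RAS+).  Every image carries a
value-semantics tag distinguishing *concentration*-like values (SUV, SUVR,
MRI intensity -- intensive, unchanged by resampling) from *amount*-like
values (extensive, produced by Jacobian modulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import (
    DimensionalityError,
    EmptyWindowError,
    FormatError,
    ParameterError,
)

CONCENTRATION = "concentration"
AMOUNT = "amount"

_INTERP_ORDER = {"nearest": 0, "linear": 1}


@dataclass
class VolumetricImage:
    """A 3-D scalar volume with world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values (MRI intensity, SUV, SUVR, probability...).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm map (RAS+ convention, 0-based indices).
    semantics : str
        ``"concentration"`` (intensive) or ``"amount"`` (extensive).
    """

    data: np.ndarray
    affine: np.ndarray
    semantics: str = CONCENTRATION

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got ndim={self.data.ndim}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        if self.semantics not in (CONCENTRATION, AMOUNT):
            raise ParameterError(f"unknown semantics tag {self.semantics!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return abs(np.linalg.det(self.affine[:3, :3])) / 1000.0

    def world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (3, nx, ny, nz)."""
        idx = np.indices(self.shape, dtype=float)
        A = self.affine
        return (
            np.einsum("ij,j...->i...", A[:3, :3], idx) + A[:3, 3, None, None, None]
        )

    def with_data(self, data, semantics=None) -> "VolumetricImage":
        return VolumetricImage(
            np.asarray(data), self.affine.copy(),
            self.semantics if semantics is None else semantics,
        )

    def copy(self) -> "VolumetricImage":
        return VolumetricImage(self.data.copy(), self.affine.copy(), self.semantics)


@dataclass
class DynamicSeries:
    """An ordered set of frames on one grid with acquisition time windows.

    ``frame_windows`` are ``(start_min, end_min)`` pairs, non-overlapping and
    increasing; all frames share a single affine.
    """

    frames: list
    frame_windows: list

    def __post_init__(self):
        if len(self.frames) != len(self.frame_windows):
            raise ParameterError("one time window per frame required")
        if not self.frames:
            raise ParameterError("series must contain at least one frame")
        a0 = self.frames[0].affine
        for f in self.frames:
            if not np.allclose(f.affine, a0, atol=1e-9):
                raise FormatError("all frames must share one affine")
        prev_end = -np.inf
        for start, end in self.frame_windows:
            if end <= start:
                raise ParameterError(f"degenerate frame window ({start}, {end})")
            if start < prev_end - 1e-9:
                raise ParameterError("frame windows overlap or are out of order")
            prev_end = end


@dataclass
class RigidTransform:
    """Rigid-body world transform: x -> R @ x + t (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ParameterError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ParameterError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, angles_deg, translation, center=None) -> "RigidTransform":
        """Euler-angle construction (xyz, degrees), optionally about ``center``."""
        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        t = np.asarray(translation, dtype=float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape (3, ...)."""
        return (
            np.einsum("ij,j...->i...", self.rotation, points)
            + self.translation[(slice(None),) + (None,) * (points.ndim - 1)]
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


# ---------------------------------------------------------------------------
# I/O


def read_volume(path) -> VolumetricImage:
    """Read a 3-D NIfTI-1 volume.

    Raises
    ------
    DimensionalityError
        If the payload is not 3-D (trailing singleton dimensions are not
        squeezed: a 4-D file is rejected).
    FormatError
        If the stored affine is singular.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3-D payload, got shape {data.shape}"
        )
    return VolumetricImage(np.asarray(data, dtype=np.float64), img.affine)


def write_volume(img: VolumetricImage, path) -> None:
    """Write ``img`` to a NIfTI-1 file (.nii or .nii.gz)."""
    nii = nib.Nifti1Image(np.asarray(img.data, dtype=np.float64), img.affine)
    nii.header.set_qform(img.affine, code=1)
    nii.header.set_sform(img.affine, code=1)
    nib.save(nii, str(path))


# ---------------------------------------------------------------------------
# Resampling


def _index_map(moving: VolumetricImage, transform: RigidTransform,
               reference: VolumetricImage):
    """4x4 map from reference voxel indices to moving voxel indices."""
    M = np.linalg.inv(moving.affine) @ transform.matrix() @ reference.affine
    return M


def resample_into(
    moving: VolumetricImage,
    transform: RigidTransform,
    reference: VolumetricImage,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> VolumetricImage:
    """Resample ``moving`` onto the grid of ``reference``.

    ``transform`` maps reference-world points to moving-world points, i.e.
    the output voxel at world position x takes the value of ``moving`` at
    ``transform(x)``.  Out-of-field voxels receive ``fill`` (default 0);
    use :func:`validity_mask` to exclude them from statistics.
    """
    if interpolation not in _INTERP_ORDER:
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    order = _INTERP_ORDER[interpolation]
    M = _index_map(moving, transform, reference)
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=float),
        M[:3, :3],
        M[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=fill,
    )
    return VolumetricImage(out, reference.affine.copy(), moving.semantics)


def validity_mask(
    moving: VolumetricImage,
    transform: RigidTransform,
    reference: VolumetricImage,
) -> np.ndarray:
    """Boolean mask of reference voxels that fall inside ``moving``'s field
    of view under ``transform`` (fill-value voxels are False)."""
    M = _index_map(moving, transform, reference)
    idx = np.indices(reference.shape, dtype=float)
    src = np.einsum("ij,j...->i...", M[:3, :3], idx) + M[:3, 3, None, None, None]
    ok = np.ones(reference.shape, dtype=bool)
    # linear-interpolation support: outside [0, n-1] the sampled value is
    # blended with the constant fill and must count as invalid
    for ax, n in enumerate(moving.shape):
        ok &= (src[ax] >= 0.0) & (src[ax] <= n - 1.0)
    return ok


def reslice_isotropic(
    img: VolumetricImage,
    target_spacing_mm: float = 1.0,
    interpolation: str = "linear",
) -> VolumetricImage:
    """Reslice onto an axis-aligned isotropic grid covering the input FOV.

    The output grid is RAS axis-aligned with spacing ``target_spacing_mm``;
    its first voxel centre sits at the minimum world corner of the input
    voxel-centre bounding box, so an already-isotropic axis-aligned input
    reslices onto itself.
    """
    if target_spacing_mm <= 0:
        raise ParameterError("target spacing must be positive")
    t = float(target_spacing_mm)
    n = np.array(img.shape)
    corners = np.array(
        [[i, j, k, 1.0] for i in (0, n[0] - 1) for j in (0, n[1] - 1)
         for k in (0, n[2] - 1)]
    ).T
    world = (img.affine @ corners)[:3]
    lo, hi = world.min(axis=1), world.max(axis=1)
    shape = np.maximum(np.ceil((hi - lo) / t - 1e-6).astype(int) + 1, 1)
    affine = np.diag([t, t, t, 1.0])
    affine[:3, 3] = lo
    ref = VolumetricImage(np.zeros(shape), affine, img.semantics)
    out = resample_into(img, RigidTransform.identity(), ref, interpolation)
    return out


def average_frames(series: DynamicSeries, window=(40.0, 60.0)) -> VolumetricImage:
    """Duration-weighted average of dynamic frames over a time window.

    Each frame contributes with weight equal to the duration of its overlap
    with ``window`` (minutes), so unequal frame lengths are handled as a
    proper time-weighted mean.  The result is tagged as a concentration.

    Raises
    ------
    EmptyWindowError
        If no frame overlaps the window.
    """
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ParameterError("window end must exceed start")
    weights, used = [], []
    for frame, (s, e) in zip(series.frames, series.frame_windows):
        ov = min(e, end) - max(s, start)
        if ov > 1e-12:
            weights.append(ov)
            used.append(frame)
    if not used:
        raise EmptyWindowError(f"no frame overlaps window ({start}, {end}) min")
    w = np.array(weights) / np.sum(weights)
    data = sum(wi * f.data for wi, f in zip(w, used))
    return VolumetricImage(data, used[0].affine.copy(), CONCENTRATION)
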