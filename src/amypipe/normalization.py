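"""Spatial normalization: rigid NMI registration and non-rigid warps.

Two non-rigid families are provided, mirroring how amyloid-PET studies move
images between a subject's native space and a common standard space:

* **MAP** -- an intensity-driven warp (global affine plus band-limited cosine
  displacement with a smoothness penalty).  One spatial estimate serves both
  value semantics: *amount-preserving* application multiplies resampled
  values by the local Jacobian determinant so the image integral is
  conserved, while *concentration-preserving* application leaves values
  untouched.
* **USM** -- a unified-segmentation warp: tissue probability maps act as
  deformable spatial priors for a Gaussian-mixture tissue classification of
  the MRI, alternating mixture updates with warp updates; applied with
  concentration-preserving semantics.

Deformation fields store a displacement (mm) on the grid of the space the
field resamples *onto*: a ``native_to_standard`` field lives on the standard
grid and pulls native-space values to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from ._gmm import fit_gmm_with_priors
from .errors import ConvergenceError, EstimationError, ParameterError, UsageError
from .image_model import (
    AMOUNT,
    CONCENTRATION,
    RigidTransform,
    VolumetricImage,
)

NATIVE_TO_STANDARD = "native_to_standard"
STANDARD_TO_NATIVE = "standard_to_native"

AMOUNT_PRESERVING = "amount_preserving"
CONCENTRATION_PRESERVING = "concentration_preserving"


@dataclass
class DeformationField:
    """Non-rigid mapping, stored as a pull-back displacement field.

    ``displacement`` has shape (3, nx, ny, nz) in mm on the grid given by
    ``affine`` (the *destination* grid).  A voxel at world position x in the
    destination space takes its value from world position ``x + d(x)`` in
    the source space.
    """

    displacement: np.ndarray
    affine: np.ndarray
    direction: str
    provenance: str = "MAP"

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ParameterError("displacement must have shape (3, nx, ny, nz)")
        if self.direction not in (NATIVE_TO_STANDARD, STANDARD_TO_NATIVE):
            raise ParameterError(f"unknown direction {self.direction!r}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.displacement.shape[1:]

    @property
    def spacing(self):
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def grid_world(self) -> np.ndarray:
        idx = np.indices(self.shape, dtype=float)
        A = self.affine
        return np.einsum("ij,j...->i...", A[:3, :3], idx) + A[:3, 3, None, None, None]

    def mapped_points(self) -> np.ndarray:
        """Source-space world coordinates sampled by each destination voxel."""
        return self.grid_world() + self.displacement

    def checksum(self) -> str:
        """Stable digest of the displacement data (shared-warp assertions)."""
        import hashlib

        return hashlib.sha1(
            np.ascontiguousarray(self.displacement).tobytes()
        ).hexdigest()

    @classmethod
    def identity(cls, reference: VolumetricImage, direction, provenance="MAP"):
        return cls(
            np.zeros((3,) + reference.shape),
            reference.affine.copy(),
            direction,
            provenance,
        )


def _sample_at_world(img: VolumetricImage, world: np.ndarray, order=1, cval=0.0,
                     mode="constant"):
    """Sample ``img`` at world points of shape (3, ...)."""
    Ainv = np.linalg.inv(img.affine)
    idx = np.einsum("ij,j...->i...", Ainv[:3, :3], world) + Ainv[
        :3, 3, None, None, None
    ]
    return ndimage.map_coordinates(
        np.asarray(img.data, dtype=float), idx, order=order, mode=mode,
        cval=cval,
    )


def _inside_mask(img: VolumetricImage, world: np.ndarray) -> np.ndarray:
    Ainv = np.linalg.inv(img.affine)
    idx = np.einsum("ij,j...->i...", Ainv[:3, :3], world) + Ainv[
        :3, 3, None, None, None
    ]
    ok = np.ones(world.shape[1:], dtype=bool)
    # linear-interpolation support: outside [0, n-1] the sampled value is
    # blended with the constant fill and must count as invalid
    for ax, n in enumerate(img.shape):
        ok &= (idx[ax] >= 0.0) & (idx[ax] <= n - 1.0)
    return ok


# ---------------------------------------------------------------------------
# Rigid registration (Normalised Mutual Information, Powell search)


def _soft_hist2d(a: np.ndarray, b: np.ndarray, bins: int,
                 a_range: tuple, b_range: tuple) -> np.ndarray:
    """Joint histogram with bilinear (Parzen-style) bin spreading.

    Linear spreading keeps the histogram -- and hence the NMI objective --
    smooth under small transform changes, avoiding the grid-artifact local
    optima of hard binning.
    """
    def coords(x, rng_):
        lo, hi = rng_
        t = (x - lo) / max(hi - lo, 1e-12) * (bins - 1)
        return np.clip(t, 0.0, bins - 1.0 - 1e-9)

    ta, tb = coords(a, a_range), coords(b, b_range)
    ia, ib = np.floor(ta).astype(int), np.floor(tb).astype(int)
    fa, fb = ta - ia, tb - ib
    h = np.zeros(bins * bins)
    for da, wa in ((0, 1.0 - fa), (1, fa)):
        for db, wb in ((0, 1.0 - fb), (1, fb)):
            h += np.bincount((ia + da) * bins + ib + db, weights=wa * wb,
                             minlength=bins * bins)
    return h.reshape(bins, bins)


def _nmi(a: np.ndarray, b: np.ndarray, bins=48,
         a_range=None, b_range=None) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B) of two samples."""
    a_range = a_range or (float(a.min()), float(a.max()))
    b_range = b_range or (float(b.min()), float(b.max()))
    h = _soft_hist2d(a, b, bins, a_range, b_range)
    p = h / max(h.sum(), 1.0)
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    hxy = ent(p.ravel())
    if hxy <= 0:
        return 2.0
    return (ent(px) + ent(py)) / hxy


def _decimate(img: VolumetricImage, stride: int) -> VolumetricImage:
    if stride <= 1:
        return img
    data = img.data[::stride, ::stride, ::stride]
    aff = img.affine.copy()
    aff[:3, :3] *= stride
    return VolumetricImage(data, aff, img.semantics)


@dataclass
class RigidRegParams:
    bins: int = 48
    n_samples: int = 30000       # fixed-image voxels entering the NMI histogram
    sample_seed: int = 0         # deterministic sampler
    max_rot_deg: float = 20.0
    max_trans_mm: float = 30.0
    coarse_maxfev: int = 400
    fine_maxfev: int = 500
    fg_threshold: float = 0.05   # sample fixed voxels above this fraction of max
    smooth_fwhm_mm: float = 4.0  # pre-smoothing of both images before NMI


def register_rigid(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    params: RigidRegParams | None = None,
) -> RigidTransform:
    """Rigid registration maximising normalised mutual information.

    Returns the transform T mapping fixed-space world points to moving-space
    world points, i.e. the transform to hand to
    :func:`amypipe.image_model.resample_into` to bring ``moving`` onto the
    grid of ``fixed``.  The NMI objective is evaluated on a deterministic
    random subsample of fixed-image voxels (the usual sampling strategy of
    registration toolkits); a two-stage Powell search (coarse bins, then
    full bins) over 3 Euler angles + 3 translations is used, with rotation
    about the fixed image's world centre.
    """
    params = params or RigidRegParams()
    if params.smooth_fwhm_mm > 0:
        # smoothing both channels equalises interpolation-induced noise
        # averaging, which otherwise biases the NMI optimum by ~1 degree
        fixed = VolumetricImage(
            ndimage.gaussian_filter(
                np.asarray(fixed.data, dtype=float),
                params.smooth_fwhm_mm / 2.3548 / fixed.spacing,
            ),
            fixed.affine, fixed.semantics,
        )
        moving = VolumetricImage(
            ndimage.gaussian_filter(
                np.asarray(moving.data, dtype=float),
                params.smooth_fwhm_mm / 2.3548 / moving.spacing,
            ),
            moving.affine, moving.semantics,
        )
    n = np.array(fixed.shape)
    center = fixed.affine[:3, :3] @ ((n - 1) / 2.0) + fixed.affine[:3, 3]

    def make_transform(theta):
        return RigidTransform.from_params(theta[:3], theta[3:], center=center)

    rng = np.random.default_rng(params.sample_seed)
    fflat = np.asarray(fixed.data, dtype=float).reshape(-1)
    cand = np.flatnonzero(fflat > params.fg_threshold * fflat.max())
    if cand.size < 1000:  # nearly flat image: fall back to uniform sampling
        cand = np.arange(fflat.size)
    nsamp = min(params.n_samples, cand.size)
    flat = rng.choice(cand, size=nsamp, replace=False)
    idx = np.stack(np.unravel_index(flat, fixed.shape)).astype(float)
    A = fixed.affine
    world = A[:3, :3] @ idx + A[:3, 3:4]
    fvals = np.asarray(fixed.data, dtype=float).reshape(-1)[flat]
    f_range = (float(fvals.min()), float(fvals.max()))
    m_range = (float(moving.data.min()), float(moving.data.max()))

    def neg_nmi(theta, bins):
        T = make_transform(theta)
        pts = T.rotation @ world + T.translation[:, None]
        Ainv = np.linalg.inv(moving.affine)
        mi = Ainv[:3, :3] @ pts + Ainv[:3, 3:4]
        ok = np.ones(nsamp, dtype=bool)
        for ax, nn in enumerate(moving.shape):
            ok &= (mi[ax] >= -0.5) & (mi[ax] <= nn - 0.5)
        if ok.sum() < 100:
            return 0.0
        samp = ndimage.map_coordinates(
            np.asarray(moving.data, dtype=float), mi[:, ok], order=1,
            mode="constant", cval=0.0,
        )
        return -_nmi(fvals[ok], samp, bins=bins, a_range=f_range,
                     b_range=m_range)

    theta = np.zeros(6)
    for xtol, maxfev in ((1e-3, params.coarse_maxfev),
                         (1e-5, params.fine_maxfev)):
        res = optimize.minimize(
            neg_nmi, theta, args=(params.bins,), method="Powell",
            options={"xtol": xtol, "ftol": 1e-10, "maxfev": maxfev},
        )
        if res.fun <= neg_nmi(theta, params.bins):  # never worse than the start
            theta = res.x
    if (
        np.any(np.abs(theta[:3]) > params.max_rot_deg)
        or np.any(np.abs(theta[3:]) > params.max_trans_mm)
    ):
        raise ConvergenceError(
            "rigid registration drifted outside the plausible range",
            best=make_transform(theta),
        )
    return make_transform(theta)


# ---------------------------------------------------------------------------
# Band-limited warp parameterisation (shared by MAP and USM)


@dataclass
class WarpParams:
    """Tuning knobs for non-rigid warp estimation.

    ``n_basis`` cosine modes per axis parameterise the displacement (the
    (0,0,0) mode is dropped -- it duplicates the affine translation);
    ``smoothness`` is the quadratic penalty weight on (frequency-weighted)
    coefficients; ``eval_stride`` decimates the estimation grid for speed.
    """

    n_basis: int = 5
    smoothness: float = 1e-5
    eval_stride: int | None = None   # None: decimate to a ~32 voxel grid
    affine_maxiter: int = 60
    joint_maxiter: int = 80
    usm_outer_iters: int = 5
    usm_warp_iters: int = 30
    usm_smoothness: float = 1e-5
    pyramid_fwhm_mm: tuple = (6.0, 0.0)

    def stride_for(self, shape) -> int:
        if self.eval_stride is not None:
            return self.eval_stride
        return max(1, int(np.ceil(max(shape) / 32)))
    jacobian_floor: float = 0.05
    max_regularisation_boosts: int = 3


class _BasisWarp:
    """Affine + separable-cosine displacement on a destination grid."""

    def __init__(self, dest: VolumetricImage, n_basis: int):
        self.dest = dest
        self.K = int(n_basis)
        shape = dest.shape
        self.world = dest.world_coords()
        lo = self.world.reshape(3, -1).min(axis=1)
        hi = self.world.reshape(3, -1).max(axis=1)
        self.center = (lo + hi) / 2.0
        span = np.maximum(hi - lo, 1e-6)
        # 1-D cosine design matrices on normalised coordinates in [0, 1]
        self.B = []
        for ax, n in enumerate(shape):
            u = (np.unique(self.world[ax].reshape(-1)) - lo[ax]) / span[ax]
            if u.size != n:  # oblique affine: fall back to index coordinate
                u = np.linspace(0.0, 1.0, n)
            self.B.append(np.cos(np.pi * np.outer(u, np.arange(self.K))))
        # frequency weights for the smoothness penalty, (0,0,0) mode excluded
        p, q, r = np.meshgrid(*(np.arange(self.K),) * 3, indexing="ij")
        self.freq_w = 1.0 + (p**2 + q**2 + r**2).astype(float)
        self.mode_mask = ~((p == 0) & (q == 0) & (r == 0))
        self.n_coef = 3 * self.K**3

    # parameter vector layout: [affine 9, translation 3, coefficients 3*K^3]
    def n_params(self):
        return 12 + self.n_coef

    def identity_params(self):
        theta = np.zeros(self.n_params())
        theta[:9] = np.eye(3).ravel()
        return theta

    def split(self, theta):
        A = theta[:9].reshape(3, 3)
        t = theta[9:12]
        c = theta[12:].reshape(3, self.K, self.K, self.K)
        return A, t, c

    def displacement_field(self, c):
        """Cosine displacement, shape (3, nx, ny, nz)."""
        Bx, By, Bz = self.B
        c = c * self.mode_mask  # (0,0,0) mode is not a degree of freedom
        d = np.einsum("ipqr,xp->ixqr", c, Bx)
        d = np.einsum("ixqr,yq->ixyr", d, By)
        d = np.einsum("ixyr,zr->ixyz", d, Bz)
        return d

    def mapped(self, theta):
        """Source world points for every destination voxel."""
        A, t, c = self.split(theta)
        xc = self.world - self.center[:, None, None, None]
        aff = np.einsum("ij,j...->i...", A, xc) + (self.center + t)[
            :, None, None, None
        ]
        return aff + self.displacement_field(c)

    def grad_contract(self, W):
        """d(sum W_i * d_i)/d(theta) for per-voxel weights W (3, nx, ny, nz)."""
        Bx, By, Bz = self.B
        xc = self.world - self.center[:, None, None, None]
        g_aff = np.einsum("ixyz,jxyz->ij", W, xc).reshape(-1)
        g_t = W.reshape(3, -1).sum(axis=1)
        g_c = np.einsum("ixyz,xp->ipyz", W, Bx)
        g_c = np.einsum("ipyz,yq->ipqz", g_c, By)
        g_c = np.einsum("ipqz,zr->ipqr", g_c, Bz)
        g_c = g_c * self.mode_mask
        return np.concatenate([g_aff, g_t, g_c.reshape(-1)])

    def penalty(self, theta, lam):
        _, _, c = self.split(theta)
        w = self.freq_w * self.mode_mask
        val = lam * np.sum(w * c**2)
        grad = np.zeros_like(theta)
        grad[12:] = (2.0 * lam * w * c).reshape(-1)
        return val, grad

    def to_field(self, theta, dest_full: VolumetricImage, direction, provenance):
        """Evaluate the fitted mapping on a (possibly finer) grid."""
        warp_full = _BasisWarp(dest_full, self.K)
        pts = warp_full.mapped(theta)
        disp = pts - warp_full.world
        return DeformationField(disp, dest_full.affine.copy(), direction, provenance)


def _image_gradient(img: VolumetricImage):
    """World-space gradient volumes (list of 3 VolumetricImage)."""
    sp = img.spacing
    grads = np.gradient(np.asarray(img.data, dtype=float), *sp)
    return [VolumetricImage(g, img.affine, img.semantics) for g in grads]


def _min_jacobian_on(theta, warp: _BasisWarp) -> float:
    pts = warp.mapped(theta)
    disp = pts - warp.world
    f = DeformationField(disp, warp.dest.affine.copy(), NATIVE_TO_STANDARD)
    return float(jacobian_determinant(f).data.min())


def _smoothed(img: VolumetricImage, fwhm_mm: float) -> VolumetricImage:
    if fwhm_mm <= 0:
        return img
    sig = fwhm_mm / 2.3548 / img.spacing
    return VolumetricImage(
        ndimage.gaussian_filter(np.asarray(img.data, dtype=float), sig),
        img.affine, img.semantics,
    )


def _fit_ssd_warp(
    moving: VolumetricImage,
    target: VolumetricImage,
    params: WarpParams,
) -> np.ndarray:
    """Fit theta minimising ||moving(T(x)) - target(x)||^2 + penalty.

    Coarse-to-fine: the fit starts on heavily smoothed copies of both
    images (wide capture range) and is then refined on the originals.
    """
    dest = _decimate(target, params.stride_for(target.shape))
    warp = _BasisWarp(dest, params.n_basis)
    norm = max(float(np.ptp(np.asarray(dest.data))), 1e-9)
    theta = warp.identity_params()

    for level, fwhm in enumerate(params.pyramid_fwhm_mm):
        tgt = np.asarray(_smoothed(dest, fwhm).data, dtype=float) / norm
        mov = VolumetricImage(
            np.asarray(_smoothed(moving, fwhm).data, dtype=float) / norm,
            moving.affine,
        )
        grads = _image_gradient(mov)
        nvox = tgt.size
        lam = params.smoothness

        def objective(theta, lam, freeze_nonlinear):
            pts = warp.mapped(theta)
            samp = _sample_at_world(mov, pts, order=1)
            ok = _inside_mask(mov, pts)
            r = np.where(ok, samp - tgt, 0.0)
            val = float(np.sum(r**2)) / nvox
            g = np.stack([
                np.where(ok, _sample_at_world(gi, pts, order=1), 0.0)
                for gi in grads
            ])
            W = (2.0 / nvox) * r[None] * g
            grad = warp.grad_contract(W)
            pv, pg = warp.penalty(theta, lam)
            val += pv
            grad = grad + pg
            if freeze_nonlinear:
                grad[12:] = 0.0
            return val, grad

        if level == 0:
            res = optimize.minimize(
                objective, theta, args=(lam, True), jac=True,
                method="L-BFGS-B", options={"maxiter": params.affine_maxiter},
            )
            theta = res.x
        cand = None
        for boost in range(params.max_regularisation_boosts + 1):
            res = optimize.minimize(
                objective, theta, args=(lam, False), jac=True,
                method="L-BFGS-B", options={"maxiter": params.joint_maxiter},
            )
            cand = res.x
            if _min_jacobian_on(cand, warp) > params.jacobian_floor:
                break
            lam *= 10.0  # stiffen and re-fit from the affine-only start
            theta = res.x.copy()
            theta[12:] = 0.0
            cand = None
        if cand is None:
            raise EstimationError(
                "warp estimate remained non-invertible after "
                "regularisation boosts"
            )
        theta = cand
    return theta


def estimate_map_warp(
    subject_mri: VolumetricImage,
    template_t1: VolumetricImage,
    params: WarpParams | None = None,
) -> DeformationField:
    """Estimate the intensity-driven (MAP-style) native->standard warp.

    The returned field lives on the template grid and pulls subject values
    into standard space.  The same field serves amount-preserving and
    concentration-preserving application; only :func:`apply_warp`'s
    modulation mode differs.
    """
    params = params or WarpParams()
    theta = _fit_ssd_warp(subject_mri, template_t1, params)
    coarse = _BasisWarp(_decimate(template_t1, params.stride_for(template_t1.shape)), params.n_basis)
    return coarse.to_field(theta, template_t1, NATIVE_TO_STANDARD, "MAP")


# ---------------------------------------------------------------------------
# Unified segmentation (USM)


def estimate_usm_warp(
    subject_mri: VolumetricImage,
    template_tpms: dict,
    params: WarpParams | None = None,
    bias_correction: bool = True,
):
    """Tissue-prior-regularised normalization (unified segmentation).

    Alternates (a) Gaussian-mixture tissue classification of the MRI under
    spatial priors obtained by warping the template tissue probability maps
    into native space with the current warp, and (b) a warp update that
    improves the agreement between class posteriors and warped priors
    (cross-entropy objective on the same affine+cosine parameterisation).
    A warp update is only accepted if the mixture negative log-likelihood
    does not increase, so the reported objective is monotone.

    Parameters
    ----------
    subject_mri : VolumetricImage
    template_tpms : dict
        ``{"GM": tpm, "WM": tpm, "CSF": tpm}`` in standard space.
    params : WarpParams

    Returns
    -------
    field : DeformationField
        ``standard_to_native`` field (on the subject grid) with provenance
        ``"USM"``; concentration-preserving semantics at apply time.
    posteriors : dict
        Native-space tissue posteriors ``{"GM", "WM", "CSF"}`` as
        VolumetricImage, plus ``"objective_trace"`` under key ``"_nll"``.
    """
    params = params or WarpParams()
    order = ("GM", "WM", "CSF")
    stride = params.stride_for(subject_mri.shape)
    tpms = [template_tpms[k] for k in order]
    dest = _decimate(subject_mri, stride)
    warp = _BasisWarp(dest, params.n_basis)
    tpm_grads = {k: _image_gradient(t) for k, t in zip(order, tpms)}

    theta = warp.identity_params()
    mri_small = np.asarray(dest.data, dtype=float)

    def warped_priors(th, grid_warp):
        pts = grid_warp.mapped(th)
        pri = [np.clip(_sample_at_world(t, pts, order=1), 0.0, 1.0) for t in tpms]
        s = np.stack(pri).sum(axis=0)
        np.clip(s, None, 1.0, out=s)
        bg = np.clip(1.0 - s, 1e-4, 1.0)
        return pri, bg, pts

    nll_trace = []
    state = None
    for it in range(params.usm_outer_iters):
        pri, bg, _ = warped_priors(theta, warp)
        cand = fit_gmm_with_priors(
            mri_small, pri, bg, state=state, bias_correction=bias_correction,
            n_em=4,
        )
        # keep-best: the robust M-step is not a strict EM ascent, so a
        # refit under unchanged priors may wobble; retain the better state
        if state is None or cand.nll <= state.nll:
            state = cand
        nll_trace.append(state.nll)

        # ---- warp update: cross-entropy between posteriors and priors
        post = state.posteriors  # list of 4 arrays (GM, WM, CSF, BG)

        def q_obj(th):
            pri_k, bg_k, pts = warped_priors(th, warp)
            pri_k = [np.clip(p, 1e-4, 1.0) for p in pri_k]
            val = 0.0
            W = np.zeros((3,) + mri_small.shape)
            for k in range(3):
                val -= float(np.sum(post[k] * np.log(pri_k[k])))
                gk = np.stack([
                    _sample_at_world(g, pts, order=1)
                    for g in tpm_grads[order[k]]
                ])
                W -= (post[k] / pri_k[k])[None] * gk
            val -= float(np.sum(post[3] * np.log(bg_k)))
            # background gradient: d(1 - sum pri)/d pts = -sum grad tpm
            gsum = np.zeros((3,) + mri_small.shape)
            for k in range(3):
                gsum += np.stack([
                    _sample_at_world(g, pts, order=1)
                    for g in tpm_grads[order[k]]
                ])
            W += (post[3] / bg_k)[None] * gsum
            nvox = mri_small.size
            val /= nvox
            grad = warp.grad_contract(W / nvox)
            pv, pg = warp.penalty(th, params.usm_smoothness)
            return val + pv, grad + pg

        res = optimize.minimize(
            q_obj, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": params.usm_warp_iters},
        )
        cand = res.x
        if _min_jacobian_on(cand, warp) <= params.jacobian_floor:
            continue  # keep previous warp; stiffness left to MAP-style boosts
        pri, bg, _ = warped_priors(cand, warp)
        cand_state = fit_gmm_with_priors(
            mri_small, pri, bg, state=state, bias_correction=bias_correction,
            n_em=1,
        )
        if cand_state.nll <= nll_trace[-1] + 1e-9:
            theta = cand
            state = cand_state

    # final posteriors on the full-resolution subject grid
    full_warp = _BasisWarp(subject_mri, params.n_basis)
    pri_full, bg_full, _ = warped_priors(theta, full_warp)
    final = fit_gmm_with_priors(
        np.asarray(subject_mri.data, dtype=float), pri_full, bg_full,
        state=state, bias_correction=bias_correction, n_em=2,
    )
    posteriors = {
        k: VolumetricImage(final.posteriors[i], subject_mri.affine.copy())
        for i, k in enumerate(order)
    }
    posteriors["_nll"] = nll_trace  # per-voxel NLL on the estimation grid
    field = full_warp.to_field(theta, subject_mri, STANDARD_TO_NATIVE, "USM")
    return field, posteriors


# ---------------------------------------------------------------------------
# Field application, inversion, Jacobian


def apply_warp(
    img: VolumetricImage,
    field: DeformationField,
    modulation: str = CONCENTRATION_PRESERVING,
    interpolation: str = "linear",
    direction: str | None = None,
    fill: float = 0.0,
) -> VolumetricImage:
    """Resample ``img`` through a deformation field.

    ``modulation="amount_preserving"`` multiplies the resampled values by
    the local Jacobian determinant of the mapping, conserving the global
    image integral; ``"concentration_preserving"`` leaves values unchanged.
    ``direction``, when given, asserts the field's direction tag.
    """
    if modulation not in (AMOUNT_PRESERVING, CONCENTRATION_PRESERVING):
        raise ParameterError(f"unknown modulation {modulation!r}")
    if direction is not None and direction != field.direction:
        raise UsageError(
            f"field direction is {field.direction}, expected {direction}"
        )
    order = {"nearest": 0, "linear": 1}[interpolation]
    pts = field.mapped_points()
    out = _sample_at_world(img, pts, order=order, cval=fill)
    semantics = img.semantics
    if modulation == AMOUNT_PRESERVING:
        out = out * jacobian_determinant(field).data
        semantics = AMOUNT
    return VolumetricImage(out, field.affine.copy(), semantics)


def warp_validity_mask(img: VolumetricImage, field: DeformationField) -> np.ndarray:
    """Destination voxels whose pull-back point lies inside ``img``'s FOV."""
    return _inside_mask(img, field.mapped_points())


def jacobian_determinant(field: DeformationField) -> VolumetricImage:
    """Central-difference Jacobian determinant of the mapping x -> x + d(x).

    Values > 1 mean the destination voxel draws from an expanded source
    neighbourhood (local volume expansion of the pull-back map).
    """
    d = field.displacement
    A3 = field.affine[:3, :3]
    # dd[i, k] = d d_i / d index_k; convert to world derivatives via inv(A3)
    dd = np.stack([np.stack(np.gradient(d[i]), axis=0) for i in range(3)])
    Ainv = np.linalg.inv(A3)
    # J_world[i, j] = delta_ij + sum_k dd[i, k] * Ainv[k, j]
    Jw = np.einsum("ik...,kj->ij...", dd, Ainv)
    for i in range(3):
        Jw[i, i] += 1.0
    a, b, c = Jw[0], Jw[1], Jw[2]
    det = (
        a[0] * (b[1] * c[2] - b[2] * c[1])
        - a[1] * (b[0] * c[2] - b[2] * c[0])
        + a[2] * (b[0] * c[1] - b[1] * c[0])
    )
    return VolumetricImage(det, field.affine.copy())


def invert_warp(
    field: DeformationField,
    reference: VolumetricImage | None = None,
    n_iter: int = 30,
    tol_voxels: float = 0.45,
) -> DeformationField:
    """Fixed-point inverse of a deformation field.

    Solves d_inv(y) = -d(y + d_inv(y)) on the grid of ``reference`` (default:
    the field's own grid).  Raises :class:`ConvergenceError` when the
    composed round-trip still displaces points by more than ``tol_voxels``
    voxels.
    """
    if reference is None:
        reference = VolumetricImage(
            np.zeros(field.shape), field.affine.copy()
        )
    idx = np.indices(reference.shape, dtype=float)
    A = reference.affine
    world = np.einsum("ij,j...->i...", A[:3, :3], idx) + A[:3, 3, None, None, None]

    disp_imgs = [
        VolumetricImage(field.displacement[i], field.affine) for i in range(3)
    ]

    def sample_disp(pts):
        # nearest-mode extrapolation keeps the fixed point consistent for
        # probe points whose pull-back leaves the stored grid slightly
        return np.stack([
            _sample_at_world(di, pts, order=1, mode="nearest")
            for di in disp_imgs
        ])

    dinv = np.zeros_like(world)
    for _ in range(n_iter):
        dinv_new = -sample_disp(world + dinv)
        step = np.max(np.abs(dinv_new - dinv))
        dinv = dinv_new
        if step < 1e-3:
            break
    residual = dinv + sample_disp(world + dinv)
    res_vox = np.abs(residual) / reference.spacing[:, None, None, None]
    # judge convergence where the round trip stays inside the field's FOV
    # (outside it the inverse is not determined by the stored field)
    inside = _inside_mask(
        VolumetricImage(np.zeros(field.shape), field.affine), world + dinv
    )
    worst = float(res_vox.max(axis=0)[inside].max()) if inside.any() else 0.0
    if worst > tol_voxels:
        raise ConvergenceError(
            f"warp inversion residual {worst:.2f} voxels exceeds tolerance"
        )
    direction = (
        STANDARD_TO_NATIVE
        if field.direction == NATIVE_TO_STANDARD
        else NATIVE_TO_STANDARD
    )
    return DeformationField(dinv, reference.affine.copy(), direction,
                            field.provenance)
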