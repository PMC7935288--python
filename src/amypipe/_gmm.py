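"""Prior-informed Gaussian mixture for tissue classification.

Four classes: GM, WM, CSF and background.  Spatial priors (warped tissue
probability maps) weight the responsibilities; an optional multiplicative
low-order polynomial bias field is estimated jointly.  Shared by the
segmentation module (native-space tissue segmentation) and the unified
segmentation warp estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError

_EPS = 1e-12


@dataclass
class GMMState:
    means: np.ndarray            # (4,) GM, WM, CSF, BG
    sds: np.ndarray              # (4,)
    bias_coefs: np.ndarray | None
    posteriors: list = field(default_factory=list)  # 4 arrays, GM WM CSF BG
    nll: float = np.inf
    anchors: np.ndarray | None = None  # initial means; EM stays near them


def _kmeans3(fg: np.ndarray):
    """Deterministic 1-D 3-means on foreground intensities (air excluded)."""
    sub = fg[fg > 0.2 * np.percentile(fg, 92)]
    if sub.size < 30:
        sub = fg
    cent = np.percentile(sub, [25, 60, 90]).astype(float)
    for _ in range(12):
        lab = np.argmin(np.abs(sub[:, None] - cent[None, :]), axis=1)
        for j in range(3):
            sel = lab == j
            if sel.any():
                cent[j] = float(np.median(sub[sel]))
    return np.sort(cent)


def _histogram_mode(vals: np.ndarray, bins: int = 48) -> float:
    """Peak of a lightly smoothed histogram (pure-tissue plateau)."""
    lo, hi = np.percentile(vals, [2, 98])
    if hi - lo < 1e-6:
        return float(np.median(vals))
    h, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    hs = np.convolve(h, kernel / kernel.sum(), mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[int(np.argmax(hs))])


def _poly_basis(shape):
    """Degree-2 polynomial basis (9 non-constant terms) on [-1, 1]^3."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    terms = [u, v, w, u * v, u * w, v * w, u * u, v * v, w * w]
    return np.stack([t.ravel() for t in terms], axis=1)


def _bias_field(shape, coefs):
    if coefs is None:
        return np.ones(shape)
    b = np.exp(_poly_basis(shape) @ coefs).reshape(shape)
    return b / b.mean()


def fit_gmm_with_priors(
    intensity: np.ndarray,
    fg_priors: list,
    bg_prior: np.ndarray,
    state: GMMState | None = None,
    bias_correction: bool = True,
    n_em: int = 4,
    order_by_intensity: bool = False,
    init_quantiles: bool = False,
) -> GMMState:
    """Run ``n_em`` EM sweeps of the 4-class mixture.

    ``fg_priors`` is [GM, WM, CSF] spatial priors; ``bg_prior`` the
    background prior.  When ``state`` is given, means/SDs/bias are warm
    started from it (used across alternating warp updates).  A bias update
    is kept only if it does not increase the negative log-likelihood, so
    repeated calls yield a monotone objective for fixed priors.
    """
    I = np.asarray(intensity, dtype=float)
    shape = I.shape
    priors = [np.clip(np.asarray(p, dtype=float), _EPS, 1.0) for p in fg_priors]
    priors.append(np.clip(np.asarray(bg_prior, dtype=float), _EPS, 1.0))

    informative = (
        all(np.ptp(p) > 1e-3 for p in fg_priors) and not init_quantiles
    )
    if state is None:
        if np.ptp(priors[3]) > 1e-3:
            fg = I[priors[3] < 0.5]
        else:  # flat priors: background is the near-zero intensity mass
            fg = I[I > 0.05 * np.percentile(I, 99.9)]
        if fg.size < 10:
            raise EstimationError("too few foreground voxels to initialise")
        if informative:
            # spatial priors available: prior-weighted intensity means
            means_fg = [
                float(np.sum(p * I) / max(np.sum(p), _EPS)) for p in fg_priors
            ]
            means = np.array(means_fg + [float(np.percentile(I, 5))])
        else:
            # flat priors inside a head mask: 1-D k-means on clearly
            # foreground intensities gives CSF < GM < WM anchors for T1
            m_csf, m_gm, m_wm = _kmeans3(fg)
            if not (m_csf < m_gm < m_wm):
                raise EstimationError(
                    "fewer than 3 distinguishable intensity modes in the MRI"
                )
            means = np.array([m_gm, m_wm, m_csf, float(np.percentile(I, 5))])
        spread = max(np.ptp(fg) / 8.0, 1e-3)
        sds = np.array([spread, spread, spread, max(spread, 1.0)])
        coefs = None
        anchors = means.copy()
    else:
        means = state.means.copy()
        sds = state.sds.copy()
        coefs = None if state.bias_coefs is None else state.bias_coefs.copy()
        anchors = state.anchors.copy() if state.anchors is not None \
            else means.copy()

    basis = _poly_basis(shape) if bias_correction else None

    # each class likelihood carries a small uniform floor over the intensity
    # range: partial-volume voxels whose intensity matches no class model
    # are then arbitrated by the spatial priors instead of by razor-thin
    # Gaussian tails (which would let a distant class capture them)
    pv_eps = 1e-2
    i_range = float(np.ptp(I)) + 1.0

    def e_step(means, sds, bias):
        Ic = I / bias
        dens = []
        for k in range(4):
            z = np.clip((Ic - means[k]) / sds[k], -35.0, 35.0)
            phi = np.exp(-0.5 * z**2) / (sds[k] * np.sqrt(2.0 * np.pi))
            dens.append((1.0 - pv_eps) * phi + pv_eps / i_range)
        w = np.stack([priors[k] * dens[k] for k in range(4)])
        tot = w.sum(axis=0)
        nll = -float(np.mean(np.log(tot)))  # per voxel, grid-size free
        return [w[k] / tot for k in range(4)], nll

    def m_step(post, bias):
        Ic = I / bias
        new_means, new_sds = means.copy(), sds.copy()
        rng_ = np.ptp(I) + 1.0
        for k in range(4):
            # robust update: the class mean is the histogram mode of the
            # assigned voxels (the pure-tissue plateau), so one-sided
            # partial-volume tails neither drag the means nor inflate a
            # class into a garbage collector; spread via MAD about the mode
            sel = post[k] > 0.5
            if sel.sum() < 50:
                wk = post[k].sum()
                if wk < 1e-6 * I.size:
                    continue  # keep previous parameters for a starved class
                mu = float(np.sum(post[k] * Ic) / wk)
                sd = float(np.sqrt(np.sum(post[k] * (Ic - mu) ** 2) / wk))
            else:
                vals = Ic[sel]
                mu = _histogram_mode(vals)
                sd = 1.4826 * float(np.median(np.abs(vals - mu)))
            # stay near the initial anchors: partial-volume skirts can
            # otherwise walk a class mean onto a neighbouring plateau
            # (residual intensity scale drift belongs to the bias field)
            new_means[k] = float(
                np.clip(mu, anchors[k] - 8e-2 * rng_, anchors[k] + 8e-2 * rng_)
            )
            # tissue SDs floored at 4% of the intensity range so noise-free
            # images keep usable tails across partial-volume bands, and
            # capped at 8% so no class inflates into a garbage collector;
            # the background class (air) may stay tight
            floor = (1e-2 if k == 3 else 4e-2) * rng_
            new_sds[k] = float(np.clip(sd, floor, 8e-2 * rng_))
        # pool the tissue SDs: image noise is class-independent, and equal
        # SDs place the class crossings at the intensity midpoints (partial
        # volume skirts otherwise skew each class's apparent spread)
        new_sds[:3] = float(np.median(new_sds[:3]))
        return new_means, new_sds

    bias = _bias_field(shape, coefs)
    post, nll = e_step(means, sds, bias)
    for _ in range(n_em):
        means, sds = m_step(post, bias)
        if bias_correction:
            new_coefs = _fit_bias(I, post, means, basis, shape)
            new_bias = _bias_field(shape, new_coefs)
            _, nll_new = e_step(means, sds, new_bias)
            _, nll_old = e_step(means, sds, bias)
            if nll_new <= nll_old:
                coefs, bias = new_coefs, new_bias
        post, nll = e_step(means, sds, bias)

    if order_by_intensity:
        # map the three foreground components to CSF < GM < WM by mean
        fg_idx = np.argsort(means[:3])  # ascending: CSF, GM, WM
        perm = [fg_idx[1], fg_idx[2], fg_idx[0], 3]
        means = means[perm]
        sds = sds[perm]
        anchors = anchors[perm]
        post = [post[i] for i in perm]

    return GMMState(means, sds, coefs, post, nll, anchors)


def _fit_bias(I, post, means, basis, shape):
    """Weighted least-squares fit of a multiplicative log-bias field."""
    fg_post = post[0] + post[1] + post[2]
    pred = (
        post[0] * means[0] + post[1] * means[1] + post[2] * means[2]
    ) / np.maximum(fg_post, _EPS)
    sel = (fg_post > 0.5) & (I > _EPS) & (pred > _EPS)
    if sel.sum() < basis.shape[1] * 10:
        return None
    resid = np.log(I[sel]) - np.log(pred[sel])
    X = basis[sel.ravel()]
    w = fg_post[sel]
    Xw = X * w[:, None]
    coefs, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ resid, rcond=None)
    return coefs
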