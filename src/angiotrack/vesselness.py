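"""Multiscale Hessian vessel enhancement.

For each analysis scale ``sigma_f`` the image is convolved with
scale-normalized second-derivative-of-Gaussian kernels; the eigenvalues of
the resulting Hessian characterize local tubularity.  A bright vessel on a
dark background produces a large negative principal eigenvalue ``lambda1``
across the vessel and a near-zero ``lambda2`` along it.  Per scale, pixels
whose ``lambda1`` falls below a (negative) gate ``r_lambda`` receive the
log response ``ln|lambda1| + c``; the per-pixel maximum over all scales,
min-max normalized to [0, 1], is the vessel feature map Z.  The vessel
direction is the eigenvector orthogonal to that of the dominant eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .config import RunConfig


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Normalized vesselness with per-pixel scale-space bookkeeping."""

    zhat: np.ndarray        # normalized vesselness in [0, 1]
    best_scale: np.ndarray  # argmax scale of the log response (px)
    lam1: np.ndarray        # principal eigenvalue at the dominant-|lam1| scale
    lam2: np.ndarray
    evec1: np.ndarray       # (H, W, 2) unit eigenvector of lam1, (x, y) order
    raw_max: float          # pre-normalization response maximum

    @property
    def shape(self):
        return self.zhat.shape


@dataclass
class DirectionMap:
    """Per-pixel unit vessel direction (orientation; sign is ambiguous)."""

    v2: np.ndarray     # (H, W, 2) unit vectors (x, y); zero where invalid
    valid: np.ndarray  # bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def hessian_eigen(image: np.ndarray, sigma: float):
    """Eigen-decomposition of the scale-normalized Hessian at one scale.

    Returns ``(lam1, lam2, ev1, ev2)`` with ``|lam1| >= |lam2|`` per pixel
    and unit-norm eigenvector fields of shape (H, W, 2) in (x, y) order.
    Bright ridges give ``lam1 < 0``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    s2 = sigma * sigma
    # ndimage derivative order is (row, col) == (y, x); reflective padding
    Hxx = s2 * ndimage.gaussian_filter(image, sigma, order=(0, 2), mode="reflect")
    Hyy = s2 * ndimage.gaussian_filter(image, sigma, order=(2, 0), mode="reflect")
    Hxy = s2 * ndimage.gaussian_filter(image, sigma, order=(1, 1), mode="reflect")

    mean = 0.5 * (Hxx + Hyy)
    root = np.sqrt(0.25 * (Hxx - Hyy) ** 2 + Hxy**2)
    ea, eb = mean + root, mean - root          # ea >= eb algebraically
    take_a = np.abs(ea) >= np.abs(eb)
    lam1 = np.where(take_a, ea, eb)
    lam2 = np.where(take_a, eb, ea)

    def _evec(lam):
        # (H - lam I) v = 0  ->  v ~ (Hxy, lam - Hxx) or (lam - Hyy, Hxy)
        vx1, vy1 = Hxy, lam - Hxx
        vx2, vy2 = lam - Hyy, Hxy
        n1 = np.hypot(vx1, vy1)
        n2 = np.hypot(vx2, vy2)
        use1 = n1 >= n2
        vx = np.where(use1, vx1, vx2)
        vy = np.where(use1, vy1, vy2)
        n = np.hypot(vx, vy)
        deg = n < 1e-12
        n = np.where(deg, 1.0, n)
        v = np.stack([vx / n, vy / n], axis=-1)
        # degenerate (isotropic) pixels: arbitrary but fixed axis
        v[deg] = (1.0, 0.0)
        return v

    ev1 = _evec(lam1)
    ev2 = np.stack([-ev1[..., 1], ev1[..., 0]], axis=-1)
    return lam1, lam2, ev1, ev2


def scale_response(lam1: np.ndarray, sigma: float, cfg: RunConfig) -> np.ndarray:
    """Thresholded log response at one scale: ``ln|lam1| + c`` where
    ``lam1 < r_lambda``, else 0; clamped at 0 from below.

    With ``c = -ln|r_lambda|`` the response is exactly 0 at the gate and
    grows with ridge strength beyond it.
    """
    r_lam = -cfg.rlambda_coeff / sigma
    if r_lam >= 0:
        raise ValueError("r_lambda must be negative")
    c = -np.log(abs(r_lam))
    with np.errstate(divide="ignore"):
        z = np.log(np.abs(lam1)) + c
    z = np.where(lam1 < r_lam, z, 0.0)
    return np.maximum(z, 0.0)


def multiscale_feature_map(image: np.ndarray, cfg: RunConfig | None = None) -> FeatureMap:
    """Maximum log response over all scales, min-max normalized to [0, 1].

    The best scale is recorded at the response argmax; eigen data (used for
    the direction map) is recorded at the scale maximizing ``|lam1|``.
    """
    cfg = cfg or RunConfig()
    image = np.asarray(image, dtype=np.float64)
    zmax = None
    for sigma in cfg.scales:
        lam1, lam2, ev1, _ = hessian_eigen(image, sigma)
        z = scale_response(lam1, sigma, cfg)
        if zmax is None:
            zmax = z.copy()
            best_scale = np.full(image.shape, sigma)
            abs1 = np.abs(lam1)
            lam1_o, lam2_o, ev1_o = lam1.copy(), lam2.copy(), ev1.copy()
        else:
            upd = z > zmax
            zmax[upd] = z[upd]
            best_scale[upd] = sigma
            a = np.abs(lam1)
            dom = a > abs1
            abs1[dom] = a[dom]
            lam1_o[dom] = lam1[dom]
            lam2_o[dom] = lam2[dom]
            ev1_o[dom] = ev1[dom]
    raw_max = float(zmax.max())
    zmin = float(zmax.min())
    if raw_max > zmin:
        zhat = (zmax - zmin) / (raw_max - zmin)
    else:
        zhat = np.zeros_like(zmax)
    return FeatureMap(zhat=zhat, best_scale=best_scale, lam1=lam1_o,
                      lam2=lam2_o, evec1=ev1_o, raw_max=raw_max)


def direction_map(fmap: FeatureMap, cfg: RunConfig | None = None) -> DirectionMap:
    """Vessel direction: unit vector orthogonal to the dominant eigenvector.

    Pixels with no vessel response, or with near-isotropic eigenvalues
    (``|lam2|/|lam1|`` above ``degenerate_ratio``), are flagged invalid; the
    tracker falls back to its previous direction there.
    """
    cfg = cfg or RunConfig()
    v2 = np.stack([-fmap.evec1[..., 1], fmap.evec1[..., 0]], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(fmap.lam2) / np.maximum(np.abs(fmap.lam1), 1e-12)
    valid = (fmap.zhat > 0) & (ratio < cfg.degenerate_ratio)
    v2 = np.where(valid[..., None], v2, 0.0)
    return DirectionMap(v2=v2, valid=valid)


def binarize_and_thin(fmap: FeatureMap, cfg: RunConfig | None = None):
    """Binary vessel mask (``Z > threshold``) and its 1-px skeleton."""
    cfg = cfg or RunConfig()
    mask = fmap.zhat > cfg.binarize_threshold
    if not mask.any():
        warnings.warn("empty vessel mask; skeleton is empty")
        return mask, np.zeros_like(mask)
    skel = skeletonize(mask)
    return mask, skel


def detect_seed(fmap: FeatureMap, skeleton: np.ndarray) -> tuple[float, float]:
    """Automatic seed: the skeleton pixel of maximal vesselness.

    Ties resolve to the first maximum in row-major order.  Returns ``(x, y)``.
    """
    if not skeleton.any():
        raise ValueError("cannot seed: skeleton is empty")
    scores = np.where(skeleton, fmap.zhat, -1.0)
    flat = int(np.argmax(scores))
    y, x = np.unravel_index(flat, scores.shape)
    return float(x), float(y)


def preprocess(image: np.ndarray, cfg: RunConfig | None = None):
    """Full preprocessing: feature map, direction map, mask, skeleton, seed."""
    cfg = cfg or RunConfig()
    fmap = multiscale_feature_map(image, cfg)
    dmap = direction_map(fmap, cfg)
    mask, skel = binarize_and_thin(fmap, cfg)
    seed = detect_seed(fmap, skel) if skel.any() else None
    return fmap, dmap, mask, skel, seed
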