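"""Probabilistic tracking operator (PTO).

From the current artery element, candidate next elements are collected from
the overlap of a sampling disk with the binarized vessel map.  Three
continuity measures — vessel feature, longitudinal direction and diameter —
are normalized per step, turned into Gaussian likelihoods whose standard
deviations adapt to the spread of the current candidate set, and the next
element is the maximum-a-posteriori candidate (the product of the three
likelihoods under a uniform prior).

The adaptive variances are what let the operator walk across contrast gaps
narrower than the disk and through stenoses/aneurysms: when all candidates
are poor the spread widens and the relative ranking still picks the most
continuous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig


@dataclass
class ArteryElement:
    """One tracked point: position, vesselness, direction, diameter."""

    position: np.ndarray          # (2,) float (x, y)
    zhat: float
    direction: np.ndarray         # (2,) unit vector; orientation (sign free)
    diameter: float

    @property
    def angle(self) -> float:
        return math.atan2(self.direction[1], self.direction[0])


@dataclass
class SamplingDisk:
    """Candidate search geometry around the current element."""

    center: np.ndarray
    radius: float        # r_S, defaults to the current diameter
    look_ahead: float    # s_t, clipped to [1, min(d/2, 7)]


def sampling_disk(element: ArteryElement, cfg: RunConfig | None = None) -> SamplingDisk:
    cfg = cfg or RunConfig()
    d = float(np.clip(element.diameter, cfg.d_min, cfg.d_max))
    # integer look-ahead so the exact on-axis pixel is never cut out of the
    # annulus by a fractional radius falling between it and its diagonals
    s_t = float(np.clip(round(d / 2.0), cfg.step_min, cfg.step_max))
    r_s = max(d, s_t + 1.0)
    return SamplingDisk(center=np.asarray(element.position, float), radius=r_s, look_ahead=s_t)


@dataclass
class CandidateSet:
    """Candidates with their per-step normalized measures and likelihood data."""

    positions: np.ndarray    # (N, 2)
    zhats: np.ndarray        # (N,)
    directions: np.ndarray   # (N, 2)
    diameters: np.ndarray    # (N,)
    q_z: np.ndarray          # measures Q in [0, 1]
    q_theta: np.ndarray
    q_d: np.ndarray
    zhat_max: float
    d_max: float
    sigmas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    expanded: bool = False   # gap-recovery expansion was needed

    def __len__(self) -> int:
        return len(self.positions)


class NoContinuation(Exception):
    """No candidate found: the disk (after gap-recovery expansion) holds no
    vessel pixels ahead."""


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def deflection_measure(theta: np.ndarray | float) -> np.ndarray | float:
    """Q_theta: normalized angular deflection, invariant to direction
    reversal (0 at deflection 0 *and* pi, maximal 1/2 at pi/2)."""
    t = np.mod(theta, np.pi)
    return np.minimum(t, np.pi - t) / np.pi


def continuity_measures(element: ArteryElement, positions, zhats, diameters,
                        zhat_max: float, d_max: float):
    """Per-candidate (Q_Z, Q_theta, Q_d) given the per-step normalizers."""
    v = np.asarray(positions, float) - np.asarray(element.position, float)[None, :]
    ang = np.arctan2(v[:, 1], v[:, 0])
    theta = ang - element.angle
    q_theta = deflection_measure(theta)
    q_z = np.abs(1.0 - np.asarray(zhats, float) / max(zhat_max, 1e-12))
    q_d = np.abs(np.asarray(diameters, float) - element.diameter) / max(d_max, 1e-12)
    return q_z, q_theta, q_d


def adaptive_sigmas(cand: CandidateSet, cfg: RunConfig | None = None):
    """Population std of each measure over the candidate set, floored so the
    Gaussian likelihoods stay finite for homogeneous candidates."""
    cfg = cfg or RunConfig()
    eps = cfg.sigma_floor
    out = []
    for q in (cand.q_z, cand.q_theta, cand.q_d):
        out.append(max(float(np.std(q)), eps))
    return tuple(out)


def likelihoods(cand: CandidateSet):
    """The three Gaussian likelihood vectors q_Z, q_theta, q_d (Eq.-style:
    1/(sqrt(2 pi) sigma) exp(-Q^2 / 2 sigma^2))."""
    sz, st, sd = cand.sigmas
    def g(q, s):
        return np.exp(-q**2 / (2 * s * s)) / (math.sqrt(2 * math.pi) * s)
    return g(cand.q_z, sz), g(cand.q_theta, st), g(cand.q_d, sd)


# ---------------------------------------------------------------------------
# candidate collection and MAP selection
# ---------------------------------------------------------------------------

def _disk_pixels(center, r_out, shape):
    """Integer pixels within r_out of center, inside the image."""
    H, W = shape
    cx, cy = center
    x0, x1 = int(max(0, math.floor(cx - r_out))), int(min(W - 1, math.ceil(cx + r_out)))
    y0, y1 = int(max(0, math.floor(cy - r_out))), int(min(H - 1, math.ceil(cy + r_out)))
    if x1 < x0 or y1 < y0:
        return np.zeros((0, 2), int), np.zeros(0)
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    dist = np.hypot(gx - cx, gy - cy)
    keep = dist <= r_out
    return np.column_stack([gx[keep], gy[keep]]), dist[keep]


def sample_candidates(element: ArteryElement, mask: np.ndarray, fmap, dmap,
                      cfg: RunConfig | None = None,
                      diameter_fn=None,
                      exclude_fn=None,
                      forward_only: bool = False,
                      cone: tuple | None = None,
                      corridor: tuple | None = None) -> CandidateSet:
    """Collect candidate elements in the annulus [s_t, r_S] around the
    current element.

    Falls back to the full disk when the annulus holds no vessel pixel, and
    then expands the radius stepwise up to the detector radius (gap
    recovery).  ``diameter_fn(position, direction) -> float`` supplies
    candidate diameters (one shared value per transversal line);
    ``exclude_fn(positions) -> bool array`` vetoes pixels (previously
    tracked paths); ``forward_only`` restricts candidates to the half-plane
    ahead of the element's direction (used just after branch spawning).

    Raises ``NoContinuation`` when nothing remains.
    """
    cfg = cfg or RunConfig()
    disk = sampling_disk(element, cfg)
    # detector radius r_D: the gap-recovery bound (gaps narrower than r_D
    # can be walked across, wider ones terminate the branch)
    r_d = max(float(np.clip(element.diameter, cfg.d_min, cfg.d_max)), disk.radius)

    pix, dist = _disk_pixels(disk.center, r_d, mask.shape)
    if len(pix) == 0:
        raise NoContinuation("sampling disk left the image")
    on_mask = mask[pix[:, 1], pix[:, 0]]
    ok = on_mask.copy()
    if exclude_fn is not None:
        ok &= ~exclude_fn(pix)
    if forward_only:
        v = pix - disk.center[None, :]
        ok &= (v @ element.direction) > 0.0
    if cone is not None:
        cdir, cos_min = cone
        v = pix - disk.center[None, :]
        nv = np.maximum(np.linalg.norm(v, axis=1), 1e-9)
        ok &= (v @ np.asarray(cdir, float)) / nv >= cos_min
    if corridor is not None:
        origin, cdir, lat_tol = corridor
        cdir = np.asarray(cdir, float)
        w = pix - np.asarray(origin, float)[None, :]
        perp = np.abs(w[:, 0] * (-cdir[1]) + w[:, 1] * cdir[0])
        ok &= (perp <= lat_tol) & ((pix - disk.center[None, :]) @ cdir > 0.0)

    expanded = False
    # the 0.5 px slack keeps the on-axis pixel available when the look-ahead
    # boundary falls between it and its diagonal neighbours
    sel = ok & (dist >= disk.look_ahead - 0.5) & (dist <= disk.radius)
    if not sel.any():
        # fallback and gap recovery are forward-restricted: they serve gaps
        # and sharp bends ahead, never a u-turn into the blur fringe
        fwd = ((pix - disk.center[None, :]) @ element.direction) > 0.0
        sel = ok & fwd & (dist >= 1.0) & (dist <= disk.radius)
        if not sel.any():
            sel = ok & fwd & (dist >= 1.0) & (dist <= r_d)
            expanded = True
    if not sel.any():
        raise NoContinuation("no vessel pixels in the sampling disk")

    pos = pix[sel].astype(float)
    zh = fmap.zhat[pix[sel][:, 1], pix[sel][:, 0]]
    dirs = dmap.v2[pix[sel][:, 1], pix[sel][:, 0]]
    # invalid directions: inherit the incoming orientation
    bad = ~dmap.valid[pix[sel][:, 1], pix[sel][:, 0]]
    if bad.any():
        dirs = dirs.copy()
        dirs[bad] = element.direction
    if diameter_fn is not None:
        dia = np.array([diameter_fn(p, d_) for p, d_ in zip(pos, dirs)])
    else:
        dia = np.full(len(pos), element.diameter)

    zmax = float(zh.max())
    dmax = float(dia.max())
    q_z, q_t, q_d = continuity_measures(element, pos, zh, dia, zmax, dmax)
    cand = CandidateSet(positions=pos, zhats=zh, directions=dirs, diameters=dia,
                        q_z=q_z, q_theta=q_t, q_d=q_d,
                        zhat_max=zmax, d_max=dmax, expanded=expanded)
    cand.sigmas = adaptive_sigmas(cand, cfg)
    return cand


def select_next(cand: CandidateSet, cfg: RunConfig | None = None) -> ArteryElement:
    """MAP selection: the candidate maximizing q_Z * q_theta * q_d.

    Ties resolve to the lowest candidate index (row-major pixel order).
    """
    if len(cand) == 0:
        raise NoContinuation("empty candidate set")
    qz, qt, qd = likelihoods(cand)
    score = qz * qt * qd
    i = int(np.argmax(score))
    direction = cand.directions[i].copy()
    n = np.linalg.norm(direction)
    direction = direction / n if n > 1e-12 else direction
    return ArteryElement(position=cand.positions[i].copy(),
                         zhat=float(cand.zhats[i]),
                         direction=direction,
                         diameter=float(cand.diameters[i]))
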