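"""Structure pattern detector (SPD).

At each tracked element a circular template samples the vesselness map on a
circle slightly larger than the local vessel radius.  Peaks of the circular
profile mark vessel limbs entering the circle; an oriented Gabor filter
bank measures how "co-vessel" each peak is with the detector centre; and a
fuzzy inferring function combines peak vesselness, Gabor response and peak
count into membership degrees for the four local patterns:

    1 termination, 2 segment, 3 bifurcation, 4 crossing.

The pattern of maximal membership controls the tracker: a bifurcation ends
the current branch and spawns the outgoing limbs, a crossing is registered
so the second vessel may later pass through, a termination ends the branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig

PATTERN_NAMES = {1: "termination", 2: "segment", 3: "bifurcation", 4: "crossing"}


# ---------------------------------------------------------------------------
# circular template
# ---------------------------------------------------------------------------

@dataclass
class CircularTemplate:
    center: np.ndarray     # (2,)
    radius: float
    angles: np.ndarray     # (n,) sample azimuths, uniform on [0, 2 pi)
    values: np.ndarray     # (n,) vesselness samples (bilinear)
    derivative: np.ndarray  # (n,) smoothed circular first derivative


@dataclass
class Peak:
    angle: float           # azimuth on the circle (radians)
    position: np.ndarray   # (2,) subpixel position on the circle
    zhat: float            # interpolated vesselness at the peak
    azimuth: np.ndarray    # (2,) unit vector centre -> peak
    gabor: float = 0.0     # co-vessel response gamma in (0, 1)


@dataclass
class PeakSet:
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def zhats(self) -> np.ndarray:
        return np.array([p.zhat for p in self.peaks])

    @property
    def gabors(self) -> np.ndarray:
        return np.array([p.gabor for p in self.peaks])


@dataclass
class PatternResult:
    pattern: int                   # i0 in {1, 2, 3, 4}
    membership: float              # mu of the winning pattern
    memberships: dict[int, float]  # all four class memberships
    peak_set: PeakSet
    template: CircularTemplate

    @property
    def name(self) -> str:
        return PATTERN_NAMES[self.pattern]


def sample_template(center, diameter: float, fmap, cfg: RunConfig | None = None,
                    alpha: float | None = None) -> CircularTemplate:
    """Sample a fixed number of vesselness values on the circle of radius
    ``alpha * d / 2`` and compute the smoothed circular derivative.

    The sample count is constant regardless of radius, keeping the detector
    scale-adaptive; bilinear interpolation reads the map between pixels.
    """
    cfg = cfg or RunConfig()
    alpha = cfg.alpha if alpha is None else alpha
    center = np.asarray(center, float)
    # the margin term lets the circle clear the PSF-smeared junction core,
    # without which the limbs of a bifurcation never separate into peaks
    r = alpha * diameter / 2.0 + cfg.spd_radius_margin * cfg.psf_sigma
    H, W = fmap.zhat.shape
    if (center[0] + r < 0 or center[0] - r > W - 1
            or center[1] + r < 0 or center[1] - r > H - 1):
        raise ValueError("circular template lies fully outside the image")
    n = cfg.n_circle_samples
    ang = 2 * np.pi * np.arange(n) / n
    pts = center[None, :] + r * np.column_stack([np.cos(ang), np.sin(ang)])
    vals = ndimage.map_coordinates(fmap.zhat, [pts[:, 1], pts[:, 0]], order=1,
                                   mode="constant", cval=0.0)
    # circular convolution with a first-derivative-of-Gaussian kernel
    s = cfg.circle_deriv_sigma
    m = int(math.ceil(4 * s))
    u = np.arange(-m, m + 1, dtype=float)
    g1 = -u / (s**3 * math.sqrt(2 * math.pi)) * np.exp(-u**2 / (2 * s * s))
    dT = ndimage.convolve1d(vals, g1, mode="wrap")
    return CircularTemplate(center=center, radius=r, angles=ang, values=vals, derivative=dT)


def detect_peaks(template: CircularTemplate, cfg: RunConfig | None = None) -> PeakSet:
    """Peaks of the circular profile: positive-to-negative sign transitions
    of the smoothed derivative, refined by a local quadratic fit; peaks
    below the binarization threshold are discarded as noise."""
    cfg = cfg or RunConfig()
    dT = template.derivative
    n = len(dT)
    # sign with a dead zone: floating-point ripple on flat stretches (and
    # the exactly-zero sample at a symmetric apex) must not mask or fake a
    # transition
    sgn = np.where(np.abs(dT) <= 1e-9, 0, np.sign(dT)).astype(int)
    nz = np.nonzero(sgn)[0]
    idx = []
    for k, i in enumerate(nz):
        j = nz[(k + 1) % len(nz)]
        if sgn[i] > 0 and sgn[j] < 0:
            # transition somewhere in (i, j]; anchor at its midpoint
            span = (j - i) % n
            idx.append((i + span // 2) % n)
    peaks: list[Peak] = []
    two_pi = 2 * np.pi
    for i in idx:
        # quadratic refinement on the profile values around the transition
        v0, v1, v2 = (template.values[(i - 1) % n], template.values[i],
                      template.values[(i + 1) % n])
        denom = v0 - 2 * v1 + v2
        frac = 0.5 * (v0 - v2) / denom if abs(denom) > 1e-15 else 0.5
        frac = float(np.clip(frac, -1.0, 1.0))
        ang = (template.angles[i] + frac * two_pi / n) % two_pi
        az = np.array([math.cos(ang), math.sin(ang)])
        pos = template.center + template.radius * az
        # interpolated height at the refined angle
        z = float(np.interp((ang / two_pi) * n, np.arange(n + 1),
                            np.append(template.values, template.values[0])))
        if z < cfg.binarize_threshold:
            continue
        peaks.append(Peak(angle=float(ang), position=pos, zhat=z, azimuth=az))
    return PeakSet(peaks)


# ---------------------------------------------------------------------------
# Gabor co-vessel responses
# ---------------------------------------------------------------------------

def _gabor_mask(size: int, theta: float):
    """Real-component Gabor mask of side ``size`` (odd), wavelength equal to
    the mask size (T = 1/f) and envelope sigma = T/2, with the wave vector
    perpendicular to the strip orientation ``theta``.  Zero-mean and
    L2-normalized so responses are comparable across sizes."""
    h = (size - 1) // 2
    y, x = np.mgrid[-h:h + 1, -h:h + 1].astype(float)
    sigma = size / 2.0
    f = 1.0 / size
    # coordinates across the strip (perpendicular to orientation theta)
    u = -math.sin(theta) * x + math.cos(theta) * y
    env = np.exp(-(x**2 + y**2) / (2 * sigma * sigma))
    m = env * np.cos(2 * np.pi * f * u)
    m -= m.mean()
    nrm = np.linalg.norm(m)
    return m / nrm if nrm > 0 else m


def _bank_sizes(diameter: float, cfg: RunConfig) -> list[int]:
    """Mask sizes tracking the local vessel diameter (clipped to 3-15 px)."""
    sizes = set()
    for fac in (0.6, 0.8, 1.0, 1.2, 1.4):
        t = int(round(diameter * fac))
        t = max(3, min(15, t))
        if t % 2 == 0:
            t += 1
        sizes.add(t)
    return sorted(sizes)


def _bank_response(point, theta: float, image: np.ndarray, diameter: float,
                   cfg: RunConfig) -> float:
    """Largest |real Gabor response| at ``point`` over mask sizes and a small
    orientation jitter around ``theta``."""
    best = 0.0
    jit = cfg.gabor_jitter
    for size in _bank_sizes(diameter, cfg):
        h = (size - 1) // 2
        y, x = np.mgrid[-h:h + 1, -h:h + 1].astype(float)
        px = point[0] + x
        py = point[1] + y
        patch = ndimage.map_coordinates(image, [py.ravel(), px.ravel()], order=1,
                                        mode="constant", cval=0.0).reshape(x.shape)
        for dth in (-jit, 0.0, jit):
            m = _gabor_mask(size, theta + dth)
            r = abs(float(np.sum(m * patch)))
            if r > best:
                best = r
    return best


def gabor_response(peak: Peak, center, image: np.ndarray, diameter: float,
                   center_direction, cfg: RunConfig | None = None) -> float:
    """Co-vessel measure gamma in (0, 1) for one peak.

    The bank is oriented along the centre->peak azimuth and evaluated at the
    peak; the normalizer g_max is the same bank's response at the detector
    centre oriented along the tracked vessel's own direction, so gamma ~ 1
    means "as vessel-like, and as aligned, as the vessel I am on".
    """
    cfg = cfg or RunConfig()
    theta = math.atan2(peak.azimuth[1], peak.azimuth[0])
    resp = _bank_response(peak.position, theta, image, diameter, cfg)
    phi = math.atan2(center_direction[1], center_direction[0])
    g_max = _bank_response(np.asarray(center, float), phi, image, diameter, cfg)
    eps = 1e-3
    if g_max <= 0:
        return eps
    return float(np.clip(resp / g_max, eps, 1.0 - eps))


def attach_gabor(peaks: PeakSet, center, image: np.ndarray, diameter: float,
                 center_direction, cfg: RunConfig | None = None) -> PeakSet:
    for p in peaks.peaks:
        p.gabor = gabor_response(p, center, image, diameter, center_direction, cfg)
    return peaks


# ---------------------------------------------------------------------------
# fuzzy inferring function
# ---------------------------------------------------------------------------

def fuzzy_memberships(peaks: PeakSet, pattern: int, cfg: RunConfig | None = None):
    """Gaussian membership degrees for one candidate pattern ``i``.

    Returns (per-peak vesselness memberships, per-peak Gabor memberships,
    pseudo-pattern membership).  The pseudo-pattern membership is 0 when the
    peak count is below the pattern's index.
    """
    cfg = cfg or RunConfig()
    m_t = len(peaks)
    if m_t == 0:
        return np.array([]), np.array([]), 1.0 if pattern == 1 else 0.0
    z = peaks.zhats
    g = peaks.gabors
    mu_z = np.exp(-((z.max() - z) ** 2) / (2 * cfg.fuzzy_sigma_z**2))
    mu_g = np.exp(-((g.max() - g) ** 2) / (2 * cfg.fuzzy_sigma_gamma**2))
    if m_t >= pattern:
        mu_m = float(np.exp(-((m_t - pattern) ** 2) / (2 * cfg.fuzzy_sigma_m**2)))
    else:
        mu_m = 0.0
    return mu_z, mu_g, mu_m


def infer_pattern(peaks: PeakSet, template: CircularTemplate,
                  cfg: RunConfig | None = None) -> PatternResult:
    """Min-max fuzzy composition: class membership is the minimum over the
    peak memberships and the pseudo-pattern membership; the inferred class
    maximizes membership, ties resolving to the simpler pattern.

    A circle with at most one peak is a termination candidate (the single
    back-peak of a distal tip); zero peaks infer termination outright.
    """
    cfg = cfg or RunConfig()
    memberships: dict[int, float] = {}
    for i in (1, 2, 3, 4):
        mu_z, mu_g, mu_m = fuzzy_memberships(peaks, i, cfg)
        parts = [mu_m]
        if len(mu_z):
            parts.append(float(mu_z.min()))
            parts.append(float(mu_g.min()))
        memberships[i] = float(min(parts))
    best = max(sorted(memberships), key=lambda i: memberships[i])
    # max() with sorted keys keeps the lowest index on ties
    best = min((i for i in memberships if memberships[i] >= memberships[best] - 1e-12),
               default=best)
    return PatternResult(pattern=best, membership=memberships[best],
                         memberships=memberships, peak_set=peaks, template=template)


def detect_structure(center, diameter: float, direction, fmap, image: np.ndarray,
                     cfg: RunConfig | None = None) -> PatternResult:
    """Full SPD pass at one location: template -> peaks -> Gabor -> FIF."""
    cfg = cfg or RunConfig()
    template = sample_template(center, diameter, fmap, cfg)
    peaks = detect_peaks(template, cfg)
    source = fmap.zhat if cfg.gabor_on_feature_map else image
    attach_gabor(peaks, center, source, diameter, direction, cfg)
    # co-vessel gate: peaks misaligned with any vessel axis (noise, pseudo
    # contours, a parallel neighbour's flank) do not count as limbs
    kept = PeakSet([p for p in peaks.peaks if p.gabor >= cfg.gamma_gate])
    return infer_pattern(kept, template, cfg)


def refine_node(positions, memberships) -> np.ndarray:
    """Among redundant detections of one node, keep the position of maximal
    membership (first on ties)."""
    if len(positions) == 0:
        raise ValueError("no detections to refine")
    i = int(np.argmax(memberships))
    return np.asarray(positions[i], float)
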