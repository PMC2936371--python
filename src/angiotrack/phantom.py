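"""Synthetic angiogram phantoms with exact ground truth.

Two families are generated: single arterial *segments* (straight, stenotic,
aneurysmal, parallel pairs, gapped, curved) and an arterial *tree* with
curving branches, bifurcations and a crossing.  Each phantom is an ideal
tube of known analytic centerline and width profile, rasterized with 4x
supersampling, Gaussian-blurred to emulate X-ray focal blur, and optionally
corrupted with additive white Gaussian noise.  The geometry (centerlines,
per-point diameters, node positions, binary mask) is returned alongside the
image, so every downstream stage can be validated without any external data.

Conventions: pixel-centered 0-based coordinates, ``x`` rightward, ``y``
downward; positions are float ``(x, y)`` pairs; images are ``[y, x]`` arrays
of floats.  Vessels are bright (``S_V``) on a dark background (``S_B``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

SUPERSAMPLE = 4  # subpixel rasterization factor

VALID_SHAPES = ("straight", "stenotic", "aneurysmal", "parallel_pair", "gapped", "curved")


# ---------------------------------------------------------------------------
# specs and ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class SegmentPhantomSpec:
    """Parameters of one simulated arterial segment.

    ``mean_width`` is the nominal lumen width L_m and ``extreme_width`` the
    extreme L_r (minimum for a stenosis, maximum for an aneurysm, second
    tube's width for a parallel pair).  ``pair_distance`` is the edge-to-edge
    gap between the two tubes of a parallel pair; ``gap_width`` the length of
    the missing-contrast stretch of a gapped tube.
    """

    vessel_intensity: float = 1.0
    background_intensity: float = 0.0
    blur_sigma: float = 3.2
    mean_width: float = 13.0
    extreme_width: float = 13.0
    length: float = 120.0
    noise_sigma: float = 0.0
    shape: str = "straight"
    pair_distance: float = 10.0
    gap_width: float = 8.0
    curve_amplitude: float = 12.0
    image_shape: tuple[int, int] = (120, 176)  # (H, W)

    def validate(self) -> None:
        if self.shape not in VALID_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {VALID_SHAPES}")
        if not self.vessel_intensity > self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity "
                             "(bright vessels on dark background)")
        for name in ("mean_width", "extreme_width", "length", "blur_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        h, w = self.image_shape
        margin = max(self.mean_width, self.extreme_width) / 2 + 2
        if self.length + 2 * margin > w or 2 * margin > h:
            raise ValueError("width/length profile exceeds image bounds; "
                             "enlarge image_shape or shrink the tube")
        if self.shape == "curved" and 2 * (margin + self.curve_amplitude) > h:
            raise ValueError("curved centerline exceeds image bounds")
        if self.shape == "parallel_pair":
            need = self.mean_width / 2 + self.extreme_width / 2 + self.pair_distance
            if 2 * margin + need > h:
                raise ValueError("parallel pair exceeds image bounds")


@dataclass
class TreeBranchSpec:
    """One branch of the simulated arterial tree.

    Root branches have ``parent=None`` and an absolute ``angle`` (radians,
    measured from +x toward +y); child branches attach to the parent at
    arclength ``attach_s`` and depart at ``angle`` relative to the parent's
    local tangent.  ``curvature`` is the signed inverse turning radius
    (1/px); the centerline is an arc of linearly varying heading.
    """

    parent: int | None
    attach_s: float
    angle: float
    length: float
    width: float
    curvature: float = 0.0
    start: tuple[float, float] | None = None  # root branches only


@dataclass
class TreePhantomSpec:
    branches: list[TreeBranchSpec] = field(default_factory=list)
    #: declared crossing branch pairs (i, j); any other tube-tube contact
    #: away from parent junctions is rejected
    crossings: list[tuple[int, int]] = field(default_factory=list)
    vessel_intensity: float = 1.0
    background_intensity: float = 0.0
    blur_sigma: float = 3.2
    noise_sigma: float = 0.0
    image_shape: tuple[int, int] = (320, 320)

    def validate(self) -> None:
        if not self.branches:
            raise ValueError("tree needs at least one branch")
        if not self.vessel_intensity > self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")
        for b in self.branches:
            if not (3.0 <= b.width <= 18.0):
                raise ValueError("branch widths must lie in [3, 18] px")
            if b.parent is None and b.start is None:
                raise ValueError("root branches need a start position")
            if b.parent is not None and not (0 <= b.parent < len(self.branches)):
                raise ValueError("branch parent index out of range")


@dataclass
class CenterlineSegment:
    """Analytic centerline of one vessel segment with per-point diameters."""

    points: np.ndarray      # (N, 2) float (x, y), ordered, ~0.5 px spacing
    diameters: np.ndarray   # (N,)
    branch_id: int = 0
    level: int = 1          # generation depth (root = 1)

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.maximum(n, 1e-12)


@dataclass
class GroundTruth:
    segments: list[CenterlineSegment]
    nodes: list[tuple[tuple[float, float], str]]  # (position, type)
    mask: np.ndarray  # bool, ideal tube occupancy > 0.5

    @property
    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def nodes_of_type(self, kind: str) -> list[tuple[float, float]]:
        return [p for p, t in self.nodes if t == kind]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _arc_points(start, heading, curvature, length, step=0.5):
    """Constant-curvature arc sampled every ``step`` px of arclength."""
    n = max(int(math.ceil(length / step)), 2)
    s = np.linspace(0.0, length, n + 1)
    if abs(curvature) < 1e-12:
        x = start[0] + s * math.cos(heading)
        y = start[1] + s * math.sin(heading)
    else:
        h = heading + curvature * s
        x = start[0] + (np.sin(h) - math.sin(heading)) / curvature
        y = start[1] - (np.cos(h) - math.cos(heading)) / curvature
    return np.column_stack([x, y]), heading + curvature * length


def _cosine_profile(s, length, w_mid, w_ext, frac=0.4):
    """Width profile: cosine-tapered dip/bulge from w_mid to w_ext centred
    on the segment, spanning ``frac`` of its length."""
    half = frac * length / 2.0
    u = (s - length / 2.0) / half
    w = np.full_like(s, float(w_mid))
    inside = np.abs(u) < 1.0
    blend = 0.5 * (1.0 + np.cos(np.pi * u[inside]))  # 1 at centre, 0 at edges
    w[inside] = w_mid + (w_ext - w_mid) * blend
    return w


def _rasterize(segments, image_shape, removed=None):
    """Supersampled occupancy of the union of tubes.

    ``removed`` is an optional list of (center, half_len) stretches where the
    tube is erased (contrast gaps).  Returns the float occupancy in [0, 1] at
    final resolution.
    """
    H, W = image_shape
    ss = SUPERSAMPLE
    # dense centerline samples with per-sample radius
    pts, rad = [], []
    for seg in segments:
        p, d = seg.points, seg.diameters
        pts.append(p)
        rad.append(d / 2.0)
    pts = np.concatenate(pts)
    rad = np.concatenate(rad)
    tree = cKDTree(pts)
    # supersampled pixel-center grid
    off = (np.arange(ss) + 0.5) / ss - 0.5
    ys = (np.arange(H)[:, None] + off[None, :]).ravel()
    xs = (np.arange(W)[:, None] + off[None, :]).ravel()
    gx, gy = np.meshgrid(xs, ys)
    q = np.column_stack([gx.ravel(), gy.ravel()])
    rmax = float(rad.max())
    dist, idx = tree.query(q, distance_upper_bound=rmax + 1.0)
    occ = np.zeros(len(q), dtype=bool)
    hit = np.isfinite(dist)
    occ[hit] = dist[hit] <= rad[idx[hit]]
    occ = occ.reshape(H * ss, W * ss).astype(np.float64)
    if removed:
        sy, sx = np.meshgrid(ys, xs, indexing="ij")
        for center, half in removed:
            d2 = (sx - center[0]) ** 2 + (sy - center[1]) ** 2
            occ[d2 <= half**2] = 0.0
    # box-downsample
    occ = occ.reshape(H, ss, W, ss).mean(axis=(1, 3))
    return occ


def add_noise(image: np.ndarray, noise_sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. Gaussian noise of std ``noise_sigma``.

    The result is *not* clipped: phantoms stay in float gray space so noise
    statistics remain exact; clipping to the valid range happens only when
    writing integer image files.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, noise_sigma, size=image.shape)


def _finish(occ, spec, seed):
    img = spec.background_intensity + (spec.vessel_intensity - spec.background_intensity) * occ
    img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    return add_noise(img, spec.noise_sigma, seed)


# ---------------------------------------------------------------------------
# segment phantoms
# ---------------------------------------------------------------------------

def render_segment(spec: SegmentPhantomSpec, seed: int = 0):
    """Render one segment phantom.  Returns ``(image, GroundTruth)``."""
    spec.validate()
    H, W = spec.image_shape
    yc = float(H // 2)
    x0 = float(round((W - spec.length) / 2.0))
    step = 0.5
    n = int(round(spec.length / step))
    s = np.linspace(0.0, spec.length, n + 1)

    segments: list[CenterlineSegment] = []
    removed = None
    if spec.shape in ("straight", "gapped"):
        pts = np.column_stack([x0 + s, np.full_like(s, yc)])
        dia = np.full_like(s, spec.mean_width)
        segments.append(CenterlineSegment(pts, dia))
        if spec.shape == "gapped":
            removed = [((x0 + spec.length / 2.0, yc), spec.gap_width / 2.0)]
    elif spec.shape in ("stenotic", "aneurysmal"):
        if spec.shape == "stenotic" and spec.extreme_width >= spec.mean_width:
            raise ValueError("stenotic phantom needs extreme_width < mean_width")
        if spec.shape == "aneurysmal" and spec.extreme_width <= spec.mean_width:
            raise ValueError("aneurysmal phantom needs extreme_width > mean_width")
        pts = np.column_stack([x0 + s, np.full_like(s, yc)])
        dia = _cosine_profile(s, spec.length, spec.mean_width, spec.extreme_width)
        segments.append(CenterlineSegment(pts, dia))
    elif spec.shape == "curved":
        y = yc + spec.curve_amplitude * np.sin(2 * np.pi * s / spec.length) - spec.curve_amplitude * 0.0
        pts = np.column_stack([x0 + s, y])
        # reparameterize diameters by true arclength is unnecessary: constant
        dia = np.full(len(pts), spec.mean_width)
        segments.append(CenterlineSegment(pts, dia))
    elif spec.shape == "parallel_pair":
        w1, w2 = spec.mean_width, spec.extreme_width
        gap = spec.pair_distance
        dy = (w1 + w2) / 2.0 + gap  # centerline separation for an edge gap of d_P
        y1 = yc - dy / 2.0
        y2 = yc + dy / 2.0
        # keep centerlines on integer rows when possible
        y1, y2 = round(y1), round(y1) + round(dy)
        p1 = np.column_stack([x0 + s, np.full_like(s, float(y1))])
        s2 = np.linspace(0.0, spec.length + 5.0, n + 11)
        p2 = np.column_stack([x0 + s2 - 2.5, np.full_like(s2, float(y2))])
        segments.append(CenterlineSegment(p1, np.full(len(p1), w1), branch_id=0))
        segments.append(CenterlineSegment(p2, np.full(len(p2), w2), branch_id=1))

    nodes = []
    for seg in segments:
        nodes.append(((float(seg.points[0, 0]), float(seg.points[0, 1])), "termination"))
        nodes.append(((float(seg.points[-1, 0]), float(seg.points[-1, 1])), "termination"))

    occ = _rasterize(segments, spec.image_shape, removed=removed)
    img = _finish(occ, spec, seed)
    return img, GroundTruth(segments, nodes, occ > 0.5)


# ---------------------------------------------------------------------------
# tree phantoms
# ---------------------------------------------------------------------------

def _build_tree_centerlines(spec: TreePhantomSpec):
    segments: list[CenterlineSegment] = []
    headings_at = []
    levels = []
    for i, b in enumerate(spec.branches):
        if b.parent is None:
            start, h0, level = np.asarray(b.start, float), b.angle, 1
        else:
            parent = segments[b.parent]
            s_par = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(parent.points, axis=0).T))])
            k = int(np.searchsorted(s_par, min(b.attach_s, s_par[-1])))
            k = min(k, len(parent.points) - 1)
            start = parent.points[k]
            tang = parent.tangents()[k]
            h0 = math.atan2(tang[1], tang[0]) + b.angle
            level = levels[b.parent] + 1
        pts, _hend = _arc_points(start, h0, b.curvature, b.length)
        segments.append(CenterlineSegment(pts, np.full(len(pts), b.width), branch_id=i, level=level))
        headings_at.append(h0)
        levels.append(level)
    return segments


def _polyline_intersection(p: np.ndarray, q: np.ndarray):
    """First transversal intersection point of two dense polylines, or None."""
    tree = cKDTree(q)
    d, idx = tree.query(p)
    k = int(np.argmin(d))
    if d[k] > 1.0:
        return None
    return tuple((p[k] + q[idx[k]]) / 2.0)


def render_tree(spec: TreePhantomSpec, seed: int = 0):
    """Render the simulated arterial tree.  Returns ``(image, GroundTruth)``."""
    spec.validate()
    segments = _build_tree_centerlines(spec)
    H, W = spec.image_shape

    # bounds check
    for seg in segments:
        r = seg.diameters.max() / 2.0
        if (seg.points[:, 0].min() < r or seg.points[:, 1].min() < r
                or seg.points[:, 0].max() > W - 1 - r or seg.points[:, 1].max() > H - 1 - r):
            raise ValueError(f"branch {seg.branch_id} leaves the image field")

    # nodes: bifurcations at attachments, crossings at declared intersections
    nodes: list[tuple[tuple[float, float], str]] = []
    child_of: dict[int, list[int]] = {}
    for i, b in enumerate(spec.branches):
        if b.parent is not None:
            p0 = segments[i].points[0]
            nodes.append(((float(p0[0]), float(p0[1])), "bifurcation"))
            child_of.setdefault(b.parent, []).append(i)
    declared = set()
    for (i, j) in spec.crossings:
        pt = _polyline_intersection(segments[i].points, segments[j].points)
        if pt is None:
            raise ValueError(f"declared crossing ({i},{j}) does not intersect")
        nodes.append(((float(pt[0]), float(pt[1])), "crossing"))
        declared.add((min(i, j), max(i, j)))

    # undeclared overlap check: tubes of unrelated branch pairs must stay
    # apart except near declared crossings or shared junctions
    node_pts = np.array([p for p, _ in nodes], float) if nodes else np.zeros((0, 2))
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            if (i, j) in declared:
                continue
            related = (spec.branches[j].parent == i or spec.branches[i].parent == j
                       or spec.branches[i].parent == spec.branches[j].parent is not None
                       or (spec.branches[i].parent is not None
                           and spec.branches[i].parent == spec.branches[j].parent))
            tree_j = cKDTree(segments[j].points)
            d, _ = tree_j.query(segments[i].points)
            lim = (segments[i].diameters.max() + segments[j].diameters.max()) / 2.0
            bad = d < lim
            if related and bad.any():
                # allow contact near the shared junction only
                junc = segments[j].points[0] if spec.branches[j].parent == i else segments[i].points[0]
                near = np.hypot(*(segments[i].points - junc).T) < 2.5 * lim
                bad = bad & ~near
            if bad.any():
                raise ValueError(
                    f"branches {i} and {j} overlap outside declared crossings/junctions")

    # terminations: free ends of every branch
    for i, seg in enumerate(segments):
        if spec.branches[i].parent is None:
            nodes.append(((float(seg.points[0, 0]), float(seg.points[0, 1])), "termination"))
        nodes.append(((float(seg.points[-1, 0]), float(seg.points[-1, 1])), "termination"))

    occ = _rasterize(segments, spec.image_shape)
    img = _finish(occ, spec, seed)
    return img, GroundTruth(segments, nodes, occ > 0.5)


def default_sat_spec(noise_sigma: float = 0.0) -> TreePhantomSpec:
    """A simulated-arterial-tree spec with curving branches, two generations
    of bifurcations and one vessel crossing (widths 6--14 px)."""
    branches = [
        TreeBranchSpec(parent=None, attach_s=0.0, angle=0.45, length=260.0,
                       width=14.0, curvature=0.0015, start=(25.0, 70.0)),
        TreeBranchSpec(parent=0, attach_s=100.0, angle=0.70, length=140.0,
                       width=9.0, curvature=0.0030),
        TreeBranchSpec(parent=0, attach_s=180.0, angle=-0.70, length=110.0,
                       width=7.0, curvature=-0.0025),
        TreeBranchSpec(parent=1, attach_s=70.0, angle=-0.75, length=115.0,
                       width=6.0, curvature=-0.0020),
        # descending trunk branch whose tube overlaps (crosses) branch 3 in
        # the 2-D projection
        TreeBranchSpec(parent=0, attach_s=215.0, angle=0.90, length=95.0,
                       width=8.0, curvature=0.0),
    ]
    return TreePhantomSpec(branches=branches, crossings=[(3, 4)],
                           noise_sigma=noise_sigma)
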