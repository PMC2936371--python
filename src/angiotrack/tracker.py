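"""Whole-image artery tracking: PTO + SPD orchestration.

Starting from the automatically detected seed, branches are tracked one at
a time.  A LIFO source-list holds pending start elements (the seed in both
orientations, plus every outgoing limb of each detected bifurcation); a
crossing-list registers detected vessel crossings so that the second vessel
may later pass through the first one's visited path.  A branch ends when
one of the stop rules fires:

1. a new bifurcation is detected (its outgoing limbs are pushed as sources);
2. the vessel feature of the next element falls below the stop threshold;
3. the path runs into a previously tracked vessel, unless inside the
   exemption zone of a registered crossing;
4. the source-list is empty (the outer loop's halt);
5. the next point would leave the image field.

In every case except a crossing the last valid point becomes a termination
node.  Tracked branches are polylines of artery elements with per-point
diameters; diameters are post-corrected for the PSF's along-axis averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import RunConfig
from .diameter import (FlatProfileError, build_calibration, correct_diameter_profile,
                       extract_profile, estimate_sigma_hat)
from .pto import ArteryElement, NoContinuation, sample_candidates, select_next
from .spd import detect_structure
from .vesselness import preprocess

log = logging.getLogger("angiotrack")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    position: np.ndarray   # (2,)
    kind: str              # termination | bifurcation | crossing
    membership: float = 1.0
    node_id: int = -1
    radius: float = 10.0   # extent of the junction/crossing region (px)


@dataclass
class TrackedBranch:
    elements: list[ArteryElement]
    level: int = 1
    spawn_node: int | None = None
    end_node: int | None = None
    end_reason: str = ""

    @property
    def points(self) -> np.ndarray:
        return np.array([e.position for e in self.elements], float)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([e.diameter for e in self.elements], float)

    @property
    def arclengths(self) -> np.ndarray:
        p = self.points
        if len(p) < 2:
            return np.zeros(len(p))
        return np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(p, axis=0).T))])

    @property
    def length(self) -> float:
        a = self.arclengths
        return float(a[-1]) if len(a) else 0.0


@dataclass
class ArteryTree:
    branches: list[TrackedBranch] = field(default_factory=list)
    nodes: list[TreeNode] = field(default_factory=list)
    seed: tuple[float, float] | None = None
    config: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def dense_points(self, step: float = 0.25) -> np.ndarray:
        """All branch polylines resampled at ``step`` px spacing."""
        out = []
        for b in self.branches:
            p = b.points
            if len(p) < 2:
                continue
            s = b.arclengths
            su = np.arange(0.0, s[-1] + step / 2, step)
            out.append(np.column_stack([np.interp(su, s, p[:, 0]),
                                        np.interp(su, s, p[:, 1])]))
        if not out:
            return np.zeros((0, 2))
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# tracking state helpers
# ---------------------------------------------------------------------------

def _vessel_radius(diameter: float, psf_sigma: float) -> float:
    """Dilation radius of the visited-path raster around one element: the
    vessel half-width plus the PSF fringe, capped so that the forward
    annulus of a thin vessel is never walled off."""
    d = max(diameter, 2.0)
    return max(d / 2.0 + 0.5, min(d / 2.0 + psf_sigma, 1.4 * d))


class _Visited:
    """Raster of previously tracked vessel area (dilated to local radius)."""

    def __init__(self, shape, psf_sigma: float):
        self.raster = np.zeros(shape, bool)
        self.psf_sigma = psf_sigma

    def mark_branch(self, branch: TrackedBranch):
        for e in branch.elements:
            Tracker._mark_disk(self.raster, e.position,
                               _vessel_radius(e.diameter, self.psf_sigma))

    def query(self, pix: np.ndarray) -> np.ndarray:
        return self.raster[pix[:, 1], pix[:, 0]]


@dataclass
class _Source:
    element: ArteryElement
    level: int
    spawn_node: int | None
    grace_radius: float
    second_element: ArteryElement | None = None


def _ls_line_intersection(points, directions, fallback):
    """Least-squares point closest to all limb axis lines; falls back to the
    detection centre for degenerate geometry."""
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for p, u in zip(points, directions):
        u = np.asarray(u, float)
        n = np.linalg.norm(u)
        if n < 1e-9:
            continue
        u = u / n
        P = np.eye(2) - np.outer(u, u)
        A += P
        b += P @ np.asarray(p, float)
    if abs(np.linalg.det(A)) < 1e-6:
        return np.asarray(fallback, float)
    x = np.linalg.solve(A, b)
    if np.linalg.norm(x - np.asarray(fallback, float)) > 30.0:
        return np.asarray(fallback, float)
    return x


# ---------------------------------------------------------------------------
# the tracker
# ---------------------------------------------------------------------------

class Tracker:
    """One tracking run over a preprocessed image."""

    def __init__(self, image: np.ndarray, cfg: RunConfig | None = None, maps=None):
        self.cfg = cfg or RunConfig()
        self.image = np.asarray(image, float)
        if maps is None:
            maps = preprocess(self.image, self.cfg)
        self.fmap, self.dmap, self.mask, self.skeleton, self.seed = maps
        self.calibration = None
        if self.cfg.k_cal is None:
            self.calibration = build_calibration(self.cfg)
        self._diam_source = (self.fmap.zhat if self.cfg.diameter_source == "feature_map"
                             else self.image)
        self._diam_cache: dict[tuple[int, int], tuple] = {}
        self.visited = _Visited(self.mask.shape, self.cfg.psf_sigma)
        self.nodes: list[TreeNode] = []
        self.crossings: list[tuple[np.ndarray, float]] = []  # (position, radius)
        self.branches: list[TrackedBranch] = []

    # -- diameters -------------------------------------------------------
    def _measure_full(self, position, direction,
                      expected_diameter: float | None = None):
        """(diameter, subpixel centre offset, profile normal) at a point."""
        centre_sigma = None
        band = None
        if expected_diameter is not None:
            centre_sigma = max(expected_diameter, 2.0) / 2.0
        key = (int(round(position[0])), int(round(position[1])),
               None if centre_sigma is None else round(centre_sigma, 1))
        hit = self._diam_cache.get(key)
        if hit is not None:
            return hit
        direction = np.asarray(direction, float)
        normal = np.array([-direction[1], direction[0]])
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 1e-12 else np.array([0.0, 1.0])
        try:
            prof = extract_profile(position, direction, self._diam_source, cfg=self.cfg)
            sh, off = estimate_sigma_hat(prof, self.cfg, return_centre=True,
                                         centre_sigma=centre_sigma,
                                         sigma_band=band)
            d = (self.cfg.k_cal * sh if self.cfg.k_cal is not None
                 else self.calibration(sh))
        except (FlatProfileError, ValueError):
            d, off = self.cfg.d_min, 0.0
        d = float(np.clip(d, 1.0, 25.0))
        out = (d, float(off), normal)
        self._diam_cache[key] = out
        return out

    def _measure(self, position, direction) -> float:
        return self._measure_full(position, direction)[0]

    # -- exclusion -------------------------------------------------------
    def _exclude_fn(self, trail: list[ArteryElement], branch_raster: np.ndarray,
                    grace_center, grace_radius):
        raster = self.visited.raster
        crossings = self.crossings
        # the element just behind the current one only blocks a small
        # neighbourhood (immediate reversals); older path is in branch_raster
        # at full vessel radius, which would wall off the forward annulus if
        # applied to the immediate trail
        prev = trail[:-1][-1:]
        trail_pts = np.array([e.position for e in prev], float) if prev else None
        trail_r = (np.array([0.75 * np.clip(e.diameter / 2.0, 1.0, 7.0) + 0.5
                             for e in prev]) if prev else None)

        def fn(pix: np.ndarray) -> np.ndarray:
            out = raster[pix[:, 1], pix[:, 0]].copy()
            if out.any():
                # crossing exemption
                for c, r in crossings:
                    near = np.hypot(pix[:, 0] - c[0], pix[:, 1] - c[1]) <= r
                    out &= ~near
                if grace_center is not None:
                    near = np.hypot(pix[:, 0] - grace_center[0],
                                    pix[:, 1] - grace_center[1]) <= grace_radius
                    out &= ~near
            out |= branch_raster[pix[:, 1], pix[:, 0]]
            if trail_pts is not None:
                d = np.hypot(pix[:, 0, None] - trail_pts[None, :, 0],
                             pix[:, 1, None] - trail_pts[None, :, 1])
                out |= (d <= trail_r[None, :]).any(axis=1)
            return out

        return fn

    @staticmethod
    def _mark_disk(raster: np.ndarray, position, radius: float):
        H, W = raster.shape
        x0, x1 = int(max(0, position[0] - radius)), int(min(W - 1, position[0] + radius))
        y0, y1 = int(max(0, position[1] - radius)), int(min(H - 1, position[1] + radius))
        if x1 < x0 or y1 < y0:
            return
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        gx, gy = np.meshgrid(xs, ys)
        d = np.hypot(gx - position[0], gy - position[1])
        sub = raster[y0:y1 + 1, x0:x1 + 1]
        sub[d <= radius] = True

    def _near_node(self, position, kinds=("bifurcation", "crossing"), radius=12.0):
        for n in self.nodes:
            if n.kind in kinds and np.linalg.norm(n.position - position) <= radius:
                return n
        return None

    # -- nodes -----------------------------------------------------------
    def _add_node(self, position, kind, membership=1.0, radius=10.0) -> TreeNode:
        node = TreeNode(position=np.asarray(position, float), kind=kind,
                        membership=float(membership), node_id=len(self.nodes),
                        radius=float(radius))
        self.nodes.append(node)
        return node

    def _limb_direction(self, point) -> np.ndarray:
        x = int(np.clip(round(point[0]), 0, self.mask.shape[1] - 1))
        y = int(np.clip(round(point[1]), 0, self.mask.shape[0] - 1))
        if self.dmap.valid[y, x]:
            return self.dmap.v2[y, x]
        return np.zeros(2)

    def _node_position(self, detections) -> np.ndarray:
        """Least-squares intersection of the limb axis lines of a node
        cluster.

        Each detection's circular template puts one peak on every limb;
        peaks of the same limb across nearby detections are grouped by
        proximity, giving 2-3 points along each limb axis.  A line is
        fitted through each group (falling back to the direction map for
        singleton groups, which is less reliable near the junction blob)
        and the node is the least-squares intersection of those lines.
        """
        if not isinstance(detections, (list, tuple)):
            detections = [detections]
        peaks = []
        for det in detections:
            for p in det.peak_set.peaks:
                if p.gabor >= self.cfg.gamma_gate:
                    peaks.append(np.asarray(p.position, float))
        # greedy grouping: same-limb peaks from nearby detections sit within
        # roughly the inter-detection spacing of each other
        groups: list[list[np.ndarray]] = []
        for p in peaks:
            for g in groups:
                if min(np.linalg.norm(p - q) for q in g) <= 8.0:
                    g.append(p)
                    break
            else:
                groups.append([p])
        pts, dirs = [], []
        for g in groups:
            if len(g) >= 2:
                arr = np.array(g)
                centre = arr.mean(axis=0)
                direction = np.linalg.svd(arr - centre, full_matrices=False)[2][0]
                pts.append(centre)
                dirs.append(direction)
            else:
                u = self._limb_direction(g[0])
                if np.linalg.norm(u) < 0.5:
                    continue
                pts.append(g[0])
                dirs.append(u)
        return _ls_line_intersection(pts, dirs, detections[0].template.center)

    def _resolve_cluster(self, branch: TrackedBranch, pending, sources,
                         cluster_dir=None):
        """Classify a completed node-detection cluster and act on it.

        The flanks of a crossing always present three limbs (a bifurcation
        pattern); only positions close to the crossing centre show all
        four.  A cluster therefore counts as a crossing whenever its
        four-limb detections reach a membership comparable to its best
        three-limb one; otherwise it is a bifurcation, which ends the
        branch.  Returns True when the branch must stop.
        """
        bifs = [(i, d) for i, d in pending if d.pattern == 3]
        crosses = [(i, d) for i, d in pending if d.pattern == 4]
        mu_bif = max((d.membership for _, d in bifs), default=0.0)
        mu_cross = max((d.membership for _, d in crosses), default=0.0)
        if crosses and mu_cross >= 0.7 * mu_bif:
            best = sorted(crosses, key=lambda t: -t[1].membership)[:3]
            transit = self._handle_crossing([d for _, d in best], cluster_dir)
            return False, transit
        if bifs:
            best = sorted(bifs, key=lambda t: -t[1].membership)[:3]
            idx = best[0][0]
            stop = self._handle_bifurcation(branch, idx, [d for _, d in best],
                                            sources)
            return stop, None
        return False, None

    # -- branch tracking -------------------------------------------------
    def _spawn_children(self, node: TreeNode, detection, incoming: np.ndarray,
                        level: int, sources: list[_Source]):
        """Push every outgoing limb of a bifurcation onto the source list."""
        peaks = [p for p in detection.peak_set.peaks if p.gabor >= self.cfg.gamma_gate]
        if not peaks:
            return
        # the incoming limb: azimuth closest to the back-direction
        back = -np.asarray(incoming, float)
        angles = [math.acos(float(np.clip(np.dot(p.azimuth, back), -1, 1))) for p in peaks]
        inc = int(np.argmin(angles))
        for i, p in enumerate(peaks):
            if i == inc:
                continue
            direction = self._limb_direction(p.position)
            if np.linalg.norm(direction) < 0.5:
                direction = p.azimuth
            if np.dot(direction, p.azimuth) < 0:
                direction = -direction
            d = self._measure(p.position, direction)
            # the child starts AT the node so its polyline covers the
            # junction; the peak position on the limb is its second element
            az = np.asarray(p.position, float) - node.position
            az_n = np.linalg.norm(az)
            az = az / az_n if az_n > 1e-9 else p.azimuth
            el0 = ArteryElement(position=node.position.copy(), zhat=float(p.zhat),
                                direction=az.copy(), diameter=d)
            el1 = ArteryElement(position=np.asarray(p.position, float),
                                zhat=float(p.zhat), direction=np.asarray(direction, float),
                                diameter=d)
            sources.append(_Source(element=el0, level=level + 1,
                                   spawn_node=node.node_id,
                                   grace_radius=max(az_n + 2.0, 1.5 * d),
                                   second_element=el1))

    def _track_branch(self, source: _Source, sources: list[_Source]) -> TrackedBranch:
        cfg = self.cfg
        e = source.element
        branch = TrackedBranch(elements=[e], level=source.level,
                               spawn_node=source.spawn_node)
        spawn_pos = e.position.copy()
        if source.second_element is not None:
            branch.elements.append(source.second_element)
            e = source.second_element
        grace_r = source.grace_radius
        pending: list[tuple[int, object]] = []  # (element index, PatternResult)
        cluster_dir = None  # travel direction at node-cluster entry
        cluster_pos = None
        cluster_d = 6.0
        max_steps = 600
        branch_raster = np.zeros(self.mask.shape, bool)
        # while inside a node region or a registered crossing, candidates
        # are confined to a corridor along the vessel's own axis so the path
        # can neither turn onto the other vessel nor drift off-axis
        transit = None  # (anchor position, locked direction, radius, lateral tol)

        def diameter_fn(pos, dirn):
            return self._measure(pos, dirn)

        grace_active = True
        for _ in range(max_steps):
            # the grace zone around the spawn point applies only until the
            # branch first leaves it; a path returning later is overlap
            if grace_active and np.linalg.norm(e.position - spawn_pos) > grace_r:
                grace_active = False
            in_grace = grace_active
            excl = self._exclude_fn(branch.elements, branch_raster,
                                    spawn_pos if in_grace else None, grace_r)
            # crossing transit: lock the travel direction while inside a
            # registered crossing zone so the path continues along its own
            # vessel instead of turning onto the other one
            if transit is not None and np.linalg.norm(e.position - transit[0]) > transit[2]:
                transit = None
            if transit is None:
                for c, r in self.crossings:
                    if np.linalg.norm(e.position - c) <= r:
                        transit = (c, e.direction.copy(), r + 2.0,
                                   max(3.0, min(e.diameter / 2.0, 4.0)))
                        break
            corridor = None
            if transit is not None:
                corridor = (transit[0], transit[1], transit[3])
            elif pending and cluster_dir is not None:
                corridor = (cluster_pos, cluster_dir,
                            max(3.0, min(cluster_d / 2.0, 4.0)))
            try:
                # travel is oriented within a branch (the seed spawns one
                # source per orientation), so candidates always lie in the
                # forward half-plane; a >90-degree kink at half-diameter
                # spacing is never vessel continuation, only blur fringe
                cand = sample_candidates(e, self.mask, self.fmap, self.dmap, cfg,
                                         diameter_fn=diameter_fn, exclude_fn=excl,
                                         forward_only=True, corridor=corridor)
                nxt = select_next(cand, cfg)
            except NoContinuation:
                branch.end_reason = "termination"
                break
            if nxt.zhat < cfg.stop_threshold:
                branch.end_reason = "low_feature"
                break
            # relative low-feature stop: a drop of 2.2 endpoint-decrements
            # below the branch's running level is past the vessel end (a
            # contrast gap or a deep stenosis dips by roughly one decrement
            # and must still pass)
            if len(branch.elements) >= 4:
                zs_ = [el.zhat for el in branch.elements]
                ref = float(np.percentile(zs_[:max(5, (3 * len(zs_)) // 5)], 60))
                d_ref = float(np.clip(np.median([el.diameter
                                                 for el in branch.elements]),
                                      cfg.d_min, cfg.d_max))
                drop = max(0.08, cfg.end_drop_intercept - cfg.end_drop_slope * d_ref)
                if nxt.zhat < ref - 2.2 * drop / max(self.fmap.raw_max, 1e-6):
                    branch.end_reason = "low_feature"
                    break
            # orient the (sign-ambiguous) direction along the travel step
            step_vec = nxt.position - e.position
            if np.dot(nxt.direction, step_vec) < 0:
                nxt.direction = -nxt.direction
            branch.elements.append(nxt)
            # retire the element two steps back into the branch's own
            # visited raster (rule 3: overlap with the previously detected
            # path, dilated to the local vessel radius)
            if len(branch.elements) > 2:
                old = branch.elements[-3]
                self._mark_disk(branch_raster, old.position,
                                _vessel_radius(old.diameter, cfg.psf_sigma))

            # SPD in parallel, suppressed right after spawning and near
            # already-registered nodes
            suppress = (np.linalg.norm(nxt.position - spawn_pos) <= grace_r
                        or self._near_node(nxt.position) is not None)
            det = None
            if not suppress:
                try:
                    det = detect_structure(nxt.position, nxt.diameter, nxt.direction,
                                           self.fmap, self.image, cfg)
                except ValueError:
                    det = None
            is_node_det = det is not None and det.pattern in (3, 4)
            if is_node_det:
                if not pending:
                    cluster_dir = e.direction.copy()
                    cluster_pos = e.position.copy()
                    cluster_d = e.diameter
                pending.append((len(branch.elements) - 1, det))
            cluster_done = pending and (
                not is_node_det
                or len(pending) >= 12
                or (branch.arclengths[-1] - branch.arclengths[pending[0][0]]
                    > 4.0 * max(nxt.diameter, 6.0)))
            if cluster_done:
                stopped, new_transit = self._resolve_cluster(
                    branch, pending, sources, cluster_dir)
                pending.clear()
                cluster_dir = None
                cluster_pos = None
                if new_transit is not None:
                    transit = new_transit
                if stopped:
                    branch.end_reason = "bifurcation"
                    break
            e = nxt

        else:
            branch.end_reason = "max_steps"

        if pending and branch.end_reason != "bifurcation":
            stopped, _ = self._resolve_cluster(branch, pending, sources, cluster_dir)
            if stopped:
                branch.end_reason = "bifurcation"
        if branch.end_reason != "bifurcation":
            self._finalize_termination(branch)
            if len(branch.elements) >= 2:
                node = self._add_node(branch.elements[-1].position, "termination")
                branch.end_node = node.node_id
        return branch

    def _finalize_termination(self, branch: TrackedBranch):
        """Prune low-feature trailing elements and refine the distal end.

        Z is a min-max normalized log response, so the point where the raw
        ridge response halves (the geometric end of a tube under isotropic
        blur) sits a fixed absolute decrement ln(2)/raw_range below the
        branch's local vesselness level.  Trailing elements below that
        level are blur fringe, not vessel; the endpoint is then advanced at
        1 px resolution up to the threshold crossing.
        """
        els = branch.elements
        if len(els) < 3:
            return
        cfg = self.cfg
        raw_range = max(self.fmap.raw_max, 1e-6)

        def delta(diameter: float) -> float:
            drop = max(0.08, cfg.end_drop_intercept - cfg.end_drop_slope * diameter)
            return drop / raw_range

        zs = np.array([e.zhat for e in els])
        # reference level from the head of the branch (the tail may be blur
        # fringe; the middle may be brightened by a crossing)
        ref = float(np.percentile(zs[:max(5, (3 * len(zs)) // 5)], 60))
        d_ref = float(np.clip(np.median([e.diameter for e in els]),
                              self.cfg.d_min, self.cfg.d_max))
        k = len(els) - 1
        while k > 2:
            if zs[k] >= ref - delta(d_ref):
                break
            k -= 1
        del els[k + 1:]
        # endpoint refinement at 1 px resolution along the tail direction
        # (PCA of the trailing polyline: the single element's direction-map
        # vector is unreliable inside junction or crossing blobs)
        last = els[-1]
        thr = ref - delta(d_ref)
        tail = np.array([el.position for el in els])
        s_tail = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(tail, axis=0).T))])
        sel = s_tail >= s_tail[-1] - 22.0
        direction = last.direction
        if sel.sum() >= 3:
            arr = tail[sel]
            pca = np.linalg.svd(arr - arr.mean(axis=0), full_matrices=False)[2][0]
            if np.dot(pca, tail[-1] - tail[sel][0]) < 0:
                pca = -pca
            direction = pca
        H, W = self.fmap.zhat.shape
        from scipy.ndimage import map_coordinates
        best = None
        for t in np.arange(1.0, 1.5 * max(last.diameter, 4.0), 1.0):
            p = last.position + t * direction
            if not (0 <= p[0] <= W - 1 and 0 <= p[1] <= H - 1):
                break
            z = float(map_coordinates(self.fmap.zhat, [[p[1]], [p[0]]], order=1)[0])
            if z < thr:
                break
            best = (p, z)
        if best is not None:
            els.append(ArteryElement(position=best[0], zhat=best[1],
                                     direction=direction.copy(),
                                     diameter=last.diameter))

    def _reposition_nodes(self):
        """Refine node positions from the tracked geometry.

        Detection-time node estimates lean on circle peaks near the
        junction blob and sit a few pixels downstream.  Once all incident
        branches exist, each limb's centerline is clean outside the blob;
        fitting a line to the 15 px of every incident polyline just outside
        the node region and intersecting the lines relocates the node on
        the true axis intersection.  Incident branch endpoints move with
        the node so polylines stay connected.
        """
        for node in self.nodes:
            if node.kind not in ("bifurcation", "crossing"):
                continue
            r0 = 0.75 * node.radius
            pts_dirs = []
            movers = []  # (element to move onto the node)
            for br in self.branches:
                raw = br.points
                if len(raw) < 2:
                    continue
                dmin = np.hypot(raw[:, 0] - node.position[0],
                                raw[:, 1] - node.position[1]).min()
                # only branches that actually touch the node (endpoints on
                # it, or a crossing pass-through); a neighbouring junction's
                # limbs would contribute lines through the wrong point
                if dmin > max(6.0, 0.35 * node.radius):
                    continue
                # densely resampled polyline so the ring holds enough points
                s = br.arclengths
                su = np.arange(0.0, s[-1] + 0.5, 1.0)
                pts = np.column_stack([np.interp(su, s, raw[:, 0]),
                                       np.interp(su, s, raw[:, 1])])
                dist = np.hypot(pts[:, 0] - node.position[0],
                                pts[:, 1] - node.position[1])
                # ring just outside the blob; for a through-path (crossing)
                # it spans both sides, and the PCA line is the vessel axis
                ring = (dist >= r0) & (dist <= r0 + 26.0)
                if br.spawn_node is not None and len(s) > 1:
                    # the straight node->limb chord inherits the old node's
                    # bias; use only the genuinely tracked part beyond it
                    ring &= su >= s[1] + 2.0
                # keep only ring runs contiguous with the node attachment
                # (the chord end for a spawned branch, the closest approach
                # otherwise), so far-away stretches of a winding branch
                # cannot pollute the fit
                if br.spawn_node == node.node_id and len(s) > 1:
                    base = s[1] + 2.0
                else:
                    base = su[int(np.argmin(dist))]
                idx = np.nonzero(ring)[0]
                if len(idx):
                    keep = np.zeros(len(su), bool)
                    for run in np.split(idx, np.where(np.diff(idx) > 1)[0] + 1):
                        gap = min(abs(su[run[0]] - base),
                                  abs(su[run[-1]] - base))
                        if gap <= r0 + 12.0:
                            keep[run] = True
                    ring = keep
                if ring.sum() >= 14:
                    # quadratic fit along arclength, evaluated at the ring
                    # end nearest the node: a straight PCA line extrapolated
                    # across a curved limb misses laterally by kappa*L^2/2
                    t = su[ring]
                    arr = pts[ring]
                    t0 = t[int(np.argmin(dist[ring]))]
                    tc = t - t.mean()
                    cx = np.polyfit(tc, arr[:, 0], 2)
                    cy = np.polyfit(tc, arr[:, 1], 2)
                    te = t0 - t.mean()
                    point = np.array([np.polyval(cx, te), np.polyval(cy, te)])
                    tang = np.array([np.polyval(np.polyder(cx), te),
                                     np.polyval(np.polyder(cy), te)])
                    nt = np.linalg.norm(tang)
                    if nt < 1e-9:
                        continue
                    pts_dirs.append((point, tang / nt))
                elif ring.sum() >= 6:
                    # short rings: a straight fit is more stable
                    arr = pts[ring]
                    centre = arr.mean(axis=0)
                    direction = np.linalg.svd(arr - centre,
                                              full_matrices=False)[2][0]
                    pts_dirs.append((centre, direction))
                if br.end_node == node.node_id and len(br.elements) >= 1:
                    movers.append(br.elements[-1])
                if br.spawn_node == node.node_id and len(br.elements) >= 1:
                    movers.append(br.elements[0])
            if len(pts_dirs) >= 2:
                new = _ls_line_intersection([p for p, _ in pts_dirs],
                                            [d_ for _, d_ in pts_dirs],
                                            node.position)
                if np.linalg.norm(new - node.position) <= node.radius:
                    node.position = new
            for el in movers:
                el.position = node.position.copy()

    def _refine_branch_diameters(self, branch: TrackedBranch):
        """Re-measure diameters densely along the final polyline, replace the
        end margins (where the transversal profile is contaminated by the
        tip or junction) with a local linear extrapolation, apply the PSF
        curvature correction, and write the result back to the elements."""
        els = branch.elements
        s_el = branch.arclengths
        L = s_el[-1]
        if L < 6 or len(els) < 3:
            return
        pts = branch.points
        su = np.arange(0.0, L + 0.5, 1.0)
        xu = np.interp(su, s_el, pts[:, 0])
        yu = np.interp(su, s_el, pts[:, 1])
        tang = np.gradient(np.column_stack([xu, yu]), axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        d = np.array([self._measure((x, y), t)
                      for x, y, t in zip(xu, yu, tang)])
        n = len(d)
        # measurements inside any junction or crossing zone are meaningless
        # (the transversal profile spans the whole blob): mask them and fill
        # by interpolation from the clean stretches on either side
        bad = np.zeros(n, bool)
        zones = [(nd.position, 1.1 * nd.radius) for nd in self.nodes
                 if nd.kind in ("bifurcation", "crossing")]
        zones += [(c, r) for c, r in self.crossings]
        for cpos, cr in zones:
            bad |= np.hypot(xu - cpos[0], yu - cpos[1]) <= cr
        if bad.any() and not bad.all():
            good = ~bad
            d = np.interp(su, su[good], d[good])
        # junction blobs and blur caps contaminate the transversal profile:
        # clean impulsive outliers against a rolling median, then extend the
        # nearest clean interior value over the end margins (the node->limb
        # chord plus half a diameter at a spawning junction; half a local
        # diameter at any other end)
        med = ndimage.median_filter(d, size=min(11, n | 1), mode='nearest')
        d = np.where(np.abs(d - med) > 1.5, med, d)
        if branch.spawn_node is not None:
            chord = s_el[1] if len(s_el) > 1 else 0.0
            m0 = int(round(chord + med[min(n - 1, int(chord) + 3)] / 2.0))
        else:
            m0 = 0
        m1 = max(2, int(round(med[-1] / 2.0)))
        m0 = min(m0, (2 * n) // 3)
        m1 = min(m1, max(n - m0 - 3, 2))
        if m0 > 0 and m0 < n:
            d[:m0] = d[m0]
        if 0 < m1 < n:
            d[n - m1:] = d[n - m1 - 1]
        d = correct_diameter_profile(d, su, self.cfg.psf_sigma)
        d = np.clip(d, 1.0, 25.0)
        for el, s in zip(els, s_el):
            el.diameter = float(np.interp(s, su, d))

    def _handle_bifurcation(self, branch: TrackedBranch, det_idx: int, detections,
                            sources: list[_Source]) -> bool:
        """End the branch at the refined node and spawn the outgoing limbs."""
        if not isinstance(detections, (list, tuple)):
            detections = [detections]
        detection = detections[0]
        pos = self._node_position(detections)
        if self._near_node(pos) is not None:
            return False
        node = self._add_node(pos, "bifurcation", detection.membership,
                              radius=detection.template.radius)
        # truncate the branch at the element nearest the node and close the
        # polyline on the node itself
        pts = branch.points
        k = int(np.argmin(np.hypot(pts[:, 0] - pos[0], pts[:, 1] - pos[1])))
        k = max(k, 1)
        del branch.elements[k + 1:]
        last = branch.elements[-1]
        if np.linalg.norm(last.position - pos) > 0.5:
            branch.elements.append(ArteryElement(position=np.asarray(pos, float),
                                                 zhat=last.zhat,
                                                 direction=last.direction.copy(),
                                                 diameter=last.diameter))
        branch.end_node = node.node_id
        if len(branch.elements) >= 2:
            incoming = branch.elements[-1].position - branch.elements[max(0, len(branch.elements) - 4)].position
        else:
            incoming = branch.elements[-1].direction
        n = np.linalg.norm(incoming)
        incoming = incoming / n if n > 1e-9 else branch.elements[-1].direction
        self._spawn_children(node, detection, incoming, branch.level, sources)
        return True

    def _handle_crossing(self, detections, cluster_dir=None):
        if not isinstance(detections, (list, tuple)):
            detections = [detections]
        detection = detections[0]
        pos = self._node_position(detections)
        if self._near_node(pos, radius=14.0) is not None:
            return None
        node = self._add_node(pos, "crossing", detection.membership,
                              radius=detection.template.radius)
        radius = detection.template.radius + 2.0
        self.crossings.append((node.position, radius))
        if cluster_dir is not None:
            # transit corridor for the rest of this branch's pass-through,
            # anchored on the crossing along the pre-cluster direction
            return (node.position, np.asarray(cluster_dir, float), radius + 2.0,
                    max(3.0, min(detection.template.radius / 4.0, 4.0)))
        return None

    # -- top level -------------------------------------------------------
    def run(self, seed: tuple[float, float] | None = None) -> ArteryTree:
        cfg = self.cfg
        if seed is not None:
            self.seed = (float(seed[0]), float(seed[1]))
        tree = ArteryTree(seed=self.seed, config=cfg.to_dict())
        if self.seed is None or not self.mask.any():
            log.warning("empty vesselness map: returning empty tree")
            tree.nodes = self.nodes
            return tree
        seed_pos = np.array(self.seed, float)
        x, y = int(seed_pos[0]), int(seed_pos[1])
        direction = self.dmap.v2[y, x]
        if np.linalg.norm(direction) < 0.5:
            direction = np.array([1.0, 0.0])
        d0 = self._measure(seed_pos, direction)
        z0 = float(self.fmap.zhat[y, x])
        sources: list[_Source] = []
        for sgn in (1.0, -1.0):
            el = ArteryElement(position=seed_pos.copy(), zhat=z0,
                               direction=sgn * np.asarray(direction, float),
                               diameter=d0)
            sources.append(_Source(element=el, level=1, spawn_node=None,
                                   grace_radius=2.0 * d0))
        max_branches = 60
        while sources and len(self.branches) < max_branches:
            src = sources.pop()
            branch = self._track_branch(src, sources)
            if len(branch.elements) < 2:
                continue
            self._refine_branch_diameters(branch)
            self.visited.mark_branch(branch)
            self.branches.append(branch)
            log.info("branch %d: %d elements, %.1f px, end=%s",
                     len(self.branches), len(branch.elements), branch.length,
                     branch.end_reason)
        self._reposition_nodes()
        self._reposition_nodes()  # second pass: endpoints moved with nodes
        tree.branches = self.branches
        tree.nodes = self.nodes
        return tree


def track_tree(image: np.ndarray, cfg: RunConfig | None = None, maps=None,
               seed: tuple[float, float] | None = None) -> ArteryTree:
    """Track the full artery tree of an image (preprocessing included).

    ``seed`` overrides the automatically detected starting point."""
    return Tracker(image, cfg, maps=maps).run(seed=seed)


# ---------------------------------------------------------------------------
# stenosis quantification
# ---------------------------------------------------------------------------

@dataclass
class StenosisReport:
    start_arclength: float
    end_arclength: float
    min_diameter: float        # L_r
    reference_diameter: float  # L_m, mean diameter of the nonstenotic part
    percent_length_stenosis: float

    @classmethod
    def from_profile(cls, s, d, lo, hi, l_m):
        l_r = float(np.min(d[lo:hi + 1]))
        pct = (1.0 - l_r / l_m) * 100.0
        return cls(float(s[lo]), float(s[hi]), l_r, float(l_m), float(pct))


def quantify_stenosis(branch: TrackedBranch, grade_threshold: float = 25.0,
                      min_samples: int = 10) -> list[StenosisReport]:
    """Locate stenoses on one tracked branch and grade them by
    %-LENGTH = (1 - L_r / L_m) * 100.

    L_m is the mean diameter of the nonstenotic part, L_r the minimal
    diameter inside the lesion.  A lesion's extent is the maximal run where
    the running %-LENGTH exceeds the lowest visual grade (25%); runs are
    found iteratively so L_m excludes the lesion itself.
    """
    d = branch.diameters
    s = branch.arclengths
    if len(d) < min_samples:
        return []
    l_m = float(np.mean(d))
    for _ in range(4):
        pct = (1.0 - d / l_m) * 100.0
        out = pct < grade_threshold
        if not (~out).any() or out.all():
            break
        new_lm = float(np.mean(d[out]))
        if abs(new_lm - l_m) < 1e-9:
            l_m = new_lm
            break
        l_m = new_lm
    pct = (1.0 - d / l_m) * 100.0
    inside = pct >= grade_threshold
    reports = []
    i = 0
    n = len(d)
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            reports.append(StenosisReport.from_profile(s, d, i, j, l_m))
            i = j + 1
        else:
            i += 1
    return reports


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    evl_percent: float     # matched truth length / total truth length
    ir_percent: float      # matched tracked length / total tracked length
    das_percent: float     # truth segments with >= 50% length matched
    e0: float              # mean perpendicular centerline error (px)
    ed: float              # mean absolute diameter error (px)
    e0_nodes: float        # e0 restricted to elements near truth nodes
    truth_length: float
    tracked_length: float
    pattern_rates: dict    # per-class node identification rates
    empty: bool = False


def _truth_dense(truth, step=0.25):
    pts, dia, tang, seg_id = [], [], [], []
    for k, seg in enumerate(truth.segments):
        p = seg.points
        s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(p, axis=0).T))])
        su = np.arange(0.0, s[-1] + step / 2, step)
        x = np.interp(su, s, p[:, 0])
        y = np.interp(su, s, p[:, 1])
        d = np.interp(su, s, seg.diameters)
        t = np.gradient(np.column_stack([x, y]), axis=0)
        t /= np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
        pts.append(np.column_stack([x, y]))
        dia.append(d)
        tang.append(t)
        seg_id.append(np.full(len(su), k))
    return (np.concatenate(pts), np.concatenate(dia), np.concatenate(tang),
            np.concatenate(seg_id))


def _perp_distance(query_pts, truth_pts, truth_tangents, tree_kd):
    d, idx = tree_kd.query(query_pts)
    off = query_pts - truth_pts[idx]
    t = truth_tangents[idx]
    along = np.sum(off * t, axis=1)
    perp = off - along[:, None] * t
    return np.linalg.norm(perp, axis=1), idx


def evaluate(tree: ArteryTree, truth, cfg: RunConfig | None = None) -> MetricsReport:
    """Compare a tracked tree with phantom ground truth.

    A point matches when it lies within ``tau_match`` of the other
    polyline.  EVL% measures truth coverage, IR% tracked correctness, DAS%
    the fraction of truth segments with at least half their length covered.
    e0/ed are mean perpendicular centerline and diameter errors over
    tracked elements; ``e0_nodes`` restricts e0 to elements within one
    local diameter of a truth node.
    """
    cfg = cfg or RunConfig()
    tau = cfg.tau_match
    t_pts, t_dia, t_tan, t_seg = _truth_dense(truth)
    truth_kd = cKDTree(t_pts)
    step = 0.25
    a_pts = tree.dense_points(step)
    truth_len = truth.total_length
    if len(a_pts) == 0:
        return MetricsReport(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, truth_len, 0.0, {},
                             empty=True)
    alg_kd = cKDTree(a_pts)

    d_t2a, _ = alg_kd.query(t_pts)    # truth -> algorithm
    matched_truth = d_t2a <= tau
    evl = 100.0 * matched_truth.mean()

    d_a2t, _ = truth_kd.query(a_pts)  # algorithm -> truth
    ir = 100.0 * (d_a2t <= tau).mean()

    seg_ids = np.unique(t_seg)
    das_hits = sum(matched_truth[t_seg == k].mean() >= 0.5 for k in seg_ids)
    das = 100.0 * das_hits / len(seg_ids)

    elements = [e for b in tree.branches for e in b.elements]
    e_pts = np.array([e.position for e in elements], float)
    e_dia = np.array([e.diameter for e in elements], float)
    perp, idx = _perp_distance(e_pts, t_pts, t_tan, truth_kd)
    e0 = float(perp.mean())
    # diameter error against the nearest point of each truth segment that
    # passes within the match tolerance: junction points are shared by all
    # incident limbs, and the error there is judged against the
    # best-matching limb (elsewhere exactly one segment qualifies, reducing
    # to plain nearest-point comparison)
    kq = min(32, len(t_pts))
    dk, ik = truth_kd.query(e_pts, k=kq)
    dk = np.atleast_2d(dk)
    ik = np.atleast_2d(ik)
    ed_vals = np.empty(len(e_pts))
    for i in range(len(e_pts)):
        # near-ties with the nearest segment also qualify: a shared junction
        # point sits a couple of pixels from each incident centerline
        lim = max(dk[i, 0] + 3.0, tau)
        best = np.inf
        seen: set[int] = set()
        for dist_j, idx_j in zip(dk[i], ik[i]):
            seg_j = int(t_seg[idx_j])
            if dist_j > lim or seg_j in seen:
                continue  # only each segment's nearest point counts
            seen.add(seg_j)
            best = min(best, abs(e_dia[i] - t_dia[idx_j]))
        ed_vals[i] = best if np.isfinite(best) else abs(e_dia[i] - t_dia[ik[i, 0]])
    ed = float(ed_vals.mean())

    node_pos = np.array([p for p, _ in truth.nodes], float)
    if len(node_pos):
        nd = cKDTree(node_pos).query(e_pts)[0]
        near = nd <= np.maximum(e_dia, 1.0)
        e0_nodes = float(perp[near].mean()) if near.any() else 0.0
    else:
        e0_nodes = 0.0

    # node identification per class
    rates = {}
    for kind in ("termination", "bifurcation", "crossing"):
        tn = [p for p, t in truth.nodes if t == kind]
        if not tn:
            continue
        found = 0
        det = [n.position for n in tree.nodes if n.kind == kind]
        for p in tn:
            if det and np.min(np.hypot(*(np.array(det) - np.array(p)).T)) <= 8.0:
                found += 1
        rates[kind] = {"detected": found, "total": len(tn),
                       "rate_percent": 100.0 * found / len(tn)}

    return MetricsReport(evl_percent=float(evl), ir_percent=float(ir),
                         das_percent=float(das), e0=e0, ed=ed, e0_nodes=e0_nodes,
                         truth_length=float(truth_len),
                         tracked_length=float(tree.total_length),
                         pattern_rates=rates)
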