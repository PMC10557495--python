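"""Synthetic paired artery/vein vascular phantoms.

Generates two intertwined binary-tree vessel systems with Murray-law radius
tapering, optional near-contact adhesions between the trees, companion
"bronchus" tubes running parallel to arterial branches (the anatomical prior
that pulmonary arteries accompany the bronchial tree), and a pseudo-CT
intensity model.  Every phantom carries its ground-truth centerlines and
voxel labels, so the topology, classification, and optimization stages can be
validated with known truth.

Conventions: physical coordinates are mm in (z, y, x) order; grids are
0-based (z, y, x); trees taper by r_parent**g = r1**g + r2**g with g = 3
(Murray's law) by default; branch length is k * radius with k uniform in
[4, 10] so trees stay tubular at every scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import log, perpendicular_frame, segment_segment_distance, unit
from .config import PhantomConfig


class GenerationError(RuntimeError):
    """Phantom geometry could not be realized under the configured constraints."""


@dataclass
class TreeSpec:
    """A branching tube tree: node positions (mm) + radii, parent->child edges."""

    nodes: list[tuple[np.ndarray, float]]
    edges: list[tuple[int, int]]
    class_label: str  # "artery" | "vein"

    @property
    def branch_count(self) -> int:
        return len(self.edges)

    @property
    def root(self) -> int:
        children = {c for _, c in self.edges}
        roots = [i for i in range(len(self.nodes)) if i not in children]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def leaves(self) -> list[int]:
        parents = {p for p, _ in self.edges}
        return [i for i in range(len(self.nodes)) if i not in parents]

    def segments(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        """(p0, p1, radius) per edge; the edge radius is the child node's."""
        return [
            (self.nodes[p][0], self.nodes[c][0], self.nodes[c][1]) for p, c in self.edges
        ]

    def validate(self, taper_exponent: float | None = None) -> None:
        n = len(self.nodes)
        if len(self.edges) != n - 1:
            raise ValueError("tree must be connected and acyclic")
        _ = self.root
        children: dict[int, list[int]] = {}
        for p, c in self.edges:
            children.setdefault(p, []).append(c)
            if self.nodes[c][1] > self.nodes[p][1] + 1e-9:
                raise ValueError("child radius exceeds parent radius")
        if taper_exponent is not None:
            g = taper_exponent
            for p, kids in children.items():
                if len(kids) == 2:
                    rp = self.nodes[p][1]
                    r1, r2 = self.nodes[kids[0]][1], self.nodes[kids[1]][1]
                    if abs(rp**g - (r1**g + r2**g)) > 1e-6 * rp**g:
                        raise ValueError("bifurcation radii violate the taper law")


@dataclass
class PhantomVolume:
    """Rasterized phantom: mask, pseudo-CT intensity, truth labels, centerlines."""

    mask: np.ndarray          # bool (z, y, x)
    intensity: np.ndarray     # float32, HU-like
    truth_labels: np.ndarray  # uint8 {0 background, 1 artery, 2 vein}
    spacing: tuple[float, float, float]
    centerlines: dict[str, list[tuple[np.ndarray, np.ndarray]]]  # label -> [(points mm, radii)]
    bronchus_mask: np.ndarray | None = None
    adhesion_sites: list[np.ndarray] = field(default_factory=list)

    def centerline_points_vox(self, label: str) -> np.ndarray:
        """All truth centerline points of one tree, in voxel coordinates."""
        sp = np.asarray(self.spacing, float)
        pts = [p for p, _ in self.centerlines[label]]
        return np.concatenate(pts, axis=0) / sp


def _rotated(axis: np.ndarray, polar_deg: float, azimuth: float) -> np.ndarray:
    u, v = perpendicular_frame(axis)
    th = np.deg2rad(polar_deg)
    return unit(
        np.cos(th) * unit(axis)
        + np.sin(th) * (np.cos(azimuth) * u + np.sin(azimuth) * v)
    )


def _steer_inside(pos, direction, length, lo, hi, radius):
    """Bend a proposed segment back toward the box center until it fits."""
    d = unit(direction)
    center = (lo + hi) / 2.0
    L = float(length)
    for _ in range(10):
        end = pos + L * d
        if np.all(end - radius >= lo) and np.all(end + radius <= hi):
            return d, L
        d = unit(d + 0.4 * unit(center - pos))
    while L > 3.0 * radius:
        L *= 0.85
        end = pos + L * d
        if np.all(end - radius >= lo) and np.all(end + radius <= hi):
            return d, L
    return None, None


def _collides(p0, p1, r, others, min_gap, skip_touching_at=None):
    for q0, q1, rq in others:
        if skip_touching_at is not None and (
            np.allclose(q0, skip_touching_at) or np.allclose(q1, skip_touching_at)
        ):
            continue
        if segment_segment_distance(p0, p1, q0, q1) < r + rq + min_gap:
            return True
    return False


def generate_tree(
    depth: int,
    root_radius: float,
    taper_exponent: float = 3.0,
    angle_range: tuple[float, float] = (20.0, 50.0),
    seed: int = 0,
    *,
    root_pos=(5.0, 40.0, 40.0),
    root_dir=(1.0, 0.0, 0.0),
    length_factor_range: tuple[float, float] = (4.0, 10.0),
    asymmetry: float = 0.0,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    avoid: list[tuple[np.ndarray, np.ndarray, float]] | None = None,
    min_gap: float = 2.0,
    class_label: str = "artery",
    max_tries: int = 30,
    tip_clearance: float = 3.0,
) -> TreeSpec:
    """Grow a binary tube tree with 2**depth leaves.

    Child radii satisfy r_parent**g = r1**g + r2**g exactly (g = taper_exponent);
    growth is collision-aware: every accepted segment keeps a surface gap of at
    least ``min_gap`` from non-adjacent own segments and from all ``avoid``
    segments (used to interleave the second tree with the first).
    Deterministic for a fixed seed and parameter set.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if root_radius <= 0:
        raise ValueError("root_radius must be positive")
    rng = np.random.default_rng(seed)
    avoid = avoid or []
    nodes: list[tuple[np.ndarray, float]] = [(np.asarray(root_pos, float), float(root_radius))]
    edges: list[tuple[int, int]] = []
    own_segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    g = float(taper_exponent)

    def grow(parent_idx: int, direction: np.ndarray, radius: float, level: int) -> None:
        pos = nodes[parent_idx][0]
        for attempt in range(max_tries):
            k = rng.uniform(*length_factor_range)
            if attempt == 0:
                d = unit(direction)
            else:
                d = _rotated(direction, rng.uniform(0.0, 25.0), rng.uniform(0.0, 2 * np.pi))
            L = k * radius
            if bounds is not None:
                d2, L2 = _steer_inside(pos, d, L, bounds[0], bounds[1], radius)
                if d2 is None:
                    continue
                d, L = d2, L2
            end = pos + L * d
            obstacles = avoid + [
                s for s in own_segments
                if not (np.allclose(s[0], pos) or np.allclose(s[1], pos))
            ]
            if _collides(pos, end, radius, obstacles, min_gap):
                continue
            if level == depth and tip_clearance > 0:
                # terminal branches must end in free space (distal vessels end
                # in parenchyma): the tip's forward extension stays clear of
                # every other vessel, so tube ends never face another vessel
                ext = end + tip_clearance * radius * d
                if _collides(end, ext, radius, obstacles, min_gap):
                    continue
            nodes.append((end, radius))
            child_idx = len(nodes) - 1
            edges.append((parent_idx, child_idx))
            own_segments.append((pos, end, radius))
            if level <= depth:
                f = float(np.clip(0.5 + asymmetry * rng.uniform(-0.5, 0.5), 0.25, 0.75))
                r1 = radius * f ** (1.0 / g)
                r2 = radius * (1.0 - f) ** (1.0 / g)
                phi = rng.uniform(0.0, 2 * np.pi)
                th1, th2 = rng.uniform(*angle_range, size=2)
                jitter = rng.uniform(-0.6, 0.6)
                grow(child_idx, _rotated(d, th1, phi), r1, level + 1)
                grow(child_idx, _rotated(d, th2, phi + np.pi + jitter), r2, level + 1)
            return
        raise GenerationError(
            f"could not place a level-{level} branch (radius {radius:.2f} mm) "
            f"after {max_tries} attempts; geometry too crowded"
        )

    grow(0, np.asarray(root_dir, float), float(root_radius), 1)
    tree = TreeSpec(nodes=nodes, edges=edges, class_label=class_label)
    tree.validate(taper_exponent=g)
    return tree


def entangle(
    artery: TreeSpec,
    vein: TreeSpec,
    min_gap: float,
    n_adhesions: int,
    seed: int = 0,
    overlap: float = 0.5,
) -> tuple[TreeSpec, TreeSpec, list[np.ndarray]]:
    """Create ``n_adhesions`` near-contact sites between the two trees.

    A mid-branch control point of a chosen vein branch is translated toward the
    nearest artery branch until the centerlines are r_a + r_v - overlap apart
    (surfaces overlapping by ``overlap`` mm, about one voxel).  Returns copies
    of both trees and the adhesion site coordinates.
    """
    artery = TreeSpec([(p.copy(), r) for p, r in artery.nodes], list(artery.edges), artery.class_label)
    vein = TreeSpec([(p.copy(), r) for p, r in vein.nodes], list(vein.edges), vein.class_label)
    sites: list[np.ndarray] = []
    if n_adhesions == 0:
        return artery, vein, sites
    rng = np.random.default_rng(seed)
    a_segs = artery.segments()
    candidates = list(range(1, len(vein.edges)))  # skip the trunk edge
    rng.shuffle(candidates)
    for edge_idx in candidates:
        if len(sites) >= n_adhesions:
            break
        p_idx, c_idx = vein.edges[edge_idx]
        p0, p1 = vein.nodes[p_idx][0], vein.nodes[c_idx][0]
        r_v = vein.nodes[c_idx][1]
        mid = (p0 + p1) / 2.0
        # nearest artery segment to the midpoint
        best = None
        for q0, q1, r_a in a_segs:
            dd = segment_segment_distance(mid, mid, q0, q1)
            if best is None or dd < best[0]:
                best = (dd, q0, q1, r_a)
        assert best is not None
        dist, q0, q1, r_a = best
        # closest point on that artery segment
        dq = q1 - q0
        t = np.clip((mid - q0) @ dq / (dq @ dq), 0.0, 1.0)
        cpt = q0 + t * dq
        target = max(r_a + r_v - overlap, 0.1)
        if dist <= target:
            continue  # already touching; unexpected under collision-aware growth
        mid_new = cpt + (mid - cpt) * (target / dist)
        vein.nodes.append((mid_new, r_v))
        m_idx = len(vein.nodes) - 1
        vein.edges[edge_idx] = (p_idx, m_idx)
        vein.edges.append((m_idx, c_idx))
        sites.append(mid_new.copy())
    if len(sites) < n_adhesions:
        raise GenerationError(
            f"only {len(sites)} of {n_adhesions} adhesions feasible for this geometry"
        )
    return artery, vein, sites


def _paint_capsule(field_arr, p0, p1, radius, spacing, shape, strict_bounds=True):
    """Min-reduce the capsule's signed surface distance into ``field_arr``."""
    sp = np.asarray(spacing, float)
    lo_mm = np.minimum(p0, p1) - radius - 1.5 * sp
    hi_mm = np.maximum(p0, p1) + radius + 1.5 * sp
    lo = np.floor(lo_mm / sp).astype(int)
    hi = np.ceil(hi_mm / sp).astype(int) + 1
    if strict_bounds and (np.any(lo_mm < -0.5 * sp) or np.any(hi_mm > (np.asarray(shape) - 0.5) * sp)):
        raise GenerationError("tree geometry exceeds the volume bounds")
    lo = np.clip(lo, 0, shape)
    hi = np.clip(hi, 0, shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) * sp[i] for i in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip((pts - p0) @ d / L2, 0.0, 1.0)
        dist = np.linalg.norm(pts - (p0 + t[..., None] * d), axis=-1)
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    np.minimum(field_arr[sl], dist - radius, out=field_arr[sl])


def rasterize(
    trees: list[TreeSpec],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    companion_bronchi: bool = True,
    seed: int = 0,
    config: PhantomConfig | None = None,
) -> PhantomVolume:
    """Rasterize tube trees into a mask + pseudo-CT volume with truth labels.

    Each edge is painted as a capsule of its radius.  With companion bronchi, a
    parallel air-like tube (offset ~1.5x radius, radius ~0.8x) accompanies every
    arterial branch thinner than the configured threshold; bronchus voxels never
    overwrite vessel voxels.  Intensities are Gaussian around the class means.
    """
    cfg = config or PhantomConfig()
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, float)
    rng = np.random.default_rng(seed)
    fields = {}
    for tree in trees:
        f = fields.setdefault(tree.class_label, np.full(shape, np.inf, dtype=np.float64))
        for p0, p1, r in tree.segments():
            _paint_capsule(f, p0, p1, r, sp, shape)
    sd_a = fields.get("artery", np.full(shape, np.inf))
    sd_v = fields.get("vein", np.full(shape, np.inf))
    mask = (sd_a <= 0.0) | (sd_v <= 0.0)
    truth = np.zeros(shape, dtype=np.uint8)
    truth[mask & (sd_a <= sd_v)] = 1
    truth[mask & (sd_a > sd_v)] = 2

    bronchus_mask = None
    if companion_bronchi:
        sd_b = np.full(shape, np.inf, dtype=np.float64)
        for tree in trees:
            if tree.class_label != "artery":
                continue
            for p0, p1, r in tree.segments():
                if r >= cfg.companion_max_radius:
                    continue
                axis = p1 - p0
                u, v = perpendicular_frame(axis)
                phi = rng.uniform(0.0, 2 * np.pi)
                offset = cfg.companion_offset_factor * r * (np.cos(phi) * u + np.sin(phi) * v)
                _paint_capsule(
                    sd_b, p0 + offset, p1 + offset, cfg.companion_radius_factor * r,
                    sp, shape, strict_bounds=False,
                )
        bronchus_mask = (sd_b <= 0.0) & ~mask

    intensity = cfg.parenchyma_mean + cfg.noise_sigma * rng.standard_normal(shape)
    intensity[mask] = cfg.vessel_mean + cfg.noise_sigma * rng.standard_normal(int(mask.sum()))
    if cfg.artery_shift != 0.0:
        art = truth == 1
        intensity[art] += cfg.artery_shift
    if bronchus_mask is not None:
        nb = int(bronchus_mask.sum())
        intensity[bronchus_mask] = cfg.bronchus_mean + cfg.noise_sigma * rng.standard_normal(nb)

    centerlines: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    step = 0.5 * float(sp.min())
    for tree in trees:
        polys = centerlines.setdefault(tree.class_label, [])
        for p0, p1, r in tree.segments():
            n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1)
            t = np.linspace(0.0, 1.0, n)
            pts = p0 + t[:, None] * (p1 - p0)
            polys.append((pts, np.full(n, r)))

    return PhantomVolume(
        mask=mask,
        intensity=intensity.astype(np.float32),
        truth_labels=truth,
        spacing=tuple(float(s) for s in sp),
        centerlines=centerlines,
        bronchus_mask=bronchus_mask,
    )


def make_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[PhantomVolume, TreeSpec, TreeSpec]:
    """Generate an artery tree + vein tree pair and rasterize them.

    The two trees start from laterally offset roots near one face and grow into
    the same box, interleaved by collision-aware growth; adhesions (if any) are
    then pulled in explicitly so their locations are known ground truth.
    Retries with derived sub-seeds if a geometry cannot be realized.
    """
    cfg = config or PhantomConfig()
    sp = np.asarray(cfg.spacing, float)
    extent = (np.asarray(cfg.shape) - 1) * sp
    margin = cfg.root_radius + 2.0 * sp.max()
    lo = np.full(3, 0.0) + margin
    hi = extent - margin
    last_err: Exception | None = None
    for attempt in range(20):
        s = (seed * 131 + attempt * 7919) % (2**31 - 1)
        try:
            artery = generate_tree(
                cfg.depth, cfg.root_radius, cfg.taper_exponent, cfg.angle_range,
                seed=s,
                root_pos=(margin, 0.42 * extent[1], 0.5 * extent[2]),
                root_dir=(1.0, 0.12, 0.0),
                length_factor_range=cfg.length_factor_range,
                asymmetry=cfg.asymmetry, bounds=(lo, hi),
                min_gap=cfg.min_gap, class_label="artery",
            )
            vein = generate_tree(
                cfg.depth, cfg.root_radius, cfg.taper_exponent, cfg.angle_range,
                seed=s + 1,
                root_pos=(margin, 0.58 * extent[1], 0.5 * extent[2]),
                root_dir=(1.0, -0.12, 0.0),
                length_factor_range=cfg.length_factor_range,
                asymmetry=cfg.asymmetry, bounds=(lo, hi),
                avoid=artery.segments() + _tip_extensions(artery),
                min_gap=cfg.min_gap, class_label="vein",
            )
            if cfg.n_adhesions > 0:
                artery, vein, sites = entangle(
                    artery, vein, cfg.min_gap, cfg.n_adhesions, seed=s + 2
                )
            else:
                sites = []
            vol = rasterize(
                [artery, vein], cfg.shape, cfg.spacing,
                companion_bronchi=cfg.companion_bronchi, seed=s + 3, config=cfg,
            )
            vol.adhesion_sites = sites
            return vol, artery, vein
        except GenerationError as e:  # crowded draw; retry with a derived seed
            last_err = e
    raise GenerationError(f"phantom generation failed after retries: {last_err}")


def _tip_extensions(tree: TreeSpec, factor: float = 3.0):
    """Forward-extension pseudo-segments of every leaf branch (kept clear so
    the second tree never parks in front of the first tree's tips)."""
    parents = {p for p, _ in tree.edges}
    segs = []
    for p, c in tree.edges:
        if c not in parents:
            p0, _ = tree.nodes[p]
            p1, r = tree.nodes[c]
            d = unit(p1 - p0)
            segs.append((p1, p1 + factor * r * d, r))
    return segs


def truth_graph(trees: list[TreeSpec], spacing: float, flip_noise: float = 0.0, seed: int = 0):
    """Build a ground-truth TopologyGraph directly from tree specs.

    Particles are placed every ~1 voxel along each edge and labeled by the
    tree's class; useful for exercising the optimizer in isolation from image
    processing.  ``flip_noise`` is consumed by the oracle classifier, not here.
    """
    from .topology import Particle, TopologyGraph

    particles: list[Particle] = []
    edges: list[tuple[int, int]] = []
    roots: list[int] = []
    truth: list[int] = []
    for tree in trees:
        node_pid: dict[int, int] = {}
        label = 1 if tree.class_label == "artery" else 2
        root_pos, root_r = tree.nodes[tree.root]
        pid = len(particles)
        particles.append(Particle(
            position=root_pos / spacing, scale=root_r / spacing,
            orientation=np.array([1.0, 0.0, 0.0]), intensity=0.0,
        ))
        truth.append(label)
        node_pid[tree.root] = pid
        roots.append(pid)
        for p, c in _bfs_edges(tree):
            p0, r0 = tree.nodes[p]
            p1, r1 = tree.nodes[c]
            L = float(np.linalg.norm(p1 - p0))
            n_steps = max(1, int(round(L / spacing)))
            prev = node_pid[p]
            direction = unit(p1 - p0)
            for k in range(1, n_steps + 1):
                pos = p0 + (k / n_steps) * (p1 - p0)
                pid = len(particles)
                particles.append(Particle(
                    position=pos / spacing, scale=r1 / spacing,
                    orientation=direction, intensity=0.0,
                ))
                truth.append(label)
                edges.append((prev, pid))
                prev = pid
            node_pid[c] = prev
    graph = TopologyGraph.from_particles(particles, edges, roots)
    graph.truth = np.asarray(truth, dtype=np.uint8)
    return graph


def _bfs_edges(tree: TreeSpec):
    children: dict[int, list[int]] = {}
    for p, c in tree.edges:
        children.setdefault(p, []).append(c)
    queue = [tree.root]
    while queue:
        n = queue.pop(0)
        for c in children.get(n, []):
            yield n, c
            queue.append(c)
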