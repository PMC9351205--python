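"""Airway-tree segmentation, skeletonization and landmark extraction.

The airway is segmented by adaptive region growing from a seed inside the
trachea, thinned to a one-voxel centerline, and searched for the four
anatomical landmarks: the tree root (top of the trachea), the carina
("center" point, where the trachea bifurcates) and the distal point of
each main bronchus ("left"/"right" points).

Orientation convention (see :mod:`lunggraph.volume`): superior = decreasing
z index, patient-left = increasing x index.  The landmark-search rules
(root = most superior endpoint, carina = branch point nearest the root,
left/right = geodesically farthest point of each side subtree) are a
reconstruction of the anatomical definitions; they are not taken from any
published search algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from lunggraph.roles import NodeRole
from lunggraph.volume import CTVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class TracheaNotFoundError(ValueError):
    pass


class CarinaNotFoundError(ValueError):
    pass


class AirwayLeakError(RuntimeError):
    pass


@dataclass
class BinaryMask:
    """Boolean 3D field aligned to its source CT."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass
class Skeleton:
    """Centerline voxels with their 26-connectivity adjacency graph."""

    graph: nx.Graph
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def points(self) -> list[tuple[int, int, int]]:
        return list(self.graph.nodes)

    def degree(self, point: tuple[int, int, int]) -> int:
        return int(self.graph.degree[point])

    @property
    def endpoints(self) -> list[tuple[int, int, int]]:
        return [p for p, d in self.graph.degree if d <= 1]

    @property
    def branch_points(self) -> list[tuple[int, int, int]]:
        return [p for p, d in self.graph.degree if d >= 3]


@dataclass
class LandmarkSet:
    """The four airway landmark voxels."""

    root: tuple[int, int, int]
    center: tuple[int, int, int]
    left: tuple[int, int, int]
    right: tuple[int, int, int]

    def as_dict(self) -> dict[NodeRole, tuple[int, int, int]]:
        return {
            NodeRole.ROOT: self.root,
            NodeRole.CENTER: self.center,
            NodeRole.LEFT: self.left,
            NodeRole.RIGHT: self.right,
        }

    def to_json(self) -> dict:
        return {k.value.lower(): list(map(int, v)) for k, v in self.as_dict().items()}


@dataclass(frozen=True)
class GrowthPolicy:
    """Adaptive threshold schedule with explosion-based leak control."""

    start_threshold_hu: float = -980.0
    step_hu: float = 20.0
    max_threshold_hu: float = -500.0
    explosion_factor: float = 2.0
    boundary_fraction: float = 0.40  # mask touching more of the volume border = leak


# ---------------------------------------------------------------------------
# Seed selection
# ---------------------------------------------------------------------------


def select_seed(
    ct: CTVolume, air_threshold_hu: float = -950.0, slab_fraction: float = 0.25
) -> tuple[int, int, int]:
    """Locate a deterministic seed voxel inside the trachea lumen.

    Searches the superior slab (top ``slab_fraction`` of slices) for
    connected sub-threshold components that do not touch the lateral image
    border, and picks the one whose centroid is nearest the sagittal
    midline (ties broken by size).  Returns the component voxel closest to
    that centroid.
    """
    Z, Y, X = ct.shape
    slab_z = max(1, int(round(Z * slab_fraction)))
    slab = ct.values[:slab_z]
    air = slab < air_threshold_hu
    if not air.any():
        raise TracheaNotFoundError("trachea not found: no air below threshold in superior slab")
    labels, n = ndimage.label(air, structure=_CONN26)
    mid_x = (X - 1) / 2.0
    best = None
    for comp_id in range(1, n + 1):
        comp = labels == comp_id
        # components hugging the lateral border are outside-air, not trachea
        if comp[:, 0, :].any() or comp[:, -1, :].any() or comp[:, :, 0].any() or comp[:, :, -1].any():
            continue
        size = int(comp.sum())
        if size < 5:
            continue
        zc, yc, xc = (c.mean() for c in np.nonzero(comp))
        key = (abs(xc - mid_x), -size)
        if best is None or key < best[0]:
            best = (key, comp, (zc, yc, xc))
    if best is None:
        raise TracheaNotFoundError("trachea not found: no interior air component")
    _, comp, centroid = best
    coords = np.argwhere(comp)
    d2 = np.sum((coords - np.asarray(centroid)) ** 2, axis=1)
    z, y, x = coords[int(np.argmin(d2))]
    return (int(z), int(y), int(x))


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------


def _component_containing(binary: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    labels, _ = ndimage.label(binary, structure=_CONN26)
    return labels == labels[seed]


def _boundary_fraction(mask: np.ndarray) -> float:
    faces = [mask[0], mask[-1], mask[:, 0], mask[:, -1], mask[:, :, 0], mask[:, :, -1]]
    touched = sum(int(f.sum()) for f in faces)
    total = sum(f.size for f in faces)
    return touched / total


def region_grow(
    ct: CTVolume, seed: tuple[int, int, int], policy: GrowthPolicy = GrowthPolicy()
) -> BinaryMask:
    """Grow the airway mask from ``seed`` with an adaptive HU threshold.

    The admission threshold is relaxed from ``start_threshold_hu`` upward
    in ``step_hu`` increments.  Growth stops when one step multiplies the
    mask volume by more than ``explosion_factor`` (a leak into parenchyma);
    the returned mask is the last pre-explosion one.
    """
    seed = tuple(int(s) for s in seed)
    hu = float(ct.values[seed])
    if hu >= policy.start_threshold_hu:
        raise ValueError(
            f"seed voxel HU {hu:.0f} is not below the starting threshold "
            f"{policy.start_threshold_hu:.0f}"
        )
    prev: np.ndarray | None = None
    t = policy.start_threshold_hu
    while t <= policy.max_threshold_hu + 1e-9:
        comp = _component_containing(ct.values < t, seed)
        size = int(comp.sum())
        if prev is not None and size > policy.explosion_factor * int(prev.sum()):
            return BinaryMask(prev, ct.spacing_mm)
        if _boundary_fraction(comp) > policy.boundary_fraction:
            raise AirwayLeakError(
                f"region growing leaked: mask covers "
                f"{100 * _boundary_fraction(comp):.0f}% of the volume boundary"
            )
        prev = comp
        t += policy.step_hu
    assert prev is not None
    return BinaryMask(prev, ct.spacing_mm)


# ---------------------------------------------------------------------------
# Skeletonization
# ---------------------------------------------------------------------------


def _skeleton_graph(skel_voxels: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    coords = [tuple(int(v) for v in c) for c in np.argwhere(skel_voxels)]
    g.add_nodes_from(coords)
    have = set(coords)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0) or (dz, dy, dx) < (0, 0, 0)
    ]
    # only forward offsets to add each edge once
    offsets = [o for o in offsets if o > (0, 0, 0)]
    for p in coords:
        for o in offsets:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if q in have:
                g.add_edge(p, q, weight=float(np.linalg.norm(o)))
    return g


def _prune_spurs(g: nx.Graph, min_length: int) -> nx.Graph:
    """Iteratively remove leaf branches shorter than ``min_length`` voxels."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        branch_pts = {p for p, d in g.degree if d >= 3}
        if not branch_pts:
            break
        for tip in [p for p, d in g.degree if d == 1]:
            path = [tip]
            cur, prev = tip, None
            while g.degree[cur] <= 2 and len(path) <= min_length:
                nbrs = [q for q in g.neighbors(cur) if q != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                if cur in branch_pts:
                    break
                path.append(cur)
            if cur in branch_pts and len(path) < min_length:
                g.remove_nodes_from(path)
                changed = True
    return g


def skeletonize(mask: BinaryMask, prune_spur_voxels: int = 5) -> Skeleton:
    """Thin a binary airway mask to its 26-connected centerline graph.

    Short leaf branches (< ``prune_spur_voxels``) produced as thinning
    artifacts are pruned so they cannot masquerade as bifurcations.
    """
    if not mask.voxels.any():
        raise ValueError("cannot skeletonize an empty mask")
    _, n = ndimage.label(mask.voxels, structure=_CONN26)
    if n != 1:
        raise ValueError(f"mask must be one connected component, found {n}")
    skel = _sk_skeletonize(mask.voxels)
    if not skel.any():  # tiny masks can thin away entirely; keep one voxel
        skel = np.zeros_like(mask.voxels)
        zs, ys, xs = np.nonzero(mask.voxels)
        skel[zs[0], ys[0], xs[0]] = True
    g = _skeleton_graph(skel)
    g = _prune_spurs(g, prune_spur_voxels)
    return Skeleton(graph=g, spacing_mm=mask.spacing_mm)


# ---------------------------------------------------------------------------
# Landmark extraction
# ---------------------------------------------------------------------------


def extract_landmarks(skel: Skeleton) -> LandmarkSet:
    """Find root, carina ("center") and distal left/right bronchus points.

    root   = most superior skeleton endpoint (smallest z index);
    center = degree >= 3 branch point geodesically closest to the root;
    left / right = the non-root endpoint at maximal geodesic distance from
    the carina on each side of it (side = sign of x relative to center).
    """
    g = skel.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty skeleton")
    if not nx.is_connected(g):
        raise ValueError("skeleton must be connected")
    endpoints = [p for p, d in g.degree if d <= 1]
    root = min(endpoints)  # lexicographic: smallest z wins, ties broken y then x
    branch_pts = [p for p, d in g.degree if d >= 3]
    if not branch_pts:
        raise CarinaNotFoundError("carina not found: skeleton has no branch point")
    dist_root = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    center = min(branch_pts, key=lambda p: (dist_root[p], p))

    dist_center = nx.single_source_dijkstra_path_length(g, center, weight="weight")
    left_side = [p for p in g.nodes if p[2] > center[2]]
    right_side = [p for p in g.nodes if p[2] < center[2]]
    if not left_side or not right_side:
        raise CarinaNotFoundError(
            "carina not found: no distal skeleton on both sides of the bifurcation"
        )
    left = max(left_side, key=lambda p: (dist_center[p], p))
    right = max(right_side, key=lambda p: (dist_center[p], p))
    return LandmarkSet(root=root, center=center, left=left, right=right)


def segment_airway(
    ct: CTVolume, policy: GrowthPolicy = GrowthPolicy()
) -> tuple[BinaryMask, Skeleton, LandmarkSet]:
    """Full airway stage: seed -> region growing -> skeleton -> landmarks."""
    seed = select_seed(ct)
    mask = region_grow(ct, seed, policy)
    skel = skeletonize(mask)
    marks = extract_landmarks(skel)
    return mask, skel, marks
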