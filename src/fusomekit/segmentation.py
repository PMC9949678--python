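"""Ring-canal-guided segmentation of 3D fusome masks.

Input is a pair of voxel grids (fusome channel, ring-canal channel), either
binary masks or class-probability maps with anisotropic voxel size.  The
fusome of a female cyst is taken as the single largest 26-connected
component; ring canals are connected components whose 3D skeleton contains a
closed loop.  Each ring marks the junction between two sister cells: the
fusome is recursively bisected by a planar disk through every ring, the cut
voxels are reassigned to the nearest resulting fragment (so total volume is
conserved exactly), and the fragment adjacencies recorded along the way form
the cyst's lineage tree.  Female trees are finally matched to the canonical
maximally branched topology to assign cell labels 1..n, with cell 1 the
larger of the two most-connected fragments.

All distances, plane fits and the skeletonization are computed in physical
units (voxel_size-scaled); arrays are indexed (z, y, x) and voxel sizes are
given as (dx, dy, dz) in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .topology import (
    CystTree,
    canonical_max_branched,
    is_embeddable,
    trees_isomorphic,
)

__all__ = [
    "VoxelGrid",
    "RingCanal",
    "FusomeFragment",
    "ReconstructedCyst",
    "MaleComponentReport",
    "EmptyClassError",
    "CutFailureError",
    "AmbiguousCutError",
    "TopologyViolationError",
    "LabelingUnavailableError",
    "threshold_probabilities",
    "extract_fusome",
    "detect_rings",
    "split_at_rings",
    "build_adjacency",
    "assign_labels",
    "fusome_connected_cells",
    "reconstruct_female",
    "reconstruct_male",
]


class EmptyClassError(ValueError):
    """Thresholding produced an empty mask."""


class CutFailureError(RuntimeError):
    """A ring's cutting disk failed to disconnect the fusome."""


class AmbiguousCutError(RuntimeError):
    """A ring's cutting disk produced more than two substantial pieces."""


class TopologyViolationError(RuntimeError):
    """Fragment adjacencies do not form a tree."""


class LabelingUnavailableError(RuntimeError):
    """The reconstructed tree is not isomorphic to the canonical topology."""


@dataclass
class VoxelGrid:
    """A 3D image (z, y, x) with physical voxel dimensions (dx, dy, dz) nm."""

    values: np.ndarray
    voxel_size: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid requires a 3D array")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")

    @property
    def spacing_zyx(self) -> np.ndarray:
        dx, dy, dz = self.voxel_size
        return np.array([dz, dy, dx])

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz * 1e-9


@dataclass
class RingCanal:
    """A detected closed-loop ring canal."""

    ring_id: int
    voxels: np.ndarray                 # (n, 3) int indices (z, y, x)
    centroid: np.ndarray               # physical (z, y, x) nm
    plane_normal: np.ndarray           # unit vector, physical (z, y, x)
    radius: float                      # nm
    fragment_pair: Optional[Tuple[int, int]] = None  # filled by split_at_rings


@dataclass
class FusomeFragment:
    """A connected set of fusome voxels assigned to one cell."""

    fragment_id: int
    voxel_count: int
    volume_um3: float
    incident_rings: Set[int] = field(default_factory=set)


@dataclass
class ReconstructedCyst:
    """Terminal product of the female pipeline."""

    fragments: List[FusomeFragment]
    tree: CystTree                      # nodes are fragment ids
    labels: Dict[int, int]              # fragment id -> canonical cell number
    fractions: Dict[int, float]         # canonical cell -> volume fraction
    label_grid: np.ndarray              # voxel -> fragment id (0 = background)
    tie_broken: bool = False            # pro-oocyte volumes were exactly equal


@dataclass
class MaleComponentReport:
    """Census entry for one connected fusome component (male mode)."""

    component_id: int
    voxel_count: int
    volume_um3: float
    n_rings_traversed: int
    n_connected_cells: int
    power_of_two: bool
    embeddable_in_max16: Optional[bool] = None


# ---------------------------------------------------------------------------
# thresholding and component extraction
# ---------------------------------------------------------------------------

def threshold_probabilities(grid: VoxelGrid, cutoff: float = 0.5) -> VoxelGrid:
    """Binarize a class-probability map at ``cutoff``."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    mask = np.asarray(grid.values) >= cutoff
    if not mask.any():
        raise EmptyClassError("no voxel reaches the probability cutoff")
    return VoxelGrid(mask, grid.voxel_size)


def extract_fusome(
    mask: VoxelGrid, mode: str = "female", min_voxels: int = 30
) -> List[np.ndarray]:
    """Connected fusome components (26-connectivity), largest first.

    Female mode returns only the largest component (the fusome is a single
    simply-connected body in intact female cysts).  Male mode returns every
    component of at least ``min_voxels`` voxels, emulating the census of the
    largest connected fusome portions in fragmented male cysts.
    """
    if mode not in ("female", "male"):
        raise ValueError("mode must be 'female' or 'male'")
    values = mask.values.astype(bool)
    if not values.any():
        raise EmptyClassError("empty fusome mask")
    lab, n = cc_label(values, connectivity=3, return_num=True)
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(sizes)[::-1] + 1
    if mode == "female":
        return [lab == order[0]]
    return [lab == i for i in order if sizes[i - 1] >= min_voxels]


# ---------------------------------------------------------------------------
# ring detection
# ---------------------------------------------------------------------------

def _has_cycle(skel: np.ndarray) -> bool:
    """Does a 26-connected voxel graph of the skeleton contain a cycle?"""
    n_nodes = int(skel.sum())
    if n_nodes < 3:
        return False
    n_edges = 0
    offsets = [
        off
        for off in ((a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1))
        if off > (0, 0, 0)
    ]
    for dz, dyy, dxx in offsets:
        a = skel[
            max(dz, 0) or None : skel.shape[0] + min(dz, 0) or None,
            max(dyy, 0) or None : skel.shape[1] + min(dyy, 0) or None,
            max(dxx, 0) or None : skel.shape[2] + min(dxx, 0) or None,
        ]
        b = skel[
            max(-dz, 0) or None : skel.shape[0] + min(-dz, 0) or None,
            max(-dyy, 0) or None : skel.shape[1] + min(-dyy, 0) or None,
            max(-dxx, 0) or None : skel.shape[2] + min(-dxx, 0) or None,
        ]
        n_edges += int(np.logical_and(a, b).sum())
    _, n_comp = cc_label(skel, connectivity=3, return_num=True)
    return n_edges - n_nodes + n_comp >= 1


def detect_rings(grid: VoxelGrid, min_voxels: int = 5) -> List[RingCanal]:
    """Closed-loop objects in the ring-canal channel.

    Each 26-connected component is skeletonized (after nearest-neighbour
    resampling to an isotropic lattice, so the anisotropic z spacing cannot
    break thin loops) and kept iff its skeleton graph contains a cycle.
    Geometry per ring: physical centroid, best-fit plane normal (least-
    variance principal axis), and mean in-plane loop radius.
    """
    values = grid.values.astype(bool)
    if not values.any():
        return []
    spacing = grid.spacing_zyx
    zoom = spacing / spacing.min()
    lab, n = cc_label(values, connectivity=3, return_num=True)
    rings: List[RingCanal] = []
    for comp_id in range(1, n + 1):
        idx = np.argwhere(lab == comp_id)
        if len(idx) < min_voxels:
            continue
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        sub = (lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] == comp_id)
        sub = np.pad(sub, 1)
        if not np.allclose(zoom, 1.0):
            sub = ndimage.zoom(sub, zoom, order=0)
        skel = skeletonize(sub)
        if not _has_cycle(skel):
            continue
        coords = (idx + 0.5) * spacing
        centroid = coords.mean(axis=0)
        w = coords - centroid
        cov = np.cov(w.T) if len(w) > 3 else np.eye(3)
        eigval, eigvec = np.linalg.eigh(cov)
        normal = eigvec[:, 0]  # least-variance axis
        par = w @ normal
        perp = np.sqrt(np.maximum((w**2).sum(axis=1) - par**2, 0.0))
        rings.append(
            RingCanal(
                ring_id=len(rings),
                voxels=idx,
                centroid=centroid,
                plane_normal=normal,
                radius=float(np.median(perp)),
            )
        )
    return rings


# ---------------------------------------------------------------------------
# recursive splitting
# ---------------------------------------------------------------------------

def _cut_region(shape, spacing, center, normal, radius, half_thick):
    """Boolean disk-slab mask (within a bounding box) and its slices."""
    ext = radius + half_thick + 2 * spacing.max()
    sl = []
    for ax in range(3):
        i0 = int(math.floor((center[ax] - ext) / spacing[ax])) - 1
        i1 = int(math.ceil((center[ax] + ext) / spacing[ax])) + 2
        sl.append(slice(max(i0, 0), min(i1, shape[ax])))
    sl = tuple(sl)
    axes = [
        ((np.arange(s.start, s.stop) + 0.5) * spacing[ax]) - center[ax]
        for ax, s in enumerate(sl)
    ]
    z = axes[0][:, None, None]
    y = axes[1][None, :, None]
    x = axes[2][None, None, :]
    par = z * normal[0] + y * normal[1] + x * normal[2]
    perp2 = np.maximum(z**2 + y**2 + x**2 - par**2, 0.0)
    region = (np.abs(par) <= half_thick) & (perp2 <= radius**2)
    return region, sl


def _nearest_index(comp_mask: np.ndarray, spacing: np.ndarray, point: np.ndarray):
    idx = np.argwhere(comp_mask)
    coords = (idx + 0.5) * spacing
    return tuple(idx[np.argmin(((coords - point) ** 2).sum(axis=1))])


def split_at_rings(
    fusome: VoxelGrid,
    rings: Sequence[RingCanal],
    disk_factor: float = 1.25,
    debris_voxels: int = 27,
) -> Tuple[List[FusomeFragment], np.ndarray]:
    """Recursively bisect the fusome at every ring canal.

    At each step an unused ring is chosen; fusome voxels inside the ring's
    cutting disk (plane slab through the ring centroid, normal to its
    best-fit plane, disk radius ``disk_factor`` x ring radius) are deleted,
    splitting the component in two; remaining rings are recursed into the
    side holding the fusome voxel nearest their centroid.  Deleted voxels
    are finally reassigned to the nearest fragment in physical units, so the
    fragment volumes sum exactly to the whole fusome.  Cut fragments smaller
    than ``debris_voxels`` are folded into the nearest large piece.

    Returns the fragments (ids 1..n_rings+1) and the fragment-label grid;
    each ring's ``fragment_pair`` is filled with the two fragments it joins.
    """
    mask = fusome.values.astype(bool)
    spacing = fusome.spacing_zyx
    labels = np.zeros(mask.shape, dtype=np.int32)
    deleted: List[Tuple[np.ndarray, int]] = []     # (indices, ring_id)
    anchors: Dict[int, Tuple[Tuple[int, ...], Tuple[int, ...]]] = {}
    next_label = [0]

    def recurse(comp: np.ndarray, todo: List[RingCanal]) -> None:
        if not todo:
            next_label[0] += 1
            labels[comp] = next_label[0]
            return
        ring = todo[0]
        rest = todo[1:]
        half_thick = max(
            spacing.min(),
            0.5 * float(np.abs(ring.plane_normal * spacing).sum()),
        ) + 1e-6
        region, sl = _cut_region(
            mask.shape, spacing, ring.centroid, ring.plane_normal,
            disk_factor * ring.radius, half_thick,
        )
        cut = np.zeros_like(comp)
        cut[sl] = region
        cut &= comp
        remaining = comp & ~cut
        lab, n = cc_label(remaining, connectivity=3, return_num=True)
        sizes = np.bincount(lab.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        if n < 2 or (n >= 2 and sizes[order[1]] < debris_voxels):
            raise CutFailureError(
                f"ring {ring.ring_id}: cutting disk did not disconnect the fusome"
            )
        big = [order[0] + 1, order[1] + 1]
        if n > 2:
            extras = [order[i] + 1 for i in range(2, n)]
            if any(sizes[e - 1] >= debris_voxels for e in extras):
                raise AmbiguousCutError(
                    f"ring {ring.ring_id}: cut produced {n} substantial components"
                )
            # fold sub-debris crumbs into the cut set for nearest reassignment
            for e in extras:
                piece = lab == e
                cut |= piece
                remaining &= ~piece
        side_a = lab == big[0]
        side_b = lab == big[1]
        deleted.append((np.argwhere(cut), ring.ring_id))
        anchors[ring.ring_id] = (
            _nearest_index(side_a, spacing, ring.centroid),
            _nearest_index(side_b, spacing, ring.centroid),
        )
        todo_a, todo_b = [], []
        for r in rest:
            iz, iy, ix = np.round(r.centroid / spacing - 0.5).astype(int)
            iz = np.clip(iz, 0, mask.shape[0] - 1)
            iy = np.clip(iy, 0, mask.shape[1] - 1)
            ix = np.clip(ix, 0, mask.shape[2] - 1)
            if side_a[iz, iy, ix]:
                todo_a.append(r)
            elif side_b[iz, iy, ix]:
                todo_b.append(r)
            else:
                na = _nearest_index(side_a, spacing, r.centroid)
                nb = _nearest_index(side_b, spacing, r.centroid)
                da = np.linalg.norm((np.array(na) + 0.5) * spacing - r.centroid)
                db = np.linalg.norm((np.array(nb) + 0.5) * spacing - r.centroid)
                (todo_a if da <= db else todo_b).append(r)
        recurse(side_a, todo_a)
        recurse(side_b, todo_b)

    recurse(mask, sorted(rings, key=lambda r: r.ring_id))

    # reassign deleted voxels to the nearest fragment (exact conservation)
    if deleted:
        _, inds = ndimage.distance_transform_edt(
            labels == 0, sampling=spacing, return_indices=True
        )
        for idx, _ring_id in deleted:
            t = tuple(idx.T)
            labels[t] = labels[inds[0][t], inds[1][t], inds[2][t]]

    counts = np.bincount(labels.ravel(), minlength=next_label[0] + 1)
    voxel_um3 = fusome.voxel_volume_um3
    fragments = [
        FusomeFragment(fid, int(counts[fid]), float(counts[fid] * voxel_um3))
        for fid in range(1, next_label[0] + 1)
    ]
    by_id = {f.fragment_id: f for f in fragments}
    for ring in rings:
        if ring.ring_id in anchors:
            na, nb = anchors[ring.ring_id]
            fa, fb = int(labels[na]), int(labels[nb])
            ring.fragment_pair = (fa, fb)
            by_id[fa].incident_rings.add(ring.ring_id)
            by_id[fb].incident_rings.add(ring.ring_id)
    return fragments, labels


def build_adjacency(
    fragments: Sequence[FusomeFragment], rings: Sequence[RingCanal]
) -> CystTree:
    """Fragment adjacency tree: one edge per ring, joining the two fragments
    it separated during the recursion."""
    edges = []
    for ring in rings:
        if ring.fragment_pair is None:
            raise TopologyViolationError(
                f"ring {ring.ring_id} has no recorded fragment pair; run split_at_rings"
            )
        fa, fb = ring.fragment_pair
        if fa == fb:
            raise TopologyViolationError(f"ring {ring.ring_id} joins a fragment to itself")
        edges.append((fa, fb))
    try:
        return CystTree.from_edges(edges, cells=[f.fragment_id for f in fragments])
    except ValueError as exc:
        raise TopologyViolationError(f"fragment adjacency is not a tree: {exc}") from exc


# ---------------------------------------------------------------------------
# canonical labeling
# ---------------------------------------------------------------------------

def _signatures(tree: CystTree, anchor: int) -> Dict[int, Tuple[int, int, Tuple[int, ...]]]:
    """Structural signature of every node: degree, hop distance to the
    anchor, and the sorted degrees of its neighbours."""
    adj = tree.adjacency()
    dist = {anchor: 0}
    frontier = [anchor]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return {
        c: (len(adj[c]), dist[c], tuple(sorted(len(adj[n]) for n in adj[c])))
        for c in tree.cells
    }


def _rooted_shape(adj, v, parent) -> str:
    subs = sorted(_rooted_shape(adj, u, v) for u in adj[v] if u != parent)
    return "(" + "".join(subs) + ")"


def _verify_mapping(tree: CystTree, canon: CystTree, mapping: Dict[int, int]) -> bool:
    if len(set(mapping.values())) != len(mapping):
        return False
    return {tuple(sorted((mapping[a], mapping[b]))) for a, b in tree.canals} == \
        set(canon.canals)


def _exact_match(tree: CystTree, canon: CystTree, root_frag: int,
                 volume: Dict[int, float]) -> Dict[int, int]:
    """Deterministic rooted isomorphism: equal-shape sibling groups are
    paired with fragments ordered by descending volume."""
    adj_t = tree.adjacency()
    adj_c = canon.adjacency()
    mapping: Dict[int, int] = {}

    def rec(u: int, pu: Optional[int], v: int, pv: Optional[int]) -> None:
        mapping[u] = v
        t_kids = [x for x in adj_t[u] if x != pu]
        c_kids = [y for y in adj_c[v] if y != pv]
        groups_t: Dict[str, List[int]] = {}
        groups_c: Dict[str, List[int]] = {}
        for x in t_kids:
            groups_t.setdefault(_rooted_shape(adj_t, x, u), []).append(x)
        for y in c_kids:
            groups_c.setdefault(_rooted_shape(adj_c, y, v), []).append(y)
        if sorted(groups_t) != sorted(groups_c) or any(
            len(groups_t[k]) != len(groups_c[k]) for k in groups_t
        ):
            raise LabelingUnavailableError("rooted shapes do not match")
        for key, xs in groups_t.items():
            xs = sorted(xs, key=lambda x: (-volume[x], x))
            ys = sorted(groups_c[key])
            for x, y in zip(xs, ys):
                rec(x, u, y, v)

    rec(root_frag, None, 1, None)
    return mapping


def assign_labels(
    tree: CystTree, fragments: Sequence[FusomeFragment],
    label_grid: Optional[np.ndarray] = None,
) -> ReconstructedCyst:
    """Map fragments onto canonical cell numbers 1..n.

    Cell 1 is the larger-volume fragment among those of maximal degree (the
    pro-oocyte with four ring canals at the 16-cell stage; exact volume ties
    break to the lowest fragment id and are flagged).  Remaining labels come
    from a minimum-cost linear assignment over structural signatures
    (degree, hop distance to cell 1, sorted neighbour degrees), verified to
    be a graph isomorphism; if equal-cost ties produce an invalid map, a
    deterministic rooted matching (volume-ordered within symmetric sibling
    groups) is used instead.
    """
    n = tree.n_cells
    if n not in (1, 2, 4, 8, 16):
        raise LabelingUnavailableError(f"no canonical topology for {n} cells")
    canon = canonical_max_branched(n)
    if not trees_isomorphic(tree, canon):
        raise LabelingUnavailableError(
            "reconstructed tree is not isomorphic to the canonical topology"
        )
    volume = {f.fragment_id: f.volume_um3 for f in fragments}
    degrees = {c: tree.degree(c) for c in tree.cells}
    max_deg = max(degrees.values())
    candidates = sorted(
        (c for c in tree.cells if degrees[c] == max_deg),
        key=lambda c: (-volume[c], c),
    )
    tie = len(candidates) > 1 and math.isclose(
        volume[candidates[0]], volume[candidates[1]], rel_tol=0.0, abs_tol=0.0
    )
    root = candidates[0]

    if n == 1:
        mapping = {next(iter(tree.cells)): 1}
    else:
        sig_t = _signatures(tree, root)
        sig_c = _signatures(canon, 1)
        frags = sorted(tree.cells)
        cells = sorted(canon.cells)
        cost = np.zeros((n, n))
        for i, fr in enumerate(frags):
            for j, ce in enumerate(cells):
                dt, ht, nt = sig_t[fr]
                dc, hc, nc = sig_c[ce]
                cost[i, j] = (
                    100.0 * (dt != dc) + 10.0 * abs(ht - hc) + 1.0 * (nt != nc)
                )
        cost[frags.index(root), :] += 1e6
        cost[frags.index(root), cells.index(1)] = 0.0
        ri, ci = linear_sum_assignment(cost)
        mapping = {frags[i]: cells[j] for i, j in zip(ri, ci)}
        if not (_verify_mapping(tree, canon, mapping) and mapping[root] == 1):
            mapping = _exact_match(tree, canon, root, volume)
            assert _verify_mapping(tree, canon, mapping)

    total = sum(volume.values())
    fractions = {mapping[f]: volume[f] / total for f in mapping}
    return ReconstructedCyst(
        fragments=list(fragments),
        tree=tree,
        labels=mapping,
        fractions=fractions,
        label_grid=label_grid if label_grid is not None else np.zeros((0, 0, 0), np.int32),
        tie_broken=tie,
    )


# ---------------------------------------------------------------------------
# male-mode census
# ---------------------------------------------------------------------------

def _ring_traversed(
    component: np.ndarray,
    ring: RingCanal,
    spacing: np.ndarray,
    disk_factor: float = 1.25,
    debris_voxels: int = 27,
) -> bool:
    """Does the fusome component pass *through* the ring?

    Operational test consistent with the splitting step: the ring counts as
    traversed iff deleting its cutting disk separates the component into two
    pieces of substantial size.  A thread that merely touches the ring plane
    (e.g. a broken male fusome stub ending near a ring) is not traversed.
    """
    half_thick = max(
        spacing.min(), 0.5 * float(np.abs(ring.plane_normal * spacing).sum())
    ) + 1e-6
    region, sl = _cut_region(
        component.shape, spacing, ring.centroid, ring.plane_normal,
        disk_factor * ring.radius, half_thick,
    )
    cut_local = np.logical_and(component[sl], region)
    if not cut_local.any():
        return False
    remaining = component.copy()
    remaining[sl] &= ~region
    lab, n = cc_label(remaining, connectivity=3, return_num=True)
    if n < 2:
        return False
    sizes = np.bincount(lab.ravel())[1:]
    return int(np.sum(sizes >= debris_voxels)) >= 2


def fusome_connected_cells(
    component: np.ndarray, rings: Sequence[RingCanal], spacing: np.ndarray
) -> Tuple[int, bool]:
    """Cells joined by one fusome component: traversed rings + 1."""
    n_trav = sum(_ring_traversed(component, r, spacing) for r in rings)
    n_cells = n_trav + 1
    return n_cells, (n_cells & (n_cells - 1)) == 0


# ---------------------------------------------------------------------------
# end-to-end reconstructions
# ---------------------------------------------------------------------------

def _as_binary(grid: VoxelGrid, threshold: float) -> VoxelGrid:
    if grid.values.dtype == bool:
        return grid
    return threshold_probabilities(grid, threshold)


def reconstruct_female(
    fusome: VoxelGrid, rings_grid: VoxelGrid, threshold: float = 0.5
) -> ReconstructedCyst:
    """Full female pipeline: threshold, largest component, ring detection,
    recursive splitting, adjacency, canonical labels, volume fractions."""
    fus_bin = _as_binary(fusome, threshold)
    ring_bin = _as_binary(rings_grid, threshold)
    component = extract_fusome(fus_bin, "female")[0]
    rings = detect_rings(ring_bin)
    if not rings:
        warnings.warn("no ring canals detected; treating the cyst as one cell")
    comp_grid = VoxelGrid(component, fusome.voxel_size)
    fragments, label_grid = split_at_rings(comp_grid, rings)
    tree = build_adjacency(fragments, rings)
    return assign_labels(tree, fragments, label_grid)


def reconstruct_male(
    fusome: VoxelGrid,
    rings_grid: VoxelGrid,
    threshold: float = 0.5,
    min_component_voxels: int = 30,
    check_embeddability: bool = True,
) -> List[MaleComponentReport]:
    """Male pipeline: component census, fusome-connected cell counts, and
    embeddability of each component's topology in the canonical 16-cell tree.

    No canonical labels are assigned; fragmented cysts are reported
    component by component, largest first.
    """
    fus_bin = _as_binary(fusome, threshold)
    ring_bin = _as_binary(rings_grid, threshold)
    components = extract_fusome(fus_bin, "male", min_voxels=min_component_voxels)
    rings = detect_rings(ring_bin)
    spacing = fusome.spacing_zyx
    voxel_um3 = fusome.voxel_volume_um3
    canon16 = canonical_max_branched(16)
    reports: List[MaleComponentReport] = []
    for comp_id, comp in enumerate(components):
        n_cells, pow2 = fusome_connected_cells(comp, rings, spacing)
        embeddable: Optional[bool] = None
        if check_embeddability:
            traversed = [r for r in rings if _ring_traversed(comp, r, spacing)]
            try:
                sub_rings = [
                    RingCanal(i, r.voxels, r.centroid, r.plane_normal, r.radius)
                    for i, r in enumerate(traversed)
                ]
                frags, _ = split_at_rings(VoxelGrid(comp, fusome.voxel_size), sub_rings)
                comp_tree = build_adjacency(frags, sub_rings)
                embeddable = comp_tree.n_cells <= 16 and is_embeddable(
                    comp_tree, canon16
                )
            except (CutFailureError, AmbiguousCutError, TopologyViolationError):
                embeddable = None
        reports.append(
            MaleComponentReport(
                component_id=comp_id,
                voxel_count=int(comp.sum()),
                volume_um3=float(comp.sum() * voxel_um3),
                n_rings_traversed=n_cells - 1,
                n_connected_cells=n_cells,
                power_of_two=pow2,
                embeddable_in_max16=embeddable,
            )
        )
    return reports
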