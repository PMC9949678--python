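"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes:

* ``simulate_volume_table`` draws per-cell fusome volume tables from the
  additive growth model with multiplicative lognormal noise, emulating the
  statistical structure of measured female cysts (2-16 cells).

* ``render_cyst`` rasterizes a cyst lineage tree into a pair of 3D voxel
  grids (fusome channel, ring-canal channel) with anisotropic voxel size.
  Each cell is a ball of prescribed volume, adjacent cells are joined by a
  cylindrical fusome thread, and every ring canal is a solid torus placed at
  the inter-cell junction, oriented normal to the connecting segment.  The
  returned answer key (per-cell voxel volumes, ring positions, topology) is
  sufficient to score every segmentation operation without human input.

Neither generator attempts photorealism (no PSF model or photon noise); an
optional Gaussian blur turns binary masks into probability-map surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .growth_model import (
    STAGES,
    DEFAULT_RATIOS,
    GrowthParams,
    predict_fractions,
    solve_plug_volumes,
)
from .segmentation import VoxelGrid
from .topology import CystTree, canonical_max_branched

__all__ = [
    "SimulationConfig",
    "RenderConfig",
    "LayoutFailureError",
    "simulate_volume_table",
    "model_cell_volumes",
    "render_cyst",
]


class LayoutFailureError(RuntimeError):
    """Raised when no overlap-free 3D embedding of the tree could be found."""


# ---------------------------------------------------------------------------
# volume tables drawn from the growth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for simulated volume tables.

    Defaults mirror the measured female data: the fitted parameter scale
    (alpha ~ 0.7, beta ~ 0.5), the 2:1:1:1 16-cell group shares, about a
    dozen cysts per stage, and ~5% relative scatter between samples.
    """

    alpha_true: float = 0.7
    beta_true: float = 0.5
    group_ratios: Tuple[float, ...] = DEFAULT_RATIOS
    n_cysts_per_stage: int = 12
    noise_sigma: float = 0.05
    seed: int = 0
    stages: Tuple[int, ...] = STAGES

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def simulate_volume_table(config: SimulationConfig) -> pd.DataFrame:
    """Draw a per-cell volume table (cyst_id, stage, cell_label, volume_um3).

    Per cyst, cell volumes are T_k * f_i(alpha*, beta*) * LogNormal(0, sigma)
    in units of the spectrosome volume (v0 = 1).  The generating parameters
    and noise-free fractions are attached under ``df.attrs["truth"]``.
    """
    params = GrowthParams(config.alpha_true, config.beta_true)
    plugs = solve_plug_volumes(params, config.group_ratios)
    rng = np.random.default_rng(config.seed)
    rows: List[Tuple[str, int, int, float]] = []
    truth_fractions: Dict[int, np.ndarray] = {}
    for stage in config.stages:
        k = int(math.log2(stage))
        frac = predict_fractions(plugs, params, stage).fractions
        truth_fractions[stage] = frac
        total = plugs.total(k)
        for rep in range(config.n_cysts_per_stage):
            noise = np.exp(rng.normal(0.0, config.noise_sigma, size=stage))
            vols = total * frac * noise
            cyst = f"s{stage}_c{rep}"
            rows.extend(
                (cyst, stage, cell + 1, float(vols[cell])) for cell in range(stage)
            )
    df = pd.DataFrame(rows, columns=["cyst_id", "stage", "cell_label", "volume_um3"])
    df.attrs["truth"] = {
        "alpha": config.alpha_true,
        "beta": config.beta_true,
        "group_ratios": tuple(config.group_ratios),
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
        "fractions": {s: f.tolist() for s, f in truth_fractions.items()},
    }
    return df


def model_cell_volumes(
    n_cells: int,
    total_um3: float = 6.0,
    alpha: float = 0.7,
    beta: float = 0.5,
) -> np.ndarray:
    """Per-cell fusome volumes (um^3) for a canonical cyst, model-shaped."""
    if n_cells == 1:
        return np.array([total_um3])
    params = GrowthParams(alpha, beta)
    plugs = solve_plug_volumes(params)
    return total_um3 * predict_fractions(plugs, params, n_cells).fractions


# ---------------------------------------------------------------------------
# 3D rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """Geometry of a rendered cyst.

    Distances in nm.  Defaults approximate confocal stacks of early female
    cysts: ~70 nm lateral / ~210 nm axial voxels, fusome threads a few
    hundred nm thick, ring canals of sub-micron radius.  ``p_frag`` breaks
    the middle of fusome threads with the given probability (male-style
    fragmentation); ``elongation`` stretches the layout along one axis as in
    male cysts.
    """

    tree: CystTree
    cell_volumes_um3: Optional[Tuple[float, ...]] = None  # sorted-cell order
    tube_radius: float = 250.0
    ring_radius: float = 350.0
    ring_minor_radius: float = 200.0
    voxel_size: Tuple[float, float, float] = (70.0, 70.0, 210.0)  # (dx, dy, dz)
    blur_sigma: float = 0.0
    clearance: float = 500.0
    elongation: float = 1.0
    p_frag: float = 0.0
    seed: int = 0
    max_voxels: int = 40_000_000


def _layout_positions(cfg: RenderConfig, radii: Dict[int, float], rng: np.random.Generator):
    """Overlap-free 3D embedding of the tree (spring layout, then rescale)."""
    import networkx as nx

    g = cfg.tree.to_networkx()
    nodes = sorted(cfg.tree.cells)
    if len(nodes) == 1:
        return {nodes[0]: np.zeros(3)}
    adj = set(cfg.tree.canals)
    for attempt in range(8):
        seed = int(rng.integers(2**31))
        pos = nx.spring_layout(g, dim=3, seed=seed, iterations=200)
        p = {c: np.asarray(pos[c], dtype=float) for c in nodes}
        if cfg.elongation != 1.0:
            for c in nodes:
                p[c][0] *= cfg.elongation
        # smallest scale s such that every pair of balls keeps its margin and
        # no fusome thread passes near a cell it does not connect
        s = 0.0
        ok = True
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                d = float(np.linalg.norm(p[a] - p[b]))
                if d < 1e-9:
                    ok = False
                    break
                if (min(a, b), max(a, b)) in adj:
                    # when threads may be broken, leave room for a capsule
                    # gap between the two ball surfaces
                    margin = 250.0 if cfg.p_frag == 0 else \
                        2 * (cfg.tube_radius + 350.0) + 500.0
                else:
                    margin = cfg.clearance
                s = max(s, (radii[a] + radii[b] + margin) / d)
            if not ok:
                break
        if ok:
            for a, b in adj:
                for c in nodes:
                    if c in (a, b):
                        continue
                    d = _point_segment_distance(p[c], p[a], p[b])
                    if d < 1e-9:
                        ok = False
                        break
                    s = max(s, (radii[c] + cfg.tube_radius + cfg.clearance) / d)
                if not ok:
                    break
        if ok:
            edges = sorted(adj)
            for i, (a, b) in enumerate(edges):
                for c, d in edges[i + 1 :]:
                    if {a, b} & {c, d}:
                        continue  # threads sharing a cell meet inside its ball
                    dd = _segment_segment_distance(p[a], p[b], p[c], p[d])
                    if dd < 1e-9:
                        ok = False
                        break
                    s = max(s, (2 * cfg.tube_radius + cfg.clearance) / dd)
                if not ok:
                    break
        if not ok:
            continue
        # enlarge until ring canals at inter-cell junctions cannot overlap
        ring_extent = 2.0 * (cfg.ring_radius + cfg.ring_minor_radius) + 150.0
        for _ in range(12):
            placed = {c: p[c] * s for c in nodes}
            junctions = [
                _junction(placed[a], placed[b], radii[a], radii[b])
                for a, b in sorted(adj)
            ]
            if len(junctions) < 2:
                return placed
            dmin = min(
                float(np.linalg.norm(junctions[i] - junctions[j]))
                for i in range(len(junctions))
                for j in range(i + 1, len(junctions))
            )
            if dmin >= ring_extent:
                return placed
            s *= min(1.1 * ring_extent / max(dmin, 1e-6), 1.5)
    raise LayoutFailureError("could not embed the tree without cell overlap")


def _point_segment_distance(q: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u = b - a
    t = float(np.clip(np.dot(q - a, u) / max(np.dot(u, u), 1e-12), 0.0, 1.0))
    return float(np.linalg.norm(q - (a + t * u)))


def _segment_segment_distance(a0, a1, b0, b1, samples: int = 17) -> float:
    """Minimum distance between two segments (dense sampling; layout-scale)."""
    ts = np.linspace(0.0, 1.0, samples)
    pts = a0[None, :] + ts[:, None] * (a1 - a0)[None, :]
    return min(_point_segment_distance(q, b0, b1) for q in pts)


def _junction(pa: np.ndarray, pb: np.ndarray, ra: float, rb: float) -> np.ndarray:
    """Point on segment a-b equidistant from the two ball surfaces."""
    length = float(np.linalg.norm(pb - pa))
    t = (length + ra - rb) / (2.0 * length)
    return pa + min(max(t, 0.05), 0.95) * (pb - pa)


def _bounds_slices(shape, lo, hi, origin, voxel_zyx):
    sl = []
    for ax in range(3):
        i0 = int(math.floor((lo[ax] - origin[ax]) / voxel_zyx[ax])) - 1
        i1 = int(math.ceil((hi[ax] - origin[ax]) / voxel_zyx[ax])) + 2
        sl.append(slice(max(i0, 0), min(i1, shape[ax])))
    return tuple(sl)


def _coords(slices, origin, voxel_zyx):
    axes = []
    for ax, sl in enumerate(slices):
        idx = np.arange(sl.start, sl.stop)
        axes.append(origin[ax] + (idx + 0.5) * voxel_zyx[ax])
    z, y, x = axes
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _paint_ball(mask, origin, voxel_zyx, center, radius):
    sl = _bounds_slices(mask.shape, center - radius, center + radius, origin, voxel_zyx)
    z, y, x = _coords(sl, origin, voxel_zyx)
    d2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    mask[sl] |= d2 <= radius**2


def _paint_tube(mask, origin, voxel_zyx, p0, p1, radius, t0=0.0, t1=1.0):
    a = p0 + t0 * (p1 - p0)
    b = p0 + t1 * (p1 - p0)
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    sl = _bounds_slices(mask.shape, lo, hi, origin, voxel_zyx)
    z, y, x = _coords(sl, origin, voxel_zyx)
    u = b - a
    ll = float(np.dot(u, u))
    if ll < 1e-9:
        return
    wz, wy, wx = z - a[0], y - a[1], x - a[2]
    t = np.clip((wz * u[0] + wy * u[1] + wx * u[2]) / ll, 0.0, 1.0)
    d2 = (wz - t * u[0]) ** 2 + (wy - t * u[1]) ** 2 + (wx - t * u[2]) ** 2
    mask[sl] |= d2 <= radius**2


def _paint_torus(mask, origin, voxel_zyx, center, axis, major, minor):
    ext = major + minor
    sl = _bounds_slices(mask.shape, center - ext, center + ext, origin, voxel_zyx)
    z, y, x = _coords(sl, origin, voxel_zyx)
    wz, wy, wx = z - center[0], y - center[1], x - center[2]
    par = wz * axis[0] + wy * axis[1] + wx * axis[2]
    perp2 = np.maximum(wz**2 + wy**2 + wx**2 - par**2, 0.0)
    mask[sl] |= (np.sqrt(perp2) - major) ** 2 + par**2 <= minor**2


def render_cyst(config: RenderConfig) -> Tuple[VoxelGrid, VoxelGrid, dict]:
    """Rasterize a cyst tree into fusome and ring-canal voxel grids.

    Returns ``(fusome, rings, truth)``.  The answer key ``truth`` records the
    topology, per-cell ground-truth voxel counts and volumes (ownership of a
    fusome voxel goes to the cell whose ball surface is nearest, which places
    the boundary exactly at the rendered ring position), ring geometry, and
    any deliberately broken threads.
    """
    tree = config.tree
    nodes = sorted(tree.cells)
    rng = np.random.default_rng(config.seed)
    if config.cell_volumes_um3 is not None:
        if len(config.cell_volumes_um3) != len(nodes):
            raise ValueError("need one cell volume per cell")
        vols_um3 = {c: float(v) for c, v in zip(nodes, config.cell_volumes_um3)}
    else:
        vols_um3 = {c: 1.4 for c in nodes}
    radii = {
        c: (3.0 * v * 1e9 / (4.0 * math.pi)) ** (1.0 / 3.0) for c, v in vols_um3.items()
    }  # nm

    pos_xyz = _layout_positions(config, radii, rng)
    # store physical coordinates in array order (z, y, x)
    pos = {c: np.asarray(p)[::-1].copy() for c, p in pos_xyz.items()}

    dx, dy, dz = config.voxel_size
    voxel_zyx = np.array([dz, dy, dx])
    pad = config.ring_radius + config.ring_minor_radius + 3 * max(config.voxel_size) \
        + 2 * config.blur_sigma
    pts = np.array([pos[c] for c in nodes])
    rmax = np.array([radii[c] for c in nodes])[:, None]
    lo = (pts - rmax).min(axis=0) - pad
    hi = (pts + rmax).max(axis=0) + pad
    shape = tuple(int(math.ceil((hi[ax] - lo[ax]) / voxel_zyx[ax])) for ax in range(3))
    n_vox = shape[0] * shape[1] * shape[2]
    if n_vox > config.max_voxels:
        raise LayoutFailureError(f"render grid of {n_vox} voxels exceeds the cap")
    origin = lo

    fus = np.zeros(shape, dtype=bool)
    rng_mask = np.zeros(shape, dtype=bool)

    for c in nodes:
        _paint_ball(fus, origin, voxel_zyx, pos[c], radii[c])

    edges = sorted(tree.canals)
    broken: List[Tuple[int, int]] = []
    ring_truth = []
    for ring_id, (a, b) in enumerate(edges):
        pa, pb = pos[a], pos[b]
        seg_len = float(np.linalg.norm(pb - pa))
        # free thread segment between the two ball surfaces; stubs are
        # capsules, so the void must clear both hemispherical caps
        t_lo = (radii[a] + config.tube_radius) / seg_len
        t_hi = 1.0 - (radii[b] + config.tube_radius) / seg_len
        t_mid = 0.5 * (t_lo + t_hi)
        half_gap = (config.tube_radius + 350.0) / seg_len
        gap_lo = t_mid - half_gap
        gap_hi = t_mid + half_gap
        breakable = gap_lo > t_lo and gap_hi < t_hi
        if config.p_frag > 0 and breakable and rng.random() < config.p_frag:
            broken.append((a, b))
            _paint_tube(fus, origin, voxel_zyx, pa, pb, config.tube_radius, 0.0, gap_lo)
            _paint_tube(fus, origin, voxel_zyx, pa, pb, config.tube_radius, gap_hi, 1.0)
        else:
            _paint_tube(fus, origin, voxel_zyx, pa, pb, config.tube_radius)
        length = float(np.linalg.norm(pb - pa))
        center = _junction(pa, pb, radii[a], radii[b])
        axis = (pb - pa) / length
        _paint_torus(rng_mask, origin, voxel_zyx, center, axis,
                     config.ring_radius, config.ring_minor_radius)
        ring_truth.append(
            {
                "ring_id": ring_id,
                "cells": (a, b),
                "center_zyx_nm": center.tolist(),
                "axis_zyx": axis.tolist(),
                "major_radius_nm": config.ring_radius,
                "broken": (a, b) in broken,
            }
        )

    # ground-truth ownership: nearest ball surface (signed distance)
    idx = np.argwhere(fus)
    coords = (idx + 0.5) * voxel_zyx + origin
    signed = np.stack(
        [np.linalg.norm(coords - pos[c], axis=1) - radii[c] for c in nodes], axis=1
    )
    owner = np.asarray(nodes)[np.argmin(signed, axis=1)]
    label_grid = np.zeros(shape, dtype=np.int16)
    label_grid[tuple(idx.T)] = owner
    voxel_um3 = dx * dy * dz * 1e-9
    counts = {int(c): int((owner == c).sum()) for c in nodes}

    fus_values: np.ndarray = fus
    ring_values: np.ndarray = rng_mask
    if config.blur_sigma > 0:
        sig = tuple(config.blur_sigma / s for s in voxel_zyx)
        fus_values = gaussian_filter(fus.astype(np.float32), sig)
        ring_values = gaussian_filter(rng_mask.astype(np.float32), sig)

    truth = {
        "tree": tree.to_json(),
        "n_cells": len(nodes),
        "n_rings": len(edges),
        "voxel_size_nm": (dx, dy, dz),
        "cell_centers_zyx_nm": {int(c): pos[c].tolist() for c in nodes},
        "cell_radii_nm": {int(c): radii[c] for c in nodes},
        "cell_voxel_counts": counts,
        "cell_volumes_um3": {c: n * voxel_um3 for c, n in counts.items()},
        "total_voxels": int(fus.sum()),
        "rings": ring_truth,
        "broken_edges": broken,
        "owner_grid": label_grid,
        "seed": config.seed,
    }
    return (
        VoxelGrid(fus_values, config.voxel_size),
        VoxelGrid(ring_values, config.voxel_size),
        truth,
    )
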