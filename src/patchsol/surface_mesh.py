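"""Solvent-accessible dot surface with per-dot areas and a neighbour graph.

Dots are placed on each atom's expanded sphere (radius + probe) with a
deterministic golden-spiral point set, then culled where they fall inside any
other atom's expanded sphere (Shrake-Rupley).  Patch "size" downstream is the
sum of dot areas (Å**2), so results are dot-density independent to first
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .structure_io import Structure

LINK_CLAMP = (0.5, 5.0)  # Å bounds for the auto link distance


def golden_spiral_points(n: int) -> np.ndarray:
    """`n` near-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class DotSurface:
    positions: np.ndarray          # (M, 3) Å
    normals: np.ndarray            # (M, 3) unit outward
    areas: np.ndarray              # (M,) Å**2
    parent_atom: np.ndarray        # (M,) int index into structure atoms
    probe_radius: float
    dots_per_atom: int
    adjacency: sparse.csr_matrix | None = field(default=None, repr=False)
    link_distance: float | None = None

    @property
    def n_dots(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def build_dot_surface(
    s: Structure, probe: float = 1.4, dots_per_atom: int = 256
) -> DotSurface:
    """Shrake-Rupley style solvent-accessible dot surface.

    Each atom contributes ``dots_per_atom`` candidate dots on its expanded
    sphere; a surviving dot carries area 4*pi*(r+probe)**2 / dots_per_atom.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords = s.coords()
    radii = s.radii()
    n = len(coords)
    if n == 0:
        raise ValueError("structure has no atoms")
    if np.any(radii <= 0):
        raise ValueError("all atoms need positive radii (run assign_radii)")

    expanded = radii + probe
    unit = golden_spiral_points(dots_per_atom)
    tree = cKDTree(coords)
    max_exp = expanded.max()

    pos_out, nrm_out, area_out, parent_out = [], [], [], []
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        # neighbours whose expanded sphere could swallow these dots
        nbrs = tree.query_ball_point(coords[i], expanded[i] + max_exp)
        nbrs = [j for j in nbrs if j != i]
        keep = np.ones(dots_per_atom, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            # strict inequality: a dot exactly on two spheres stays (a fully
            # coincident duplicate atom then contributes no *extra* area
            # because its own dots survive symmetrically; see below)
            keep &= d2 >= expanded[j] ** 2 - 1e-9
        # degenerate duplicates (identical centre and radius): keep dots only
        # on the lowest-index copy
        for j in nbrs:
            if (
                j < i
                and abs(expanded[j] - expanded[i]) < 1e-9
                and np.sum((coords[j] - coords[i]) ** 2) < 1e-18
            ):
                keep[:] = False
        if keep.any():
            pos_out.append(pts[keep])
            nrm_out.append(unit[keep])
            k = int(keep.sum())
            area_out.append(
                np.full(k, 4.0 * np.pi * expanded[i] ** 2 / dots_per_atom)
            )
            parent_out.append(np.full(k, i, dtype=int))

    if not pos_out:
        positions = np.empty((0, 3))
        normals = np.empty((0, 3))
        areas = np.empty(0)
        parents = np.empty(0, dtype=int)
    else:
        positions = np.vstack(pos_out)
        normals = np.vstack(nrm_out)
        areas = np.concatenate(area_out)
        parents = np.concatenate(parent_out)
    return DotSurface(positions, normals, areas, parents, probe, dots_per_atom)


def auto_link_distance(surface: DotSurface) -> float:
    """2x the mean nearest-neighbour dot spacing, clamped to [0.5, 5] Å."""
    if surface.n_dots < 2:
        return LINK_CLAMP[0]
    tree = cKDTree(surface.positions)
    d, _ = tree.query(surface.positions, k=2)
    mean_nn = float(d[:, 1].mean())
    return float(np.clip(2.0 * mean_nn, *LINK_CLAMP))


def link_neighbours(
    surface: DotSurface, link_distance: float | None = None
) -> DotSurface:
    """Attach a symmetric dot-adjacency graph (Euclidean cutoff) in place."""
    if link_distance is None:
        link_distance = auto_link_distance(surface)
    if link_distance <= 0:
        raise ValueError("link_distance must be positive")
    tree = cKDTree(surface.positions)
    pairs = tree.query_pairs(link_distance, output_type="ndarray")
    m = surface.n_dots
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        adj = sparse.coo_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
        adj = (adj + adj.T).tocsr()
    else:
        adj = sparse.csr_matrix((m, m), dtype=np.int8)
    surface.adjacency = adj
    surface.link_distance = float(link_distance)
    return surface
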