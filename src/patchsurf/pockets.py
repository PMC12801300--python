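"""Dual-probe pocket detection.

A pocket is a region of space accessible to the water-sized probe but not to
a bigger one: voxels inside the SES built with the big probe (3.0 A by
default) and outside the regular SES.  The two surfaces are colored on the
same grid, their volumetric difference is taken on a plain dense grid (the
read/write-heavy flood fill makes the bilevel layout counterproductive
here), and 6-connected components above a size threshold become pockets,
each triangulated by Marching Cubes on its binary voxel mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import AtomSet, SurfaceConfig
from .meshing import TriMesh, approximate_normals, marching_cubes
from .pipeline import color_atoms
from .raytrace import RayGrid
from .storage import Status, StatusMap

log = logging.getLogger("patchsurf")

__all__ = ["Pocket", "PocketSet", "differential_grid", "isolate_pockets",
           "triangulate_pocket", "detect_pockets", "min_pocket_voxels"]


@dataclass
class Pocket:
    voxels: np.ndarray            # (k, 3) node indices, 6-connected
    volume: float                 # voxel count * h^3, A^3
    mesh: TriMesh | None = None


@dataclass
class PocketSet:
    pockets: list[Pocket] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pockets)


def min_pocket_voxels(grid_scale: float) -> int:
    """Size filter suppressing shell noise near the surface: 8 voxels at
    s = 2, scaled with voxel density (s/2)^3."""
    return max(1, int(round(8.0 * (grid_scale / 2.0) ** 3)))


def differential_grid(atoms: AtomSet, config: SurfaceConfig,
                      grid: RayGrid | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, RayGrid]:
    """Dense difference mask: inside the big-probe SES and outside the
    regular one.  Returns (diff, inside_big, inside_small, grid); both runs
    share one grid sized for the big probe."""
    if config.big_probe_radius <= config.probe_radius:
        raise ValueError("big_probe_radius must exceed probe_radius")
    if grid is None:
        grid = RayGrid.from_atoms(atoms, config, probe=config.big_probe_radius)
    inside_small = color_atoms(atoms, config, grid, config.probe_radius)
    inside_big = color_atoms(atoms, config, grid, config.big_probe_radius)
    if inside_small.shape != inside_big.shape:
        raise RuntimeError("dual-probe grids have mismatching dims")
    diff = inside_big & ~inside_small
    log.info("pockets: differential grid has %d marked voxels", int(diff.sum()))
    return diff, inside_big, inside_small, grid


def isolate_pockets(diff: np.ndarray, grid: RayGrid,
                    min_voxels: int | None = None) -> PocketSet:
    """Split the differential mask into 6-connected components (iterative
    flood fill), discarding components below the size threshold."""
    if min_voxels is None:
        min_voxels = min_pocket_voxels(1.0 / grid.h)
    structure = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
    labels, n = ndimage.label(diff, structure=structure)
    pockets: list[Pocket] = []
    h3 = grid.h**3
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_voxels:
            continue
        pockets.append(Pocket(voxels=vox, volume=len(vox) * h3))
    pockets.sort(key=lambda p: -p.volume)
    log.info("pockets: %d components kept of %d (threshold %d voxels)",
             len(pockets), n, min_voxels)
    return PocketSet(pockets)


def triangulate_pocket(pocket: Pocket, grid: RayGrid) -> TriMesh:
    """Closed boundary mesh of the pocket's voxel region by Marching Cubes on
    its binary mask (midpoint vertices; no analytic intersections exist for a
    volumetric difference)."""
    if len(pocket.voxels) == 0:
        raise ValueError("cannot triangulate an empty pocket")
    mask = np.zeros(grid.dims, dtype=np.uint8)
    mask[tuple(pocket.voxels.T)] = int(Status.INSIDE)
    status = StatusMap.from_dense(mask)
    mesh, dangling = marching_cubes(status, None, None, grid)
    mesh = approximate_normals(mesh, dangling)
    pocket.mesh = mesh
    return mesh


def detect_pockets(atoms: AtomSet, config: SurfaceConfig,
                   min_voxels: int | None = None) -> tuple[PocketSet, RayGrid]:
    """Full pocket pipeline: dual-probe difference, isolation, triangulation."""
    diff, _big, _small, grid = differential_grid(atoms, config)
    pockets = isolate_pockets(diff, grid, min_voxels)
    for p in pockets.pockets:
        triangulate_pocket(p, grid)
    return pockets, grid
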