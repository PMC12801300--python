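"""End-to-end surface pipeline: buildup -> ray tracing -> coloring ->
Marching Cubes -> normals approximation -> smoothing -> measures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AtomSet, SurfaceConfig
from .meshing import TriMesh, approximate_normals, marching_cubes, mesh_statistics, smooth
from .raytrace import (RayGrid, RayIntersectionSet, apply_skipping_set,
                       color_status_map, estimate_volume_area,
                       repair_failed_rays, trace_patches)
from .ses import PatchSet, build_ses
from .storage import StatusMap

log = logging.getLogger("patchsurf")

__all__ = ["SurfaceResult", "build_surface", "color_atoms"]


@dataclass
class SurfaceResult:
    mesh: TriMesh
    status: StatusMap
    grid: RayGrid
    patches: PatchSet
    volume: float
    area: float
    stats: dict = field(default_factory=dict)


def build_surface(atoms: AtomSet, config: SurfaceConfig,
                  grid: RayGrid | None = None,
                  torus_solver=None) -> SurfaceResult:
    """Run the full pipeline on an atom set and return mesh plus measures."""
    log.info("stage buildup: %d atoms, probe %.2f A, scale %.2f 1/A",
             atoms.count, config.probe_radius, config.grid_scale)
    patches = build_ses(atoms, config)
    if grid is None:
        grid = RayGrid.from_atoms(atoms, config)
    log.info("stage RT: grid dims %s, h = %.3f A", grid.dims, grid.h)
    edge_rays = trace_patches(patches, grid, "edge", torus_solver=torus_solver)
    cell_rays = trace_patches(patches, grid, "cell", torus_solver=torus_solver)
    for rays in (edge_rays, cell_rays):
        apply_skipping_set(rays, config.skip_strategy, config.skip_eps)
        repair_failed_rays(rays)
    log.info("stage coloring")
    status = color_status_map(edge_rays, grid)
    log.info("stage MC")
    mesh, dangling = marching_cubes(status, None, edge_rays, grid)
    mesh = approximate_normals(mesh, dangling)
    log.info("stage smoothing: %d iterations", config.smoothing_iterations)
    mesh = smooth(mesh, config.smoothing_iterations)
    volume, area = estimate_volume_area(edge_rays, cell_rays, mesh, grid)
    stats = mesh_statistics(mesh)
    stats.update(
        n_patches=len(patches),
        patch_counts=patches.counts_by_kind(),
        n_failed_rays=len(edge_rays.failed) + len(cell_rays.failed),
        n_dangling=int(dangling.count()) if dangling.length else 0,
    )
    return SurfaceResult(mesh=mesh, status=status, grid=grid, patches=patches,
                         volume=volume, area=area, stats=stats)


def color_atoms(atoms: AtomSet, config: SurfaceConfig, grid: RayGrid,
                probe: float) -> np.ndarray:
    """Dense inside mask of the SES at the given probe radius on a fixed
    grid (used by dual-probe pocket detection)."""
    cfg = config.with_(probe_radius=probe,
                       halo_thickness=max(config.halo_thickness, 2.0 * probe))
    patches = build_ses(atoms, cfg)
    rays = trace_patches(patches, grid, "edge")
    apply_skipping_set(rays, cfg.skip_strategy, cfg.skip_eps)
    repair_failed_rays(rays)
    from .raytrace import family_inside
    votes = sum(family_inside(rays, d).astype(np.int8) for d in range(3))
    return votes >= 2
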