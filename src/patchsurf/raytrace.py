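"""Patch-based axis-aligned ray tracing and parity grid coloring.

Classic surface sampling iterates over rays and needs spatial indices to find
the patches each ray pierces.  Because no SES patch occludes another and every
patch is pierced by some ray at sane resolutions, the iteration can be
inverted: walk the patch list once, find the rays of all three axis-aligned
families that pass through each patch's trimming-solid bounding box, and
accumulate intersections in per-ray buckets.  No acceleration structure is
needed anywhere.

Rays are cast from *pixels*, the lattice points of a bounding-box face;
``edge`` rays run through grid nodes and drive coloring and meshing, ``cell``
rays run through cell centers and contribute a fourth, independent volume
estimate.  By construction rays start and finish outside the surface, so a
complete ray crosses it an even number of times; odd (failed) rays are
repaired by copying the previous ray of the raster scan, which keeps the
extracted surface manifold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import AtomSet, SurfaceConfig
from .quartic import Torus, ray_torus_intersect
from .ses import CONCAVE_SPHERE, CONVEX_SPHERE, TORUS, Patch, PatchSet
from .storage import Status, StatusMap

log = logging.getLogger("patchsurf")

__all__ = [
    "RayGrid",
    "RayIntersectionSet",
    "rays_through_bbox",
    "intersect_patch",
    "trace_patches",
    "apply_skipping",
    "repair_failed_rays",
    "color_status_map",
    "estimate_volume_area",
]

_AXES = np.eye(3)
# Pixel axes per ray family, ascending.
_PIXEL_AXES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


@dataclass(frozen=True)
class RayGrid:
    """Regular node grid; spacing h = 1/s.  Node (i,j,k) sits at
    ``origin + (i,j,k) * h``.  The box encloses every atom inflated by its
    radius plus the probe plus a 2h margin, so rays always start and finish
    outside the surface."""

    origin: np.ndarray
    h: float
    dims: tuple[int, int, int]

    @classmethod
    def from_atoms(cls, atoms: AtomSet, config: SurfaceConfig,
                   probe: float | None = None) -> "RayGrid":
        h = config.spacing
        rp = config.probe_radius if probe is None else probe
        margin = rp + 2.0 * h
        lo = np.min(atoms.centers - atoms.radii[:, None], axis=0) - margin
        hi = np.max(atoms.centers + atoms.radii[:, None], axis=0) + margin
        dims = tuple(int(math.ceil((hi[a] - lo[a]) / h)) + 1 for a in range(3))
        return cls(origin=lo, h=h, dims=dims)

    def pixel_dims(self, family: int, ray_class: str = "edge") -> tuple[int, int]:
        a1, a2 = _PIXEL_AXES[family]
        off = 0 if ray_class == "edge" else 1
        return self.dims[a1] - off, self.dims[a2] - off

    def ray_origin(self, family: int, iu: int, iv: int, ray_class: str = "edge") -> np.ndarray:
        a1, a2 = _PIXEL_AXES[family]
        p = self.origin.copy()
        shift = 0.0 if ray_class == "edge" else 0.5
        p[a1] += (iu + shift) * self.h
        p[a2] += (iv + shift) * self.h
        return p

    def node_coords(self, idx: np.ndarray) -> np.ndarray:
        return self.origin[None, :] + np.asarray(idx, dtype=float) * self.h


class RayIntersectionSet:
    """Per-ray ordered intersection lists for the three axis-aligned
    families.  Each record is (t, outward unit normal, patch id)."""

    def __init__(self, grid: RayGrid, ray_class: str = "edge"):
        self.grid = grid
        self.ray_class = ray_class
        self.families: list[dict[tuple[int, int], list]] = [{}, {}, {}]
        self.failed: set[tuple[int, int, int]] = set()
        self._final = False

    def add(self, family: int, pixel: tuple[int, int], t: float,
            normal: np.ndarray, patch_id: int) -> None:
        self.families[family].setdefault(pixel, []).append((t, normal, patch_id))

    def finalize(self) -> None:
        """Sort each ray's records ascending in t (patch id breaks ties)."""
        for fam in self.families:
            for pixel, recs in fam.items():
                recs.sort(key=lambda r: (r[0], r[2]))
        self._final = True

    def records(self, family: int, pixel: tuple[int, int]) -> list:
        return self.families[family].get(pixel, [])

    def n_records(self) -> int:
        return sum(len(r) for fam in self.families for r in fam.values())


def rays_through_bbox(bbox: np.ndarray, grid: RayGrid, family: int,
                      ray_class: str = "edge") -> list[tuple[int, int]]:
    """Pixels whose ray line intersects the closed axis-aligned box."""
    a1, a2 = _PIXEL_AXES[family]
    nu, nv = grid.pixel_dims(family, ray_class)
    shift = 0.0 if ray_class == "edge" else 0.5
    out: list[tuple[int, int]] = []
    rng = []
    for a, n in ((a1, nu), (a2, nv)):
        lo = (bbox[0][a] - grid.origin[a]) / grid.h - shift
        hi = (bbox[1][a] - grid.origin[a]) / grid.h - shift
        i0 = max(0, int(math.ceil(lo - 1e-9)))
        i1 = min(n - 1, int(math.floor(hi + 1e-9)))
        if i1 < i0:
            return []
        rng.append((i0, i1))
    (u0, u1), (v0, v1) = rng
    for iu in range(u0, u1 + 1):
        for iv in range(v0, v1 + 1):
            out.append((iu, iv))
    return out


# ---------------------------------------------------------------------------
# patch / ray intersection


def _sphere_hits(patch: Patch, origins: np.ndarray, d: int) -> list[tuple[int, float, np.ndarray]]:
    """Vectorized sphere-ray intersections for a bundle of parallel rays."""
    oc = origins - patch.center[None, :]
    b = oc[:, d]
    c = np.einsum("ij,ij->i", oc, oc) - patch.radius**2
    disc = b * b - c
    sel = np.flatnonzero(disc >= 0.0)
    hits: list[tuple[int, float, np.ndarray]] = []
    if len(sel) == 0:
        return hits
    sq = np.sqrt(disc[sel])
    for sign in (-1.0, 1.0):
        ts = -b[sel] + sign * sq
        pts = origins[sel].copy()
        pts[:, d] += ts
        ok = patch.on_patch(pts)
        for ridx, t, p in zip(sel[ok], ts[ok], pts[ok]):
            hits.append((int(ridx), float(t), p))
    return hits


def _torus_hits(patch: Patch, origins: np.ndarray, d: int,
                torus_solver=None) -> list[tuple[int, float, np.ndarray]]:
    solver = torus_solver or ray_torus_intersect
    tor = Torus(patch.center, patch.axis, patch.ring_radius, patch.radius,
                frame=patch.frame)
    direction = _AXES[d]
    hits: list[tuple[int, float, np.ndarray]] = []
    for ridx in range(len(origins)):
        ts = solver(origins[ridx], direction, tor)
        if not ts:
            continue
        pts = origins[ridx][None, :] + np.asarray(ts)[:, None] * direction[None, :]
        ok = patch.on_patch(pts)
        for t, p, keep in zip(ts, pts, ok):
            if keep:
                hits.append((ridx, float(t), p))
    return hits


def _patch_ray_hits(patch: Patch, origins: np.ndarray, d: int,
                    torus_solver=None) -> list[tuple[int, float, np.ndarray]]:
    if patch.kind == TORUS:
        return _torus_hits(patch, origins, d, torus_solver)
    return _sphere_hits(patch, origins, d)


def intersect_patch(patch: Patch, ray: tuple[np.ndarray, np.ndarray],
                    torus_solver=None) -> list[tuple[float, np.ndarray]]:
    """All (t, outward normal) intersections of one ray with a trimmed patch.

    ``ray`` is (origin, unit axis-aligned direction).  Sphere patches solve
    the quadratic, torus patches the analytic quartic; every candidate is
    kept only if it lies on the trimmed patch.
    """
    origin, direction = (np.asarray(v, dtype=float) for v in ray)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("ray direction must be a unit vector")
    d = int(np.argmax(np.abs(direction)))
    if abs(abs(direction[d]) - 1.0) > 1e-9:
        raise ValueError("rays are axis-aligned in this tracer")
    flip = direction[d] < 0
    hits = _patch_ray_hits(patch, origin[None, :], d, torus_solver)
    out = []
    for _, t, p in hits:
        tt = -t if flip else t
        n = patch.surface_normal(p[None, :])[0]
        out.append((tt, n))
    out.sort(key=lambda r: r[0])
    return out


def trace_patches(patches: PatchSet, grid: RayGrid, ray_class: str = "edge",
                  torus_solver=None, cull: bool = True) -> RayIntersectionSet:
    """Patch-based tracing of all three ray families.

    For each patch the rays piercing its trimming-solid bounding box are
    enumerated (``cull=False`` tests every ray of the grid instead, which is
    the ray-centric reference behavior), intersections are stored per ray,
    then each ray's list is sorted along the ray.
    """
    rays = RayIntersectionSet(grid, ray_class)
    for patch in patches.patches:
        for d in range(3):
            if cull:
                pixels = rays_through_bbox(patch.trim.bbox, grid, d, ray_class)
            else:
                nu, nv = grid.pixel_dims(d, ray_class)
                pixels = [(iu, iv) for iu in range(nu) for iv in range(nv)]
            if not pixels:
                continue
            origins = np.array([grid.ray_origin(d, iu, iv, ray_class) for iu, iv in pixels])
            for ridx, t, p in _patch_ray_hits(patch, origins, d, torus_solver):
                n = patch.surface_normal(p[None, :])[0]
                rays.add(d, pixels[ridx], t, n, patch.id)
    rays.finalize()
    log.info("RT (%s rays): %d intersection records", ray_class, rays.n_records())
    return rays


# ---------------------------------------------------------------------------
# skipping, repair, coloring


def apply_skipping(records: list, strategy: str = "two_point", eps: float = 1e-7) -> list:
    """Remove suspicious near-coincident entry/exit pairs from one sorted ray.

    Records are paired (0,1), (2,3), ...; when an exit lies closer than
    ``eps`` to its entry partner, ``one_point`` drops the exit only while
    ``two_point`` drops both, preserving the parity the ray already had.
    """
    if strategy not in ("one_point", "two_point"):
        raise ValueError(f"unknown skip strategy {strategy!r}")
    out: list = []
    k = 0
    while k < len(records):
        if k + 1 < len(records) and records[k + 1][0] - records[k][0] < eps:
            if strategy == "one_point":
                out.append(records[k])
            k += 2
            continue
        out.append(records[k])
        k += 1
    return out


def apply_skipping_set(rays: RayIntersectionSet, strategy: str = "two_point",
                       eps: float = 1e-7) -> RayIntersectionSet:
    dropped = 0
    for fam in rays.families:
        for pixel in list(fam):
            before = fam[pixel]
            after = apply_skipping(before, strategy, eps)
            dropped += len(before) - len(after)
            if after:
                fam[pixel] = after
            else:
                del fam[pixel]
    if dropped:
        log.info("skipping (%s): removed %d records", strategy, dropped)
    return rays


def repair_failed_rays(rays: RayIntersectionSet) -> RayIntersectionSet:
    """Replace odd-count rays with a copy of the previously processed ray of
    the same family (raster order); the first ray of a family falls back to
    the empty list (all outside).  Afterwards every ray is even."""
    n_failed = 0
    for d in range(3):
        nu, nv = rays.grid.pixel_dims(d, rays.ray_class)
        fam = rays.families[d]
        prev: list = []
        for iu in range(nu):
            for iv in range(nv):
                rec = fam.get((iu, iv), [])
                if len(rec) % 2 == 1:
                    rays.failed.add((d, iu, iv))
                    n_failed += 1
                    if prev:
                        fam[(iu, iv)] = list(prev)
                    elif (iu, iv) in fam:
                        del fam[(iu, iv)]
                    rec = prev
                prev = rec
    if n_failed:
        log.info("repair: %d failed rays replaced", n_failed)
    return rays


def family_inside(rays: RayIntersectionSet, family: int) -> np.ndarray:
    """Dense inside mask induced by one edge-ray family alone."""
    grid = rays.grid
    nx, ny, nz = grid.dims
    inside = np.zeros((nx, ny, nz), dtype=bool)
    a1, a2 = _PIXEL_AXES[family]
    nd = grid.dims[family]
    coords = np.arange(nd) * grid.h
    for (iu, iv), recs in rays.families[family].items():
        ts = np.array([r[0] for r in recs])
        parity = np.searchsorted(ts, coords, side="left") % 2 == 1
        idx = [None, None, None]
        idx[family] = slice(None)
        idx[a1] = iu
        idx[a2] = iv
        inside[tuple(idx)] = parity
    return inside


def color_status_map(rays: RayIntersectionSet, grid: RayGrid) -> StatusMap:
    """Parity coloring: a node between an odd and the next even crossing of
    its ray is inside.  The three families vote independently; a node is
    inside on a 2-of-3 majority (with three binary votes there are no ties,
    so the tie-breaks-to-outside rule is vacuous but stated)."""
    votes = np.zeros(grid.dims, dtype=np.int8)
    for d in range(3):
        votes += family_inside(rays, d)
    inside = votes >= 2
    n_in = int(inside.sum())
    log.info("coloring: %d interior nodes of %d", n_in, votes.size)
    return StatusMap.from_dense(inside.astype(np.uint8) * int(Status.INSIDE))


def boundary_cells(status: StatusMap) -> np.ndarray:
    """Boolean mask of grid cells with mixed-status corners."""
    dense = status.to_dense() == int(Status.INSIDE)
    c = dense[:-1, :-1, :-1]
    mixed = np.zeros_like(c)
    agree = np.ones_like(c)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                nx, ny, nz = dense.shape
                corner = dense[dx : nx - 1 + dx, dy : ny - 1 + dy, dz : nz - 1 + dz]
                agree &= corner == c
    mixed = ~agree
    return mixed


# ---------------------------------------------------------------------------
# volume and area


def _family_volume(rays: RayIntersectionSet, family: int) -> float:
    total = 0.0
    for recs in rays.families[family].values():
        ts = [r[0] for r in recs]
        for k in range(0, len(ts) - 1, 2):
            total += ts[k + 1] - ts[k]
    return total * rays.grid.h**2


def estimate_volume_area(edge_rays: RayIntersectionSet,
                         cell_rays: RayIntersectionSet | None,
                         mesh, grid: RayGrid) -> tuple[float, float]:
    """Volume as the mean of four independent parity estimates (one per
    edge-ray family plus one from the cell rays), each the sum of inside
    segment lengths times h^2; area as the summed mesh triangle area."""
    estimates = [_family_volume(edge_rays, d) for d in range(3)]
    if cell_rays is not None:
        estimates.append(_family_volume(cell_rays, 0))
    volume = float(np.mean(estimates))
    area = 0.0
    if mesh is not None and len(mesh.triangles):
        v = mesh.vertices
        t = mesh.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    log.info("volume estimates %s -> %.6g A^3; area %.6g A^2", estimates, volume, area)
    return volume, area
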