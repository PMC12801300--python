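"""Brute-force reference implementations used only by the test suite.

Each oracle is independent of the production code path it checks: companion
matrices for polynomial roots, dense angular/volumetric sampling for probe
geometry, explicit neighbor lists for smoothing, BFS for components.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from patchsurf.io import AtomSet, SurfaceConfig
from patchsurf.quartic import Torus
from patchsurf.raytrace import RayGrid, RayIntersectionSet, trace_patches


def companion_roots(coeffs) -> list[float]:
    """Real roots of a monic polynomial via companion-matrix eigenvalues."""
    coeffs = np.asarray(coeffs, dtype=float)
    assert coeffs[0] == 1.0
    n = len(coeffs) - 1
    comp = np.zeros((n, n))
    comp[1:, :-1] = np.eye(n - 1)
    comp[:, -1] = -coeffs[1:][::-1]
    ev = np.linalg.eigvals(comp)
    real = [float(z.real) for z in ev if abs(z.imag) <= 1e-10 * (1.0 + abs(z.real))]
    return sorted(real)


def probe_pair_edge_oracle(atoms: AtomSet, probe_radius: float, i: int, j: int,
                           n_angles: int = 4000) -> bool:
    """Can a probe be placed tangent to atoms i and j without intersecting any
    other inflated atom?  Fine angular sampling of the probe-center circle."""
    C, R = atoms.centers, atoms.radii + probe_radius
    d = np.linalg.norm(C[j] - C[i])
    if d >= R[i] + R[j] or d <= abs(R[i] - R[j]):
        return False
    u = (C[j] - C[i]) / d
    t = (d * d + R[i] ** 2 - R[j] ** 2) / (2.0 * d)
    rho2 = R[i] ** 2 - t * t
    if rho2 <= 0.0:
        return False
    rho = math.sqrt(rho2)
    o = C[i] + t * u
    k = int(np.argmin(np.abs(u)))
    seed = np.zeros(3)
    seed[k] = 1.0
    e1 = seed - u * (seed @ u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    ang = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    pts = o[None, :] + rho * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    others = [l for l in range(atoms.count) if l not in (i, j)]
    if not others:
        return True
    dist = np.linalg.norm(pts[:, None, :] - C[others][None, :, :], axis=2)
    free = np.all(dist >= R[others][None, :] - 1e-9, axis=1)
    return bool(free.any())


def ray_centric_trace(patches, grid: RayGrid, ray_class: str = "edge") -> RayIntersectionSet:
    """Conventional tracing: every ray tested against every patch (no
    bounding-box culling)."""
    return trace_patches(patches, grid, ray_class, cull=False)


def dense_status_oracle(atoms: AtomSet, config: SurfaceConfig,
                        grid: RayGrid, probe: float | None = None) -> np.ndarray:
    """Approximate inside mask by probe-center sampling at h/2 resolution.

    A node is inside iff it lies in an atom ball, or in an inflated ball
    while no freely placeable probe ball covers it.  Accurate away from the
    surface; use with a one-voxel tolerance band.
    """
    rp = config.probe_radius if probe is None else probe
    C, r = atoms.centers, atoms.radii
    R = r + rp
    h = grid.h
    nx, ny, nz = grid.dims
    idx = np.indices((nx, ny, nz)).reshape(3, -1).T
    nodes = grid.origin[None, :] + idx * h

    in_atom = np.zeros(len(nodes), dtype=bool)
    in_inflated = np.zeros(len(nodes), dtype=bool)
    for a in range(atoms.count):
        dd = np.linalg.norm(nodes - C[a], axis=1)
        in_atom |= dd <= r[a]
        in_inflated |= dd <= R[a]

    inside = in_atom.copy()
    cand = in_inflated & ~in_atom
    if cand.any() and rp > 0.0:
        # Free probe centers sampled on an h/2 lattice over the padded box.
        step = h / 2.0
        lo = grid.origin - rp
        hi = grid.origin + (np.array(grid.dims) - 1) * h + rp
        axes = [np.arange(lo[a], hi[a] + step, step) for a in range(3)]
        P = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        free = np.ones(len(P), dtype=bool)
        for a in range(atoms.count):
            free &= np.linalg.norm(P - C[a], axis=1) >= R[a] - 1e-9
        ftree = cKDTree(P[free])
        dist_free, _ = ftree.query(nodes[cand])
        inside[np.flatnonzero(cand)[dist_free > rp]] = True
    elif cand.any():
        inside |= cand
    return inside.reshape(nx, ny, nz)


def mixed_neighborhood(mask: np.ndarray) -> np.ndarray:
    """Nodes whose 3x3x3 neighborhood is not constant: the one-voxel band
    where an approximate oracle may legitimately disagree."""
    out = np.zeros_like(mask)
    nx, ny, nz = mask.shape
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                sl = mask[max(dx, 0):nx + min(dx, 0), max(dy, 0):ny + min(dy, 0),
                          max(dz, 0):nz + min(dz, 0)]
                tgt = out[max(-dx, 0):nx - max(dx, 0), max(-dy, 0):ny - max(dy, 0),
                          max(-dz, 0):nz - max(dz, 0)]
                tgt |= sl != mask[max(-dx, 0):nx - max(dx, 0), max(-dy, 0):ny - max(dy, 0),
                                  max(-dz, 0):nz - max(dz, 0)]
    return out


def bisect_torus_roots(origin, direction, torus: Torus, t_max: float = 60.0,
                       n_samples: int = 10000) -> list[float]:
    """Dense-sampling sign-change bracketing of the ray-torus quartic followed
    by bisection refinement."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)

    def f(t):
        return torus.implicit(o + t * d)

    ts = np.linspace(-t_max, t_max, n_samples)
    vals = np.array([f(t) for t in ts])
    roots = []
    for k in range(len(ts) - 1):
        a, b = ts[k], ts[k + 1]
        fa, fb = vals[k], vals[k + 1]
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0.0:
            for _ in range(80):
                m = 0.5 * (a + b)
                fm = f(m)
                if fa * fm <= 0.0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
    return sorted(roots)


def degraded_torus_solver(origin, direction, torus: Torus) -> list[float]:
    """Deliberately loose iterative solver (coarse sampling, shallow
    bisection): the pre-analytical baseline for failed-ray comparisons."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)

    def f(t):
        return torus.implicit(o + t * d)

    ts = np.linspace(0.0, 60.0, 300)      # coarse: misses grazing pairs
    roots = []
    prev_t, prev_f = ts[0], f(ts[0])
    for t in ts[1:]:
        ft = f(t)
        if prev_f * ft < 0.0:
            a, b, fa = prev_t, t, prev_f
            for _ in range(12):           # loose tolerance
                m = 0.5 * (a + b)
                fm = f(m)
                if fa * fm <= 0.0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
        prev_t, prev_f = t, ft
    return roots


def neighbor_list_smooth(mesh, iterations: int = 1):
    """Explicit neighbor-list Laplacian smoothing (with duplicate checks),
    the reference for the doubled-count scheme."""
    verts = mesh.vertices.copy()
    normals = mesh.normals.copy()
    nbrs: list[set[int]] = [set() for _ in range(len(verts))]
    for a, b, c in mesh.triangles:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    order = [sorted(s) for s in nbrs]
    for _ in range(iterations):
        nv = np.zeros_like(verts)
        nn = np.zeros_like(normals)
        for v, ns in enumerate(order):
            nv[v] = verts[ns].mean(axis=0)
            m = normals[ns].mean(axis=0)
            ln = np.linalg.norm(m)
            nn[v] = m / ln if ln > 0 else m
        verts, normals = nv, nn
    out = mesh.copy()
    out.vertices = verts
    out.normals = normals
    return out


def bfs_components(mask: np.ndarray) -> np.ndarray:
    """6-connected component labels by explicit BFS (0 = background)."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                n = (i + di, j + dj, k + dk)
                if (0 <= n[0] < mask.shape[0] and 0 <= n[1] < mask.shape[1]
                        and 0 <= n[2] < mask.shape[2] and mask[n] and not labels[n]):
                    labels[n] = nxt
                    stack.append(n)
    return labels
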