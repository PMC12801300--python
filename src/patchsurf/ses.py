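"""Analytical solvent-excluded surface (SES) construction.

The SES of a set of atom spheres under a rolling probe of radius r_p is a
union of three analytic patch families:

* a convex spherical patch per surface-exposed atom (the atom sphere where
  the probe touches it directly),
* a toroidal patch per alpha-complex edge (the inward face of the torus swept
  by the probe rolling over two atoms), and
* a concave spherical patch per fixed probe position resting on three atoms
  (two positions per alpha triangle when the probe fits on both sides).

Which pairs and triples of atoms the probe can actually touch is encoded by
the zero-alpha complex of the atoms weighted by (r_i + r_p)^2.  Here that
complex is built directly from its geometric characterization: an edge (i, j)
exists iff some point of the probe-center circle around the pair is free of
every other inflated atom (an exact occlusion-arc computation on the circle),
and a triangle iff a trilaterated probe position tangent to all three atoms is
unoccluded.  For non-degenerate input this coincides with the alpha-complex
filtration of the regular (weighted Delaunay) triangulation.

The buildup supports a deterministic slab decomposition along Y with halo
bands, mirroring a multithreaded domain decomposition: patches are built per
slab over slab+halo atoms and duplicates are removed by the bottom-vertex
rule.  Because every quantity entering a patch is computed from the same atom
coordinates in the same (globally sorted) order regardless of the slab, the
result is bitwise independent of the slab count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import AtomSet, SurfaceConfig
from .quartic import _axis_frame

log = logging.getLogger("patchsurf")

__all__ = [
    "TrimmingSolid",
    "Patch",
    "PatchSet",
    "AlphaComplex",
    "SlabPartition",
    "build_alpha_complex",
    "build_patches",
    "slab_partition",
    "dedup_patches",
    "build_ses",
]

# Geometric tolerances (Angstrom unless noted).
_OCC_TOL = 1e-9        # clearance below which a probe counts as intersecting
_ARC_TOL = 1e-7        # minimum free-arc length (radians) for an edge to exist
_TRIM_TOL = 1e-9       # half-space membership slack
_MIN_SLAB = 12.0       # minimum slab thickness, Angstrom
_MINI_SLAB = 1.0       # mini-slab binning width, Angstrom


@dataclass(frozen=True)
class TrimmingSolid:
    """Convex solid clipping a patch: intersection of half-spaces
    ``normal . x <= offset``; ``vertices`` are its corner points when the
    construction yields them (empty for unbounded solids); ``bbox`` is an
    axis-aligned box enclosing the clipped patch geometry."""

    normals: np.ndarray   # (m, 3) unit normals
    offsets: np.ndarray   # (m,)
    vertices: np.ndarray  # (k, 3)
    bbox: np.ndarray      # (2, 3) min/max corners

    def contains(self, points: np.ndarray, tol: float = _TRIM_TOL) -> np.ndarray:
        pts = np.atleast_2d(points)
        if len(self.normals) == 0:
            return np.ones(len(pts), dtype=bool)
        return np.all(pts @ self.normals.T <= self.offsets[None, :] + tol, axis=1)

    def bottom_vertex_y(self) -> float:
        """Y coordinate of the bottom-most vertex (bbox corner fallback for
        solids without explicit corners); drives slab dedup."""
        if len(self.vertices):
            return float(np.min(self.vertices[:, 1]))
        return float(self.bbox[0, 1])


CONVEX_SPHERE = "convex_sphere"
TORUS = "torus"
CONCAVE_SPHERE = "concave_sphere"


@dataclass
class Patch:
    """A typed SES patch with its trimming solid.

    ``atoms`` are the global ids of the generating atoms; together with
    ``side`` (concave patches only: +1/-1 for the two probe positions) they
    identify a patch uniquely, which the slab dedup relies on.  Torus patches
    additionally carry the free-arc set of the rolling circle and the
    deterministic torus frame; ``band`` holds the two tangency-circle axial
    coordinates and the tangency ring radii.
    """

    kind: str
    center: np.ndarray
    radius: float
    trim: TrimmingSolid
    atoms: tuple[int, ...]
    id: int = -1
    side: int = 0
    axis: np.ndarray | None = None
    ring_radius: float | None = None
    frame: np.ndarray | None = None
    arcs: list[tuple[float, float]] | None = None   # None = full circle
    # Concave patches: (unit normal, offset) radical half-spaces against
    # overlapping neighbor probe balls (self-intersection trim).
    probe_clips: tuple[np.ndarray, np.ndarray] | None = None

    def sort_key(self):
        return ({CONVEX_SPHERE: 0, TORUS: 1, CONCAVE_SPHERE: 2}[self.kind], self.atoms, self.side)

    # -- membership beyond the half-space trim ------------------------------
    def on_patch(self, points: np.ndarray, tol: float = _TRIM_TOL) -> np.ndarray:
        """True for surface points that belong to the trimmed patch."""
        pts = np.atleast_2d(points)
        ok = self.trim.contains(pts, tol)
        if self.kind == CONCAVE_SPHERE and self.probe_clips is not None and ok.any():
            cn, co = self.probe_clips
            ok &= np.all(pts @ cn.T <= co[None, :] + tol, axis=1)
        if self.kind == TORUS and ok.any():
            q = pts - self.center
            z = q @ self.axis
            rho2 = np.einsum("ij,ij->i", q, q) - z * z
            # Inner torus half only: the probe-facing side.
            ok &= rho2 <= (self.ring_radius + tol) ** 2
            if self.ring_radius < self.radius:
                # Spindle torus: the probe self-intersects across the axis at
                # z = +-sqrt(r_p^2 - R^2); the lens between those circles is
                # interior to the SES solid and must be excluded.
                zc2 = self.radius**2 - self.ring_radius**2
                ok &= z * z >= zc2 - 1e-9
            if self.arcs is not None:
                u = q @ self.frame[0]
                v = q @ self.frame[1]
                phi = np.arctan2(v, u) % (2.0 * math.pi)
                in_arc = np.zeros(len(pts), dtype=bool)
                for a, b in self.arcs:
                    # Arcs stored with a <= b on the unwrapped circle.
                    ph = np.where(phi < a - tol, phi + 2.0 * math.pi, phi)
                    in_arc |= (ph >= a - 1e-9) & (ph <= b + 1e-9)
                ok &= in_arc
        return ok

    def surface_normal(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normals of the SES at on-patch surface points."""
        pts = np.atleast_2d(points)
        if self.kind == CONVEX_SPHERE:
            n = pts - self.center
        elif self.kind == CONCAVE_SPHERE:
            n = self.center - pts          # inward radial: toward probe center
        else:
            q = pts - self.center
            z = (q @ self.axis)[:, None]
            planar = q - z * self.axis[None, :]
            lp = np.linalg.norm(planar, axis=1, keepdims=True)
            lp[lp == 0.0] = 1.0
            ring_pt = self.center + self.ring_radius * planar / lp
            n = ring_pt - pts              # toward the rolling probe center
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        return n / norm


@dataclass
class PatchSet:
    patches: list[Patch]
    probe_radius: float

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patches]
        if ids != list(range(len(ids))):
            raise ValueError("patch ids must be unique and contiguous")

    def counts_by_kind(self) -> dict[str, int]:
        out = {CONVEX_SPHERE: 0, TORUS: 0, CONCAVE_SPHERE: 0}
        for p in self.patches:
            out[p.kind] += 1
        return out

    def __len__(self) -> int:
        return len(self.patches)


# ---------------------------------------------------------------------------
# alpha complex


@dataclass
class EdgeInfo:
    atoms: tuple[int, int]
    center: np.ndarray      # probe-circle center
    axis: np.ndarray        # unit, from atom i to atom j (i < j)
    ring_radius: float      # probe-circle radius
    free_arcs: list[tuple[float, float]] | None  # None = full circle
    frame: np.ndarray


@dataclass
class TriangleInfo:
    atoms: tuple[int, int, int]
    probes: list[tuple[int, np.ndarray]]  # (side, probe center)


@dataclass
class AlphaComplex:
    vertices: list[int]            # exposed atom ids (global)
    edges: dict[tuple[int, int], EdgeInfo]
    triangles: list[TriangleInfo]
    neighbor_pairs: dict[int, list[int]] = field(default_factory=dict)


def _merge_arcs(arcs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of angular intervals given as (start, end) with end > start,
    reduced mod 2*pi.  Returns disjoint sorted intervals covering the union,
    unwrapped so start is in [0, 2pi) and end may exceed 2pi."""
    two_pi = 2.0 * math.pi
    segs: list[tuple[float, float]] = []
    for a, b in arcs:
        span = min(b - a, two_pi)
        a %= two_pi
        segs.append((a, a + span))
    segs.sort()
    merged: list[list[float]] = []
    for a, b in segs:
        if merged and a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # Wrap-around: the last interval may spill past 2pi and absorb leading
    # intervals; iterate until stable.
    changed = True
    while changed and len(merged) > 1:
        changed = False
        if merged[-1][1] - two_pi >= merged[0][0] - 1e-12:
            a_l, b_l = merged.pop()
            merged[0][0] = a_l - two_pi
            merged[0][1] = max(merged[0][1], b_l - two_pi)
            changed = True
        while len(merged) > 1 and merged[0][1] >= merged[1][0] - 1e-12:
            merged[0][1] = max(merged[0][1], merged[1][1])
            merged.pop(1)
            changed = True
    return [(a, b) for a, b in merged]


def _free_arcs(center: np.ndarray, frame: np.ndarray, rho: float,
               occ_centers: np.ndarray, occ_radii: np.ndarray) -> list[tuple[float, float]] | None:
    """Free (unoccluded) arcs of the circle of radius ``rho`` about ``center``
    in ``frame`` (rows u, v, axis), against occluding spheres.

    Returns ``None`` for a fully free circle, ``[]`` for a fully occluded one,
    else the list of free (start, end) arcs.  Exact per-sphere arc solve: the
    point at angle phi is inside occluder l iff A cos(phi) + B sin(phi) > C.
    """
    if len(occ_centers) == 0:
        return None
    v = occ_centers - center[None, :]
    A = 2.0 * rho * (v @ frame[0])
    B = 2.0 * rho * (v @ frame[1])
    C = rho * rho + np.einsum("ij,ij->i", v, v) - occ_radii**2
    M = np.hypot(A, B)
    occluded: list[tuple[float, float]] = []
    for a, b, c, m in zip(A, B, C, M):
        if c >= m - _OCC_TOL:
            continue                      # this sphere never reaches the circle
        if c <= -m:
            return []                     # circle entirely inside this sphere
        delta = math.acos(min(1.0, max(-1.0, c / m)))
        alpha = math.atan2(b, a)
        occluded.append((alpha - delta, alpha + delta))
    if not occluded:
        return None
    merged = _merge_arcs(occluded)
    if len(merged) == 1 and merged[0][1] - merged[0][0] >= 2.0 * math.pi - _ARC_TOL:
        return []
    # Complement on the circle.
    two_pi = 2.0 * math.pi
    free: list[tuple[float, float]] = []
    for k, (a, b) in enumerate(merged):
        nxt = merged[(k + 1) % len(merged)][0] + (two_pi if k == len(merged) - 1 else 0.0)
        if nxt - b > _ARC_TOL:
            free.append((b % two_pi, (b % two_pi) + (nxt - b)))
    return free


def build_alpha_complex(atoms: AtomSet, probe_radius: float) -> AlphaComplex:
    """Zero-alpha complex of the atoms weighted by (r_i + r_p)^2.

    Edges, triangles and exposed vertices are determined by exact probe
    tangency and occlusion tests (see module docstring).  Coincident centers
    with equal radii are resolved deterministically: the lower global id wins
    the (fully occluded) duplicate.
    """
    n = atoms.count
    C = atoms.centers
    R = atoms.radii + probe_radius
    if n == 1 or probe_radius < 0.0:
        return AlphaComplex(vertices=[0], edges={}, triangles=[])

    tree = cKDTree(C)
    pairs = tree.query_pairs(r=float(2.0 * R.max()), output_type="ndarray")
    # Proper sphere-sphere intersections of the inflated spheres.
    nbrs: dict[int, list[int]] = {i: [] for i in range(n)}
    contained = np.zeros(n, dtype=bool)
    proper: list[tuple[int, int, float]] = []
    for i, j in pairs:
        i, j = int(min(i, j)), int(max(i, j))
        d = float(np.linalg.norm(C[j] - C[i]))
        if d >= R[i] + R[j]:
            continue
        i_in_j = d + R[i] <= R[j] + _OCC_TOL
        j_in_i = d + R[j] <= R[i] + _OCC_TOL
        if i_in_j and j_in_i:
            contained[j] = True           # coincident equal spheres: low id wins
            continue
        if i_in_j:
            contained[i] = True           # inflated i swallowed by j
            continue
        if j_in_i:
            contained[j] = True
            continue
        nbrs[i].append(j)
        nbrs[j].append(i)
        proper.append((i, j, d))
    for i in nbrs:
        nbrs[i].sort()

    edges: dict[tuple[int, int], EdgeInfo] = {}
    has_circle = np.zeros(n, dtype=bool)
    for i, j, d in proper:
        u = (C[j] - C[i]) / d
        t = (d * d + R[i] ** 2 - R[j] ** 2) / (2.0 * d)
        rho2 = R[i] ** 2 - t * t
        if rho2 <= _OCC_TOL**2:
            continue                      # tangency: no occluding cap either
        has_circle[i] = has_circle[j] = True
        rho = math.sqrt(rho2)
        o = C[i] + t * u
        frame = _axis_frame(u)
        # Occluders: any other atom whose inflated sphere can reach the circle.
        cand = tree.query_ball_point(o, r=float(rho + R.max()))
        occ = [l for l in sorted(cand) if l != i and l != j
               and np.linalg.norm(C[l] - o) < R[l] + rho]
        arcs = _free_arcs(o, frame, rho, C[occ], R[occ]) if occ else None
        if arcs is not None and not arcs:
            continue                      # fully occluded
        edges[(i, j)] = EdgeInfo((i, j), o, u, rho, arcs, frame)

    # Triangles: probe resting on three atoms, per side, unoccluded.
    triangles: list[TriangleInfo] = []
    edge_nbrs: dict[int, list[int]] = {}
    for i, j in edges:
        edge_nbrs.setdefault(i, []).append(j)
        edge_nbrs.setdefault(j, []).append(i)
    seen: set[tuple[int, int, int]] = set()
    for i in sorted(edge_nbrs):
        js = sorted(k for k in edge_nbrs[i] if k > i)
        for a_idx in range(len(js)):
            for b_idx in range(a_idx + 1, len(js)):
                j, k = js[a_idx], js[b_idx]
                if (j, k) not in edges or (i, j, k) in seen:
                    continue
                seen.add((i, j, k))
                probes = _probe_positions(C, R, i, j, k)
                if not probes:
                    continue
                kept = []
                for side, p in probes:
                    cand = tree.query_ball_point(p, r=float(R.max()) + 1e-6)
                    clear = True
                    for l in cand:
                        if l in (i, j, k):
                            continue
                        if np.linalg.norm(C[l] - p) < R[l] - _OCC_TOL:
                            clear = False
                            break
                    if clear:
                        kept.append((side, p))
                if kept:
                    triangles.append(TriangleInfo((i, j, k), kept))

    # Exposure: an atom is on the surface iff it is not swallowed whole and
    # either no neighbor sphere actually cuts a cap out of it, or at least one
    # of its pair circles keeps a free arc (the boundary of any uncovered
    # spherical region necessarily lies on some pair circle).
    has_edge = np.zeros(n, dtype=bool)
    for i, j in edges:
        has_edge[i] = has_edge[j] = True
    vertices = [i for i in range(n)
                if not contained[i] and (not has_circle[i] or has_edge[i])]
    return AlphaComplex(vertices=vertices, edges=edges, triangles=triangles,
                        neighbor_pairs=nbrs)


def _probe_positions(C: np.ndarray, R: np.ndarray, i: int, j: int, k: int):
    """Probe centers tangent to inflated spheres i, j, k (0, 1 or 2 of them),
    by trilateration in the local orthonormal frame of the triangle."""
    e1 = C[j] - C[i]
    e2 = C[k] - C[i]
    d = np.linalg.norm(e1)
    if d == 0.0:
        return []
    ahat = e1 / d
    nvec = np.cross(e1, e2)
    nn = np.linalg.norm(nvec)
    if nn < 1e-12:
        return []                          # collinear centers
    nhat = nvec / nn
    bhat = np.cross(nhat, ahat)
    x = (d * d + R[i] ** 2 - R[j] ** 2) / (2.0 * d)
    e2a = float(e2 @ ahat)
    e2b = float(e2 @ bhat)
    if abs(e2b) < 1e-12:
        return []
    y = (float(e2 @ e2) + R[i] ** 2 - R[k] ** 2 - 2.0 * x * e2a) / (2.0 * e2b)
    z2 = R[i] ** 2 - x * x - y * y
    if z2 <= 1e-18:
        if z2 <= -1e-12:
            return []
        p = C[i] + x * ahat + y * bhat
        return [(1, p)]                    # grazing: single mid-plane position
    z = math.sqrt(z2)
    base = C[i] + x * ahat + y * bhat
    return [(1, base + z * nhat), (-1, base - z * nhat)]


# ---------------------------------------------------------------------------
# patches


def _sphere_bbox(center: np.ndarray, radius: float) -> np.ndarray:
    return np.stack([center - radius, center + radius])


def build_patches(complex_: AlphaComplex, atoms: AtomSet, probe_radius: float) -> PatchSet:
    """Derive patch parameters and trimming solids from the alpha complex."""
    C = atoms.centers
    r = atoms.radii
    R = r + probe_radius
    patches: list[Patch] = []

    # Convex spherical patches: atom sphere clipped by the radial shrink of
    # its power-cell planes (one per neighbor whose inflated sphere overlaps).
    for i in complex_.vertices:
        normals, offsets = [], []
        for j in complex_.neighbor_pairs.get(i, []):
            dvec = C[j] - C[i]
            d = float(np.linalg.norm(dvec))
            if d == 0.0:
                continue
            nhat = dvec / d
            t = (d * d + R[i] ** 2 - R[j] ** 2) / (2.0 * d)
            lam = r[i] / R[i] if R[i] > 0 else 1.0
            normals.append(nhat)
            offsets.append(float(nhat @ C[i]) + lam * t)
        trim = TrimmingSolid(
            normals=np.array(normals).reshape(-1, 3),
            offsets=np.array(offsets, dtype=float),
            vertices=np.zeros((0, 3)),
            bbox=_sphere_bbox(C[i], r[i]),
        )
        patches.append(Patch(CONVEX_SPHERE, C[i].copy(), float(r[i]), trim, (i,)))

    if probe_radius > 0.0:
        for (i, j), e in complex_.edges.items():
            patches.append(_torus_patch(e, C, r, R, probe_radius))
        # Fixed probe balls that overlap contribute, pairwise, their spheres
        # clipped at the mutual radical plane (the boundary of the union of
        # the two excluded balls); for the two probes of one triangle that
        # plane is exactly the atom-centers plane.  Collect every kept probe
        # first so each concave patch can be trimmed against its neighbors.
        probe_pts = []
        for tri in complex_.triangles:
            for side, p in tri.probes:
                probe_pts.append(p)
        probe_arr = np.array(probe_pts).reshape(-1, 3)
        ptree = cKDTree(probe_arr) if len(probe_arr) else None
        pidx = 0
        for tri in complex_.triangles:
            for side, p in tri.probes:
                cn, co = [], []
                if ptree is not None:
                    for q_id in sorted(ptree.query_ball_point(p, r=2.0 * probe_radius - 1e-9)):
                        if q_id == pidx:
                            continue
                        q = probe_arr[q_id]
                        dpq = float(np.linalg.norm(q - p))
                        if dpq < 1e-9:
                            continue       # coincident probes: degenerate input
                        nhat = (q - p) / dpq
                        cn.append(nhat)
                        co.append(float(nhat @ p) + 0.5 * dpq)
                clips = (np.array(cn), np.array(co)) if cn else None
                patches.append(_concave_patch(p, side, tri.atoms, C, probe_radius,
                                              probe_clips=clips))
                pidx += 1

    patches.sort(key=Patch.sort_key)
    for pid, p in enumerate(patches):
        p.id = pid
    return PatchSet(patches, probe_radius)


def _torus_patch(e: EdgeInfo, C, r, R, probe_radius: float) -> Patch:
    i, j = e.atoms
    o, u, rho = e.center, e.axis, e.ring_radius
    z_i = float(u @ (C[i] - o)) * probe_radius / R[i]   # tangency circle heights
    z_j = float(u @ (C[j] - o)) * probe_radius / R[j]
    z_lo, z_hi = min(z_i, z_j), max(z_i, z_j)
    rho_i = rho * r[i] / R[i]
    rho_j = rho * r[j] / R[j]
    normals = np.stack([u, -u])
    offsets = np.array([float(u @ o) + z_hi, -(float(u @ o) + z_lo)])
    # Corner points of the two tangency-circle bounding squares in the
    # deterministic torus frame; these drive slab dedup.
    verts = []
    for zc, rc in ((z_i, rho_i), (z_j, rho_j)):
        for su in (-1.0, 1.0):
            for sv in (-1.0, 1.0):
                verts.append(o + zc * u + su * rc * e.frame[0] + sv * rc * e.frame[1])
    verts = np.array(verts)
    ux = np.abs(u)
    planar = rho * np.sqrt(np.maximum(0.0, 1.0 - ux * ux))
    lo = o + np.minimum(z_lo * u, z_hi * u) - planar
    hi = o + np.maximum(z_lo * u, z_hi * u) + planar
    trim = TrimmingSolid(normals=normals, offsets=offsets, vertices=verts,
                         bbox=np.stack([lo, hi]))
    return Patch(TORUS, o.copy(), float(probe_radius), trim, (i, j),
                 axis=u.copy(), ring_radius=float(rho), frame=e.frame,
                 arcs=e.free_arcs)


def _concave_patch(p: np.ndarray, side: int, ids: tuple[int, int, int], C,
                   probe_radius: float, probe_clips=None) -> Patch:
    """Concave spherical triangle: probe sphere clipped by the cone from the
    probe center through the three atom centers (the apex faces of the
    spanned tetrahedron).  ``probe_clips`` carries radical half-spaces
    against overlapping neighbor probe balls - the boundary of a union of
    equal balls lies on each sphere's far side of the perpendicular bisector
    of the centers, which for the mirror probe of the same triangle is
    exactly the atom-centers plane."""
    pts = np.array([C[ids[0]], C[ids[1]], C[ids[2]], p])
    faces = [(0, 1, 3, 2), (0, 2, 3, 1), (1, 2, 3, 0)]
    normals, offsets = [], []
    for a, b, c, opp in faces:
        nvec = np.cross(pts[b] - pts[a], pts[c] - pts[a])
        ln = np.linalg.norm(nvec)
        if ln < 1e-12:
            continue
        nhat = nvec / ln
        off = float(nhat @ pts[a])
        if float(nhat @ pts[opp]) > off:   # orient inward-facing constraint
            nhat, off = -nhat, -off
        normals.append(nhat)
        offsets.append(off)
    bbox = _sphere_bbox(p, probe_radius)
    trim = TrimmingSolid(normals=np.array(normals), offsets=np.array(offsets),
                         vertices=pts, bbox=bbox)
    return Patch(CONCAVE_SPHERE, p.copy(), float(probe_radius), trim, ids,
                 side=side, probe_clips=probe_clips)


# ---------------------------------------------------------------------------
# slab decomposition


@dataclass
class SlabPartition:
    n_slabs: int
    boundaries: np.ndarray            # (N+1,) increasing Y coordinates
    halo: float
    per_slab_atom_ids: list[np.ndarray]
    per_slab_halo_ids: list[np.ndarray]


def slab_partition(atoms: AtomSet, requested_slabs: int, halo: float) -> SlabPartition:
    """Partition atoms into Y slabs of near-equal population.

    The slab count is capped so every slab is at least 12 A thick; boundaries
    sit on 1 A mini-slab bin edges chosen to equalize per-slab atom counts.
    Halo lists hold atoms within ``halo`` of a slab's interval but outside it.
    The outermost slabs extend to infinity for membership purposes.
    """
    if requested_slabs < 1:
        raise ValueError("requested_slabs must be >= 1")
    y = atoms.centers[:, 1]
    y_min, y_max = float(y.min()), float(y.max())
    extent = y_max - y_min
    n = max(1, min(int(requested_slabs), int(extent // _MIN_SLAB)))
    if n != requested_slabs:
        log.info("slab count capped to %d (Y extent %.2f A, min slab %.0f A)",
                 n, extent, _MIN_SLAB)
    if n == 1:
        all_ids = np.arange(atoms.count)
        return SlabPartition(1, np.array([y_min, y_max]), halo, [all_ids],
                             [np.array([], dtype=int)])

    nbins = max(1, int(math.ceil(extent / _MINI_SLAB)))
    edges = y_min + np.arange(nbins + 1) * (extent / nbins if extent > 0 else 1.0)
    counts, _ = np.histogram(y, bins=edges)
    cum = np.concatenate([[0], np.cumsum(counts)])
    total = atoms.count
    bounds = [y_min]
    prev_edge_idx = 0
    for k in range(1, n):
        target = total * k / n
        lo_idx = prev_edge_idx
        while lo_idx < nbins and edges[lo_idx] < bounds[-1] + _MIN_SLAB - 1e-9:
            lo_idx += 1
        hi_idx = nbins
        while hi_idx > 0 and edges[hi_idx] > y_max - _MIN_SLAB * (n - k) + 1e-9:
            hi_idx -= 1
        if lo_idx > hi_idx:
            lo_idx = hi_idx
        cand = np.arange(lo_idx, hi_idx + 1)
        best = cand[np.argmin(np.abs(cum[cand] - target))]
        # Bin granularity can leave no edge inside the feasible window; clamp
        # off-grid so the 12 A minimum slab thickness is preserved.
        pos = min(max(float(edges[best]), bounds[-1] + _MIN_SLAB),
                  y_max - _MIN_SLAB * (n - k))
        bounds.append(pos)
        prev_edge_idx = int(best)
    bounds.append(y_max)
    boundaries = np.array(bounds)

    per_slab, per_halo = [], []
    for s in range(n):
        lo = -np.inf if s == 0 else boundaries[s]
        hi = np.inf if s == n - 1 else boundaries[s + 1]
        in_slab = (y >= lo) & (y < hi)
        in_halo = (~in_slab) & (y >= (boundaries[s] - halo)) & (y <= (boundaries[s + 1] + halo))
        per_slab.append(np.flatnonzero(in_slab))
        per_halo.append(np.flatnonzero(in_halo))
    log.info("slab partition: N=%d, per-slab atoms %s", n, [len(s) for s in per_slab])
    return SlabPartition(n, boundaries, halo, per_slab, per_halo)


def dedup_patches(per_slab_patchsets: list[PatchSet], partition: SlabPartition) -> PatchSet:
    """Merge per-slab patch sets, keeping a patch only in the slab whose
    half-open [lower, upper) Y interval contains the bottom-most vertex of
    its trimming solid; the outermost intervals are unbounded."""
    kept: list[Patch] = []
    probe = per_slab_patchsets[0].probe_radius if per_slab_patchsets else 0.0
    n = partition.n_slabs
    for s, pset in enumerate(per_slab_patchsets):
        lo = -np.inf if s == 0 else float(partition.boundaries[s])
        hi = np.inf if s == n - 1 else float(partition.boundaries[s + 1])
        for p in pset.patches:
            by = p.trim.bottom_vertex_y()
            if lo <= by < hi:
                kept.append(p)
    kept.sort(key=Patch.sort_key)
    for pid, p in enumerate(kept):
        p.id = pid
    return PatchSet(kept, probe)


def build_ses(atoms: AtomSet, config: SurfaceConfig) -> PatchSet:
    """Full SES buildup: slab partition, per-slab alpha complex and patches
    over slab+halo atoms, then duplicate removal.  The result is independent
    of the slab count (the determinism contract standing in for threads)."""
    part = slab_partition(atoms, config.slab_count, config.halo_thickness)
    per_slab: list[PatchSet] = []
    for s in range(part.n_slabs):
        ids = np.sort(np.concatenate([part.per_slab_atom_ids[s], part.per_slab_halo_ids[s]]))
        sub = atoms.subset(ids)
        cx = build_alpha_complex(sub, config.probe_radius)
        pset = build_patches(cx, sub, config.probe_radius)
        _relabel(pset, ids)
        per_slab.append(pset)
    merged = dedup_patches(per_slab, part)
    log.info("buildup: %d patches (%s)", len(merged), merged.counts_by_kind())
    return merged


def _relabel(pset: PatchSet, ids: np.ndarray) -> None:
    """Map local atom indices in patch identities back to global ids."""
    for p in pset.patches:
        p.atoms = tuple(int(ids[a]) for a in p.atoms)
    pset.patches.sort(key=Patch.sort_key)
    for pid, p in enumerate(pset.patches):
        p.id = pid
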