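"""Marching-Cubes extraction, normals approximation and Laplacian smoothing.

Where a grid-cell edge changes in/out status, the mesh vertex is the exact
analytic ray-surface intersection stored for that edge during ray tracing, so
vertices are guaranteed to lie on the SES.  When the status flips but no
intersection was recorded (the rare aftermath of a repaired ray), a vertex is
created at the midpoint of the cube edge and flagged *dangling*; its normal is
reconstructed afterwards by averaging incident triangle normals.

Cell polygonization is done by face-consistent contour tracing: on every cell
face the edge crossings are paired into directed contour segments using only
the face's own corner states (on an ambiguous face - two diagonal inside
corners - the inside corners are kept connected, the same choice seen from
both adjacent cells), and the segments chain into closed loops inside each
cell which are fan-triangulated.  Because the pairing is a function of face
data alone, adjacent cells always agree on shared segments and the output
mesh passes the closed-manifold edge census by construction.  This is the
standard 15-case table with a fixed, globally consistent sub-case choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raytrace import _PIXEL_AXES, RayGrid, RayIntersectionSet
from .storage import BitBuffer, Status, StatusMap, VertexIndexMap

log = logging.getLogger("patchsurf")

__all__ = [
    "TriMesh",
    "MeshContractError",
    "marching_cubes",
    "approximate_normals",
    "smooth",
    "mesh_statistics",
    "mesh_volume",
]


class MeshContractError(RuntimeError):
    """The mesh violates the closed-manifold contract an algorithm relies on."""


@dataclass
class TriMesh:
    """Closed manifold triangle surface with per-vertex outward normals."""

    vertices: np.ndarray                  # (n, 3) Angstrom
    normals: np.ndarray                   # (n, 3) unit
    triangles: np.ndarray                 # (m, 3) int, outward orientation

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.normals.copy(), self.triangles.copy())


def _edge_counts(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Undirected edge census: unique edges and their triangle incidence."""
    if len(triangles) == 0:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64)
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


# Face corner orderings, CCW as seen from outside the cell.  For face (a, s)
# the in-face axes are b = (a+1)%3 and c = (a+2)%3 (right-handed, so the
# corner cycle below is CCW viewed from +a; the s = 0 face is viewed from -a
# and uses the mirrored cycle).
_FACE_CYCLE = {1: ((0, 0), (1, 0), (1, 1), (0, 1)),
               0: ((0, 0), (0, 1), (1, 1), (1, 0))}


def marching_cubes(status: StatusMap, vmap: VertexIndexMap | None,
                   rays: RayIntersectionSet | None, grid: RayGrid
                   ) -> tuple[TriMesh, BitBuffer]:
    """Extract the isosurface between inside and outside nodes.

    Returns the mesh and the dangling-vertex flag buffer.  ``rays`` may be
    None (pure midpoint vertices, e.g. when meshing a binary mask)."""
    dense = status.to_dense() == int(Status.INSIDE)
    nx, ny, nz = dense.shape
    if vmap is None:
        vmap = VertexIndexMap((nx, ny, nz))

    # Mixed cells only.
    core = dense[:-1, :-1, :-1]
    agree = np.ones_like(core)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                agree &= dense[dx:nx - 1 + dx, dy:ny - 1 + dy, dz:nz - 1 + dz] == core
    cells = np.argwhere(~agree)

    verts: list[np.ndarray] = []
    vnormals: list[np.ndarray] = []
    dangling: list[bool] = []
    tris: list[tuple[int, int, int]] = []
    loops: list[list[int]] = []
    tri_owner: list[int] = []
    h = grid.h

    def vertex_for_edge(axis: int, node: tuple[int, int, int]) -> int:
        idx = vmap.get(axis, *node)
        if idx != -1:
            return idx
        idx = len(verts)
        pos = grid.origin + np.array(node, dtype=float) * h
        normal = None
        if rays is not None:
            a1, a2 = _PIXEL_AXES[axis]
            recs = rays.records(axis, (node[a1], node[a2]))
            t_lo = node[axis] * h
            for t, n, _pid in recs:
                if t_lo - 1e-12 <= t < t_lo + h - 1e-12:
                    pos[axis] = grid.origin[axis] + t
                    normal = n
                    break
        if normal is None:
            pos[axis] += 0.5 * h          # dangling: midpoint of the cube edge
            verts.append(pos)
            vnormals.append(np.zeros(3))
            dangling.append(True)
        else:
            verts.append(pos)
            vnormals.append(np.asarray(normal, dtype=float))
            dangling.append(False)
        vmap.put(axis, *node, idx)
        return idx

    for cx, cy, cz in cells:
        cell = (int(cx), int(cy), int(cz))
        chords: dict[tuple, tuple] = {}
        for a in range(3):
            b, c = (a + 1) % 3, (a + 2) % 3
            for s in (0, 1):
                cyc = _FACE_CYCLE[s]
                corners = []
                for p, q in cyc:
                    off = [0, 0, 0]
                    off[a], off[b], off[c] = s, p, q
                    corners.append((cell[0] + off[0], cell[1] + off[1], cell[2] + off[2]))
                states = [dense[n] for n in corners]
                crossings = []            # (cyclic pos, is_entry, edge key)
                for k in range(4):
                    k2 = (k + 1) % 4
                    if states[k] == states[k2]:
                        continue
                    n0, n1 = corners[k], corners[k2]
                    eaxis = next(ax for ax in range(3) if n0[ax] != n1[ax])
                    lower = tuple(min(n0[ax], n1[ax]) for ax in range(3))
                    crossings.append((k, not states[k], (eaxis, lower)))
                if not crossings:
                    continue
                m = len(crossings)
                for idx0, (_, is_entry, key) in enumerate(crossings):
                    if is_entry:
                        continue
                    # Exit: chord to the next entry in cyclic order, which
                    # keeps the inside region of the face on the left as seen
                    # from outside the cell (ambiguous faces: inside corners
                    # stay connected).
                    for step in range(1, m + 1):
                        _, e2, key2 = crossings[(idx0 + step) % m]
                        if e2:
                            chords[key] = key2
                            break
        # Chain directed chords into loops.
        visited: set = set()
        for start in chords:
            if start in visited:
                continue
            loop = [start]
            visited.add(start)
            nxt = chords[start]
            while nxt != start:
                loop.append(nxt)
                visited.add(nxt)
                nxt = chords[nxt]
            if len(loop) < 3:
                continue
            vids = [vertex_for_edge(ax, node) for ax, node in loop]
            loops.append(vids)

    for lidx, vids in enumerate(loops):
        for k in range(1, len(vids) - 1):
            tri_owner.append(lidx)
            tris.append((vids[0], vids[k], vids[k + 1]))
    _resolve_fan_collisions(loops, tris, tri_owner, verts, vnormals, dangling)

    if not verts:
        mesh = TriMesh(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        return mesh, BitBuffer(0)
    mesh = TriMesh(np.array(verts), np.array(vnormals), np.array(tris, dtype=np.int64))
    _orient_outward(mesh, dense, grid)
    flags = BitBuffer(len(verts))
    for i, dflag in enumerate(dangling):
        if dflag:
            flags.set(i)
    n_dangling = int(np.sum(dangling))
    log.info("MC: %d vertices (%d dangling), %d triangles",
             len(verts), n_dangling, len(tris))
    return mesh, flags


def _resolve_fan_collisions(loops: list[list[int]], tris: list, tri_owner: list[int],
                            verts: list, vnormals: list, dangling: list) -> None:
    """Repair the rare fan-chord collisions between cells.

    Fan-triangulating a contour loop introduces chord edges interior to its
    cell; two cells can occasionally generate the same chord, breaking the
    every-edge-twice census.  Affected loops are re-triangulated around a
    centroid Steiner vertex (flagged dangling), whose spokes are unique to
    the loop by construction."""
    for _ in range(4):
        if not tris:
            return
        t = np.asarray(tris, dtype=np.int64)
        uniq, counts = _edge_counts(t)
        bad = uniq[counts != 2]
        if len(bad) == 0:
            return
        bad_set = {tuple(e) for e in bad}
        rebuild: set[int] = set()
        for lidx, vids in enumerate(loops):
            if len(vids) < 4:
                continue
            for k in range(2, len(vids) - 1):
                chord = (min(vids[0], vids[k]), max(vids[0], vids[k]))
                if chord in bad_set:
                    rebuild.add(lidx)
                    break
        if not rebuild:
            return
        keep = [(tri, own) for tri, own in zip(tris, tri_owner) if own not in rebuild]
        tris.clear()
        tri_owner.clear()
        for tri, own in keep:
            tris.append(tri)
            tri_owner.append(own)
        for lidx in sorted(rebuild):
            vids = loops[lidx]
            cidx = len(verts)
            verts.append(np.mean([verts[v] for v in vids], axis=0))
            vnormals.append(np.zeros(3))
            dangling.append(True)
            for k in range(len(vids)):
                tri_owner.append(lidx)
                tris.append((cidx, vids[k], vids[(k + 1) % len(vids)]))


def _orient_outward(mesh: TriMesh, dense: np.ndarray, grid: RayGrid) -> None:
    """Flip all windings if triangle normals point into the body.

    The contour-tracing convention is globally consistent, so a single signed
    test decides: the mesh's signed volume (divergence theorem) is positive
    for outward orientation."""
    if mesh_volume(mesh) < 0.0:
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]


def mesh_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume via the divergence theorem (positive for
    outward-oriented closed meshes)."""
    if len(mesh.triangles) == 0:
        return 0.0
    v = mesh.vertices
    t = mesh.triangles
    return float(np.einsum("ij,ij->", v[t[:, 0]],
                           np.cross(v[t[:, 1]], v[t[:, 2]]))) / 6.0


def approximate_normals(mesh: TriMesh, dangling_flags: BitBuffer) -> TriMesh:
    """Reconstruct normals of dangling vertices from incident triangles.

    Auxiliary storage is allocated only for the flagged vertices (an index
    map plus their accumulation buffers), never full-size."""
    if dangling_flags.length == 0 or not dangling_flags.any():
        return mesh
    flagged = np.flatnonzero(dangling_flags.to_array())
    slot = {int(v): k for k, v in enumerate(flagged)}      # partial index map
    acc = np.zeros((len(flagged), 3))
    touched = np.zeros(len(flagged), dtype=bool)
    v = mesh.vertices
    t = mesh.triangles
    fnorm = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    for col in range(3):
        for tri_idx, vid in enumerate(t[:, col]):
            k = slot.get(int(vid))
            if k is not None:
                acc[k] += fnorm[tri_idx]
                touched[k] = True
    if not touched.all():
        raise AssertionError("dangling vertex without incident triangle on a closed mesh")
    norms = np.linalg.norm(acc, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    mesh.normals[flagged] = acc / norms
    return mesh


def smooth(mesh: TriMesh, iterations: int = 1) -> TriMesh:
    """Laplacian smoothing by the doubled-count scheme.

    Looping over triangles, each vertex accumulates the coordinates and
    normals of the two opposite vertices and one count per incident triangle,
    with no neighbor-list and no duplicate check: on a closed surface every
    undirected edge is shared by exactly two triangles, so each neighbor is
    accumulated exactly twice and the sums are divided by twice the counts.
    Raises :class:`MeshContractError` on an open mesh, where the doubling
    identity fails.
    """
    if iterations == 0 or len(mesh.triangles) == 0:
        return mesh
    _, counts = _edge_counts(mesh.triangles)
    if len(counts) and not np.all(counts == 2):
        raise MeshContractError("doubled-count smoothing requires a closed mesh "
                                f"(edge incidence {sorted(set(counts.tolist()))})")
    out = mesh.copy()
    t = out.triangles
    a, b, c = t[:, 0], t[:, 1], t[:, 2]
    for _ in range(iterations):
        acc = np.zeros_like(out.vertices)
        nacc = np.zeros_like(out.normals)
        cnt = np.zeros(len(out.vertices))
        v, n = out.vertices, out.normals
        np.add.at(acc, a, v[b] + v[c])
        np.add.at(acc, b, v[c] + v[a])
        np.add.at(acc, c, v[a] + v[b])
        np.add.at(nacc, a, n[b] + n[c])
        np.add.at(nacc, b, n[c] + n[a])
        np.add.at(nacc, c, n[a] + n[b])
        np.add.at(cnt, a, 1.0)
        np.add.at(cnt, b, 1.0)
        np.add.at(cnt, c, 1.0)
        denom = 2.0 * cnt[:, None]
        out.vertices = acc / denom
        nn = nacc / denom
        ln = np.linalg.norm(nn, axis=1, keepdims=True)
        ln[ln == 0.0] = 1.0
        out.normals = nn / ln
    return out


def mesh_statistics(mesh: TriMesh) -> dict:
    """Area, counts, Euler characteristic and the closed-manifold census."""
    nv = len(mesh.vertices)
    nt = len(mesh.triangles)
    if nt == 0:
        return {"area": 0.0, "n_vertices": nv, "n_triangles": 0,
                "euler_characteristic": nv, "is_closed": True}
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    edges, counts = _edge_counts(t)
    return {
        "area": area,
        "n_vertices": nv,
        "n_triangles": nt,
        "euler_characteristic": nv - len(edges) + nt,
        "is_closed": bool(np.all(counts == 2)),
    }
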