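"""Deterministic toy molecules with known analytic facts.

These generators stand in for protein-scale inputs at desk scale: every
fixture is reproducible bitwise from (name, seed) and small enough that
brute-force reference computations stay cheap in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AtomSet

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES", "ray_torus_corpus"]

FIXTURE_NAMES = ("single_atom", "pair", "triple", "tetrahedral", "ring_pocket",
                 "random_cluster", "elongated_cluster")


@dataclass(frozen=True)
class Fixture:
    name: str
    atoms: AtomSet
    expected: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(name: str, n: int = 50, seed: int = 0) -> Fixture:
    """Build a named fixture.

    single_atom        one sphere r = 2 at the origin (volume 4/3 pi 8)
    pair               two atoms r = 1.5, centers 3 A apart
    triple             equilateral triangle, side 3, r = 1.5
    tetrahedral        regular tetrahedron, side 3.2, r = 1.5
    ring_pocket        6-atom ring (r = 1.8, ring radius 3.5) capped by 3
                       atoms: a cup the 1.4 A probe enters but a 3 A probe
                       cannot
    random_cluster     n atoms in a 15 A cube, min separation 2.4 A,
                       radii ~ U(1.2, 1.9)
    elongated_cluster  same recipe in a 15 x 50 x 15 A box (Y extent large
                       enough for up to 4 slabs)
    """
    if name == "single_atom":
        atoms = AtomSet([[0.0, 0.0, 0.0]], [2.0])
        return Fixture(name, atoms, expected={
            "volume_probe0": 4.0 / 3.0 * math.pi * 8.0,
            "area_probe0": 16.0 * math.pi,
            "patch_counts": {"convex_sphere": 1, "torus": 0, "concave_sphere": 0},
        })
    if name == "pair":
        atoms = AtomSet([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]], [1.5, 1.5])
        return Fixture(name, atoms, expected={
            "patch_counts": {"convex_sphere": 2, "torus": 1, "concave_sphere": 0},
        })
    if name == "triple":
        s = 3.0
        atoms = AtomSet([[0.0, 0.0, 0.0], [s, 0.0, 0.0],
                         [s / 2.0, s * math.sqrt(3.0) / 2.0, 0.0]], [1.5] * 3)
        return Fixture(name, atoms, expected={
            "patch_counts": {"convex_sphere": 3, "torus": 3, "concave_sphere": 2},
        })
    if name == "tetrahedral":
        s = 3.2
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        pts *= s / (2.0 * math.sqrt(2.0))
        return Fixture(name, AtomSet(pts, [1.5] * 4))
    if name == "ring_pocket":
        centers, radii = [], []
        ring_r, atom_r = 3.5, 1.8
        for k in range(6):
            a = 2.0 * math.pi * k / 6.0
            centers.append([ring_r * math.cos(a), ring_r * math.sin(a), 0.0])
            radii.append(atom_r)
        # Three capping atoms close the top of the channel, turning the
        # central hole (clearance 1.7 A: passes a 1.4 A probe, blocks 3 A)
        # into a cup open only from below.  Azimuths and heights deliberately
        # break the ring's 6-fold symmetry: symmetric placements create
        # probes tangent to four atoms at once, a degeneracy the double
        # precision buildup (unlike exact arithmetic) should not be fed.
        for a_deg, zc in ((20.0, 2.35), (135.0, 2.50), (255.0, 2.62)):
            a = math.radians(a_deg)
            centers.append([1.75 * math.cos(a), 1.75 * math.sin(a), zc])
            radii.append(atom_r)
        return Fixture(name, AtomSet(np.array(centers), np.array(radii)))
    if name == "random_cluster":
        return _cluster(name, n, seed, box=np.array([15.0, 15.0, 15.0]))
    if name == "elongated_cluster":
        return _cluster(name, n, seed, box=np.array([15.0, 50.0, 15.0]))
    raise ValueError(f"unknown fixture name {name!r}")


def ray_torus_corpus(n: int, seed: int):
    """Seeded corpus of ray-torus intersection problems for solver accuracy
    studies: random tori (ring and tube radii ~ U(0.2, 3) A, random center
    and axis) against axis-aligned rays offset to pass near the torus.

    Yields (origin, direction, Torus) triples; the monic quartic of each is
    what the analytic solver and any reference method both consume.
    """
    from .quartic import Torus

    rng = np.random.default_rng(seed)
    for _ in range(n):
        ring = float(rng.uniform(0.2, 3.0))
        tube = float(rng.uniform(0.2, 3.0))
        center = rng.uniform(-3.0, 3.0, 3)
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) < 1e-12:
            axis = rng.normal(size=3)
        tor = Torus(center=center, axis=axis, ring_radius=ring, tube_radius=tube)
        d = np.zeros(3)
        d[int(rng.integers(3))] = 1.0
        # Offset the ray within the torus extent so most rays pierce it.
        span = ring + tube
        origin = center + rng.uniform(-span, span, 3)
        origin -= d * (float(d @ (origin - center)) + 12.0)
        yield origin, d, tor


def _cluster(name: str, n: int, seed: int, box: np.ndarray,
             min_sep: float = 2.4) -> Fixture:
    """Random sequential insertion with a jittered-lattice fallback.

    Sequential insertion jams below ~180 atoms at 2.4 A separation in a 15 A
    cube, so atoms that cannot be placed in a bounded number of attempts are
    put on free lattice sites with a separation-preserving jitter; the result
    is deterministic for a given seed.
    """
    if n < 1 or n > 200:
        raise ValueError("cluster size must be in [1, 200]")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    for _ in range(n):
        ok = False
        for _attempt in range(2000):
            p = rng.uniform(0.0, 1.0, 3) * box
            if all(np.linalg.norm(p - q) >= min_sep for q in placed):
                placed.append(p)
                ok = True
                break
        if not ok:
            break
    if len(placed) < n:
        pitch = min_sep + 0.1
        jit = 0.02
        counts = np.maximum(1, (box / pitch).astype(int))
        sites = [np.array([i, j, k]) * pitch + pitch / 2.0
                 for i in range(counts[0]) for j in range(counts[1]) for k in range(counts[2])]
        for site in sites:
            if len(placed) == n:
                break
            p = site + rng.uniform(-jit, jit, 3)
            if all(np.linalg.norm(p - q) >= min_sep for q in placed):
                placed.append(p)
        if len(placed) < n:
            raise ValueError(f"cannot place {n} atoms in box {box}")
    centers = np.array(placed) - box / 2.0
    radii = rng.uniform(1.2, 1.9, n)
    return Fixture(name, AtomSet(centers, radii), seed=seed)
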