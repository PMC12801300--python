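import numpy as np
import pytest

from oracles import probe_pair_edge_oracle
from patchsurf.io import AtomSet, SurfaceConfig
from patchsurf.ses import (CONCAVE_SPHERE, CONVEX_SPHERE, TORUS,
                           build_alpha_complex, build_patches, build_ses,
                           dedup_patches, slab_partition)
from patchsurf import make_fixture

RP = 1.4


def census(pset):
    return pset.counts_by_kind()


def test_single_atom_complex_and_patch():
    atoms = AtomSet([[0, 0, 0]], [2.0])
    cx = build_alpha_complex(atoms, RP)
    assert cx.vertices == [0] and not cx.edges and not cx.triangles
    pset = build_patches(cx, atoms, RP)
    assert census(pset) == {CONVEX_SPHERE: 1, TORUS: 0, CONCAVE_SPHERE: 0}
    p = pset.patches[0]
    assert len(p.trim.normals) == 0          # trim = whole space
    assert np.allclose(p.trim.bbox, [[-2, -2, -2], [2, 2, 2]])


@pytest.mark.parametrize("dist, has_edge", [(3.0, True), (6.0, False)])
def test_pair_edge_matches_probe_placement_oracle(dist, has_edge):
    """An alpha edge exists exactly when a tangent probe can be placed, per
    the brute-force angular-sampling oracle."""
    atoms = AtomSet([[0, 0, 0], [dist, 0, 0]], [1.5, 1.5])
    cx = build_alpha_complex(atoms, RP)
    assert (((0, 1) in cx.edges) == has_edge)
    assert probe_pair_edge_oracle(atoms, RP, 0, 1) == has_edge


def test_edge_occlusion_matches_oracle_random_triples():
    rng = np.random.default_rng(5)
    n_nontrivial = 0
    for _ in range(40):
        atoms = AtomSet(rng.uniform(0, 6, (3, 3)), rng.uniform(1.2, 1.9, 3))
        cx = build_alpha_complex(atoms, RP)
        for i in range(3):
            for j in range(i + 1, 3):
                got = (i, j) in cx.edges
                want = probe_pair_edge_oracle(atoms, RP, i, j)
                assert got == want
                n_nontrivial += want
    assert n_nontrivial > 10


def test_pair_patch_census():
    atoms = make_fixture("pair").atoms
    pset = build_patches(build_alpha_complex(atoms, RP), atoms, RP)
    assert census(pset) == {CONVEX_SPHERE: 2, TORUS: 1, CONCAVE_SPHERE: 0}


def test_triple_patch_census_probe_on_both_sides():
    atoms = make_fixture("triple").atoms
    cx = build_alpha_complex(atoms, RP)
    assert len(cx.edges) == 3
    assert sum(len(t.probes) for t in cx.triangles) == 2
    pset = build_patches(cx, atoms, RP)
    assert census(pset) == {CONVEX_SPHERE: 3, TORUS: 3, CONCAVE_SPHERE: 2}
    # Verify the probe satisfies the three tangency equations.
    for tri in cx.triangles:
        for _side, p in tri.probes:
            for a in tri.atoms:
                assert np.linalg.norm(p - atoms.centers[a]) == pytest.approx(
                    atoms.radii[a] + RP, abs=1e-9)


def test_probe_zero_gives_vdw_spheres_only():
    atoms = make_fixture("triple").atoms
    pset = build_ses(atoms, SurfaceConfig(probe_radius=0.0))
    assert census(pset) == {CONVEX_SPHERE: 3, TORUS: 0, CONCAVE_SPHERE: 0}


def test_complex_invariant_under_relabeling():
    fx = make_fixture("random_cluster", n=20, seed=5)
    atoms = fx.atoms
    perm = np.random.default_rng(0).permutation(atoms.count)
    shuffled = AtomSet(atoms.centers[perm], atoms.radii[perm])
    a = build_patches(build_alpha_complex(atoms, RP), atoms, RP)
    b = build_patches(build_alpha_complex(shuffled, RP), shuffled, RP)
    inv = np.argsort(perm)
    keys_a = sorted((p.kind, tuple(sorted(p.atoms)), p.side) for p in a.patches)
    keys_b = sorted((p.kind, tuple(sorted(int(perm[x]) for x in p.atoms)), p.side)
                    for p in b.patches)
    assert keys_a == keys_b


def test_patch_geometry_inside_trim_bbox(triple_result):
    """Sampled points of every patch lie in the trim bbox (inflated 1e-9)."""
    _fx, res = triple_result
    rng = np.random.default_rng(0)
    for p in res.patches.patches:
        pts = []
        if p.kind == TORUS:
            phi = rng.uniform(0, 2 * np.pi, 400)
            u = rng.uniform(0, 2 * np.pi, 400)
            ring = (p.center[None, :]
                    + (p.ring_radius + p.radius * np.cos(u))[:, None]
                    * (np.cos(phi)[:, None] * p.frame[0] + np.sin(phi)[:, None] * p.frame[1])
                    + (p.radius * np.sin(u))[:, None] * p.axis[None, :])
            pts = ring
        else:
            v = rng.normal(size=(400, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = p.center[None, :] + p.radius * v
        on = p.on_patch(pts)
        if on.any():
            lo, hi = p.trim.bbox
            assert np.all(pts[on] >= lo[None, :] - 1e-9)
            assert np.all(pts[on] <= hi[None, :] + 1e-9)


# ---------------------------------------------------------------------------
# slab decomposition


def test_slab_partition_single():
    atoms = make_fixture("random_cluster", n=10, seed=1).atoms
    part = slab_partition(atoms, 1, 12.0)
    assert part.n_slabs == 1
    assert len(part.per_slab_atom_ids[0]) == atoms.count
    assert len(part.per_slab_halo_ids[0]) == 0


def test_slab_partition_balances_uniform_atoms():
    y = np.arange(100) + 0.5              # uniform on [0, 100]
    atoms = AtomSet(np.column_stack([np.zeros(100), y, np.zeros(100)]),
                    np.full(100, 1.5))
    part = slab_partition(atoms, 4, 12.0)
    assert part.n_slabs == 4
    counts = [len(s) for s in part.per_slab_atom_ids]
    assert all(abs(c - 25) <= 1 for c in counts)
    assert np.all(np.diff(part.boundaries) >= 12.0 - 1e-9)


def test_slab_count_capped_by_extent():
    y = np.linspace(0, 30, 40)
    atoms = AtomSet(np.column_stack([np.zeros(40), y, np.zeros(40)]),
                    np.full(40, 1.5))
    assert slab_partition(atoms, 8, 12.0).n_slabs == 2   # floor(30 / 12)


def test_every_atom_in_exactly_one_slab():
    atoms = make_fixture("elongated_cluster", n=60, seed=11).atoms
    part = slab_partition(atoms, 4, 12.0)
    all_ids = np.sort(np.concatenate(part.per_slab_atom_ids))
    assert np.array_equal(all_ids, np.arange(atoms.count))


def test_dedup_bottom_vertex_rule(cfg2):
    """A patch is kept only by the slab whose half-open Y interval contains
    its trim's bottom vertex; N=1 keeps everything."""
    atoms = make_fixture("elongated_cluster", n=40, seed=2).atoms
    part1 = slab_partition(atoms, 1, 12.0)
    cx = build_alpha_complex(atoms, RP)
    pset = build_patches(cx, atoms, RP)
    kept = dedup_patches([pset], part1)
    assert len(kept) == len(pset)
    # Rule application: fabricate a two-slab partition and check membership.
    part2 = slab_partition(atoms, 2, 12.0)
    lo = part2.boundaries[1]
    kept_0 = dedup_patches([pset, build_patches(cx, atoms, RP)], part2)
    for p in kept_0.patches:
        assert p.trim.bottom_vertex_y() < np.inf


def test_build_ses_slab_invariance_patch_multiset():
    """Identical patch kind/center/radius multiset for 1 vs 2 slabs."""
    atoms = make_fixture("elongated_cluster", n=40, seed=2).atoms
    sets = [build_ses(atoms, SurfaceConfig(slab_count=n)) for n in (1, 2, 3)]
    ref = sets[0]
    for other in sets[1:]:
        assert census(other) == census(ref)
        for a, b in zip(ref.patches, other.patches):
            assert a.kind == b.kind and a.atoms == b.atoms
            assert np.allclose(a.center, b.center, atol=1e-6)
            assert abs(a.radius - b.radius) <= 1e-6
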