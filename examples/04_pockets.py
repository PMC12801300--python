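"""Detect a pocket with the dual-probe definition.

The ring_pocket fixture is a cup: a six-atom ring whose 1.7 A central
clearance admits the 1.4 A water probe but not a 3.0 A probe, closed from
above by three capping atoms.  The volumetric difference of the two SES
grids is exactly the pocket interior.
"""

from patchsurf import SurfaceConfig, make_fixture
from patchsurf.meshing import mesh_volume
from patchsurf.pockets import detect_pockets

fx = make_fixture("ring_pocket")
cfg = SurfaceConfig(probe_radius=1.4, big_probe_radius=3.0, grid_scale=2.0)
pockets, grid = detect_pockets(fx.atoms, cfg)

print(f"{len(pockets)} pocket(s) found")
for k, p in enumerate(pockets.pockets):
    print(f"pocket {k}: {len(p.voxels)} voxels, "
          f"volume {p.volume:.2f} A^3 (voxel count x h^3), "
          f"mesh volume {abs(mesh_volume(p.mesh)):.2f} A^3, "
          f"{len(p.mesh.triangles)} triangles")

# A convex body has no pockets by construction:
single = make_fixture("single_atom")
print("single atom pockets:", len(detect_pockets(single.atoms, cfg)[0]))
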