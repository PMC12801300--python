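# Methods

## The surface model

The solvent-excluded surface (SES) of a molecule is the boundary traced by
the inward face of a spherical probe of radius r_p (water: 1.4 Å) rolling
over the atom spheres.  It decomposes into three analytic patch families:

* **convex spherical** — the part of atom sphere i the probe touches
  directly.  Its valid region is the radial shrink (factor r_i/(r_i+r_p))
  of atom i's cell in the power diagram of the inflated spheres
  (r_j + r_p, weights (r_j+r_p)²), so the trimming solid is the
  intersection of one half-space per overlapping neighbor, each the
  radially scaled radical plane of the inflated pair.
* **toroidal** — the inward band of the torus swept while the probe rolls
  around a pair of atoms.  Axis: the interatomic direction; ring radius:
  the probe-center circle radius; tube radius: r_p.  The band is clipped
  by the two tangency-circle planes, restricted to the inner half
  (distance from axis ≤ ring radius), and limited to the free arcs of the
  rolling circle.  Spindle tori (ring radius < r_p) additionally exclude
  the lens |z| < sqrt(r_p² − R²), where the probe surface self-intersects
  across the axis.
* **concave spherical** — the probe sphere frozen in a position tangent to
  three atoms, clipped by the cone from the probe center through the three
  atom centers (the apex faces of the spanned tetrahedron).  Where two
  fixed probe balls overlap (including the mirror probe on the other side
  of the same atom triangle, whose bisector plane is exactly the
  atom-centers plane), each sphere is further clipped at the perpendicular
  bisector of the two centers — the exact boundary of the union of two
  equal balls.  This removes the dominant class of SES self-intersections;
  intersections involving the continuum of rolling probe positions are not
  removed and are absorbed by the failed-ray repair.

### The zero-alpha complex

Which pairs and triples of atoms carry patches is the zero-alpha complex of
the atoms weighted by (r_i + r_p)².  Rather than computing a regular
(weighted Delaunay) triangulation and filtering it, the complex is read off
its geometric characterization directly:

* **edge (i, j)** — present iff the probe-center circle of the pair retains
  a free arc.  Each other atom occludes an angular interval of the circle,
  solved in closed form (the condition is A cos φ + B sin φ > C); the
  union of intervals is merged exactly and the complement kept.
* **triangle (i, j, k)** — present per side iff the trilaterated probe
  position tangent to all three inflated spheres clears every other
  inflated atom.
* **vertex (exposed atom)** — an atom is surface-exposed iff it is not
  contained in another inflated sphere and either no neighbor cuts a cap
  from its inflated sphere or at least one of its circles keeps a free arc
  (the boundary of any uncovered spherical region lies on a pair circle).

For non-degenerate input this coincides with the alpha-complex filtration
of the regular triangulation; it avoids exact-arithmetic machinery
entirely.  Coincident equal atoms are resolved deterministically (the lower
index survives).  Configurations with four exactly co-tangent atoms are
genuinely degenerate for any double-precision construction; the bundled
fixtures deliberately avoid them (the pocket fixture's cap atoms break the
ring's 6-fold symmetry for precisely this reason).

## Slab-parallel buildup semantics

The buildup supports a domain decomposition along Y: atoms are counted in
1 Å mini-slab bins, N slab boundaries are placed on bin edges to equalize
atom counts (N is capped so each slab is at least 12 Å thick), and each
slab is built over its atoms plus a 12 Å halo band.  A patch is kept by the
slab whose half-open [lower, upper) interval contains the bottom-most
vertex of its trimming solid (torus solids use the corner points of the two
tangency-circle bounding squares in a deterministic frame; unbounded convex
solids fall back to the patch bbox corner); the outermost intervals extend
to infinity.  Because every quantity entering a patch is computed from the
same coordinates in the same globally sorted order regardless of the slab,
the merged patch set — and everything downstream — is *bitwise* independent
of the slab count.  The decomposition is executed sequentially here; the
contract it certifies is exactly what a threaded execution would need.

## Patch-based ray tracing

Axis-aligned rays are cast from the pixels of all three bounding-box faces
(edge rays through grid nodes; cell rays through cell centers).  The tracer
iterates over patches, not rays: each patch's trim bbox selects the pixel
ranges it can touch in each family, intersections (sphere: stable
quadratic; torus: analytic quartic) are filtered by patch membership and
bucketed per ray, and each ray's list is finally sorted.  No spatial index
of any kind exists.  The ray-centric every-ray-vs-every-patch scheme is
retained in the test suite as the equivalence oracle.

In/out status is a parity argument per ray; the three families vote and a
node is inside on a 2-of-3 majority.  Entry/exit pairs closer than 1e-7 Å
are discarded in pairs (2-point skipping, parity-preserving; the 1-point
variant that drops only the exit is kept for comparison).  Rays left with
odd counts are replaced by a copy of the previously processed ray of the
raster scan, keeping the sampled surface locally constant and manifold.

Volume is the mean of four parity estimates — inside segment lengths × h²
for each edge-ray family plus one cell-ray family (cell rays are traced
along X only; they feed the volume average, not the coloring).  Area is
summed mesh-triangle area.

## Quartic and cubic solvers

Ray–torus intersection reduces to a monic quartic.  Cubics use Cardano in
trigonometric/hyperbolic form (no complex arithmetic, no division by small
leading quantities); the quartic is factored into two quadratics through
the largest positive resolvent root m (Ferrari), with a biquadratic branch
when |m| ≤ 1e-12·max(1, |p|) and stable quadratic formulas throughout.
Negative quadratic discriminants within 1e-10 of zero (relative) are
clamped to a grazing double root, which 2-point skipping then removes.
Each root takes up to two guarded Newton steps, accepted only when they
reduce the residual.  When the direct factorization leaves relative
residuals above 1e-9 and the constant term is nonzero, the equation is
re-solved in the rescaled unknown x̂ = 4e(x − d) and the better-verifying
root set is kept; an unconditional rescale triggered by coefficient size
proved harmful, because any quartic with roots of magnitude ~50 (a ray
origin a box-length from a torus) has an astronomically large discriminant
while being perfectly well conditioned.

## Storage

The status grid is bilevel: a coarse grid at 1/4 resolution whose cells
lazily allocate 4×4×4 fine blocks; statuses pack 2 bits each into 32-bit
words (4 words per block), and all index arithmetic is shifts and masks.
Dimensions need not be multiples of 4 (edge blocks keep unused lanes).
Boolean buffers pack 32 flags per word.  Vertex indices are keyed by grid
edge in three bilevel grids (one per edge direction); the vertex's normal
lives at the same index in the mesh arrays, so one structure indexes both.
Pocket detection converts to a plain dense array first: flood fill is
read/write heavy and defeats the lazy layout.

## Marching cubes and smoothing

Mesh vertices on status-flipping cell edges are the *exact* analytic
ray-surface intersections recorded for that edge, with the patch's analytic
normal; if repair removed the record, the vertex sits at the edge midpoint
and is flagged dangling, and its normal is later averaged from incident
triangles (auxiliary buffers are allocated for flagged vertices only).
Cells are polygonized by face-consistent contour tracing: each face pairs
its crossings using only its own corner states (ambiguous faces keep the
inside corners connected), paired segments chain into closed loops inside
the cell, and loops are fan-triangulated.  Because the pairing is a
function of face data alone, adjacent cells always agree and the mesh
passes the closed-manifold edge census by construction; this is equivalent
to the standard case table with one fixed, globally consistent sub-case
choice.  The rare cross-cell fan-chord collision (two cells generating the
same interior chord) is repaired by re-triangulating the affected loops
around a centroid vertex, flagged dangling.  A single signed-volume test
orients all windings outward.

Laplacian smoothing (umbrella weights, displacement factor 1, default 1
iteration) uses the doubled-count scheme: looping over triangles, each
vertex accumulates both opposite vertices and one count per incident
triangle with no neighbor lists and no duplicate checks; on a closed
surface every undirected edge is seen from exactly two triangles, so the
sums are divided by twice the counts.  An open mesh breaks that identity
and raises a contract error.

## Pockets

A pocket is space accessible to the regular probe but not to a bigger one
(default 3.0 Å).  Both surfaces are colored on one grid sized for the big
probe; voxels inside the big-probe SES and outside the regular SES form the
differential mask, split into 6-connected components (scipy.ndimage.label;
a BFS oracle cross-checks in tests).  Components below 8 voxels at s = 2
(scaled by (s/2)³) are discarded as shell noise.  Each pocket is meshed by
marching cubes on its binary mask — midpoint vertices, since no analytic
intersections exist for a volumetric difference — replacing a skin-surface
construction over virtual probe atoms, which is out of scope here.

## Parameters

| parameter | default | meaning |
|---|---|---|
| probe_radius | 1.4 Å | rolling solvent probe; 0 gives the van der Waals surface |
| grid_scale s | 2.0 Å⁻¹ | grid points per Å (spacing h = 1/s) |
| halo_thickness | 12 Å | slab halo band; conservative bound on patch reach |
| slab_count | 1 | requested buildup slabs (capped by Y extent / 12 Å) |
| skip_strategy | two_point | near-pair removal variant |
| skip_eps | 1e-7 Å | entry/exit gap below which a pair is suspicious |
| big_probe_radius | 3.0 Å | pocket-defining probe |
| smoothing_iterations | 1 | Laplacian passes on the final mesh |

Internal tolerances: occlusion clearance 1e-9 Å, minimum free arc 1e-7 rad,
half-space membership slack 1e-9 Å, quartic graze clamp 1e-10 (relative),
mini-slab width 1 Å.

## Synthetic inputs and what they do not cover

The fixture generator produces toy molecules (1–200 atoms): closed-form
bodies (a single atom), the minimal pair/triple/tetrahedron exercising each
patch family, a cup-shaped 9-atom ring that admits a 1.4 Å probe through a
1.7 Å channel but excludes a 3 Å probe (the pocket reference), and random
clusters in 15 Å or 15×50×15 Å boxes with 2.4 Å minimum separation and
radii U(1.2, 1.9) Å — sequential random insertion with a jittered-lattice
fallback past the jamming density, deterministic per seed.  These reproduce
the geometric regimes of real molecules (all patch types, spindle tori,
buried atoms, self-intersections, cavities, pockets, multi-slab extents)
but not their scale: results here say nothing about wall-clock or memory
behavior on protein-sized inputs, about PDB-derived radius conventions, or
about heavily degenerate symmetric geometries, which the double-precision
buildup does not claim to handle.

Problem sizes used by the default test run: clusters up to 200 atoms,
grid scales 2–8 Å⁻¹, a 10,000-quartic solver corpus; the acceptance script
re-runs the solver corpus at 10,000 quartics.

## Known limitations

* Self-intersections between a fixed probe ball and the rolling (toroidal)
  continuum are not trimmed; they surface as rare odd-parity rays and are
  absorbed by the repair step, exactly like other numerically missed
  intersections.
* Four-atom co-tangencies and identical stacked atoms are handled by
  deterministic tie-breaks, not exact arithmetic; adversarially degenerate
  inputs can mis-classify patches.
* The ray tracer only casts axis-aligned rays; `intersect_patch` accepts
  any unit direction for spheres and tori but the grid machinery assumes
  the three canonical families.
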