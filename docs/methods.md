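# Methods

## Problem and model

A lattice splint is printable exactly when its geometry satisfies three
contracts: (i) the bar centerlines lie a constant clearance above the skin
(the bar radius, so the printed surface just touches the limb), (ii) the
lattice is even enough that no region is dense (blocking airflow) or coarse
(weak), and (iii) every exported solid is watertight with consistent
winding. The pipeline enforces each contract with an explicit geometric
mechanism, and the test suite checks the contracts rather than pictures.

### Offset shell

The draft shell displaces every vertex of the (closed, manifold) limb mesh
by distance `d` along its angle-weighted vertex normal. Angle weighting
makes the normal independent of tessellation. Per-vertex normal offsetting
is exact for a sphere and correct to `O(d * kappa)` for curvature `kappa`;
with `d = 2 mm` against limb curvature radii of 25 mm and up, the relative
clearance error stays below 2% (measured, not assumed: the acceptance suite
recomputes the mean nearest-point distance from the draft lattice back to
the limb). Offsets that locally self-intersect (concave creases tighter
than `1/d`) are detected — any offset vertex closer than `0.95 d` to the
input — and warned about, not repaired; repair is out of scope.

### Profile crop

Cut planes clip triangles exactly: crossing edges get their interpolated
intersection point (computed once per mesh edge, so the new rim is a welded
closed polyline on the plane), crossing triangles are re-triangulated, and
no cap is added. Exactness here is what makes two invariants testable at
1e-6: the rim lies on the plane, and the areas of the two complementary
cuts sum to the input area.

### Isotropic remeshing

The remesher is the standard incremental scheme: per iteration, split edges
longer than 4/3 h, collapse edges shorter than 4/5 h (link-condition
guarded, with a no-new-long-edges check), flip interior edges when that
reduces the squared deviation from valence 6 (4 on the boundary), smooth
tangentially, and project every vertex back to the *original* cropped shell
(interior vertices to the closest surface point, boundary vertices to the
closest point of the original rim polyline, so the crop profile survives
remeshing). Closest-point queries use a two-phase exact search: k nearest
triangle centroids, then a verification re-query within
(best distance + max triangle reach), which guarantees the true nearest
triangle is examined.

The target edge length h is exposed in config (demo default 12 mm). No
target density is inherent to the method; 12 mm gives bar spacing
comparable to commercial lattice splints on a wrist-sized limb.

### Mass-spring relaxation

Each lattice edge is a spring with the single uniform rest length
`L0 = Fscale * sqrt(sum |e|^2 / E)`, `Fscale = 1.2` (the uniform-density
scaling constant of the DistMesh family of mesh generators). Default
springs are bilateral Hooke springs `f = k (L0 - L)`: compressed springs
push, stretched springs pull, which both opens small triangles and shrinks
large ones. A `repulsive_only` mode (force clamped at zero when stretched)
reproduces strict DistMesh behavior. The integrator is semi-implicit Euler
with multiplicative velocity damping; the damping factor `1 - c*dt/m` must
lie in (0, 1), which makes speed non-increasing under zero force and the
integration unconditionally non-divergent at any stiffness the defaults
reach. After each step every node is projected back to the offset shell
(boundary nodes to the rim polyline) and the surface-normal component of
its velocity is removed, so momentum lives in the tangent plane where the
relaxation happens.

Defaults: `k = 1`, `m = 1`, `dt = 0.2`, `c = 1` (damping factor 0.8),
`tolerance = 1e-3 * L0` on the max per-node step displacement,
`max_iterations = 2000`. These are package choices, stable on all presets;
on the wrist demo the relaxation converges in roughly 1400–1600 iterations.
Convergence failure is a warning plus a flag in the report, never an
exception — the partial result is still a valid lattice.

Projection targets the cropped offset shell (the pre-remesh, fine surface)
rather than the draft itself: the splint's clearance contract is against
the skin, and the fine shell tracks it to well under 0.1 mm, whereas the
coarse draft's facets sag up to h^2/8R below the true offset.

### Wireframe to solid

The solid is the union of a sphere per node and a capsule (cylinder +
hemispherical caps) per edge, all of one diameter (4 mm in the demo; the
sphere is the capsule end by construction, so junctions are smooth). The
union is evaluated as `min` over primitive signed distance fields sampled
on a voxel grid and extracted with marching cubes at a level offset of
1e-4 pitch — the offset keeps the level set off grid nodes, which would
otherwise produce degenerate, non-manifold triangles. Narrow-band
evaluation (each primitive only touches voxels inside its bounding box plus
a 2-pitch band) keeps the cost linear in primitive count. Pitch defaults to
diameter/8 (0.5 mm for 4 mm bars): volume error against closed forms is
then under 2% and cross-section diameter error under 1%, both asserted in
tests. Exact mesh booleans are deliberately not used: robust union of
hundreds of mutually tangent primitives is their known failure mode, while
the SDF route trades a pitch-bounded geometric error for unconditional
watertightness.

Strap blocks are oriented boxes merged into the same field, their
through-holes subtracted as finite cylinders extended 2 mm past the block
faces. A block pose is derived from a single surface anchor point: block z
is the outward surface normal, x the tangential projection of the limb
axis, the hole runs circumferentially (block y), and the block is embedded
2 mm into the shell so it fuses with the struts. Blocks are 20 x 12 x 10 mm
with 4 mm holes by default; the 10 mm height places the hole centerline
3 mm above the shell — 1 mm clear of the 2 mm strut radius, so the strap
channel cannot be blocked by a bar passing under the block.

The through-channel check probes each block with two segments: one along
the hole axis (an open bore lets it pass with zero surface crossings) and
one offset into the wall beside the hole (exactly two crossings prove the
wall exists). Counting only wall hits, or only bore clearance, would pass
degenerate geometry; the pair is the minimal sufficient test.

### Two-piece split

The split reuses the exact plane clip and closes each rim loop with a flat
ear-clipped cap, oriented per-triangle against the outward cap normal.
Because clipping is exact and caps are planar, the two pieces' volumes sum
to the whole to floating-point accuracy (the test budget of 1% absorbs
nothing in practice). Caps assume each rim loop is a simple polygon — true
for transverse strut cross-sections; nested (annular) loops, which would
arise if the split plane passed through a strap hole, are not handled, and
the demo layout keeps blocks 9 mm clear of the split plane for that reason.

## Synthetic limb generator

The generator emulates what a structured-light scan of a forearm segment
provides: a watertight, genus-0, smoothly tapered tube, 10k–50k triangles.
Cross-sections are superellipses `|x/a|^p + |y/b|^p = 1` lofted along a
(possibly bent) axis with linearly interpolated semi-axes; a Gaussian
radial bump (default 4 mm, sigma 18 mm) plays the styloid prominence; seeded
Gaussian noise, smoothed over the loft grid so normals stay well defined,
is added radially. Defaults (length 250 mm, proximal 45 x 35 mm, distal
30 x 25 mm) match adult forearm anthropometry. What it does *not* emulate:
scan holes, flipped normals, non-uniform triangle density, fingers, or any
real anatomy — so passing tests demonstrate the pipeline's geometric
contracts, not robustness to defective scans (offsetting requires a closed
manifold input by design).

The density-graded preset used to demonstrate the optimizer reparameterizes
the draft's axial coordinate by a power law (gamma = 2.5, spacing ~3x
denser at one end) and reprojects onto the shell — an exaggerated version
of the uneven triangulations interactive remeshers produce. On it, the
relaxation cuts the edge-length CV from ~0.43 to ~0.16 (a 60%+ drop, tested
against a 30% floor), raises the minimum triangle area, and lowers the
maximum.

## Numerical choices and degenerate inputs

- Weld tolerance 1e-4 mm on mesh read (STL stores facets independently);
  far below the 0.2 mm print layer.
- All coordinates are millimetres; no unit conversion anywhere.
- Self-intersection checking is sampled (KD-tree-pruned exact
  segment-triangle tests, capped pair count) because the full check is
  O(n^2) in the worst case.
- Zero-length springs raise an error naming the edge; a collapse that would
  flip or degenerate a surviving triangle is rejected rather than patched.
- The optimizer contains no randomness: identical inputs produce
  bitwise-identical outputs, and the pipeline's OBJ artifacts are
  byte-reproducible for a fixed config and seed.
- Plane cuts that miss the mesh return the input unchanged with a warning
  (no-op rather than error, so configured cut lists can be permissive).

## Problem sizes

The demo preset runs a ~15k-triangle limb, a ~10k-triangle cropped shell
remeshed to ~300 nodes / ~900 bars, and a ~19M-voxel solidification grid at
0.5 mm pitch producing a ~1M-triangle solid. These sizes were chosen so the
full pipeline completes in a few minutes on one core while keeping every
measured quantity (clearance, strut diameter, volumes) inside its stated
tolerance; all of them scale through config.

## Known limitations

- Normal offsetting cannot handle concave creases tighter than the offset
  distance (warned, not repaired); a signed-distance offset is out of scope.
- No adaptive target edge length: the lattice is uniform by design.
- No strength analysis or air-circulation metric — the lattice statistics
  (edge CV, triangle area extremes, minimum angle) are geometric proxies.
- Split caps require simple rim loops (see above).
- The remesher assumes an orientable surface with at most a few boundary
  loops; it does not repair non-manifold input.
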