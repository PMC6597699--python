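# Methods

## Problem and model

Surviving strands of myocardium inside dense infarct scar conduct slowly and
can sustain reentrant ventricular tachycardia. The package identifies such
**heterogeneous tissue (HT) channels** purely from anatomy: a channel is a
narrow corridor of viable myocardium surrounded by scar and connected to
healthy myocardium, and it is *heterogeneous* when its surface is
structurally complex (a mixture of preserved and fibrotic tissue), which on
a triangulated model shows up as a high triangle count per unit length.

The input is a segmentation, not an intensity image: a 3D integer label map
with myocardium and scar codes and physical voxel spacing in mm. Everything
downstream is resolution-independent except where noted.

## Stage 1 — viable-myocardium volume

`extract_viable` computes `(M ∩ dilate(S, d)) \ dilate(S, m)` with
neighborhood `d = 30 mm` and scar margin `m = 1 mm`. Distances are
Euclidean between voxel centers in physical mm (exact distance transform,
`scipy.ndimage.distance_transform_edt` with the spacing as sampling), so
"isotropic" growth is isotropic in space even on anisotropic grids. The
grid is treated as padded with background; dilation never wraps. Scar
voxels outside the myocardium label still seed the neighborhood — scar
containment in myocardium is not assumed. An empty scar yields an empty
viable mask and, downstream, zero channels (a valid result, not an error).

A distance comparison tolerance of 1e-7 mm absorbs floating-point noise at
radii that are exactly attainable on the lattice.

## Stage 2 — structural model and curve skeleton

**Meshing.** Marching cubes at iso-level 0.5 on the background-padded mask,
vertices in mm. The mesh is then decimated by quadric edge collapse
(Garland–Heckbert quadrics, optimal-position placement with a determinant
gate, orientation-flip rejection) to a default budget of 10 000 faces with
an error guard of 0.5 mm (half a typical voxel): a collapse whose quadric
error exceeds the guard is never applied. **The guard takes precedence over
the budget.** This is deliberate: it bounds the geometric error of the
model and it is what lets structural complexity survive simplification —
smooth regions decimate to large triangles while rough regions keep small
ones, which is the signal the HT index measures. On complex models the face
budget may therefore be overshot. Duplicate faces (orientation-insensitive
vertex multisets, a marching-cubes seam artifact) are removed, then
isolated face-connected components under 100 triangles (noise) are dropped;
connectivity is face adjacency via shared edges. Finally the model is
centered in a unit cube with its longest axis spanning exactly 1 (uniform
scale; the transform is inverted before any physical measurement).

**Contraction.** The mesh vertices are treated as a point cloud. One-rings
come from per-point local Delaunay triangulation: each vertex and its
k = 8 nearest neighbors are projected onto their PCA plane, triangulated,
and the triangles incident to the center vertex join the global one-ring
set. Iteration solves the stacked least-squares system

```
[ W_L · L ] P' = [ 0 ],     [ W_H ] P' = [ W_H · P ]
```

with a cotangent Laplacian recomputed from current positions on fixed
connectivity, `W_L ← 3 · W_L` per iteration (cap 2048), initial
`W_L = 1/(10 √(mean one-ring area))`, and per-vertex attraction
`W_H,i = sqrt(A_i⁰ / A_iᵗ)`. Termination: total one-ring area below 0.1%
of initial, stagnation (< 0.1 percentage-point progress on two consecutive
iterations), an area increase of more than five points (overshoot — the
previous state is kept), or 20 iterations; non-convergence returns the best
state with a flag.

Two stabilizations matter on sheet-like anatomy (a ventricular wall is a
thick curved sheet, which this family of methods handles far less
gracefully than tubes):

* cotangent weights are clamped to [0, 100] (negative weights from obtuse
  triangles and unbounded weights from degenerate ones both destabilize the
  solve), and each Laplacian row's total weight is capped at the initial
  median row weight. Without the cap, the near-degenerate one-rings of an
  already-collapsed region carry enormous weights and the amplified
  contraction term overwhelms the attraction term — a collapsed curve then
  keeps shortening and the skeleton loses length.
* a vertex whose one-ring has become **locally one-dimensional at a scale
  commensurate with its original extent** (second principal component below
  1e-3 of the first, largest component at least 30% of its original value)
  is snapped onto its neighborhood's principal line and frozen for all
  remaining iterations with a large attraction weight (1e3). The scale
  condition distinguishes transversal collapse — the vertex has reached the
  curve skeleton — from isotropic shrinkage (a sphere contracting toward
  its centroid), which must continue.

A closed curved shell still contracts toward its center of curvature, off
the tissue; that is intrinsic to curvature-flow contraction. Skeleton
containment inside the (dilated) source mask therefore holds for tubular
structures but **not** for wall-like regions of an anatomical model; the
containment property test covers cylinders and tori. Detection is
unaffected: nodes that drift off tissue measure no cross-section and can
never be channel nodes.

**Thinning.** Skeletal nodes are a farthest-point subsample of the
contracted points (seeded initial pick, lowest-index tie-break) at a
spacing of `sample_radius_mm = 3.5 mm`. The spacing is an absolute length,
not a fraction of model size, because the quantity it must dominate —
residual contraction fuzz, ~1 mm at 1 mm voxels — is absolute. Vertices
are assigned to nodes by **geodesic Voronoi cells** on the mesh-adjacency
graph with edge lengths measured between contracted positions, so cells are
always mesh-connected and spatially coincident but unconnected structures
can never fuse into one node. Node positions are cell centroids of
contracted points, mapped back to mm.

Edges join cells containing mesh-adjacent vertices, with three guards
against fuzz artifacts, applied in order: (1) mesh edges longer (in
contracted space) than the sample radius can leap across a whole cell and
are only used where needed to keep a mesh component connected (shortest
first, Kruskal-style); (2) nodes joined by an edge shorter than the sample
radius are merged (parallel cells inside fuzz); (3) the long edge of any
graph triangle whose third node lies on the segment between the other two
(longest ≥ 0.9 × sum of the others) is a topological shortcut and is
dropped. All three are deterministic. Faces map to the node owning the
majority of their vertices (ties: the node of the face's lowest-index
vertex).

## Stage 3 — channel detection

Per node, the local axis is the direction between its two neighbors
(degree 2), toward its single neighbor (degree 1), or the principal
direction of its incident edge vectors (degree ≥ 3, flagged as branch).
The cross-sectional plane orthogonal to the axis is sampled on a
30 × 30 mm window at 0.25 mm pixels with nearest-neighbor mask lookup
(indices by `floor(x + 0.5)`, so every voxel's cell has exactly one voxel
width); only the in-plane connected region containing the node counts —
an unbounded plane would credit distant tissue to the node. A node off
tissue with nothing within one voxel in-plane measures no area and is never
narrow. The area is computed against the viable mask in mm space; the
90 mm² threshold is physical.

Channels are maximal connected runs of ≥ 3 narrow (< 90 mm²) non-branch
nodes; runs never cross a degree ≥ 3 node (the axis definition presumes
chain segments, and branch points separate distinct corridors). Channel
length is the arc length of the node path — centroid to centroid, which
undersamples the true corridor by up to half a cell per end; at the default
node spacing this stays within the validated 15% on 20–40 mm channels. The
HT index is total mapped faces of the run's nodes divided by that length,
with faces counted on the decimated, cleaned mesh (the model that was
skeletonized); face counts therefore depend on the decimation settings,
which the run manifest records. A channel is additionally annotated
`anchored` when each terminal node has a neighbor outside the run that is
wide or a branch junction — the operational reading of "connected to
healthy myocardium". The annotation does not gate detection, because the
detection algorithm itself does not.

## Synthetic phantoms

The phantom module emulates the anatomy the workflow targets: a
half-ellipsoid ventricular wall (default outer radii 45×45×80 mm, 10 mm
wall, 128×128×96 grid at 1 mm isotropic), a dense scar sleeve (12 mm
radius) wrapped around a mid-wall channel tunneled along a meridian, with
controllable channel radius (3 mm), length (20–40 mm), and wall roughness.
Roughness is seeded band-limited noise (six random-phase modes in arclength
and wall angle, unit RMS, ~6 mm wavelength) scaling the channel radius; an
amplitude of 1.2 mm produces an HT-positive channel while 0 mm yields a
smooth, viable-but-not-HT channel — the two study conditions of the
detection truth table. The scar sleeve has rounded caps and the channel
pierces them into open wall, so every designed channel is scar-surrounded
and healthy-anchored. Optional myocardium specks float in the cavity with
radii chosen so their meshes bracket the 100-triangle cleanup filter.

Phantoms are label maps only: no MR intensities, acquisition noise or
partial-volume physics (the pipeline's input is a segmentation). Passing
tests on phantoms therefore validate the geometry processing and decision
rules, not segmentation robustness on real images. Real viable-myocardium
anatomy is also patchier and less smooth than the phantom wall; the
HT-index scale on real data depends on image resolution and decimation
settings in ways the phantom only samples at one operating point.

## Numerical and design choices

* Defaults follow the workflow's stated values: 30 mm neighborhood, 1 mm
  scar margin, 100-triangle filter, 90 mm² area threshold, minimum 3
  connected segments, HT index threshold 26 faces/mm.
* The Fisher test (two-sided by default; the sidedness flag exists, and for
  the study's detection table both choices coincide because one tail is
  empty) is delegated to `scipy.stats.fisher_exact`; an exact rational
  enumeration oracle cross-checks it in the tests. Empty-margin tables
  return p = 1, flagged degenerate.
* Cohort means are reported at one decimal with round-half-up; raw values
  are always retained in the JSON summary.
* Everything is deterministic given the configuration: phantom noise and
  farthest-point sampling are seeded, ties break on lowest index, and two
  identical runs produce byte-identical artifacts.
* Problem sizes used in the validation suite: phantoms at 128×128×96 / 1 mm
  with 10 000-face models, geometric primitives (cylinders, tori, spheres)
  at 1 mm with ~3–4000-face models. A 0.5 mm phantom preset exists for
  runs closer to ex-vivo resolution.

## Known limitations

* Quadric collapse does not enforce the edge-link condition; tiny closed
  components can degenerate into face fragments when decimated far below
  their size. The pipeline's 100-triangle filter removes such debris.
* Curve skeletons of wall-like regions drift inward (see above); only
  channel-bearing, tube-like structure is metrically reliable.
* Channel length is quantized by the skeletal node spacing (±~half a cell
  per end); very short channels (≲ 3 cells) carry proportionally larger
  length uncertainty.
* Detection operates at the macro level: sub-voxel or intramural
  micro-channels below the mask resolution are out of reach by
  construction.
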