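# Methods

This note documents the model, the numerical choices and the limits of
what the test suite demonstrates.

## The 2D-to-3D consensus model

An instance segmentation is two couplable objects: a foreground binary
and a per-voxel object ID. If every object were eroded until spatially
separated, the IDs would be recoverable from the binary alone by
connected components. `useg3d` makes that erosion *continuous and
reversible*: each 2D cell is represented by a scalar potential Φ whose
gradient flow contracts the cell onto a medial attractor, and the history
of the flow carries IDs back to the un-eroded voxels. Because the medial
axis of a 3D object is consistent with the medial axes of its 2D slices,
attractors assembled from three orthogonal stacks of 2D slices land near
each other in 3D, so spatial proximity — not cross-slice label matching —
identifies 3D objects. The pipeline is:

1. per-slice, per-cell 2D distance transform and unit gradient field;
2. content-weighted fusion of the per-view foregrounds into a 3D binary
   B, and of the per-view gradient components into a unit 3D field;
3. suppressed gradient descent of all B voxels along the field;
4. density-based clustering of final positions; IDs mapped back to the
   initial voxels;
5. QC filters and guide-image refinement.

### Distance transforms

* `edt` — Euclidean distance to the background (image border counts as
  background, so Φ > 0 on every foreground pixel).
* `poisson` — the discrete problem −∇²Φ = 1 with Φ = 0 on the first
  background pixel; 5-point stencil, solved sparsely per cell on its
  padded bounding box. A 1×N bar therefore reduces to a tridiagonal
  system, which the tests exploit as an exact oracle; a single interior
  pixel solves 4Φ = 1, i.e. Φ = 0.25.
* `poisson_point` / `poisson_skeleton` — Laplace's equation away from an
  explicit source (the unit source term only on the source set), so the
  interior maximum sits on the source. The point source is the pixel with
  EDT above the 10th percentile nearest the coordinate-wise median of the
  cell; the skeleton source is a thinning of the Gaussian-smoothed
  (σ = 3), mean-rethresholded mask. The point variant supports the power
  transform (Φ − Φ_min)^p, default p = 1.
* `geodesic_point` / `geodesic_skeleton` — within-mask travel time from
  the source, computed by Dijkstra on the 8-neighbor pixel graph with
  metric edge weights (`skimage.graph.MCP_Geometric`), stored flipped
  (Φ = T_max − T) so the source is the maximum. This first-order
  discretization overestimates true geodesic distances by up to ~8%
  (the metricization error of the 8-neighbor stencil); the tests compare
  against an independent sparse-graph Dijkstra at matching tolerance.

One convention removes all sign ambiguity downstream: every stored
gradient field points **toward** the attractor (ascending Φ, since every
stored Φ attains its interior maximum on the attractor), is
unit-normalized, and vanishes outside the mask, on flat plateaus and on
explicit source pixels. The descent update then simply adds η·field.
Cells of 1–2 pixels fall back to the EDT for the explicit variants, whose
linear systems degenerate there.

### Fusion

The content-based average weights each view by the inverse of its local
standard deviation plus a pseudo-count α (default 0.5, ε = 1e−20). Local
SD uses the population estimator over a P-wide cube with reflective
(symmetric) edge padding — the estimator and edge rule are our choices;
alternatives shift third-decimal values only. Defaults: P = 1 for
gradients and probabilities (simple mean), P = 3 for binary foregrounds.
Gradient stacks are pre-smoothed per 2D slice (σ_pre = 1, preserving view
independence), fused component-wise — x from the x-y and x-z views, y
from x-y and y-z, z from x-z and y-z — post-smoothed in 3D (σ_post = 1)
and re-normalized on the foreground support. With fewer views, the
unobserved components start at zero and are imputed only by the
post-smoothing. Foreground binarization uses 0.5 (majority vote) for
binary inputs and multi-class Otsu for probability inputs.

Measured on a radius-14 digital sphere, the fused field deviates from the
true 3D EDT gradient direction by a median of ~8°, with 95% of
off-boundary voxels within 18°; the residual is a systematic
mid-latitude tilt of the equal-weight component fusion, not noise.

### Descent

η(t) = δ/(1 + t·τ) with momentum μ on the previous iteration's sampled
gradient; the first step has zero history, so it moves by η·δ/(δ+μ).
Field sampling is nearest-voxel by *rounding* during descent; *flooring*
is reserved for the final rasterization onto the grid. Positions are
clipped to the volume every step. Points on zero-gradient voxels stay
put and are handled by clustering (possibly assigned 0 and reported)
rather than NaN-guarded normalization.

The total travel distance is bounded by Σ η(t) ≈ (δ/τ)·ln(1 + τT), which
is why thin networks need a larger τ (default presets: 0.5 convex/
branched, 2.0 networks): stopping the erosion early keeps an elongated
object's attractor in one piece instead of fragmenting it.

Tiled descent covers the volume with overlapping tiles (default 25%
overlap); each foreground voxel is advected in exactly one owning tile
(ownership cores partition the volume at overlap midpoints) with
clipping at the tile bounds, and results are globalized by the tile
offset. The tiled result equals the full-volume result whenever each
cell's attractor basin is visible within the overlap margin; the tests
assert exact label equality on a two-sphere fixture whose spheres
straddle tile seams.

### Clustering

Final positions are floored, clipped, counted and smoothed with a
Gaussian (σ = 1) into a density ρ; the attractor support is
ρ > mean(ρ) + k·std(ρ) with k = 0 by default (k = 1 is the documented
conservative alternative), labeled with 26-connectivity, and IDs are
carried back by indexing. With T = 0 the procedure short-circuits to
connected-component labeling of B — the exact iteration-0 limit —
because the density-threshold path only guarantees that equality up to
boundary effects. Increasing σ merges nearby attractors (non-increasing
label count), which is the intended control for branched structures.

### Postprocessing

Recommended order: size filter (default 200 voxels; each survivor also
reduced to its largest connected component) → gradient-consistency
filter → statistical large-cell filter → label diffusion → guided
filter.

The consistency filter re-slices each cell's own binary mask, recomputes
its transform and fused 3D field, and removes cells whose mean (over
their voxels) Euclidean norm of the field difference exceeds 0.85. The
Euclidean-norm reading of the error is deliberate: independent random
unit fields give an expected per-voxel difference magnitude of ~4/3 in
3D, comfortably above the 0.85 default, while the per-component mean
absolute error of random fields (~2/3) would never trip it.

The large-cell filter keeps volumes ≤ mean + k·std (k = 5) of the cell
volumes observed on entry, in one pass; with zero spread nothing is
removed. Note that a single outlier among n cells has a z-score of at
most √(n−1), so this filter is inert for fewer than ~26 cells at k = 5.

Label diffusion runs per cell (binary versus background) on a crop
padded by 25 voxels: 6-neighbor affinities blend guide-intensity
similarity exp(−D²/(2·mean(D)²)) with plain adjacency (weight α = 0.5),
rows are sum-normalized so z ← (1−γ)Az + γL is a contraction (the
normalization is our addition), γ = 0.75, 25 iterations, argmax
assignment, largest-component cleanup, and no overwriting of neighboring
cells. γ = 1 or zero iterations is the identity. A joint multi-label
variant (`diffuse_multilabel`) diffuses a partial seeding, for which the
uniform-guide decision boundary falls on the spatial midline. The
affinity neighborhood is 6-connected by default (26 available): the
sparsity buys an order of magnitude in speed and the refinement is
insensitive to the choice on our fixtures.

The guided filter is the standard local-linear filter (cube window of
half-width r = 35, regularizer ε = 1e−4, box filters with reflective
edges) of the cell's binary mask against the guide image
I_guide = α·I_norm + (1−α)·I_ridge, rebinarized by two-class Otsu with
other cells masked out. With the mask as its own guide and small ε it is
an identity; with huge ε it degenerates to an Otsu-rebinarized double
box blur — both limits are asserted.

### Evaluation

Optimal one-to-one matching on 1 − IoU via linear sum assignment, with
centroid k-nearest-candidate sparsification (k = 10) above 50 objects and
exact dense matching below. Both labelings are first relabeled
sequentially after an indirect stable sort of their (x, y, z) centroids,
making the result invariant to ID permutation. TPs at a cutoff are
matched pairs with IoU ≥ cutoff; AP = TP/(TP+FP+FN) and
F1 = 2TP/(2TP+FP+FN) over 11 cutoffs equisampling [0.5, 1.0]. A
both-empty image scores 1 (no objects, no errors); pred-empty versus
non-empty scores 0. The reference-foreground restriction removes
predicted cells in foreground components sharing < 25% (or 1% for thin
vessels) of their volume with a reference component.

## Synthetic fixtures

The generator emulates three super-morphotypes seen across real 3D cell
datasets: `convex` (non-overlapping, optionally touching digital spheres,
membership = voxel-center distance ≤ r), `branched` (a trunk plus 1–4
arms diverging from a junction, rasterized as distance-to-polyline ≤ r)
and `network` (random nearest-neighbor trees of thin tubes, radii clipped
to 1–3 voxels). Slicing treats every contiguous in-plane region of every
object as an anonymous 2D cell (8-connectivity in-plane), exactly the
information a slice-by-slice 2D segmenter would produce; corruption
injects dropped, split and merged 2D labels and boundary jitter in a
fixed order (drop → split → merge → jitter) so seeds reproduce exactly.

Default study conditions used by the tests and the acceptance script:
96³ volumes, 4–8 objects, radii 8–12 voxels for spheres (tube radius 4,
network radii 1–3); these sizes put several cells per tile seam while
keeping a full reconstruction under a few seconds. What the generator
does **not** emulate: optics (PSF, shot noise, anisotropic blur),
intensity texture, cell crowding beyond touching, or systematically
biased 2D segmenters; passing tests therefore certify the geometry of
the reconstruction machinery, not robustness to real microscopy
artifacts — the preprocessing module and corruption model exist to probe
the latter separately.

## Degenerate inputs and tie-breaks

Empty masks raise; empty slices produce zero fields; constant images
make percentile normalization and Otsu thresholding error out rather
than silently return. Zero-magnitude gradients (plateaus, sources,
outside-mask) are exact zeros, never normalized. Attractor-less points
(density below threshold) keep ID 0 and are counted in the run report —
silent reassignment would mask gradient errors. Coordinates are 0-based
(z, y, x) everywhere; gradient arrays are component-first.

## Known limitations

* The geodesic transform is a first-order graph approximation of the
  Eikonal solution (see above); power-transform exponents per dataset
  are exposed but default to 1.
* Tiled descent assumes attractor basins fit in the tile overlap; cells
  larger than the overlap margin can split at seams.
* The per-cell binary diffusion and guided filter do not arbitrate
  overlapping claims between neighboring cells beyond "first mask wins";
  the joint multi-label diffusion handles that at higher cost.
* AP/F1 with the k-nearest candidate restriction is exact only when the
  optimal assignment is within the candidate set; below 50 objects the
  exact dense matcher is always used.
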