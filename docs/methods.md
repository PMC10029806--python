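# Methods

This note documents the models, estimators and numerical choices behind
`leafvox`, what the synthetic phantoms do and do not emulate, and the
known limitations of each stage.

## Input model

All stages operate on a `LabeledStack`: a 3D integer label volume with an
isotropic voxel size in µm and a seven-role legend (background, adaxial
and abaxial epidermis, mesophyll cell, intercellular airspace,
vasculature, stomatal pore).  Anisotropic voxel sizes are rejected —
every estimator assumes one edge length.  The canonical orientation puts
the slice index on axis 0, the leaf normal on axis 1 (adaxial side at low
indices) and leaf width on axis 2; `canonicalize` finds the normal axis
as the one separating the two epidermis centroids farthest and applies
only axis permutations and flips, so per-label voxel counts are
invariant.  Stoma voxels are pore openings piercing the abaxial
epidermis: they act as the sources of all geodesic computations, and
their (tiny) volume is grouped with the epidermis so tissue volumes sum
exactly to the whole-leaf volume.

## Tissue traits

* **Thicknesses** are medians over voxel columns taken along the leaf
  normal; a column participates if it contains any non-background voxel
  ("along the leaf area"), so empty margins do not bias the median.
* **Volumes** are voxel sums times the voxel volume.  V_mes = V_cl +
  V_ias by definition.
* **Two leaf thicknesses are carried.**  `L_leaf` is the descriptive
  median-column thickness.  `L_eff_leaf = V_leaf/LA` is the effective
  (volume-derived) thickness; with this choice the identity
  S_m,LA = S_m,Vcl·(1−θ_ias)·f_mes·L_eff_leaf closes algebraically to
  machine precision, which the decomposition stage relies on.  The two
  coincide for a perfect slab and differ slightly for rough or tilted
  laminae; the decomposition defaults to `L_eff_leaf`.
* **LA of a scan** is the paradermal footprint of the grid
  (axis-0 × axis-2 extent).  This assumes the scanned strip is fully
  covered by leaf, which both phantoms guarantee.

### Mesophyll surface area

S_m is the marching-cubes area of the airspace boundary restricted to
faces adjacent to mesophyll cells.  Numerical choices:

* The isosurface is extracted at the zero level of the **signed Euclidean
  distance field** of the binary airspace mask, Gaussian-smoothed with
  σ = 0.8 voxels, at marching-cubes step size 2 (both configurable).
  Marching cubes applied directly to a binary mask overestimates the
  area of smooth objects by a staircase factor of roughly 9 % on digital
  spheres at any step size; the smoothed distance field reduces the
  sphere error to below 1 % over radii 20–60 voxels (decreasing with
  radius) while planar faces remain exact.  The cost is a controlled
  underestimate near sharp edges (≈5 % on an axis-aligned cube, from
  corner rounding).
* **Face ownership**: each triangle is attributed to the label of the
  nearest voxel *outside* the mask at its centroid (via the EDT feature
  transform), and only mesophyll-adjacent triangles are counted.
  Epidermis- and vasculature-adjacent airspace surface is excluded, since
  S_m is defined as *mesophyll cell* surface.  The same rule makes
  per-vaporshed surfaces consistent: where one vaporshed abuts another,
  the nearest outside voxel is airspace, so the face is counted by
  neither, and per-vaporshed values aggregate to the whole-scan value up
  to mesh-boundary effects (≲3 %).
* The estimator is exactly invariant under axis flips; axis permutations
  can land on different marching-cubes table entries at saddle
  configurations, changing the area by ~0.1 %.
* At step 2, structures only a few voxels wide are meshed coarsely (the
  sampling grid quantizes wall positions by 2 voxels), so per-vaporshed
  surfaces of narrow channels carry a ~10 % position-dependent wobble.
  Real scans at 0.16–0.33 µm voxels resolve airspace features far more
  finely than the desk-scale phantoms used in the tests.

## Palisade cells

Full 3D instance segmentation of mesophyll cells is deliberately
avoided.  Instead, three paradermal planes are sampled — the first plane
fully below the adaxial epidermis, the last palisade plane, and their
midpoint.  The palisade bottom is not encoded in the tissue labels; it is
supplied explicitly or detected as the largest jump (> 0.10) in the
per-plane porosity profile, which works when the palisade/spongy
transition is abrupt and otherwise raises an error asking for explicit
bounds.

Per plane, cells are separated by a marker-controlled watershed on the
Euclidean distance transform of the cell mask, with h-maxima marker
suppression (default depth h = 2 voxels; deeper h merges fragmenting
maxima, shallower h oversegments lobed cells).  Cells touching any image
edge are excluded from diameter statistics ("completely enclosed");
cells touching the left or bottom edge are excluded from the packing
density so a tiling of images counts each cell exactly once.  Cell radius
is the equivalent-area disk radius, r = √(A/π); the per-slice summary
uses the **median** radius, robust to watershed fragments.

A cell is modelled as two stacked frusta (top→middle, middle→bottom)
with volume V = (πh/3)(r_a² + r_a r_b + r_b²) and lateral area
S = π(r_a + r_b)√(h² + (r_a − r_b)²).  Lateral (not total) area is used
because palisade end caps are typically pressed against the epidermis or
neighbouring cells rather than exposed to airspace.  The slant term uses
the standard (r_a − r_b)² radicand of frustum geometry.

## Stomatal vaporsheds

The airspace is modelled as a graph: nodes are airspace plus stoma
voxels, edges connect 26-neighbours with quasi-Euclidean weights (voxel
size × 1, √2, √3).  This is the closest local approximation to
unconstrained shortest paths through the airspace; it overestimates true
Euclidean geodesics by at most ~4 % (the fixed-direction error of
26-connectivity chamfer metrics).  Distances are computed with Dijkstra's
algorithm (`scipy.sparse.csgraph`).

* **Assignment**: per-stoma distances L_geo,i are computed independently;
  the whole-scan L_geo is their minimum, and each reachable airspace
  voxel joins the stoma attaining it.  Ties within 1e-9 µm go to the
  lowest stoma id — deterministic and independent of evaluation order.
  Unreachable airspace (sealed cavities) is flagged separately and
  reported as a fraction.
* **Enclosure**: trait statistics per stoma are only reliable when the
  vaporshed is fully contained in the field of view.  This is
  operationalized as: a stoma is *enclosed* iff its vaporshed touches no
  lateral (axis-0/axis-2) boundary face of the volume.
* **Tortuosity and path lengthening** are evaluated at airspace voxels
  face-adjacent to mesophyll cells (the diffusive surface):
  τ = L_geo/L_euclid with L_euclid the straight-line distance to the
  nearest stoma centroid, and λ = L_geo/L_normal with L_normal the
  leaf-normal depth to the abaxial surface plane (the outermost plane
  containing abaxial epidermis or stoma), floored at one voxel.  Both
  ratios are floored at 1 per voxel (a geodesic cannot beat a straight
  line); the scan summary is the median.  These follow the common
  convention for lateral path lengthening; other definitions (e.g.
  surface-to-surface averages) can be built from the exposed
  `DistanceField`.
* **Airspace conductance** defaults to g_ias = D_c·θ/(τ·λ·ΔL)·P/(RT)
  with ΔL = L_mes/2 — the mean gas path of a hypostomatous leaf where CO₂
  enters abaxially and the diffusive sink is distributed over the
  mesophyll depth — using D_c = 1.54e-5 m² s⁻¹ (CO₂ in air at 25 °C) and
  ideal-gas molar conversion.  The formulation is pluggable: any callable
  with the same signature can replace it.

## Response-coefficient decomposition

For a multiplicative identity T = Πx_i, the response coefficient of each
factor for a condition contrast is RC_x = Δlog x/Δlog T (the log base
cancels).  When the identity holds in both conditions the coefficients
sum to 1 exactly; this is asserted to 1e-9 and holds for any identity,
not just the S_m,LA factorization (an LMA decomposition passes the same
property).  Group aggregation is geometric (mean of logs per
condition×group cell) and the group-level target is recomputed from the
mean-log factors rather than averaged independently — this keeps the
identity exact within every cell.  Relative contributions are reported as
signed percentages; negative shares (a factor moving against the target)
are meaningful and expected, e.g. for S_m,Vcl in sun leaves.
Assimilation normalizations (per mass, per leaf volume, per cell volume)
and per-cellular-volume concentrations are plain unit conversions with
effective depths in µm.

## Synthetic phantoms

The phantoms emulate the geometric features the pipeline measures, not
leaf optics or biology.  Shared layout: background padding, adaxial
epidermis, mesophyll, abaxial epidermis pierced by stomatal pores on a
regular lattice (centered in the footprint, pitch configurable).

* **Slab phantom** — fully deterministic: solid mesophyll pierced by
  square vertical air channels on the stomatal lattice.  The channel
  window is chosen by exhaustive search over integer widths (the strict
  symmetric criterion |i − c| < w/2 keeps the pattern mirror-symmetric
  whenever the lattice is) so the voxelized porosity lands within ±0.02
  of the target; infeasible targets (channels would fuse) raise an
  error.  Ideal for exact conservation, partition and symmetry tests; the
  straight channels give τ = λ = 1.
* **Leaf phantom** — hexagonally packed palisade frusta (radius linearly
  interpolated top→bottom, voxelized by center-inclusion) over a spongy
  layer whose porosity is grown by placing random spherical pores that
  must overlap already-connected air, seeded from vertical channels under
  each stoma.  The overlap rule guarantees by induction that every
  airspace voxel is reachable from a stoma; a post-check verifies global
  connectivity and retries with wider channels before erring.  All
  randomness flows from the spec's seed; identical spec + seed gives an
  identical stack.

Ground truth records exact post-voxelization volumes and thicknesses
(voxel counts, layer extents) plus analytic values (frustum S/V per cell,
targeted porosity) kept separately, because surface measures carry
voxelization error that volume measures do not.  Defaults describe a thin
dicot leaf at 1 µm voxels: 200 µm lamina, 15 µm epidermes, palisade
fraction 0.5 with 6–9 µm cell radii on a 20 µm pitch, 30 % spongy
porosity, stomata every 60 µm.

What passing tests on phantoms do **not** show: robustness to real
segmentation noise (rough cell walls, mislabelled voxels), to lobed or
irregular cell shapes, to veins interrupting the airspace, or to
anisotropic resolution.  The phantoms validate the estimators'
correctness on known geometry, not the segmentation upstream of them.

## Test problem sizes

The suite runs phantoms of roughly 60–120 voxels per side (well under
100³), where the brute-force Dijkstra oracle and the marching-cubes
sphere battery complete in seconds while still exercising multi-stoma
partitions, symmetry and parameter recovery.  Larger stacks change
nothing structurally: all algorithms are linear or n log n in the voxel
count.

## Known limitations

* The porosity-jump detector for the palisade bottom fails on gradual
  transitions; explicit bounds are then required.
* S_m at step 2 is biased low near sharp edges (~5 % on cubes) and noisy
  on structures a few voxels wide; use step 1 and/or smaller smoothing
  for very thin airspace networks.
* τ uses stoma centroids (not pore surfaces) for the Euclidean reference,
  which slightly inflates τ for voxels near a pore.
* The g_ias expression is a one-dimensional effective-medium estimate;
  it is not a replacement for reaction–diffusion simulation inside
  vaporsheds.
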