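# Methods

## Scope and data model

The package quantifies already-traced cytoskeletal segmentations; it does
not segment densities. A *scene* is one quantification unit (one tomogram
or one image volume): a frame (voxel size, dimensions, tilt axis), filament
centerlines tagged `actin` or `mt`, up to one ventral-membrane (VM) and one
dorsal membrane model, and organelle sets (ISGs and similar). Coordinates
are nanometres, axis order (x, y, z); voxel masks are (z, y, x). The nm
conversion happens exactly once, at I/O time: `units="voxel"` coordinates
are 0-based voxel indices at voxel centers, nm = index × voxel size.
Filaments with fewer than two points, duplicate consecutive points, or
non-finite coordinates are rejected rather than dropped, so upstream
tracing faults surface immediately.

The traced "filament" is the segmentation unit of template-based tracing:
a cylinder of fixed length (60 nm actin, 100 nm MT) and diameter (8 nm,
15 nm). The volume-ratio estimator builds on exactly this model —
Σ π(d/2)² × arc length over centerlines divided by frame volume — rather
than voxel-counting a rendered segmentation, so it is reproducible from
coordinates alone.

## Geometry

**Resampling.** Centerlines are resampled at fixed arc-length intervals
(default 4 nm) by linear interpolation along the polyline: samples at arc
positions 0, h, 2h, …, plus the terminal point even when the final
remainder is shorter than h. Each sample records its arc position, so the
covered arc length equals the polyline arc length exactly; this is what
makes length-derived quantities (volume ratios) independent of the
resampling grid.

**Orientation.** A filament's orientation is its end-to-end chord, not a
local tangent — the estimator of choice for short, nearly straight
segmentation units, and deliberately insensitive to tracing wiggle. Angle
to a membrane plane is arcsin(|u·n̂|) ∈ [0°, 90°]; the VM is by convention
the tomogram XY plane, with a least-squares plane fit (smallest singular
vector of the centered surface points) available for mask-derived or
tilted membranes. Pair angles come in two flavors: undirected
min(θ, 180°−θ) ∈ [0°, 90°] for general filament pairs (a filament has no
intrinsic polarity) and directed arccos(u₁·u₂) ∈ [0°, 180°] for anchored
filaments, whose near-to-far vector gives them one.

**Class boundary.** θ ≥ 45° is quasi-orthogonal, θ < 45° semi-parallel;
the boundary belongs to the quasi-orthogonal class. All histograms use
half-open, left-closed bins so boundary values route unambiguously
(a distance of exactly one bin width falls in the second bin). Class
fractions count segmentation units; length weighting is not applied (with
fixed-length units the two coincide up to remainder segments).

**Distances.** Point-set queries go through a KD-tree and are exact, not
approximate; unit tests and the acceptance suite verify equality with
exhaustive enumeration at 1e-9 on ≤50-filament scenes. Membrane distance is
unsigned plane distance (plane representation) or nearest-surface-point
distance (mask-derived). Organelle surface distance is
max(‖p − c‖ − r, 0) for spheres and a Euclidean distance transform of the
mask complement at native voxel size for masks; points on or inside an
organelle get 0, never a negative value, since every reported analysis
measures approach from outside. Voxelization bounds the mask-vs-analytic
discrepancy by one voxel diagonal (verified at 1 nm and 4 nm).

**Nearest-neighbor convention.** The filament–filament statistic records
one sample per resampled point (its nearest point on any *other*
filament), not one per filament pair — so long filaments contribute
proportionally to their length. Per-pair minima can be derived from the
sample table when needed. Likewise the actin-to-nearest-MT distance is by
default the per-filament minimum over resampled points, with the per-point
sample cloud available via `per_point=True`.

## VM anchoring

Anchored: min over the two termini of VM distance ≤ 60 nm, *inclusive* —
the threshold is one actin segmentation-unit length. Neighbors: near
endpoints strictly < 120 nm apart (twice the unit). The asymmetry
(inclusive vs. strict) mirrors the respective definitions ("within" vs.
"less than"); both thresholds are configurable. When both termini are
exactly equidistant from the VM, the first point in stored order is the
near endpoint and a degeneracy flag is set, keeping the directed vector
deterministic. Each neighbor pair contributes two samples to the
angle–orientation map, one per member, so a pair straddling the 45° class
boundary informs both histograms.

Periphery height is the mean over VM surface samples of the distance to
the dorsal membrane — an estimator chosen for robustness to membrane
roughness; for two parallel planes it reduces to their separation.

## Meshwork skeleton analysis

Thresholding uses iterative intermeans (IsoData) — the classic "default"
histogram threshold — with Otsu as a pluggable alternative; thinning is
topology-preserving 2D/3D skeletonization. A *junction* is a cluster of
skeleton voxels with more than two skeleton neighbors (8-/26-
connectivity), merged by adjacency so one thick crossing counts once.
Branch length is the geodesic pixel-path length with axis/diagonal step
weights 1, √2, √3 scaled by the (possibly anisotropic) pixel size; each
branch component's length is the weight of the minimum spanning tree of
its voxel-adjacency graph, which equals the path length for clean
unit-width branches. Branches shorter than one pixel are excluded from the
total length; junctions are counted on the full skeleton (the length
filter is a length filter, not a topology edit). VM-proximal angle
analysis selects branches with any voxel within 300 nm of the VM and
reports the chord (endpoint-to-endpoint) angle to the VM plane.
Subsection crops are squares of area 0.97 µm² (side ≈ 31 px at the 31.3 nm
SIM pixel).

## Synthetic phantoms

The generator emulates the statistical structure of peripheral-tomogram
segmentations, with every output a pure function of (recipe, seed); the
seed feeds per-component child generators (bundles, free filaments, ISGs,
MTs) in fixed order, so scenes are byte-reproducible.

Defaults (one scene): a 1000 × 1000 × 260 nm slab; VM at z = 0 and dorsal
plane at 200 nm (within the observed ~190–260 nm periphery range); four
bundles of eight exactly parallel in-plane filaments at 12.5 ± 0.5 nm
lateral spacing; 200 free filaments of length 60 nm (the segmentation
unit) whose chord elevation is a two-class mixture — uniform [45°, 90°)
with probability `frac_quasi_orthogonal`, else uniform [0°, 45°) — with
uniform azimuth; near endpoints at z ∈ [2, 66] nm so roughly 90% of
filaments are anchored at the 60 nm rule; five ISG spheres with radii
100–175 nm (a typical granule scale — a modeling choice, not a measured
value) and ≥ 20 nm pairwise clearance; four 400 nm MTs tilted ≤ 10°.

Two presets encode the contrasted conditions: *basal*
(`frac_quasi_orthogonal = 0.03`, ISGs placed without a standoff from
actin) and *stimulated* (`0.15`, three bundles, filaments laid ≥ 60 nm
from every ISG surface). Because all free filaments point away from the VM
(+z), raising the quasi-orthogonal fraction automatically produces the
co-directed "blooming" anchored geometry, while the basal preset's
in-plane filaments cross at large mutual angles ("netlike") — no extra
dials. ISGs are placed first and the filament standoff is enforced at
filament endpoints during placement; for 60 nm segments against ≥ 100 nm
spheres the mid-segment sag below the nominal standoff is ≤ ~3 nm.

What the phantoms do *not* model: filament curvature and persistence
length, the missing wedge and other tomographic anisotropies, membrane
roughness, polydisperse filament lengths, and spatial correlation between
filaments and organelles beyond the clearance rule. Passing tests
therefore establish that the estimators recover known geometry and
statistics from idealized scenes — not that biological effect sizes are
reproduced from real tomograms.

Image rendering rasterizes 2D segments as unit-intensity strokes (the
ground-truth skeleton), applies a Gaussian PSF, and adds seeded Gaussian
or Poisson noise. Mask rendering voxelizes spheres and membrane slabs by a
voxel-center-inside test; a sphere's voxel count matches its volume to ~2%
at 1 nm voxels.

## Statistics

The statistical unit is the scene, never the pooled segment — pooling
resampled points across tomograms would pseudo-replicate. Summaries are
mean ± SEM (sd/√n, n = scenes). Multi-group comparisons: one-way ANOVA +
Tukey HSD (scipy implementations, cross-checked against an independent
reference implementation to 1e-9 in the tests). Two-group comparisons: a
two-sided variance-ratio F-test gates the t variant — Student's pooled t
when equality of variances is retained at α = 0.05, Welch's t otherwise;
the gating is a documented convention of this package. Degenerate inputs
(all values identical) raise instead of returning a meaningless p; zero
within-variance with distinct means legitimately yields F = ∞.

2D density maps use a product-Gaussian KDE with per-axis Scott's-rule
bandwidths h_i = σ̂_i n^(−1/6) (overridable), on a grid spanning the data
range padded by two bandwidths, renormalized to unit integral over the
grid. For boundary-concentrated data (axial angles near 0°) the padded
grid can place the argmax marginally outside the physical support, so
`DensityMap.mode` accepts bounds to restrict the search to the variable's
domain. All-identical samples have no data-driven bandwidth and require an
explicit one.

## Problem sizes and tolerances

Test and acceptance runs use scenes of ~230 filaments (≈3,800 resampled
pair samples), 2,000-filament draws for fraction recovery, 8 scenes per
condition for the discrimination analysis, 1,000 replicates for the ANOVA
null calibration, 64 × 64 px rendered phantoms, and 200³ voxel volumes for
mask-distance validation — sizes at which every brute-force oracle is
still exact and affordable. Key tolerances: arc-length conservation 1e-9
nm; accelerated-vs-exhaustive distance equality 1e-9 nm; cylinder volume
closed form 1e-12 (relative); mask-vs-analytic distance ≤ one voxel
diagonal; phantom skeleton length 5%, junction count exact; fraction
recovery ±2 percentage points at n = 2000; ANOVA type-I error within
[0.035, 0.065] at α = 0.05.

## Known limitations

- Membrane models are planes or raw surface point sets; no curved-surface
  fitting beyond the least-squares plane.
- The per-point nearest-neighbor statistic is sensitive to the resampling
  grid at sub-interval scales (reversal of a polyline whose arc length is
  not a multiple of the interval shifts sample positions by < h).
- Junction clustering merges by 8-/26-adjacency only; junctions closer
  than one voxel apart merge into one cluster by construction.
- The SpatialGraph reader covers the ASCII VERTEX/EDGE/POINT dialect only,
  not binary variants.
- The skeleton branch-length MST equals the true geodesic only for
  unit-width branches; pathological non-thin inputs (not produced by the
  bundled skeletonizer) would be underestimated.
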