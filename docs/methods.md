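# Methods

This note records the models, conventions and numerical choices behind
`tractkit`, in the order the pipeline applies them. Nothing here asserts an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Coordinate and data conventions

Volumes are 3D/4D arrays with a 4×4 voxel-index→world-mm affine (RAS world
frame, 0-based indices, voxel centre at the integer index). All stages
assume co-registered inputs on a shared grid; registration itself is out of
scope. Gradient tables follow the FSL `bval`/`bvec` dialect (a single-file
N×4 b-table reader is provided as a convenience); directions on weighted
volumes are normalised to unit length on read, and a volume counts as b0
when b < 50 s/mm² (a common convention; the threshold is configurable).
Resampling to a working resolution (default 2 mm isotropic, overridable or
skippable) uses trilinear interpolation for continuous data and nearest
neighbour for labels and masks, preserving the world-space extent to within
one voxel.

## Gradient-frame (flip/swap) scoring

Converter bugs can permute or sign-flip gradient components relative to the
image axes. The 48 candidate corrections form the symmetry group of the
coordinate frame; `score_axis_transforms` fits the tensor under each and
scores the principal-direction field by *tract-continuation coherence*:
from every sufficiently anisotropic voxel (FA ≥ 0.15), walk ±1, ±2 and ±3
voxels along e₁ and average |e₁(v)·e₁(w)| with the voxel landed in, a walk
leaving the anisotropic set contributing 0. Real fibre fields continue
along their own orientation, so the correct frame maximises the score.

Two facts shaped this choice. First, pairwise neighbour coherence of e₁ is
*invariant* under frame errors — fitting with a transformed design returns
D′ = F·D·F, so e₁′ = F·e₁ and every pairwise |dot| is unchanged — hence a
spatial-continuation score is required, not merely preferred. Second, some
errors are physically undetectable: a single-axis flip leaves the signal of
an axis-aligned tensor unchanged (only off-diagonal tensor elements see
signs), and the all-axes flip leaves *every* diffusion signal unchanged.
Scoring therefore recovers the correction only up to the antipodal twin,
and only on obliquely oriented anatomy; ties resolve deterministically by
enumeration order (identity first). Several strides are averaged because a
single rounded stride aliases directions that differ in a weak component.

## Synthetic phantoms

Phantoms define the study conditions for every downstream test. Bundles
are tubes of radius r around polyline centrelines; a voxel belongs to a
bundle iff its centre lies within r of the centreline (no partial volume,
keeping ground truth exact). In-bundle signal follows the axially symmetric
single-tensor model S = S₀·exp(−b·gᵀDg) with D aligned to the local
tangent; voxels inside several bundles mix compartments with equal weight;
background is isotropic. Rician noise, when requested, is the magnitude of
a complex Gaussian perturbation (two N(0,σ) draws), from one seeded RNG
stream. Defaults: 20³ voxels at 2 mm, λ∥ = 1.7×10⁻³, λ⊥ = 0.3×10⁻³ mm²/s
(typical white matter), background diffusivity 0.7×10⁻³ mm²/s, S₀ = 1000,
tube radius 4 mm, end caps spanning 1.5 voxels of arc length at each end,
acquisition 1 b0 + 30 Fibonacci-sphere directions at b = 1000 s/mm².

`make_odf_field` returns the phantom's ground-truth orientation profile as
a sum of Gaussian diffusion ODFs, ψ_c(u) ∝ (uᵀD_c⁻¹u)^(−3/2) per
compartment. The sharper lobe model is necessary for crossings: a sum of
quadratic forms is itself a quadratic form, so uᵀDu profiles cannot carry
two lobes. The quadratic form is retained in `tensor_to_odf`, which only
bridges single-fibre tensor data onto the ODF substrate.

What the phantoms do *not* emulate: partial-volume fractions, eddy-current
or EPI distortion, motion, spatially varying noise, fanning or kissing
fibre configurations, and real cortical folding. Passing phantom tests
therefore demonstrates correctness of the algorithms under their own model
assumptions, not clinical performance.

## Reconstruction

The tensor is fitted per voxel by unweighted linear least squares on
ln(S/S₀) (S₀ = mean of b0 volumes); voxels with any non-positive signal are
marked invalid instead of fitted. The scheme must provide ≥ 6 weighted
directions of full design rank. On noiseless synthetic signal the fit
inverts the forward model to ~10⁻¹⁷ mm²/s (floating-point level), which the
acceptance script measures over 1000 random SPD tensors.

Scalar definitions: ADC is the eigenvalue mean; FA the usual normalised
eigenvalue dispersion, defined as 0 for the zero tensor. GFA uses
sqrt(n·Σ(ψᵢ−ψ̄)² / ((n−1)·Σψᵢ²)), which is 0 for a constant ODF and exactly
1 for a one-sample delta; skewness and kurtosis are the standardised 3rd
and 4th central moments of the amplitude sample, kurtosis reported as
excess, and both defined as 0 in the degenerate constant case. P₀ is the
mean normalised signal over the weighted q-space samples, monotone
decreasing in diffusivity under the single-tensor model.

ODFs are sampled on a frequency-6 geodesic icosahedron (10·6²+2 = 362
vertices), which is antipodally symmetric by construction; the neighbour
graph connects samples within 1.6× the median nearest-neighbour angle
(~17°). A sample is a maximum iff it reaches `rel_threshold` (default 0.1)
of the voxel peak and strictly exceeds all neighbours, with exact-tie
plateaus broken deterministically by lowest sample index — exact ties are
measure-zero on real data but routine in noiseless synthetic fields.
Maxima are kept greedily by descending amplitude subject to a 25° minimum
separation, at most 3 per voxel, and each retained direction is refined by
a least-squares quadratic fit on the gnomonic tangent-plane projection of
its two-ring neighbourhood (exact for quadratic-form ODFs; reduces the
~½-sample-step quantisation to well under a degree; falls back to the raw
sample on degenerate fits). `refine=False` restores the raw samples, which
is what the brute-force oracle in the tests enumerates.

## Parcellation

Surface meshes and voxel lattices both reduce to a region graph: atomic
units with an area (cm²), an anatomical region id, and spatial adjacency.
Cortical regions are split into k = max(1, round(area/target)) connected
parcels (target 1.5 cm² by default) by a two-phase heuristic: (1) k
farthest-point seeds by hop distance, then area-balanced greedy accretion
(always grow the currently smallest parcel); (2) boundary refinement that
moves units between adjacent parcels to reduce area variance, additionally
accepting variance-neutral moves from a larger into a smaller parcel so
that area can migrate along chains of parcels (a two-parcel move cannot
change the area multiset). A few seeded restarts keep the best result;
everything is deterministic for a fixed seed. Subcortical structures and
the brainstem are never split. Coarser scales merge adjacent sibling
parcels within each region on a geometric count schedule down to the
anatomical regions at scale 1; nesting, connectivity and unit conservation
are asserted as invariants.

The packaged five-scale whole-brain hierarchy reproduces the standard label
totals 1015/463/234/129/83 (1000/448/219/114/68 cortical parcels plus 14
deep-grey nuclei and the brainstem, never subdivided). Because the true
per-subject tables derive from surface geometry this package does not
process, the shipped hierarchy is synthetic: parcels are apportioned to
plausible per-region surface-area weights by largest-remainder rounding
with per-scale exact totals and nested caps, grouped contiguously. It
carries the structure of the convention, not any subject's anatomy. How
deep-grey nuclei participate at intermediate scales is not standardised;
they are treated as never-split at every scale.

## Tractography

Seeds: per mask voxel and per ODF maximum, `seeds_per_voxel` points
(default 32) uniform in the voxel cube, from a seeded RNG. Propagation is
bidirectional from each seed with a fixed step (default 0.5× the smallest
voxel edge): the direction set of the *nearest voxel* is consulted (no
interpolation of directions — the substrate is discrete maxima), the
candidate with the largest |dot| to the incoming direction is chosen, its
sign is fixed to continue forward, and the track halts when the next point
leaves the mask, the turn exceeds the angle threshold (default 60°), no
direction is available, or `max_steps` is reached. Halves are joined at the
seed; tracks shorter than 3 points are discarded; length filtering
(defaults 10–300 mm) and least-squares cubic B-spline smoothing (control
points every given arc-length spacing; straight lines are fixed points;
too-short streamlines pass through) are separate, optional steps.
Tractograms serialise to TrackVis TRK via nibabel with points in world mm.

Known limitation, quantified by the acceptance script: on the quarter-circle
phantom (20 mm radius of curvature, 4 mm tube, 2 mm voxels) about 90% of
retained streamlines connect the end caps. The shortfall is geometric:
with a tube only two voxels in radius, roughly a third of the cross-section
lies within half a voxel of the wall, and trajectories riding the wall
terminate on staircase notches of the voxelised mask. The effect saturates
with step size (0.25–1 mm changes the rate by ~1 point) and is a property
of the piecewise-constant direction substrate, not of the integrator; on
the straight bundle every retained streamline connects the caps.

## Connectome construction

Endpoints take the label of their containing voxel; unlabelled endpoints
search outward along the terminal direction in quarter-voxel steps up to
2 mm, nearest distance first, ties to the lowest label id. Streamlines
with an unresolved endpoint are dropped; self-connections are excluded by
default (configurable). Edge weights: fibre count; mean streamline length;
per scalar map, the mean over contributing streamlines of the nearest-voxel
along-tract average; and connection density 2/(Sᵢ+Sⱼ)·Σ 1/l(f), where the
interface surface Sᵢ counts label-i voxels face-adjacent to the
white-matter mask (voxel-face units). Diffusion carries no directionality,
so all matrices are symmetric by construction, and Σ of the upper triangle
of the fibre count equals the number of assigned streamlines. Coarser
scales relabel the *endpoints* through the parent maps and re-aggregate
fibre-wise — mean weights are recomputed from streamlines, never averaged
from the finer matrix — with fibres collapsing onto the diagonal excluded
under the default self-connection policy. A fibre can by construction link
exactly two regions (endpoints only; intermediate regions it traverses do
not count).

Display note: "logarithmic scale" fibre-count views are an export transform
(log10(1+count), emitted alongside the raw count in graph exports), never
the stored weight.

## Pipeline and exports

`run_pipeline` executes phantom → recon → track → connectome → export from
one TOML config into `<root>/<project>/<subject>/<timepoint>/<stage>/`,
validating each stage's declared inputs before it runs and declared outputs
after (pre-flight vs contract-violation errors, CLI exit codes 1 vs 2); a
`parameters.json` in each stage directory makes single-stage re-runs
reproducible, and a manifest plus log record the run. Graphs export to
GraphML/GML (networkx) and DOT (minimal built-in writer); matrices to CSV
with node labels as headers. With fixed seeds two runs produce
byte-identical matrices — asserted by test and acceptance script. No
built-in parallelism: one process per subject, batching is the caller's
concern.

## Problem sizes used in the checks

Tests and the acceptance script use 20³-voxel phantoms (≈ 260-voxel
bundles), 1–32 seeds per voxel per maximum, 30-direction schemes, 1000
random tensors for recovery, and toy region graphs of ≤ 60 units — sizes
chosen so the whole suite runs in well under a minute apiece while every
oracle stays exact.
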