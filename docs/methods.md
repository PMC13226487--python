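# Methods

This note documents the models, conventions and numerical choices behind
vesselbench, and what the synthetic phantoms do and do not establish about
real imaging data.

## Coordinate and unit conventions

Volumes are arrays indexed `(z, y, x)`. Skeleton node positions are
continuous 0-based voxel-index coordinates in `(x, y, z)` order (sub-voxel
positions allowed); radii are physical micrometres. The voxel size —
canonically 1 × 1 × 2 μm for the targeted imaging modality — converts
between the two spaces. Distances used by the *matching metrics* are
Euclidean in voxel-index space (thresholds of 3 and 5 are voxel counts);
distances used by *rendering* and *branch angles* are physical. SWC files
store coordinates/radii as in memory; floats are printed with shortest
exact decimals so write → read round trips are bit-faithful. Anastomoses,
which an SWC parent forest cannot hold, ride along as `#FUSION i j`
comment lines and re-enter the graph as ordinary edges.

## Phantom generator

`generate_skeleton` grows each vessel tree by stepwise tip extension: one
voxel-index unit per step, direction perturbed by a Gaussian of scale
`tortuosity`, bifurcation with probability `branch_prob` per step (both
children of a branching node are created at the moment the event fires, so
the number of bifurcations in an unobstructed tree is exactly
Binomial(steps, p)). Child radii are 0.6–0.95 of the parent, floored at
`r_min`; tips die at the radius-aware volume boundary. `steps_per_tree` is
a total budget shared by all branches of one tree.

`render_volume` marks a voxel foreground iff its anisotropy-aware physical
distance to the centerline is at most the local radius (the polyline is
densely sampled at 0.5-voxel spacing, so the discretization error of the
point-based distance is ≤ 0.25 voxel). Vessels wider than
`hollow_radius_threshold` are rendered hollow in the image — voxels closer
than `lumen_fraction × radius` to the axis stay at background level —
while the binary ground-truth mask stays solid; this reproduces the
wall-only staining of large vessels. The image is
`background_level + foreground_intensity·indicator + N(0, noise_sd)`,
rounded and clipped to the 8-bit range.

Defaults emulate the targeted data: radii 2 μm (capillaries) to 20 μm
(trunk vessels), hollow threshold 6 μm, 8-bit intensities with weak-signal
cases down to a foreground mean of 10, additive Gaussian noise. The five
named fixtures fix these conditions deterministically: `straight_tube`
(r = 3 μm, noise-free), `y_junction` (symmetric 90° fork), `hollow_trunk`
(r = 10 μm, lumen radius 5 μm), `capillary_mesh` (r = 2 μm, low contrast,
one anastomosis), `weak_signal` (foreground mean 10, σ = 2).

What the phantoms do *not* emulate: optics (no PSF, so vessel edges are
one-voxel sharp), Poisson/photon statistics (noise is additive Gaussian),
staining inhomogeneity along a vessel, and whole-brain scale. Passing the
fixture suite therefore demonstrates correctness of the geometry, topology
and metric computations under controlled conditions — not segmentation
robustness on real microscopy data.

## Supervision maps and regions

The rendering kernel width is tied to the region thresholds: with
σ_p = r_p / √(2 ln(1/0.404)) the map of an isolated centerline point
crosses 0.404 exactly at physical distance r_p, so S₂ (map > 0.404) is the
vessel interior and S₁ (map > 0.012 ≈ value at 2.2 r_p) the surrounding
transition halo. Kernels compose by voxelwise maximum (a sum would exceed
1 where kernels overlap) and are truncated at 3σ, where the Gaussian is
≈ 0.011 < 0.012, so truncation never changes a region mask. Zero-radius
points contribute a single-voxel impulse. Thresholds are strict
inequalities; with t₂ > t₁, S₂ ⊆ S₁ by construction. The four loss terms
are unweighted by default (optional weights provided); terms over an empty
region are defined as 0.

Skeleton smoothing holds endpoints and branch points bit-identical and
replaces edge interiors by a centered moving average (default window 5)
re-parameterized through an interpolating B-spline (default degree 3);
edges shorter than the window pass through unchanged. Resampling is linear
in arc length (voxel-index space) at ≤ 1-voxel spacing with both endpoints
preserved.

## Ray geometry

The camera model is orthographic by default (a perspective pinhole is
available); the viewing problem as posed only needs back-projection of a
screen coordinate to a ray. Closest points between rays are computed on
half-lines (t ≥ 0, rays emanate from viewpoints): the unconstrained
common-perpendicular solution is used when feasible, otherwise both
boundary candidates (t = 0 and u = 0, each with the other parameter's
clamped 1-D minimizer) are evaluated and the closer pair kept — exact for
this convex problem. Parallel rays (|d₁·d₂| within 1e−12 of 1) are
flagged and anchored at the first ray's origin.

Profiles are sampled trilinearly at unit voxel steps; out-of-bounds
samples are zero and flagged. The interactive interval pick of the
annotation workflow is replaced by a deterministic surrogate: the maximal
run around the profile peak with value ≥ (max+min)/2, extended on each
side by the linearly interpolated sub-sample half-level crossing. On a
noise-free binary tube this overestimates the diameter by up to one
sample (the wall voxel itself is at full intensity), which bounds the
radius error at 0.5 μm for isotropic axes — within the 0.5 μm / 15%
recovery tolerance asserted by the tests.

## Lumen filling

The published pipeline order is kept exactly: half-resolution nearest
downsample → min-max normalization → Gaussian smoothing (σ = 2 truncated
to a 3×3×3 kernel, reading the stated "3 × 3 kernel" as its 3D
counterpart) → Otsu binarization (256 bins) → morphological closing
(ball, radius 2) → connected-background hole filling → nearest upsample →
OR with the binarized input. The hole-filling step is the minimal addition
needed for the stated purpose: closing at any practical radius cannot seal
a lumen that runs the length of the vessel, whereas background regions not
connected to the volume border are unambiguously interior. The OR merge
makes the output a strict superset of the input foreground. Constant
inputs (Otsu undefined) pass through with a warning. One consequence of
operating at half resolution is a 1–2 voxel dilation band around thin
structures; the tests bound it geometrically (output within a 2-voxel
shell) rather than by a volume percentage, which would be meaningless for
high-surface/volume objects.

## Tracers

**Voxel scooping.** Per 26-connected component, the tracer seeds at the
Euclidean-distance-transform maximum and repeatedly advances the shell of
unvisited foreground adjacent to the active fronts. Each shell is
partitioned into connected clusters; each cluster becomes a node at its
centroid (snapped to the nearest member voxel if the centroid of a concave
cluster falls outside the mask) with radius = EDT there, linked to the
front it touches most. A cluster touching several fronts is a front merge:
the largest contact is the parent, the rest become fusion links — this is
how loops (anastomoses) are recorded. Every foreground voxel is visited
exactly once, so skeleton components equal mask components.

**Thinning.** Topology-preserving 3D thinning produces a one-voxel
skeleton; voxels are classified by 26-neighbour count (1 endpoint, ≥ 3
junction), junction clusters collapse to centroid nodes, degree-2 runs
become edges, and surviving cycles are closed with fusion links. Radii
come from the EDT of the input mask, not of the thinned set.

**Pruning.** Both tracers emit short terminal twigs on thick vessels (a
node per shell/voxel of a bulbous surface). A terminal edge hanging off a
branch point is removed when its node count is below `min_len` (default 5)
or its physical length is below `radius_factor` (default 1.5) times the
radius at the branch point — a twig shorter than the vessel is wide is a
surface artefact. Unbranched chains are never pruned. The pass iterates to
a fixed point and merges surviving degree-2 junctions.

## Metrics

Matching is threshold-on-nearest-neighbour with a strict `<` (flags switch
to `≤`, to squared distances, or to one-to-one Hungarian assignment for
control experiments). Nearest-neighbour matching lets duplicated
predictions inflate precision; this is intentional fidelity to the
evaluation protocol, and the Hungarian mode quantifies the effect.
Skeleton-level evaluation resamples both skeletons at 1-voxel arc steps
before matching (thre = 3); branch points match at thre = 5.

Branch angles take each incident edge's direction as the unit vector (in
physical coordinates) from the branch node to the 5th resampled point
(~5 μm) along the edge, or the edge end if shorter; angles are emitted per
unordered edge pair, labelled child–child or parent–child since the
literature is split on which to report. Vessel density resamples the
skeleton at 1-voxel steps and assigns each inter-sample segment's physical
length to the 64³-voxel sub-block containing its midpoint (midpoint
assignment makes the length-conservation identity exact); boundary cells
use their exact partial volumes. SNR divides the mean skeleton-point
intensity by the standard deviation of the voxels outside the mask dilated
3 times (a guard band against partial-volume voxels). The review-region
proposer slides a window (default 32³, stride 16) and flags windows with
≥ 2 endpoints or ≥ 1 branch point, merging overlapping flags into
bounding boxes.

## Problem sizes

Fixtures are 64³–96·48·40 voxel volumes with 50–160 ground-truth nodes;
property suites use random 8³ volumes (loss), ≤ 200-point sets (matching)
and ≤ 20 random ray pairs / phantom skeletons per check. These sizes make
the full test suite and the acceptance script run in well under a minute
each while still exercising every code path, and were chosen as the
smallest volumes on which the fixtures' geometry (a 10 μm hollow trunk, a
90° fork, an anastomotic loop) fits with comfortable margins.

## Known limitations

- The scooping tracer's shells are synchronized per component, so node
  spacing follows the BFS front (~1 voxel); radii are EDT values, which
  underestimate at bifurcations.
- Fusion-link detection reports front merges; it cannot distinguish a true
  anastomosis from two vessels fused by a segmentation adhesion.
- The FWHM interval surrogate assumes a single dominant vessel across the
  profile; crossing vessels within the sampling extent bias it toward the
  brighter structure.
- `fill_hollow` at half resolution thickens structures thinner than ~2
  voxels; for capillary-only volumes it is better skipped (the spur pruner
  and the OR merge keep it safe, but not free).
- NRRD support covers the raw-encoded subset with diagonal space
  directions used here, not the full format.
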