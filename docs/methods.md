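# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `waveseg`.

## PIV engine

Displacements between consecutive frames are estimated per interrogation
window by minimizing the normalized squared-difference score

    NSQ(d) = Σ_x (a(x) − b(x+d))² / sqrt(Σ_x a(x)² · Σ_x b(x+d)²)

over all integer displacements `d` with |d| ≤ `search_margin` per axis.
Normalizing by the local energies makes the score robust to intensity
changes between frames; the exact constant factor of the normalization
does not affect the argmin. The window sums over shifted positions are
computed with frequency-domain products (`scipy.signal.fftconvolve`);
windows near the image border are clipped, never wrapped, so border nodes
have an asymmetric (possibly insufficient) search range — the shift-recovery
guarantees therefore apply to interior nodes. Placements with zero signal
energy get an infinite score; a node whose own window is all zero, or with
no feasible placement, is flagged invalid and carries a zero vector.

Sub-pixel refinement fits a parabola through the three scores around the
integer minimum independently per axis and is disabled when the minimum
touches the search border or the curvature is non-positive. On synthetic
particle images (Gaussian spots, ψ ≈ 2 px) interior-node errors are below
0.2 px.

Defaults: interrogation 32 px/axis (2D) or 24 vx/axis (3D), search margin
10, grid step = half the interrogation size (50 % overlap), minimum mask
overlap 0.5. These are standard PIV practice for nuclei-scale texture at
micrometer pixel pitch; none of them is critical to the segmentation
stage, which consumes whatever grid the PIV produces. A static mask is
used for all time steps so that every field slice shares one coordinate
set. No multi-pass or window-deformation scheme is implemented; optional
vector post-smoothing is deliberately left out of the contract (the
segmentation tolerates raw fields).

## Wave segmentation

Each grid position is processed independently. Writing v̂ for the unit
vector of v (zero vectors stay zero) and r for the unit reference
direction of the V phase:

1. **Direction similarity.** ρ(t) is the mean of v̂_{t′} · r over the
   window [t−N, t+N], clipped at the series ends (the divisor is the
   actual window length). Zero vectors contribute a zero summand rather
   than being skipped, so quiescent windows pull ρ toward 0 instead of
   being undefined. The windowed mean is *not* re-normalized before the
   dot product; ρ therefore also rewards low intra-window spread.
2. **Candidate pairs.** Strict local maxima of ρ are paired with the next
   local minimum. Plateaus resolve to their first frame; series endpoints
   are never extrema; a leading minimum and a trailing unpaired maximum
   are dropped.
3. **Angle gates.** A pair (t_max, t_min) survives iff
   v̂_{t_max} · r > cos θ_r, v̂_{t_max} · v̂_{t_min} < cos θ_VD, and —
   when the dorsal half-plane gate is on — v̂_{t_min} · d > 0 for the
   configured unit dorsal axis d. The raw vector at t_max (not the window
   average) is used as the V representative: at a ρ maximum it sits inside
   a low-variance window and is the least smoothed representative
   available. Angle thresholds are stated in degrees and compared through
   cosines; all angle comparisons are strict.
4. **Phase expansion.** V grows outward from t_max (D from t_min, with
   θ_D in place of θ_V): unvisited frames are tested nearest-to-farthest,
   alternating sides (at equal distance the later frame is tested first —
   an arbitrary but fixed tie-break), and frame t joins iff
   v̂_t · Ŝ_avg > cos θ_phase and ‖v_t‖ > M_min, where S_avg is the mean
   of the raw vectors currently in the set. A side closes at its first
   failing frame. V may not cross t_min; D starts after the final V frame
   (this is slightly stronger than "D may not cross t_max" and guarantees
   disjoint phases); neither may cross frames claimed by a previously
   accepted wave at the same position.
5. **Interface.** If a gap of g frames separates V and D, the wave is
   rejected for g > max_gap (default 2). Otherwise the gap is split so
   each frame joins the phase whose unit average direction it matches
   best; contiguity is enforced by choosing the split point with the
   largest summed normalized dot products, which reduces to the per-frame
   rule in the common single-gap-frame case. Exact ties go to V.
6. **Acceptance.** The wave is kept iff mean ‖v_t‖ over V ≥ M_avg and
   Σ_{t∈V∪D} ‖v_t‖ ≥ M_total. Magnitude filters use ≥ (a wave exactly at
   threshold passes); the expansion speed gate uses strict > as stated in
   its rule.

Candidate pairs are processed in temporal order; accepted waves claim
their frames and later candidates whose t_max or t_min is already claimed
are skipped. The implementation is checked against an independent
plain-loop reference implementation of the same written rules on
thousands of random short series.

**Window half-width N** defaults to 2 frames (a 5-frame window): the
smallest window that suppresses single-frame direction noise while
resolving waves whose phases last only a few frames at ~3-min sampling.
It is exposed in the configuration. The count of second-phase vectors is
not a separate parameter: phases grow adaptively, so no fixed M is used.

**Reference geometry.** Reference vectors are per-position
(`ReferenceField`); a constant vector is broadcast for lateral
projections and 3D volumes, and cylinder projections use two mirrored
vectors split at a configurable column, with polar rows cropped before
analysis. Anatomical components (x anteroposterior, y dorsal-up) map to
array components as (−ry, rx) in 2D and (rz, −ry, rx) in 3D; the dorsal
axis "up" is (−1, 0) / (0, −1, 0). Packaged presets (`lateral`,
`volume`, `cylinder`) carry the thresholds and reference directions for
the three data representations; the dorsal half-plane gate defaults to on
for lateral/volume and off for cylinder maps, where only θ_VD constrains
the D direction.

## Spatial post-processing

The temporal segmentation knows nothing about space, so label maps are
cleaned per frame and per phase: binary opening with a square/cube
structuring element of side 2·radius + 1 (this preserves solid blocks
exactly, corners included, while removing segmentations thinner than the
element), removal of face-connected components smaller than `min_size`
cells (components of exactly `min_size` are kept), and removal of
components whose centroid (rounded mean member coordinate) falls inside a
user-supplied exclusion region, e.g. around the head of the embryo. All
three operations are idempotent and only ever delete labels. Defaults
(radius 1, min_size 50 grid cells in 2D) suit PIV grids with ~16 px node
spacing; both are exposed. Post-processing is per frame, not on the
space-time volume.

## Cartography

Cylinder maps distort lengths: meridian (pole-to-pole) distances are
rendered shortened toward the poles and circumferential distances
elongated, while the equator is distortion-free. `correct_distortion`
multiplies each vector's longitudinal component (axis 0) and latitudinal
component (axis 1) by the true-length/map-length factor of the containing
10 × 10 px tile (nearest-tile lookup, matching the sampling granularity
of the factor grids). Angles are not corrected — angular distortion is
significant only very close to the poles, which are cropped. The
operation is exactly inverted by the reciprocal grid.

The analytic phantom (`make_cylinder_distortion`) models a cylinder with
spherical caps whose map rows sample the axial coordinate z = R·sin φ at
pixel pitch: the longitudinal factor is 1/cos φ (growing toward the
pole) and the latitudinal factor cos φ (shrinking), both exactly 1 on the
cylindrical body. The phantom is geometrically self-consistent when the
cap spans R rows; the test suite verifies corrected one-tile steps
against numerically evaluated geodesic arcs to within 5 %.

`extract_surface_mask` reconstructs a closed shell around a bright
surface: global threshold, morphological closing at scale `alpha` (which
bridges holes up to roughly that size — a behavioral stand-in for an
alpha-shape reconstruction of a sampled point cloud), interior filling to
discard inner structures, and a Euclidean-distance shell of the boundary
layer plus `shell_in` (default 6) layers inward and `shell_out` (default
3) outward. The closed-shell property (an exterior flood fill cannot
reach the interior) is asserted on phantoms. Foreground segmentation is
a plain global threshold; smarter segmentation can be substituted
upstream. Masks from several time points are combined by voxelwise union
into one static mask.

## Descriptors

The divergence map correlates the field with an expanding template — unit
vectors pointing away from the kernel center, zero at the center:
D(p, t) = Σ_q k(q) · v_{p+q,t}. The template is centrally antisymmetric,
so correlation versus convolution changes only the sign convention; the
sign is fixed as positive = expansion, negative = constriction. The
template size (default 17 × 17 nodes) sets the spatial scale. Borders use
clipped kernels (partial sums), attenuating rather than inflating border
values; consequently a uniform field gives exactly zero only at interior
nodes. Divergence extrema are reported per frame after strict
non-maximum suppression within one kernel radius (flat fields report
nothing); extrema are not linked across frames.

Kymographs are summed-intensity projections along one spatial axis,
indexed (retained axis, time); label maps yield one kymograph per phase,
and a mean reduction is available for density views.

## Synthetic scenes

The generator injects idealized two-phase waves: within a disk (or
arbitrary mask), `v_duration` frames at `v_speed` along the V direction
followed immediately by `d_duration` frames along the D direction, with
an optional linear onset ramp, plus optional constant background flow and
isotropic Gaussian component noise. Truth labels mark exactly the
injected cells. Scenes are bit-reproducible per seed.

The demo scene (`mini_scene`) uses a 100-frame, 32 × 48-node recording
with five pre-rupture waves (every 14 frames from frame 8; V 4 frames at
2.0 units/frame, D 6 frames at 1.5; disk radius 9 nodes, centers drifting
along the axis) and one post-rupture wave at frame 86 whose D direction
is rotated from the full 180° reversal to straight dorsal (135° from V);
the rupture frame is 80 and the default vector noise is σ = 0.2. The V
phase is deliberately shorter than the D phase (abrupt contraction,
extended relaxation). Particle images are Gaussian spots (bilinear splat
plus Gaussian PSF) advected by uniform per-frame displacements with
optional sqrt-intensity ("photon-like") noise.

What the generator does *not* emulate: spatially curved flow within a
wave, PIV estimation noise with spatial correlation, intensity artifacts
(bleaching, drift, occlusion), deforming or moving wave regions, and
rupture mechanics. Passing the recovery tests therefore demonstrates the
correctness of the segmentation logic under the stated noise model, not
performance on real microscopy data; the PIV stage is validated
separately on particle images, and the two are composed in the
end-to-end CLI test.

## Reported quantities

`scripts/acceptance.py` recomputes, from freshly generated inputs under a
given seed: the canonical-series segmentation; demo-scene label recovery
(%), false-positive rate (%), pre-/post-rupture wave counts and median
phase durations; worst-case integer and sub-pixel PIV shift errors (px);
the maximum deviation between the divergence map and a double-loop
evaluation; and the distortion equator factors and round-trip error.
Problem sizes (128² images, a 13 × 15-node grid for the brute-force
divergence, the 32 × 48 × 100 demo scene) are chosen so each check
isolates one mechanism at desk scale.

## Known limitations

- Single-pass PIV only; strong shear within an interrogation window
  biases vectors.
- The segmentation detects exactly two phases per wave and assumes the V
  direction is known a priori per position; it does not infer reference
  directions from data.
- Wave-event counting in the report is by temporal occupancy of the label
  map, which merges waves that overlap in time at different positions.
- Cylinder-map generation itself (surface parameterization, atlas
  stitching) is out of scope; maps and distortion grids are inputs.
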