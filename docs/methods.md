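# Methods

`mastreg` quantifies intravital confocal time-lapse movies of mouse ear
skin in which dermal mast cells carry a red (tdTomato) reporter,
regulatory T cells (Tregs) or Langerhans cells a green (eGFP) reporter,
and a third blue channel records tissue autofluorescence.  Every stage
is validated against a synthetic movie generator that emits exact ground
truth, so this note covers both the measurement procedures and the
generative model they are scored against.

## Image model and calibration

A recording is a 5-axis intensity volume indexed `(t, z, c, y, x)` with
physical calibration: lateral pixel size (default 0.72 µm/px), axial
step (default 1.5 µm) and frame interval.  Two duty cycles are used, as
in the acquisitions the pipeline is modeled on: ~4 min between time
points for contact monitoring, and 40 s (0.667 min) for Treg velocity,
because a 5 µm/min cell moves ~20 µm per 4-min frame — comparable to the
inter-cell spacing — and identity assignment becomes ambiguous at that
stride.

The default pixel size is chosen so that the 5-pixel correlation window
(below) spans 3.6 µm.  Wide-field stage-mosaic acquisitions
(450 µm / 1024 px ≈ 0.44 µm/px) are supported by passing the calibration
explicitly; it is never inferred beyond what the file metadata states.

Coordinates are 0-based `(y, x)` with y increasing downward; positions
refer to pixel centers, so `position_um = index × pixel_size_um`.

## Projection and temporal color coding

All analyses operate on maximum Z-projections: per-pixel maxima over the
axial dimension collapse the 20–45 µm imaged slab onto one plane so that
populations in different focal layers (dermal mast cells, infiltrating
Tregs, epidermal Langerhans cells) appear in one micrograph.

Motility is visualized by triad encoding: output frame *k* overlays
frames *k−1/k/k+1* in blue/green/red, normalized by the joint maximum of
the triad (an all-zero triad stays zero).  Static structures receive
equal contributions and appear gray/white; pixels about to be occupied
are red-dominant, vacated pixels blue-dominant.  Normalizing per triad
rather than per plane means intensity changes — not only displacement —
produce color.  The two boundary frames are dropped rather than padded:
padding would fabricate motion at the sequence ends.

## Segmentation and density

Cells are enumerated per projected frame: global Otsu threshold,
8-connected components, hole filling (mast-cell nuclei exclude the
cytoplasmic tdT marker and would otherwise split a cell), then an area
filter (defaults 20–600 µm² for mast cells, 10–200 µm² for Tregs).
Components whose fractional overlap with the Otsu foreground of the blue
channel exceeds 0.3 are discarded: hair follicles and sebaceous glands
autofluoresce in both red and blue ("yellow") and must not be counted as
cells.  A constant plane yields an empty detection list with a warning,
not an exception.

Planar density applies the counting formula exactly, with no rounding:

    density (cells/mm²) = n_cells / area_um2 × 10⁶

The characteristic spacing of a planar network of density ρ (cells/mm²)
is defined as the square-lattice spacing `1000/√ρ` µm.  Under this
definition a steady-state network of 360 cells/mm² has a spacing of
52.7 µm (≈53 µm).  The nearest-neighbor distance of an ideal Poisson
process (`0.5/√ρ` ≈ 26 µm at the same density) is a different statistic
and is not what this operation reports.

Mast-cell repopulation after conditional (diphtheria-toxin) ablation is
modeled as a piecewise-linear density curve through
(day 0, baseline), (6, 5), (11, 30), (90, 150) cells/mm², constant
thereafter: profound depletion within a week, first repopulating cells
around day 11, and slow, partial recovery to ~150 cells/mm² at three
months.

## Tracking and velocity

Detections are linked frame-to-frame by greedy globally-nearest-neighbor
matching: all (open track, detection) pairs within a gating radius
(default 3× the expected per-frame step) are matched in ascending
distance order with deterministic tie-breaks; unmatched detections open
tracks; tracks silent for more than `max_gap` frames (default 1) close.
An optimal-assignment or probabilistic tracker is deliberately out of
scope — at these cell densities and the fast duty cycle, greedy matching
is adequate and exactly reproducible.

Velocity is the mean frame-to-frame speed: total path length divided by
total linked time, a step spanning a g-frame gap contributing g × Δt.
Net displacement over total time would report near zero for a Treg
wobbling around a mast cell, which contradicts what such cells visibly
do.  Single-point tracks have no defined speed and are reported as
missing, never as zero.

For *between-arm* velocity comparisons the pipeline additionally exposes
speeds restricted to gap-free tracks (`contiguous_track_speeds`).  A
gap-bridging step measures the chord of two walk steps and biases speed
low; the frequency of such gaps scales with cell density (touching blobs
merge into one detection for a frame), so the bias is arm-dependent and
would masquerade as a velocity difference between a sparse control arm
and a dense post-challenge arm.  Gap-free selection is blind to speed
itself.  The comparison uses Welch's two-sample test at α = 0.05 and is
descriptive output, not a gate.

## Contact mapping

Contacts are detected on the projected red/green planes through a local
correlation map: with S the normalized Gaussian smoothing operator
(sd = window_px/2 = 2.5 px, truncated at 3 sd),

    μR = S(R), μG = S(G)
    cov = S(R·G) − μR·μG,  varR = S(R²) − μR²,  varG likewise
    r = cov / √(varR·varG)   where both variances exceed 1e−12

This is the Pearson coefficient of the two channels under a Gaussian
window around each pixel: positive for superimposed profiles, ≈0 for
unrelated ones, negative for juxtaposed profiles — one signal rising
exactly where the other falls, the signature of touching membranes.
The default 5 px window spans 3.6 µm at the default calibration.  The
map is exactly symmetric in its arguments and invariant to positive
affine rescaling of either channel; undefined pixels carry 0 and a
False mask bit.

The contact mask is the gated negative component: coefficient ≤ −0.2
*and* Gaussian-local mean of each channel ≥ 0.5× that channel's Otsu
threshold.  The floors keep anticorrelated dim background out of the
mask; both gates are configurable and were checked for sensitivity — on
noise-free rendered scenes, thresholds in the range −0.15…−0.25 and
floor fractions 0.35…0.5 all give the same per-episode recovery.

Each 8-connected mask region is attributed to every (mast cell, Treg)
detection pair whose masks, dilated by 2 px, both intersect the region;
regions adjacent to no such pair are dropped.  Per-frame pairs are
linked into events — per identity pair, maximal runs with gaps of at
most `max_gap` missing frames (operation default 1; the pipeline uses 2
to ride out brief mask dropouts).  Events on the same mast cell whose
Treg tracks sit within 12 µm of each other at the junction are stitched:
they describe one physical contact interrupted only by a track
re-identification.  Durations count first and last frame inclusively
((end − start + 1) × Δt — a single-frame contact at a 4 min duty cycle
lasts 4 min, not 0) and are classified as short (<10 min), intermediate
(10–50 min inclusive at both ends) or long (>50 min); the boundary
values 10 and 50 fall in the intermediate bin, since ">50" strictly
excludes 50.

## The synthetic scene generator

The generator emulates the features of the real movies that the
measurements depend on, with exact ground truth:

* **Mast cells** — sessile ellipses (20 × 8 µm, random orientation,
  intensity 1.0) with a central tdT-negative nuclear hole (0.35× the
  cell axes), placed by hard-core sampling with exactly
  N = round(density × area) cells (default 360/mm²).  Fixed-N placement
  makes density-recovery tests free of seeding variance.  The hard-core
  separation is 22 µm — just above the major axis — so two cells never
  merge into one thresholded component; the network's characteristic
  spacing at default density is 53 µm, so this barely perturbs geometry.
  Cells also avoid follicle footprints, which occupy space in real
  dermis.
* **Tregs** — Gaussian blobs (sd 3 µm) at 18/mm² baseline, ×15 in the
  anaphylaxis (PCA) arm, performing a fixed-step isotropic random walk
  (step = speed × Δt, default 5 µm/min) reflected at the field borders.
  The default speed is a generator choice of realistic magnitude, not a
  measured value.  Outside contact episodes the walk avoids a 10 µm
  buffer around every mast-cell boundary (distances measured against
  sampled boundary points, since the radial approximation can
  overestimate clearance by several µm on elongated ellipses); this
  guarantees that the scheduled episodes are the *only* contacts and the
  ground truth is unambiguous.
* **Contact episodes** — per Treg, one scheduled episode whose duration
  is drawn from the arm's model: exponential with mean 3 min in control
  arms; in PCA arms a mixture 0.6·U[10,50] + 0.25·U[50,80] +
  0.15·U[0,10] minutes.  These mixtures are generator configuration
  chosen to reproduce the qualitative post-challenge shift (modal bin
  10–50 min with a sustained >50 min class); they are not measured
  values.  During an episode the Treg sits 0.5–1.5 µm outside the
  assigned cell's boundary (along the outward normal; within the 2 µm
  adjacency tolerance) and crawls along it at its nominal speed with the
  per-frame angular excursion capped, i.e. it wobbles locally rather
  than jumping across the cell.  Each mast cell hosts at most one Treg
  at a time, with a 4-frame buffer between successive guests.
* **Follicles** — disks (40 µm, intensity 0.8) rendered in red *and*
  blue, never green.
* **Langerhans cells** (optional) — somata plus four dendrite tips per
  cell whose radial extension oscillates sinusoidally (period 10 min,
  amplitude 5 µm), purely to exercise the triad encoder; they occupy a
  z-slab distinct from the dermal populations so projection merges the
  layers.
* **Optics and noise** — everything is convolved with a Gaussian PSF
  (sd 1 px); defaults add a 0.05 background and Gaussian read noise
  (sd 0.02) on a scale where a cell body is 1.0; Poisson shot noise is
  optional.  Identical configuration and seed give bit-identical stacks
  and ground truth.

What the generator does **not** emulate: photobleaching and focus drift,
anisotropic PSFs, motion blur, cell shape change and mast-cell
degranulation morphology, Treg directional persistence or chemotaxis,
vascular structures, and segmentation-hostile clutter beyond follicles.
Passing recovery tests therefore demonstrates that the measurement
chain is correct and internally consistent — not that it is robust to
every artifact of real microscopy.

## Numerical choices

* Otsu thresholds use scikit-image defaults (256 bins); segmentation
  connectivity is 8; holes are filled before the area filter.
* The correlation map computes in float64; defined values are clipped
  to [−1, 1] (floating-point excursions are ≤1e−12); it matches a
  direct per-pixel Gaussian-weighted Pearson computation (reflect
  padding) to better than 1e−9.
* Greedy linking sorts candidates by (distance, track id, detection
  label), making the result independent of input record order.
* Welch's test comes from `scipy.stats.ttest_ind(equal_var=False)`.
* Episode durations convert to frames by `max(1, round(d/Δt))`, so a
  28 min episode at Δt = 4 min spans exactly 7 frames.

## Problem sizes

Validation runs use fields the analysis is intended for: 0.45 × 0.45 mm
enumeration fields (~73 mast cells; 0.6 × 0.6 mm — ~130 cells — for the
noisy-recovery check), 0.42 × 0.42 mm contact videos of 30 frames at
Δt = 4 min (120 min of observation, enough for a >50 min contact class
to complete), and 0.6 × 0.6 mm velocity videos of 20 frames at
Δt = 0.667 min.  Fold-change recovery uses a 1 mm² single-frame field so
the seeded 15:1 arm ratio is represented by exact counts (18 vs 270
cells).  Between-arm velocity replicates pool three control fields
(~20 tracks, matching the scale of cells a study of this design
actually measures) against one post-challenge field.

## Known limitations

* Enumeration, tracking and contact mapping are strictly 2-D (on
  projections); volumetric segmentation and 3-D contact surfaces are
  out of scope.
* The greedy linker switches identities when unrelated cells pass
  within a step length of each other at the slow duty cycle; contact
  linking compensates by stitching, and velocity work uses the fast
  duty cycle, but individual long-range trajectories at Δt = 4 min are
  not trustworthy.
* The blue-overlap exclusion assumes autofluorescent structures are
  bright in blue; dim sebaceous material below the blue Otsu threshold
  would not be excluded.
* The correlation window (3.6 µm) is of the same order as a mast cell's
  half-thickness; much larger windows dilute the juxtaposition
  signature of thin structures and are not recommended.
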