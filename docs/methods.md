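# Methods

## Overview

`tractdistill` implements a two-stage teacher-student framework for
streamline tractography and the machinery needed to study it end to end on
synthetic data: a spherical-harmonic (SH) fiber-orientation-distribution
(FOD) representation with deterministic peak tracking, a recurrent
*teacher* network that learns streamline propagation from FOD features, a
*student* network that reproduces the teacher's behavior from a FLAIR-like
scalar volume plus population-level anatomical context, a fiber-phantom
generator, and a tractogram comparison suite.

The scientific question behind the design: does streamline propagation
learned from diffusion-derived FODs transfer to a structural contrast that
carries no diffusion information?  The mechanism is model stitching — the
student's GRU hidden layer and output head are the teacher's, copied and
frozen, and its trainable front end must map structural features into the
representation those frozen layers expect.

## Coordinate conventions

All streamline points are world millimeters.  Integer voxel index
(i, j, k) refers to the voxel *center*; the NIfTI affine maps index to
world.  Trilinear interpolation is defined on the index domain
[0, n-1] per axis; sampling outside returns a NaN sentinel rather than
zero so trackers can distinguish "left the volume" from "zero signal"
(training treats out-of-field as an error instead).

Directions are parameterized as polar angle theta in [0, pi] from +z and
azimuth phi in (-pi, pi]; phi is normalized to 0 at the poles so
round-trips are deterministic.

## FOD representation

FODs are even-order real SH expansions (default order 4, 15
coefficients).  The basis is fixed for interoperability: degrees
l = 0, 2, ..., L, orders m = -l..l within each degree, with
sqrt(2) Re(Y_l^|m|) for m < 0, Y_l^0 for m = 0, sqrt(2) Im(Y_l^m) for
m > 0 (Condon-Shortley phase included) — the "descoteaux"-style ordering
of common diffusion tools.  Saved FOD volumes carry a JSON sidecar naming
the basis and order.

Peak extraction is a discrete search over 724 antipodally paired
Fibonacci-spiral directions (local maxima against the six nearest
neighbors, amplitude threshold default 0.1), followed by two deterministic
cap-refinement passes that shrink the search radius below the set's ~8
degree spacing; in practice refined peaks land well under 1 degree from
the analytic axis of a single-fiber kernel.  With a prior direction, the
candidate peaks are sign-flipped into the prior's hemisphere and the
closest one wins — the "follow the peak nearest the incoming direction"
rule of deterministic SD-stream-style tracking.

Single-fiber kernels are the axially symmetric function |d . v|^8
projected onto the basis by least squares on the direction set; axial
symmetry guarantees the truncated expansion peaks exactly at +-v.

## Phantom generator

A phantom is a deterministic function of (bundle specs, grid, noise_sd,
seed).  Bundle centerlines come from three parametric families (straight
segment, circular arc, helix); streamlines are parallel transports of the
centerline offset within the tube radius (offsets drawn uniformly over the
disc).  Per-bundle occupancy voxels receive a single-fiber SH kernel
aligned with the nearest centerline tangent; voxels crossed by several
bundles receive the coefficient *sum* (linear SH superposition), giving
genuinely multi-peaked crossing FODs.

The FLAIR-like channel is `1 - 0.6 * density / max(density)` (fiber
density = count of distinct streamlines visiting a voxel) plus Gaussian
noise of standard deviation `noise_sd` (default 0.02 on the unit intensity
scale), then intensity-normalized by clamping at the 99.9th percentile and
dividing by the clamp value so the maximum is 1.  The monotone
density-to-intensity map makes the contrast an invertible density cue,
emulating the darker appearance of white matter relative to surrounding
tissue on FLAIR; division by the clamp value is this package's scaling
choice (the normalization rule itself only fixes the clamp).

The context stack holds five tissue-probability channels (white matter =
smoothed occupancy support, the complement assigned to the cortical-GM
channel as a stand-in for all non-WM tissue, remaining channels zero;
channels sum to one everywhere) plus one smoothed probability map per
bundle, emulating atlas-derived tissue and bundle-probability priors.

What the phantom does *not* emulate: MR physics (relaxometry, partial
volume, bias fields, lesions), realistic bundle geometry (fanning,
kissing, bottlenecks), registration error between channels, or
inter-subject variability — every channel is perfectly co-registered and
noise is i.i.d. Gaussian.  Passing results therefore demonstrate the
*mechanics* of the method (losses, frozen-weight stitching, trackability
of a learnable contrast), not clinical-scale performance.

## Reference tracker

Deterministic FOD-peak propagation: jittered seeds (uniform within each
mask voxel, RNG-seeded), initial direction = global FOD peak at the seed,
bidirectional branches (second branch starts from the negated initial
direction), per-step stop conditions: mask exit / out-of-field, no peak
above threshold, per-step turn above `max_angle_deg`, or the length budget
(shared across branches) exhausted.  Defaults: step 1 mm (half the 2 mm
working voxel), 30 degree angle limit, lengths 10-200 mm, one seed per
mask voxel.  These are standard deterministic-tracker settings, declared
here as package defaults.

## Networks

Teacher: input MLP (two tanh hidden layers of width 64) maps the sampled
SH coefficient vector to the 64-wide feature f_T; two stacked GRU layers
(hidden width 64) model streamline dynamics; an output MLP (one hidden
layer of width 64) regresses two numbers squashed to theta in [0, pi]
(sigmoid) and phi in (-pi, pi) (tanh).  Converting (theta, phi) to a unit
vector before the loss keeps the azimuth degeneracy at the poles from
destabilizing training.  Widths are sized for CPU-scale phantom training.

Student: a three-layer 3x3x3 same-padded convolutional encoder (default
demo widths 12-12-8 channels, chosen to keep a full training stage in CPU
minutes; the general default is 16-32-8) over the concatenated FLAIR +
context channels produces a feature volume, trilinearly sampled at each
streamline point; then an input MLP and GRU input layer of the teacher's
widths, both freshly initialized and trainable; the GRU *hidden* layer and
the output MLP are copied bit-exactly from the teacher and frozen.  The
GRU input layer is the "mapping layer" of the stitching construction and
deliberately stays trainable.  The feature-alignment site is the input to
the GRU input layer (f_S vs f_T).

All networks run on an in-package numpy reverse-mode autograd tape
(float32 parameters); backpropagation through time falls out of the tape.
Optimization is Adam (lr 1e-3, betas 0.9/0.999), batches of whole
streamlines (16 for stage 1, 32 for stage 2), full-sequence BPTT with
hidden state reset at streamline boundaries, and a held-out validation
split (20% of sequences) recorded per epoch.

## Losses

Direction loss: `1 - <d_pred, d_label> / (|d_pred| |d_label|)`, range
[0, 2].  Student loss adds the same cosine penalty between f_S and f_T,
range [0, 4].  Zero-norm vectors are rejected (the cosine is undefined);
a student encoder that collapses to zero output trips this guard rather
than producing NaNs.

## Sequence orientation (a deliberate design choice)

Training sequences are *canonically oriented* — a streamline is reversed
when the dominant component of its end-to-end displacement is negative —
rather than presented in both directions.  With inputs that depend only on
position, the two orientations of one streamline give identical input
sequences with opposite labels; the symmetric problem has no useful
minimizer (the mean direction loss is bounded below by 1 on a straight
bundle), so direction regression requires a consistent orientation
convention.  Nothing downstream depends on the convention: tracking is
bidirectional and sign-aligns each predicted direction with the previous
step, so a model that has learned the tangent field up to sign tracks both
ways.

Resampling walks the polyline at uniform arc-length steps (default 1 mm);
the terminal remainder is kept when longer than half a step, trading exact
uniformity of the final segment for total-length preservation (within 2%
on curvature radii at least five steps).

## Model-based tracking

Identical seeding and stopping rules to the reference tracker, with the
FOD peak replaced by the network's predicted direction.  The first step
direction comes from the model itself at the seed (zero hidden state) —
the student has no FOD to consult — and each branch gets a fresh hidden
state.  All seeds propagate in lockstep (batched inference); stopped
branches are masked out.

## Evaluation suite

* Voxelization: streamlines are walked at quarter-voxel steps and each
  sample marked in its nearest voxel — a documented approximation to exact
  segment-voxel intersection.  Counts are distinct-streamline visits.
* Dice: `2|A&B| / (|A| + |B|)` on binary occupancy masks; two empty masks
  give 0 by convention (the comparison is vacuous).
* Bundle adjacency: mean over all reference streamline points of the
  distance to the nearest candidate point — pooled over points and
  one-directional (reference to candidate), matching the definition of a
  per-point minimum distance to the comparison tractogram.
* Geometry: average fiber length (mean polyline arc length); volume
  (occupied voxels x voxel volume); diameter `2 sqrt(V / (pi L))` — the
  effective cylinder with the bundle's volume and length; surface area =
  exposed occupancy faces x per-face area.  These follow common
  tractometry conventions; each formula is documented at its
  implementation.
* Mann-Whitney U: midrank statistic; exact two-sided p by enumeration of
  rank combinations for pooled sizes up to 16 (valid under ties),
  otherwise the normal approximation with tie and continuity correction.
  At single-phantom scale the per-bundle samples are per-streamline metric
  values (each streamline's own occupancy geometry), giving the test a
  distribution to compare where a cohort of subjects is unavailable.

## Demo experiment and problem sizes

The `full` demo preset is the package's standard desk-scale study: a
32-voxel (2 mm isotropic) grid, one straight bundle (radius 3.5 mm) and
one 180-degree arc (tube radius 3 mm, curvature radius ~14 mm), 50 truth
streamlines per bundle, noise 0.02; reference tracking at one seed per
white-matter voxel; teacher and student each trained 200 epochs on a
128- / 96-streamline subsample of the reference tractogram.  These sizes
were chosen so a complete run (phantom through report) executes in CPU
minutes while leaving several hundred voxels of bundle volume for the
overlap metrics.  The `tiny` preset (16-voxel grid, one bundle, 8 epochs)
exists for smoke and determinism checks.

Every stage draws its randomness from sub-seeds derived from the single
demo seed; two runs with the same seed reproduce loss histories and report
tables to floating-point reduction-order tolerance.

## Known limitations

* The autograd engine and layers implement exactly the operations this
  package needs; they are not a general deep-learning framework.
* The phantom's FLAIR surrogate is by construction informative about fiber
  density; real FLAIR contrast is far less specific, so phantom-scale
  student performance overstates what the same architecture achieves on
  clinical data.
* Canonical sequence orientation can assign conflicting signs where two
  bundles with near-parallel tangents cross; sign alignment at tracking
  time absorbs this, but the pointwise direction loss in such voxels is
  pessimistic.
* The discrete peak search resolves crossing angles down to roughly the
  direction-set spacing; very shallow crossings merge into single peaks.
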