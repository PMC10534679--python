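# Methods

## Problem and model

`armalign` rigidly registers the point clouds produced by a handheld
three-camera depth scanner moved around an upper limb. The limb is treated as
rigid for the duration of the scan; every pose's triplet of sensor clouds is
assumed co-registered by the rig's extrinsic calibration (an input, not
something this package computes). All coordinates are millimetres.

The registration chain is anatomical-feature-first: 21-slot hand landmarks
and forearm key points constrain a closed-form coarse alignment (Horn's
weighted absolute orientation), and a bounded 6-DOF minimization of
`1/(f1·f2)` refines it, where `f1` is the fraction of point pairs closer than
`toll` and `f2` the mean agreement of the paired surface normals. `f2` is what
lets the objective reject poses that overlay the *front* of one scan onto the
*back* of another — on thin, quasi-cylindrical limb geometry, plain
closest-point distances cannot tell those apart.

### Reading of the pair matrix

The pair set D is literally the full M×N distance matrix with entries ≥
`toll` dropped: one point may appear in several pairs, so `f1` can exceed 1
on dense clouds. The normal-agreement matrix V is defined on exactly the same
index set (v_ij exists iff d_ij < toll); this is the only reading under which
`f2` is an average over matched pairs, and the implementation follows it. The
0.75 mm voxel grid applied before optimization bounds the pair multiplicity
at `toll` = 1.5 mm.

When |D| = 0 or f2 ≤ 0 the objective is undefined as written; the
implementation returns a penalty constant of 1e6, which keeps the optimizer
bounded and steers it back toward overlapping configurations.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| detection score threshold | 0.5 | – | minimum landmark-set confidence per sensor |
| FKP heights | −200,−250,−300,−350 | mm | forearm key points below the hand barycenter |
| w_H | 1 | – | Horn correspondence weights (uniform) |
| voxel | 0.75 | mm | grid for optimization copies and the accumulated union |
| toll | 1.5 | mm | pair-distance threshold in f1/f2 |
| SLSQP stop | 1e-4 | – | objective-change stopping tolerance |
| N_iter_ex | 9 | – | epochs of the global loop |
| SOR | k=20, ratio=2.0 | – | statistical outlier removal (single pass) |
| normals k | 30 | – | kNN neighborhood for normal estimation |
| bounds | ±10°, ±10 mm | | box bounds around the incoming pose |
| slice pitch / band | 10 / ±2 | mm | forearm cross-section slicing |
| cluster eps / min size | 30 / 10 | mm / pts | single-linkage slice clustering |
| RANSAC tol / iters / seed | 3 mm / 500 / 0 | | line fit through slice centers |

SOR defaults, normal-estimation k, slicing extents (−50 to −350 mm) and the
RANSAC settings are package choices where no standard value exists; all are
configurable. The slice-clustering linkage distance of 30 mm is set by the
sensor-coverage geometry: with three sensors of limited incidence tolerance,
a cross-section ring arrives as a few disjoint azimuthal arcs separated by up
to ~20 mm, which must connect into one cluster for the ellipse fit to be
well-conditioned, while genuinely detached structures (the other arm, gross
outlier clumps) sit at ≳100 mm and stay excluded.

### Numerical choices in the optimizer

The count-based `f1` makes the objective piecewise-flat, so SLSQP runs with
scaled variables in which one finite-difference step equals 1e-3 rad /
0.1 mm, and a coarse-to-fine schedule of step multipliers (10×, 3×, 1×)
straddles pair-set changes early and resolves the basin late. Two further
mechanisms address structural weaknesses of the landscape, both engaged only
when the incoming pose is materially wrong (a near-converged pose takes a
single fine-step descent — the common case inside the global loop):

- **Sliding-mode scan.** Rotation about and translation along the limb's
  long axis are weakly observed on a quasi-cylindrical surface: their capture
  basin (set by the hand's asymmetric geometry) is ~1.5°/2 mm, far narrower
  than the ±10° bounds. A grid scan over that 2-DOF plane around the current
  pose re-seeds the descent.
- **Tilt multi-start.** Partial overlap admits "see-saw" local minima in
  which only the mid-section of the long cloud stays paired. Descents are
  restarted from ±3° and ±6° tilts about the two axes perpendicular to the
  limb axis.

Rotations are parameterized as xyz Euler angles about the moving cloud's
centroid (better conditioning than world-origin rotations). The returned
transform is always the best pose *evaluated*, so the reported objective
trace is monotone non-increasing regardless of optimizer internals. Normals
are rotated with the initial estimate rather than recomputed per candidate
pose — for rigid motion the two are equivalent.

Inertia-frame sign conventions (nowhere standard): the long axis points so
the hand-landmark barycenter (when known) or the farthest point has positive
coordinate; the intermediate axis follows the sign of the third moment of its
projections (falling back to the farthest-point rule); the third axis
completes a right-handed basis. These make canonical frames of near-identical
clouds agree, which the evaluation relies on.

Degenerate inputs: collinear/coincident clouds raise a geometry error;
slices with too few points are skipped; ellipse fits with fewer than five
points or non-elliptical solutions fall back to the cluster centroid with a
flag; a pose without three usable correspondences is exported unregistered
with a machine-readable flag rather than dropped; pairs whose objective is
penalty-valued in the whole probe neighborhood return identity with a
`no_overlap` flag.

## The synthetic data generator

The simulator emulates the study conditions of a three-camera rig (sensors
90° apart on a ring of radius 350 mm, working range 250–450 mm) scanning an
arm from six poses around the limb axis. The arm is a union of analytic
primitives — conical-frustum forearm (250 mm long, radii 45→30 mm), ellipsoid
palm, five capsule-chain fingers — with the 21 landmarks anchored on the
primitive surfaces in the standard slot order. Per pose it emulates:

- **visibility**: back-face culling plus a maximum incidence angle
  (default 32°). Stereo depth quality collapses at grazing incidence; the
  32° cone also reproduces the *partial* adjacent-pose overlap (~0.3–0.5 at
  60° pose steps) that makes multi-pose registration nontrivial. The culling
  primitive itself defaults to 90° (pure back-face).
- **sampling density**: 8000 points per sensor (~1.3 mm spacing). This is a
  deliberate scale-down of real depth-camera output (hundreds of thousands of
  points per frame) chosen so that the 0.75 mm voxel / 1.5 mm pair threshold
  remain meaningful relative to point spacing; at much sparser sampling the
  pair-count term becomes noise-limited along the sliding mode and the
  registration floor rises.
- **noise and outliers**: isotropic Gaussian depth noise (default 0.5 mm,
  matching sub-millimetre sensor error at close range); 2% outliers split
  between gross random displacements and systematic "peripheral" outliers
  displaced along the viewing ray at silhouette boundaries.
- **detections**: per-sensor 21-slot sets with independent slot dropouts
  (default 10%) and a per-image confidence drawn from [0.7, 0.99].
- **ground truth**: each pose's true transform (60° azimuth steps plus a
  random ≤3° tilt and ≤10 mm shift) is recorded for tests and evaluation
  only; the pipeline never reads it.

Everything is a pure function of the config seed: identical seeds give
bitwise-identical triplets.

**What passing synthetic tests does not show.** The simulator has no
articulated or non-rigid motion between poses (involuntary finger/wrist
movement during a real scan breaks the rigidity assumption and is a known
error source), no sensor-specific noise spectra or depth-dependent error
growth, no skin texture driving real landmark detectors (detections are
simulated directly in 3D), and simplified anatomy. Results on synthetic data
therefore validate the algorithmic chain, not clinical performance.

## Evaluation

Registration quality is measured as one-sided nearest-neighbor distances from
the automatically assembled cloud to a reference assembly, after mapping both
into their common inertia frames (origin at the centroid, z along the
lowest-inertia axis, x along the intermediate one) — this removes the
arbitrary global pose of either result. Reports give the mean, standard
deviation and fractions below 3/5/6/10 mm, overall and split into hand/arm
regions at a plane 100 mm below the hand-landmark barycenter along the
inertia z-axis (a reproducible surrogate for an anatomical hand/arm
boundary).

On the synthetic analog (five 6-pose datasets, 0.5 mm noise, standard
parameters) the acceptance script computes these quantities from scratch;
problem sizes are ~78k points per dataset. The tests additionally verify the
solver oracles (Horn vs SVD superposition; the objective vs a literal M×N
matrix), exact noiseless transform recovery in the coarse stage, skeleton
recovery within 1° noiseless / 3° under 1 mm noise + 2% outliers, sub-voxel
(0.75 mm) pair recovery from 3°/3 mm perturbations, and bitwise determinism
of repeated runs.

## Known limitations

- The fine objective's minimum can sit slightly off the true pose when
  coverage is gappy (stacking visibility arcs can raise the pair count);
  the global loop's accumulated-union strategy suppresses this, single-pair
  registration of sparse, low-overlap scans is less reliable.
- Landmark heights anchor on each pose's own hand-landmark barycenter; with
  heavy dropout the barycenters (hence FKPs) shift slightly between poses,
  adding a small coarse-stage bias that the fine stage absorbs.
- A straight skeleton line assumes an extended, roughly straight forearm;
  strongly bent poses violate it.
- Runtime scales with cloud size times SLSQP evaluations; the defaults are
  tuned for tens of thousands of points per pose on one CPU.
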