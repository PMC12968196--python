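# Methods

`cedplan` re-creates, on fully synthetic data, a planning study for
convection-enhanced drug delivery (CED) into the putamen: which putamen
quadrant receives the most motor cortical input, whether frontal and
occipital catheter trajectories into that quadrant can be planned safely,
and how much of the quadrant a small set of spherical infusions along each
trajectory can cover. This note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Coordinate conventions

All geometry is computed in world millimetres in a RAS+ frame; NIfTI files
with other orientations are reoriented on load. Voxel indices are 0-based,
a voxel's world position is its center, and a voxel belongs to a region iff
its center satisfies the predicate (sphere membership, quadrant side,
mask membership). Distances, radii and margins are therefore correct on
anisotropic grids without special cases. The anisotropy-aware Euclidean
distance transform (`scipy.ndimage.distance_transform_edt` with physical
sampling) backs both safety margins and sphere containment; it assumes the
affine's axes are orthogonal, which holds for every grid this package
generates.

## AC-PC quadrant parcellation

The stereotactic frame is built from three landmarks: AC, PC and a
superior midline reference. `y_ap` is the unit vector from PC to AC,
`z_si` the superior reference orthogonalized against it, and
`x_lr = y_ap x z_si`, giving right-handed orthonormal axes. A putamen
voxel with center `p` is *superior* iff `(p - ac) . z_si >= 0` and
*anterior* iff `(p - ac) . y_ap >= 0`; the four combinations are coded
1 superior-anterior, 2 superior-posterior, 3 inferior-posterior,
4 inferior-anterior.

Open choices, resolved as follows:

* **Both cutting planes pass through AC.** Anchoring at the
  mid-commissural point instead would shift the coronal plane ~13 mm
  posterior; the AC anchor follows the segmentation's stated anatomical
  reference and is the simplest reproducible rule. Swapping anchors is a
  one-line change (`build_acpc_frame` input) if a sensitivity analysis is
  wanted.
* **Boundary voxels (dot product exactly 0) go to superior/anterior.**
  A deterministic tie-break on a measure-zero set; it is the only reason
  the partition is not rotation-equivariant to the last voxel when
  landmarks sit exactly on voxel-center planes.
* **A third landmark is required** because two points do not fix the roll
  angle about the AC-PC axis; the phantom supplies it in its manifest.

## Synthetic phantom

The phantom emulates the study's acquisition geometry — 2.0 mm isotropic
voxels (64^3 grid), 64 diffusion directions at b = 1000 s/mm^2 — with known
ground truth. Components, all parameterized in `PhantomSpec`:

* **Brain / putamen / ROIs**: ellipsoids and spherical blobs; the putamen
  (semi-axes 8 x 14 x 10 mm, ~4.8 mL) straddles all four AC-PC quadrants by
  construction and generation fails loudly if jitter breaks that.
* **Fiber bundles**: tubes of radius 3 mm swept along quadratic Bezier
  centerlines, one from the superior-posterior quadrant to an SMA-like
  blob and one from the inferior-posterior quadrant to an amygdala-like
  blob. Tensors inside a tube are axially symmetric with the principal
  eigenvector along the local tangent. For target FA `f` and mean
  diffusivity `m` the eigenvalues are `m(1+2d), m(1-d), m(1-d)` with
  `d = f / sqrt(3 - 2 f^2)`, which makes the FA exact by construction
  (default bundle FA 0.7, background FA 0.05, MD 0.7e-3 mm^2/s).
* **DWI forward model**: `S_i = S0 exp(-b_i g_i^T D g_i)` with optional
  Rician noise (two Gaussian quadrature channels, matching magnitude MRI;
  default sigma 0 so fixtures are exactly invertible). The shipped
  gradient table is one b=0 volume plus 64 electrostatically repelled unit
  vectors; the b=0 volume is required because on a single shell of unit
  vectors the log-signal intercept is collinear with the tensor trace.
* **Critical structures**: a midline ventricle slab and two vessel-like
  cylinders, one near each approach corridor.
* **Trajectories**: one frontal (anterior-superior entry) and one
  occipital (posterior entry) per hemisphere. Each approach has its own
  target placed at the far end of the superior-posterior segment along its
  path, mirroring the planning principle that targets maximize in-segment
  trajectory length.
* **Cohort variability** (`jitter_mm`, default 1.5 in `StudyConfig`):
  seeded uniform offsets of the putamen, ROI blobs, entries and vessel
  positions per subject. Vessel corridors are placed so that this
  anatomical jitter makes clearances straddle the 2 mm margin — some
  hemispheres are safely plannable by one approach only, which is the
  variability the cohort statistics are meant to exercise.

All randomness flows through the single spec seed; cohort sub-seeds are
derived with `numpy.random.SeedSequence` spawn keys.

What the phantom does *not* emulate: cortical folding, partial-volume
effects, crossing fibers, susceptibility distortion, the curved tapering
shell shape of the real putamen, or realistic CSF/vessel anatomy. Passing
tests therefore show the algorithms are correct on controlled geometry,
not that the pipeline is robust to clinical image quality. In particular,
the phantom's superior-posterior segment is a compact convex blob, so
optimized sphere coverage (~50%) runs far above what the study's
constrained anatomy allows (<10%); coverage values are meaningful only for
comparing the two approaches within the phantom.

## Tensor fit, FA, tracking

The fit is the classical log-linear least-squares single-tensor solution:
one pseudo-inverse of the shared 65 x 7 design applied to all brain voxels
at once; voxels with non-positive signal are flagged invalid rather than
NaN, and negative eigenvalues are clamped to 1e-7 mm^2/s. FA uses the
standard eigenvalue formula `sqrt(3/2) ||lambda - mean|| / ||lambda||`
with FA(0) defined as 0.

Tracking is deterministic fixed-step Euler integration along the principal
eigenvector, bidirectional from each seed, with trilinear interpolation of
the six tensor components followed by eigen-decomposition at every step.
Stop criteria are the routine clinical settings: FA < 0.2, per-step
turning angle > 50 degrees, leaving the brain mask, or the step budget;
joined tracks shorter than 20 mm are discarded. Defaults chosen where the
original software's internals are unreported: step 1.0 mm (half the
smallest voxel edge), one seed per segment-voxel center, eigenvector sign
aligned with the incoming direction. At the default step the 50-degree
criterion is applied per step exactly as stated; changing the step changes
the effective curvature limit and is the user's responsibility.

A connection between a cortical region and a putamen segment is *present*
iff at least one retained streamline has a point in both masks (traversal,
not endpoint, semantics — matching "any streamlines observed between"),
and cohort heat maps count hemispheres with a present connection on a
fixed 0..2n color scale.

## Trajectories and safety

A trajectory is discretized into 100 equidistant points including both
endpoints ("100 equidistant steps" read as 100 sample points; the
101-point reading is available via `n_points`). Sample points whose voxel
lies in the target segment are the valid centers. Safety is a hard test:
the trajectory is safe iff every sample point keeps at least `margin_mm`
(default 2 mm) of trilinearly interpolated distance from every
critical-structure mask; the verdict, the minimum distance and the
offending structure are reported. Safety is monotone in the margin by
construction. Binary outcomes are coded 0 = unsafe, 1 = safe for the
statistics layer.

## Infusion GA

A plan is an ordered list of (center, radius) spheres; centers must come
from the valid-center set. At evaluation each sphere is shrunk on the
ladder `requested - k * step` (floored at 0, where it still covers its
containing voxel) until its voxel mask lies inside the allowed region —
deterministic phenotypic repair, which implements the boundary penalty.
Fitness is the covered fraction of target-segment voxels (union
semantics). Containment defaults to the target segment itself, the
conservative reading; passing the brain mask gives the permissive mode.

GA defaults: 20 generations; population 50; tournament selection (size
3); one-point crossover with probability 0.7; mutation probability 0.3
(replace one sphere's center by a uniform valid center); elitism of one;
at most 4 spheres; radius ladder 0.5 mm steps up to 6 mm. Only the
generation count is dictated by the study design — the remaining
hyperparameters are package defaults, all exposed in `GAConfig`.
Crossover uses a single shared cut point in `[0, min(len_a, len_b)]` with
tail swap: the pair's sphere multiset is conserved, offspring lengths are
the parents' lengths swapped (so counts stay within bounds), and identical
parents produce identical offspring; sphere-count diversity enters through
initialization and selection. On tiny instances the GA is audited against
exhaustive enumeration: it can never exceed the optimum and matches it in
>= 90% of seeded runs.

## Statistics

* **Contingency / proportions**: paired safety outcomes per hemisphere
  give a 2x2 table (a both-safe, b frontal-only, c occipital-only, d
  both-unsafe); marginal safe proportions and the discordant split are
  exact arithmetic, with the 0/0 discordant split flagged undefined.
* **Mid-p McNemar**: with `n_d = b + c`, `m = max(b, c)`,
  `X ~ Binomial(n_d, 1/2)`: `p = 2 P(X >= m) - P(X = m)`, capped at 1 and
  defined as 1 at `n_d = 0`. This is the standard two-sided mid-p form;
  for (b=7, c=6) it gives 0.79053. Published analyses of the same table
  have printed other values depending on the software's mid-p variant,
  which is why the package pins the formula explicitly and verifies it
  against exhaustive enumeration of all `2^(b+c)` discordant orderings.
* **Paired t / mean CI**: textbook one-sample t on the differences with
  Student-quantile 95% intervals, cross-checked against
  `scipy.stats.ttest_rel` to 1e-10; zero-variance differences return a
  flagged degenerate result.

## Pipeline and problem sizes

`run_study` chains the stages per subject and hemisphere, selects the
infusion target as the segment with the highest presence count among the
motor-associated regions (the phantom's SMA surrogate; superior-posterior
by construction), and writes parcellations, streamlines (TCK), count
matrices, safety tables, coverage masks and the summary JSON. Re-running
with the same configuration is bit-identical.

Problem sizes used by the shipped analyses and checks — chosen so each
stage's property (exact truth recovery, oracle agreement, bit
reproducibility) is demonstrated on the smallest cohort that exercises it:
a 4-subject noise-free cohort for connectivity recovery, 20 seeded tiny
instances (<= 6 centers, <= 2 spheres, 3 radius levels) for the GA audit,
a 2-subject run for end-to-end reproducibility, and a 20-subject cohort
(40 hemispheres, matching the study's paired sample size) for the
headline statistics.

## Interface

The package is a library plus numbered analysis drivers under
`analysis/`; these scripts and the `run_study` entry point are the
intended interface, so no separate shell CLI is shipped.

## Known limitations

Single-tensor deterministic tractography cannot represent crossing or
kissing fibers; the phantom avoids them by construction. The infusion
model is purely geometric (no convection-diffusion physics, anisotropic
spread, or backflow). The EDT-based geometry assumes orthogonal grid
axes. Absolute coverage numbers on the phantom are optimistic (see the
phantom section) and only approach *comparisons* are meaningful.
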