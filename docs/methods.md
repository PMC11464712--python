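# Methods

This note documents the models, conventions, numerical choices and known
limitations of `pennadti`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Coordinate conventions

Voxel indices are 0-based `(i, j, k)`; world coordinates are millimetres via
the NIfTI affine. All geometry — tendon direction, eigenvectors, pennation
angles, streamline lengths — is computed in the world frame, so results are
invariant to voxel-size changes (asserted by test). Gradient directions are
interpreted as unit vectors in the world frame; for the axis-aligned affines
of the phantom this coincides with the index frame, and for real data the
caller is responsible for supplying bvecs in the frame the affine maps from.
The imaging plane is the plane spanned by the two in-plane voxel axes; its
normal is their cross product, i.e. the slice-select direction of the
acquired (possibly oblique) grid, not a scanner axis. Angles are reported
in degrees throughout.

## Tensor model and estimator

Signal model: `S(b, g) = S0 exp(-b g^T D g)` with `D` symmetric positive.
The fit is ordinary least squares on log-signals against the 7-column design
`(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`; a gradient scheme that cannot
determine all seven parameters (fewer than six non-collinear weighted
directions) is rejected up front. OLS was chosen as the transparent
baseline; a one-pass reweighted WLS (weights = fitted signal) is available
behind `weighted=True` and recorded in the output metadata. For a noiseless
consistent system OLS is exact, which is the basis of the forward-simulation
oracle used everywhere (observed max relative tensor error ~1e-14).

Numerical policies:

* Non-positive samples are excluded per voxel; if fewer than 7 usable
  samples remain the voxel is fitted on signals floored at `1e-6 * S0` and
  flagged `valid=False`.
* Eigenvalues are stored unclamped (information preserved); negatives are
  clamped to zero only inside FA, keeping FA in [0, 1]. `FA =
  sqrt(3/2) ||lambda - MD|| / ||lambda||`, with the all-zero triple mapped
  to FA 0; `MD = mean(lambda)`.
* Eigenvectors are sign-canonicalized (first non-zero component positive) —
  fiber orientation is axial, so ±v are equivalent and a deterministic
  representative keeps outputs reproducible.
* The default fit mask is "mean b=0 above an Otsu threshold", overridable by
  an explicit mask.

At the muscle-typical b = 450 s/mm² and eigenvalues (2.1, 1.6, 1.4)e-3
mm²/s the tensor contrast `b (l1 - l2) ≈ 0.23` is low, so the principal
eigenvector is noise-sensitive: at SNR 30 the per-voxel angular error has a
median near 5° (seeded regression test). ROI averaging is what makes the PA
estimate stable — over ~1500-voxel ROIs the mean PA is recovered within
0.1–0.2° at SNR 30.

## Pennation-angle map

The tendon is annotated once per examination as an ordered polyline on one
slice. Its direction `T` is the total-least-squares (principal-axis) line
through the vertices in world coordinates — one global direction per slice,
not per-voxel local tangents, because a single drawn tendon defines a single
angle convention; curvature handling is an open extension and the choice is
recorded in the output metadata. Vertex scatter perpendicular to the line
(hand jitter) is tolerated by construction of the TLS fit.

Per voxel, `v_p = v - (v·n) n` and `PA = arccos(|v_p·T| / |v_p|)`, folded
into [0, 90°] by the absolute value (axial fibers; reported muscle values of
~10–16° are folded angles). `|v_p| < 1e-6` (fiber essentially perpendicular
to the plane) yields NaN and is excluded from ROI statistics, as are
unfitted or invalid voxels. ROI summaries are NaN-excluding mean, SD
(ddof=1, zero for a single voxel) and count per label; a label with no
finite voxel is dropped with a warning rather than reported as NaN.

Verified properties: equality with the closed-form in-plane angle on a dense
[0, 90°] grid (1e-10), invariance to eigenvector sign and to joint in-plane
rotation of `v` and `T` (1e-8), and removal of out-of-plane elevation by the
projection (a fiber at 30° elevation and 10° in-plane azimuth maps to 10°).

## Registration

All volumes are aligned to the first b = 0 volume with intensity-based
rigid (Euler) or affine registration: correlation metric, two-level
multi-resolution (shrink 2/1, smoothing 1/0), regular-step gradient descent,
linear interpolation, single resampling onto the input grid with clamping at
zero. The reference volume is passed through bit-identically; a failed
optimization falls back to identity with a logged warning. Registration is
3D per-volume. The reported translation follows the "content shift undone"
convention: a volume whose content moved +2 voxels is reported as −2 voxels
(recovered within 0.002 voxel on the phantom).

A correlation metric assumes linearly related intensities; between
diffusion-weighted volumes of differently oriented compartments this is only
approximate, and the optimum can sit a few hundredths of a voxel off
identity on a pre-aligned multi-contrast phantom. This is harmless at PA-map
level (ROI means shift < 0.2° between `none` and `rigid` on a noiseless
phantom) but is why the fixed-point test uses a uniform-fiber phantom.
Non-rigid correction, the method of choice for in-vivo eddy-current
distortion, is deliberately out of scope; `nonrigid_hook` lets an external
tool supply the warped volumes while the rest of the pipeline is unchanged.

## Tractography

Deterministic tensor-line tracking for visualization. At every step the
tensor is refitted to trilinearly interpolated diffusion-weighted signals at
the current point (interpolation of signals, not of tensors or directions),
and the trajectory follows the principal eigenvector, sign-aligned with the
previous step. Integration is first-order Euler, bidirectional from each
seed; seeds are drawn uniformly inside the mask from a seeded RNG, so runs
are bit-reproducible. Termination: mask exit, invalid local fit, or
inter-step turn above the angular cutoff. Streamlines shorter than the
minimum length are discarded. Defaults: cutoff 20°, minimum length 50 mm,
100,000 streamlines, step 0.1 × smallest voxel dimension (a common
deterministic-tracking default, fine relative to grid curvature); a
seed-attempt cap of 100 × the target count guarantees termination on
pathological masks, returning fewer streamlines with a warning.

Enforced contracts (tested): retained length = (points − 1) × step; maximum
inter-step angle ≤ cutoff; on an 80+ mm parallel-fiber slab all retained
streamlines are ≥ 50 mm and laterally straight to < 0.5 voxel, while a
30 mm slab retains none; mirrored ±45° bundles cannot be crossed end-to-end
because that would require a turn beyond the cutoff within ~2 voxels.
Desk-scale runs (tests, acceptance script) use 1,000 streamlines at a 1 mm
step on a 2 mm-voxel slab; the defaults remain the full-scale values above.

## Reliability statistics

`icc_absolute` implements the absolute-agreement ICC from the two-way ANOVA
decomposition of a complete subjects × measurements matrix
(`MSR`, `MSC`, `MSE`):

* single measures: `(MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)`
* average measures: `(MSR − MSE) / (MSR + (MSC − MSE) / n)`

95% confidence intervals use the F-based construction with
Satterthwaite-style denominator degrees of freedom; the average-measures
interval is the k-average (Spearman–Brown) transform of the single-measures
one. Estimates and CIs match an independent implementation (pingouin's
ICC(A,1)/ICC(A,k)) and a from-scratch sums-of-squares oracle to 1e-10; the
nominal 95% interval covers the true value in ≥ 93% of 1000 simulated 10×3
tables. Missing cells are a hard error (no imputation), as is a
zero-total-variance matrix (ICC undefined). Single measures is the default
reported variant, with the variant always labeled in the output — the
average-measures analog is behind a flag, and no attempt is made to guess
which variant an external report used.

Categories follow the Koo–Li convention: > 0.90 excellent, 0.75–0.90 good
(0.90 itself is "good"), 0.50–0.75 moderate, < 0.50 poor.

Design handling: `design_slices` builds per-rater subjects × sessions
matrices (test-retest), per-session subjects × raters matrices
(inter-reader), and per-session subjects × reading-occasions matrices
(intra-reader; requires the optional `occasion` column). When repeated
occasions exist, test-retest and inter-reader use the first occasion.
`aggregate_ratings` averages a balanced table per subject over sessions
and/or raters; with balanced data the grand mean equals the mean of the
per-rater-per-session cell means, which is what lets cohort-level cell
means be aggregated when subject-level data are unavailable. Unbalanced
designs are a hard error naming the offending subjects.

## Phantom

The synthetic dataset emulates a bipennate muscle in cross-section: a
straight intramuscular tendon along the first in-plane axis; an anterior
compartment whose two sub-bundles mirror each other at ±PA_ant about the
tendon line (default 16°); a posterior parallel-fibered compartment at
PA_post (default 11°); optional out-of-plane elevation per compartment. A
1-voxel exclusion zone around the tendon carries tendon-parallel fibers but
is unlabeled, mirroring the practice of excluding the tendon from ROIs.
Default grid 64×64×15 at 0.75×0.75×3 mm (the acquisition's slice count and
thickness at a reduced in-plane matrix); default eigenvalues
(2.1, 1.6, 1.4)e-3 mm²/s, typical literature values for skeletal muscle;
default scheme 3 b=0 volumes plus 64 quasi-uniform (golden-angle spiral)
directions at b = 450 s/mm²; S0 = 1000 with background at 2% of S0 so the
Otsu mask separates foreground. Noise is Rician — the magnitude of
`(S + N(0, sigma), N(0, sigma))` with `sigma = S0/SNR` — matching magnitude
MRI; the background mean follows the Rayleigh limit `sigma sqrt(pi/2)`
(tested). Generation is bit-reproducible from the spec's seed.

The truth sidecar (per-voxel tensor, e1, PA, ROI labels, annotation) is the
oracle for the rest of the package: the truth PA map equals the projection
rule applied to the truth e1 field exactly, including under elevation.

`generate_ratings` simulates balanced rating tables as
`value = mean + subject + rater + session + residual` with configurable
Gaussian variance components; the implied single-measures ICC of a
subjects × raters slice is `sigma_s² / (sigma_s² + sigma_r² + sigma_e²)`,
used for parameter-recovery checks (0.8 recovered within 0.02 at n = 5000).

What the phantom does *not* emulate: realistic supraspinatus geometry,
tendon curvature, fat infiltration, partial-volume mixing at compartment
borders beyond interpolation, susceptibility/EPI distortion, and motion
between volumes. Passing phantom tests therefore validates the computational
chain and its contracts, not in-vivo accuracy.

## Scale of the shipped checks

Test-suite and acceptance-script problem sizes are chosen to keep a full
run in the tens of seconds on one core while still exercising every path at
meaningful size: tensor-recovery grids of 32×48×5 (5,600 muscle voxels × 67
volumes), the full 64×64×15 default phantom for PA recovery, 1,000
streamlines for tracking, 200 random tables plus n = 5000 simulations for
the ICC checks. All sizes are explicit in the tests and in
`scripts/acceptance.py` and scale up by changing the spec objects.
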