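# Methods

## Coordinate frame and data model

All geometry lives in a single RAS world frame (+x right, +y anterior,
+z superior) in millimetres. A `VoxelGrid` describes voxel *centers*:
index (0,0,0) sits at `origin`, indices are 0-based, and all volumes in
one analysis share a grid unless explicitly resampled. Synthetic grids
default to 1 mm isotropic spacing so mm³ equals voxel count; anisotropic
spacing is supported throughout and exercised in the tests. Grids built
by the generator are centered (`origin = −(dims−1)/2·spacing`) so that
index mirroring is exactly the reflection about the midsagittal plane
x = 0 — with an even voxel count there is otherwise no self-mirroring
midline column.

Masks are transported between spaces with nearest-neighbor resampling of
hard labels (no partial volume): each target voxel takes the membership
of the source voxel nearest to its inverse-mapped center. A translation
by a whole number of voxels is exact. Estimating transforms
(registration, bias correction, template building) is out of scope; the
package applies supplied affines only.

Percentiles use linear interpolation between closest ranks (the common
scientific default); the conventions (q=50 median, q=100 maximum) are
pinned by tests.

## Ablation-core segmentation

The whole-ablation (penumbra outer) boundary is an *input*, reflecting
the clinical workflow where it is traced manually. The core is recovered
automatically:

1. median and 99th percentile of the post-treatment intensities over the
   thalamus *excluding* the whole ablation ("normal-appearing" — the
   exclusion is applied so lesion hyperintensity cannot inflate the
   reference; the 99th percentile rather than the maximum protects the
   scale from a few stray ventricle voxels);
2. re-scale: **anchored** mode `(x − med)/(P99 − med)` maps the median
   to 0 and the 99th percentile to 1 and is invariant to affine
   intensity changes. A **literal** mode `(x − med)/P99` is provided as
   a configuration option because the two normalizations circulate in
   the field's descriptions of this method; it is *not* shift-invariant,
   and a test documents the difference. Anchored is the default and the
   mode actually used is recorded in every pipeline summary;
3. threshold: scaled intensity strictly greater than 1.25 (an empirical
   constant of the method, kept as a config default and not re-derived);
4. binary closing with the connectivity-1 structuring element (the
   7-voxel 3D cross), which fills the small central hypointensity seen
   inside many cores;
5. intersection with the traced whole-ablation mask, since closing near
   the boundary could otherwise let the core escape the penumbra.

Raising the threshold can only shrink the pre-closing core
(monotonicity); the central hypointense spot is deliberately *not*
segmented as its own region.

## Vim and stereotactic targets

Vim is defined operationally as the ventral half of VLp: the cutting
plane lies midway (in mm) between the two transaxial planes bounding
VLp, voxels below it are ventral, and a voxel exactly on the plane is
assigned ventral — one deterministic rule so the halves always partition
VLp.

The standard initial target is
`x = wall_x ± 11 mm` (into the treated hemisphere),
`y = PC_y + 0.25·(AC_y − PC_y)`, `z = AC-PC plane`. The landmark report
(midline distance, PC distance, signed %AC–PC, signed AC–PC-plane
distance) uses the signed formula for the percentage.

Equal-volume sphere targets are rasterized by *exact-count ranking*:
all voxels sorted by (distance to the center, then lexicographic index),
taking the first `round(volume/voxel volume)`. This makes "a sphere of
the same volume" exact and deterministic, which a radius cutoff cannot.

Majority-vote label fusion assigns each voxel its plurality label; any
tie — including with background — yields background, so fused anatomy is
never invented.

## Probabilistic target construction

In template space (right-treated patients flipped left first), the
intersection of all patients' whole ablations is eroded with the full
3×3×3 cube kernel while the result stays at or above the 20 mm³ stopping
volume. Erosion is quantized, so the step that would undershoot is
replaced by a deterministic peel: boundary voxels (26-connectivity) are
removed one at a time, farthest from the current centroid first,
lexicographic index breaking ties, until the count equals
`round(stop volume / voxel volume)` exactly. The final target therefore
always has the exact stopping volume whenever the intersection is large
enough, is contained in every patient's ablation, and is invariant to
patient order. The cube kernel is deliberately distinct from the
segmentation's cross kernel. A `min_fraction` option generalizes the
100 %-overlap requirement for cohorts with an empty full intersection;
it is off (1.0) by default. Warping the target to a patient applies the
inverse of the patient-to-template affine with nearest-neighbor
resampling.

## Outcome statistics

CRST A+B (treated hand, parts A+B summed; 0–32, lower is better) at
baseline and 1 month. Cohort summaries use sample (n−1) standard
deviations. The paired *t* uses `t = mean(d)/(sd(d)/√n)`, `d = baseline −
follow-up`, df = n−1. The Wilcoxon signed-rank test drops zero
differences, midranks ties, takes W as the smaller signed-rank sum, and
applies the normal approximation with tie correction and a 0.5
continuity correction. Pearson correlations get two-sided p-values from
`t = r√((n−2)/(1−r²))` on n−2 df. Both tests and the correlation are
implemented from their definitions and cross-checked against scipy in
the test suite. No multiple-comparison adjustment is applied to the
metric-correlation table — each of the eight metrics is reported as-is,
which is a caveat for interpretation.

The packaged 14-patient CRST table is reference input data; its
summaries (1-month 8.21 ± 4.61) and paired t (9.70) are pinned by tests.
Recomputing from the printed integer scores gives t = 9.70 and baseline
SD 3.83 versus the published 9.74 and 3.78; the <1.5 % residuals are
rounding in the source data and are not reconciled. With the continuity
correction the Wilcoxon p on this table is 1.06 × 10⁻³.

## Synthetic cohort generator

The generator emulates exactly the features the analysis consumes:

* **Anatomy.** Seven axis-aligned ellipsoidal nuclei (VA, VLa, VLp, VPL,
  MD, CM, Pul) mirrored into both hemispheres on a 96³ × 1 mm centered
  grid; white matter dark (400 ± 30), thalamic gray bright (1000 ± 30)
  with per-nucleus contrast offsets (−80 … +120). VLp is rasterized last
  so its voxelization is exactly its analytic ellipsoid. Midline AC/PC
  (24 mm apart), third-ventricle wall at |x| = 2.5 mm.
* **Ablation.** Three concentric spherical zones: penumbra (r = 6 mm,
  scaled level 0.6), core (r = 1.7 mm ≈ 20 mm³, level 1.5), central
  hypointensity (r = 0.6 mm, level 0.5). Zone tissue is *set* to its
  level (in scaled units of the normal-thalamus distribution) plus mild
  texture (sd 0.05) — ablated tissue loses nucleus contrast and looks
  smoother than normal thalamus, which is also what makes the fixed
  1.25 threshold coherent: an additive boost on top of full tissue noise
  would push ~6 % of penumbra voxels over the threshold wherever the
  penumbra overlies a bright nucleus, because the P99 normalization by
  construction places 1 % of normal tissue above scaled 1.0. Non-
  hypointense core voxels are floored at scaled 1.3, so planted cores
  are recoverable by the threshold rule *by construction*. A zone with
  level exactly 0 leaves the image untouched (a zero-contrast ablation
  is invisible). The penumbra radius (6 mm, ≈ 900 mm³ whole ablation,
  realistic for an immediate post-treatment lesion with edema) is a
  calibration choice: it must be large enough relative to the targeting
  scatter that a 14-patient intersection retains ≥ 20 mm³, which a
  design-phase computation showed holds essentially always at these
  defaults (and fails for most seeds below ~5 mm).
* **Targeting variability.** Each ablation center is the hidden
  efficacious center plus N(0, 1.5² mm) per axis, re-drawn until inside
  the thalamus (honoring the planting precondition). Three of fourteen
  default patients are right-treated; their anatomy and ablation are
  mirrored, exercising the lateral flip exactly once in the pipeline.
* **Spaces.** Patient-to-template transforms are whole-millimetre
  translations. Integer offsets make nearest-neighbor mask transport
  exact; with fractional offsets every patient's template-space ablation
  boundary acquires ±1-voxel resampling noise that measurably degrades
  the consensus target for reasons unrelated to targeting variability.
  General affines (rotation, scaling) remain supported and tested in the
  resampler itself.
* **Outcomes.** `one_month = clip(round(baseline − α − β·f − ε), 0, 32)`
  with `baseline ~ clip(round(N(20, 3.78)))`, α = 8, β = 10 points per
  unit overlap, ε ~ N(0, 2²); `f` is the fraction of the hidden
  efficacious region covered by the patient's true core. The hidden
  region is a 4 mm³ sphere at (−14.5, −7.5, −1.0): inside the ventral
  half of the left VLp (the Vim), ~2 mm from the standard stereotactic
  target — a focal sweet spot distinct from the atlas-derived point.
  Its small volume makes `f` vary steeply with targeting error, giving
  the cohort both a realistic ~11-point mean improvement and enough
  overlap variance for the correlation analysis to have signal. All of
  baseline mean/SD and the ~12-point improvement match the treated
  cohort's printed moments.

What the generator does **not** emulate: MR physics (bias fields,
k-space artifacts, noise correlations), irregular lesion shapes,
nonlinear anatomical variability (the per-patient transforms are
translations; the real analysis uses diffeomorphic warps), segmentation
error in the traced penumbra, and longitudinal lesion evolution. Passing
tests therefore certify the *computational* pipeline — geometry,
morphology, statistics — not robustness to real-image confounds.

## Replicate surfaces and what they show

`correlation_recovery_surface` reruns the full imaging pipeline on
replicate cohorts (reduced 64³ grid; one replicate ≈ 0.7 s) and records
the Pearson correlation of both targeting metrics with the 1-month
score. `type_i_rejection_rate` uses a geometric fast path (overlap
fractions straight from the jittered centers — when β = 0 no imaging
step can introduce dependence) over 200 null cohorts; it sits at the
nominal 5 % level (0.045 at seed 1, recomputed by
`scripts/acceptance.py`).

A finding worth stating plainly: under this generative model the
consensus-target construction is a noisy estimator of the hidden
efficacious center. The intersection of all patients' ablations is
governed by the *extreme* centers — its deepest point is approximately
the minimax (Chebyshev) center of the scattered ablation centers — so
its placement error (~1.6 mm at n = 14, jitter 1.5 mm; commensurate with
the 1.7 mm core radius) is attracted toward outlier patients. This both
attenuates the correlation between measured and true overlap and gives
poorly-targeted patients spuriously high measured coverage. The
consequence, computed by the acceptance script: with the default effect
size the probabilistic-target overlap correlation is negative on average
and significant in ~16 % of replicates — consistently *more* often than
the standard-sphere metric (~1–3 %), preserving the method's directional
advantage — but far below what perfect measurement of the true overlap
would yield (~68 % power at these noise levels). A design-phase scan
over efficacious-region volumes (1–113 mm³), centers, overlap
denominators and jitters (0.75–2.0 mm) found no setting of the generator
that lifts the faithful construction above ~0.38. Leave-one-out target
construction (`leave_one_out_targets`) is provided to remove the
circularity of evaluating the target on the cohort that built it; it is
an extension, off by default.

## Problem sizes and numerical choices

Default phantoms are 96³ voxels at 1 mm (a full 14-patient cohort plus
analysis runs in ~15 s); the replicate surfaces use 64³, which still
contains the whole thalamic anatomy with >10 mm margin. Deterministic
tie-breaks are used everywhere a rank can tie (sphere rasterization,
erosion peel, Vim midplane, majority vote), so every pipeline output is
bit-reproducible for a fixed seed and configuration; the run summary
embeds the seed, package version and a configuration hash. Degenerate
inputs (empty masks, single-slice VLp, constant intensity distributions,
singular transforms, empty cohort intersections) raise `ValueError` with
stage and patient identification rather than propagating silently.
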