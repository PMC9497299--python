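# Methods

This note documents the models, conventions and design choices behind
`consenseg`, in the package's own terms. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Problem setting

When several radiation oncologists contour the same tumor (here: meningioma,
where somatostatin-receptor PET adds functional information to CT/MRI), their
delineations disagree. The package quantifies that inter-observer variability
(IOV), builds a consensus reference per lesion and modality condition, tests
whether adding PET information reduces IOV, and evaluates how well a simple
SUVmax-percentage threshold segmentation of the PET lesion approximates the
expert consensus.

## Data model and geometry

All inputs live on one shared regular voxel grid (`ImageGrid`): shape,
spacing in mm, origin, and orthonormal direction cosines, exactly as a NIfTI
affine encodes them. Voxel indices are 0-based; the world coordinate of voxel
`i` is `origin + direction @ (spacing * i)` with no additional half-voxel
offset. The pipeline *refuses* inputs on different grids (tolerance 1e-3 mm)
instead of resampling: metric comparisons assume voxel-wise correspondence,
and silent resampling would corrupt them. Registration and DICOM-RT
conversion are explicitly out of scope; convert externally and resample in
your planning system before use. Which common grid to resample to (PET vs CT)
is a workflow decision the package deliberately does not make.

## Agreement metrics

For an observer mask A and reference B on the same grid:

* **Dice** `2|A∩B| / (|A|+|B|)` — undefined (an error) only when both masks
  are empty.
* **Volume** — occupied voxels × voxel volume, reported in cm³.
* **Hausdorff distance** — the classical symmetric maximum over directed
  nearest-boundary distances, in mm. Boundaries are occupied voxels with a
  face-adjacent (6-neighborhood) background or out-of-grid neighbor;
  distances are Euclidean between voxel centers in physical coordinates.
  A `percentile` parameter gives HD95-style robust variants; the default is
  the 100th percentile, the form consistent with reporting large outliers
  caused by stray contour fragments. The implementation samples a Euclidean
  distance transform at boundary voxels; the test suite requires exact
  agreement with an all-pairs brute-force scan, so the fast path is an
  optimization, never an approximation.

Voxel-center distances (rather than sub-voxel surface meshes) make every
number reproducible bit-for-bit at the cost of a sub-voxel-scale bias on very
coarse grids; this is a documented convention, shared by both the
implementation and its oracle.

## Binary STAPLE consensus

The consensus reference is estimated by binary STAPLE: the unknown true
segmentation is a latent voxel field T, each observer j a noisy channel with
sensitivity `p_j = P(D_j=1|T=1)` and specificity `q_j = P(D_j=0|T=0)`,
assumed voxel-wise independent. EM alternates a per-voxel posterior
(E-step) with closed-form performance updates (M-step); see the module
docstring for the exact formulas. Choices that matter:

* **Initialization** `p_j = q_j = 0.9` — standard, avoids the absorbing
  state at exactly 1.
* **Prior γ** is fixed during EM, by default at the mean observer occupancy
  fraction. This is the common published heuristic, and a knowably *biased*
  one: the expected occupancy is `γ·p̄ + (1−γ)(1−q̄)`, which exceeds the true
  prevalence as soon as specificity is imperfect. At the agreement levels of
  well-trained raters the effect on the consensus is negligible, but when
  false-positive rates reach ~20% the sensitivity estimates can be biased
  low by several points. Supplying a known prevalence through
  `prior_mode="fixed"` removes the bias; updating γ within EM is a
  non-goal. The parameter-recovery test runs under the exact generative
  model (including its true prior) for this reason.
* **Region restriction**: EM runs inside the bounding box of the union of
  masks padded by 5 voxels (configurable); outside voxels are unanimous
  background with weight 0 and are excluded from γ and the M-step sums.
  Without this, the overwhelming empty background of a head-sized volume
  drives γ toward 0. A test checks consensus insensitivity to the margin.
* **Convergence**: relative change of ΣW below 1e-6, max 100 iterations.
  The observed-data log-likelihood is recorded each iteration and asserted
  non-decreasing on every run — the EM guarantee, used as a self-check.
* **Consensus cutoff** 0.5 on the posterior weights, with ≥ (ties occupied).
* Numerics: E-step in log space, performance parameters clipped to
  `[1e-12, 1−1e-12]` so unanimous raters converge to 1 cleanly. Two
  perfectly disagreeing raters are degenerate-but-defined: every voxel has
  one vote and the posterior follows the prior.

Only the spatially unregularized binary algorithm is implemented; MRF-
regularized, multi-label and probability-input variants are non-goals. The
implementation is cross-checked against SimpleITK's STAPLE filter on
simulated raters (matching performance estimates and consensus).

## SUVmax-percentage threshold segmentation

Per lesion, SUVmax is the maximum SUV inside a lesion ROI (by default the
union of available observer masks, bounding-box-padded by 3 voxels — "within
the lesion" needs an operational definition and this is ours). The
segmentation at threshold t is the 26-connected component, seeded at the
SUVmax voxel, of `{SUV ≥ (t/100)·SUVmax}`, using ≥ so t = 100% retains the
seed. Growth is *unclipped* by default, which knowingly reproduces the
clinical failure mode of leaking into nearby physiological hot spots (the
pituitary gland under SSTR tracers); `clip_to_roi=True` is the safeguard,
and a constructed decoy phantom pins both behaviors. Connectivity (6/26) and
the ≥ convention are configuration, since reasonable implementations differ.

The sweep evaluates t = 0.0, 0.5, …, 100.0 (201 thresholds), scores each
segmentation against the consensus by Dice (empty segmentations score 0 so
the mean stays defined), and selects the threshold maximizing the unweighted
mean Dice over lesions. Argmax ties break toward the smaller threshold — the
more inclusive gross tumor volume, the conservative radiotherapy choice.
Because voxel values are discrete, an interval of thresholds can produce the
identical region; the planted-isocontour phantom generator therefore reports
the canonical (smallest-grid-value) representative of that interval, computed
directly from the voxel values adjacent to the region, and threshold-recovery
tests compare against it. A tuned threshold is transferred to a validation
cohort with no re-optimization.

## Paired statistics

Conditions are compared by a two-sided Wilcoxon signed-rank test on
(lesion × observer) pairs: zero differences dropped (Wilcoxon's original
treatment), exact null for n ≤ 25, normal approximation with continuity
correction above. The exact branch is pinned against exhaustive enumeration
of all 2ⁿ sign assignments, and a 200-replicate null simulation checks the
type-I error at the 5% level. The threshold-vs-volume relationship uses
Spearman's rank correlation (average ranks on ties, two-sided p), pinned
against a rank-then-Pearson oracle. Alpha is 0.05 and p-values are reported
raw; multiplicity correction across the three metrics is a non-goal. Lesions
are treated as independent even when several share a patient — exact for the
synthetic generator, a caveat for real cohorts.

## Synthetic study generator

Patient imaging of this kind is not shareable, so the generator supplies the
entire test bed with known ground truth.

**Phantoms.** An ellipsoidal lesion (truth = voxel centers inside the
ellipsoid) of uptake 5–15 SUV on a 0.3-SUV background, convolved with an
isotropic Gaussian of FWHM 7 mm standing in for the reconstruction point
spread, plus iid Gaussian noise (sd 0.1 SUV), clipped at 0, on a
64×64×32 grid of 4×4×5 mm voxels — PET-like scale kept small enough for fast
iteration. The default volumes (a few to a few tens of cm³) match skull-base
meningioma scale. Noise is Gaussian in the image domain, not Poisson in
projections: reconstruction simulation is out of scope and only image-domain
statistics reach the pipeline. A blurred-ball radial-profile oracle (closed
form via erf, root-solved for the isocontour radius) verifies the phantom's
isocontour volumes to within 5%.

**Observers.** Two error models:

* `iid_flip` — voxel-wise independent errors with planted per-observer
  (p_j, q_j): exactly STAPLE's generative model, making parameter recovery a
  well-posed test.
* `boundary_field` — the truth surface displaced by a per-observer constant
  bias plus a smooth zero-mean Gaussian field (white noise filtered at a
  10 mm correlation length, scaled to a target sd in mm): contiguous over-
  and under-contoured patches, the realistic shape of rater disagreement.

**Study defaults.** 27 lesions × 5 observers × two conditions, mirroring a
single-institution cohort; the independent validation cohort is 12 lesions ×
3 observers with the PET-assisted condition only. The anatomical-only
condition uses boundary sd 3.8 mm / bias sd 1.8 mm, the PET-assisted
condition 3.2 / 1.5 mm. These levels were chosen once so the default study
sits at clinically realistic agreement (mean Dice ≈ 0.84 vs ≈ 0.88,
Hausdorff ≈ 9 vs ≈ 7 mm) with the PET-assisted condition tighter — the
qualitative IOV-reduction effect the pipeline is designed to detect. All
generators are pure functions of their parameters and a seed; identical
seeds reproduce bundles byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomical background structure and osseous
infiltration, reconstruction artifacts and Poisson noise, non-ellipsoidal
lesion shapes, inter-lesion correlation within a patient, and observers who
read anatomy rather than geometry. Consequences are visible in the synthetic
optimum: the Dice-maximizing threshold lands near 40% of SUVmax with mean
Dice ≈ 0.96, whereas clinical SSTR-PET meningioma delineation favors much
lower thresholds with far lower consensus agreement — high-contrast
blurred ellipsoids are simply easier than real lesions. The pipeline's
claims are therefore about *correctness of the machinery* (metrics, EM,
sweep, statistics), validated against oracles and planted parameters, not
about reproducing clinical threshold values.

## Problem sizes and determinism

Default test-time problem sizes: ~1e5-voxel grids for parameter recovery,
20 planted-isocontour phantoms for threshold recovery, 200 record-level null
replicates for test calibration, and ten 27-lesion studies for the planted
end-to-end effect — sizes chosen to give stable statistics while keeping the
whole suite fast on one CPU. Every random quantity flows from an explicit
seed (numpy `SeedSequence` spawning), and the end-to-end driver writes a
manifest of every planted parameter and seed alongside its outputs.

## Known limitations

* Mean-occupancy prior bias at high false-positive rates (discussed above).
* Hausdorff on voxel centers under-resolves sub-voxel boundary differences.
* The threshold sweep recomputes connected components per threshold; at
  clinical grid sizes (say 168×168×74) a full 201-step sweep over dozens of
  lesions is minutes, not seconds.
* `iid_flip` observers are unrealistically rough at equal error rates;
  use `boundary_field` for anything meant to look like a human contour.
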