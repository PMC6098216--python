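# Methods

This note documents the models, parameters and numerical choices behind
`fstseg`, and what the synthetic experiments do and do not demonstrate.

## The feature-space transformation

**Model.** Let **x**ᵢˢ ∈ ℝᵈ be a training voxel's feature vector under the
source protocol *s*, and let {(*z*ᵢˢ, *z*ₗᵗ)} be voxelwise feature
correspondences obtained from unlabeled rescan pairs: images of the same
subject under *s* and the target protocol *t*, aligned upstream so voxel
pairing is exact. The transformation maps

f_{s→t}(x) = x + medoid( zₗ₁ᵗ − z𝚌₁ˢ, …, zₗₖᵗ − z𝚌ₖˢ ),

where z𝚌₁ˢ…z𝚌ₖˢ are the k nearest stored source samples of x and the
medoid is the member vector with minimal total Euclidean distance to the
rest. Because x is close to its nearest source sample, f_{s→t}(x) ≈ zₗᵗ,
i.e. approximately a draw from the target feature distribution. Using the
medoid rather than the mean guarantees the applied shift is an observed
transformation, which keeps the map on the data manifold when a voxel's
neighborhood spans multiple tissues.

**Assumptions.** (1) Rescan pairs exist and anatomy is unchanged between
the two acquisitions; (2) alignment is exact (in the phantoms it is by
construction; with real data residual registration error adds
correspondence noise); (3) tissue classes map one-to-one between
protocols — the scanner change must be (locally) invertible in feature
space, which a monotone global remap plus per-tissue mean changes
satisfies; (4) source and target features live in the same ℝᵈ. The types
admit differing source/target dimensionalities, but `apply_fst` rejects
them: the additive form above requires a shared space, and no principled
projection exists without extra modeling.

**Parameters.** k (neighbors, default 1) trades fidelity against
smoothness of the map; N (pairs pooled, default all) only grows the
correspondence set. The pipeline transforms only the 10 appearance
features; the multi-atlas prior is scanner-independent and bypasses the
FST. Spatial coordinates are deliberately excluded from the FST feature
space so the map is driven by appearance, not location.

**Determinism.** Nearest-neighbor queries run on a k-d tree; results are
re-sorted by (distance, row index) so equal-distance ties resolve to the
lowest pooled row index, reproducibly across runs and library versions
(the tree fetches 8 extra candidates to resolve boundary ties). Medoid
ties also break to the lowest index. The test suite verifies tree queries
against brute force and medoid selection against exhaustive enumeration.

## Segmentation pipeline

1. **Range matching.** Each image is affinely rescaled so its in-mask 4th
   and 96th intensity percentiles map to 0 and 1. Percentiles are
   per-image (not pooled per scanner). Constant images are rejected.
2. **Appearance features.** Intensity; Gaussian-smoothed intensity,
   gradient magnitude (L2 norm of first derivatives) and Laplacian (sum
   of second derivatives) at σ ∈ {1, 2.2, 5} mm. σ is converted to voxel
   units per axis (anisotropic kernels allowed); derivatives are per mm.
   Filtering uses reflect padding — avoiding edge darkening near the mask
   border — and a truncation radius of 6σ, at which the derivative
   kernels' DC response (~1e-8) is negligible, so constants have
   numerically zero derivatives.
3. **Standardization.** Appearance features are z-scored per scanner
   (population SD; the pooled voxel counts make the convention
   immaterial, but it is fixed for reproducibility). When rescan pairs
   are present, each scanner's parameters are fit on the brain-mask
   voxels of *that scanner's pair images*: both pools then contain the
   same anatomies, so parameter differences reflect the scanner effect
   alone — and two identical scanner models yield bitwise-identical
   normalizations, making the FST an exact no-op in the same-scanner
   limit. Without pairs, the fallback pool is all images of the scanner.
   The atlas-prior feature is z-scored within the ROI (it is ~0 outside),
   fit on the pooled training-image ROI voxels.
4. **Atlas prior and ROI.** The prior is the voxelwise mean of registered
   binary atlases per structure (left/right separately). The ROI is
   prior ≥ 0.10 (inclusive); majority vote is prior ≥ 0.5, with the tie
   at exactly 0.5 counted as foreground, consistent with the inclusive
   ROI rule and necessary for even atlas counts. Training images' priors
   include their own registered atlas by default; a leave-self-out switch
   exists because either convention is defensible.
5. **Classification.** One Gaussian-kernel SVM per hemisphere (left and
   right appearance differs slightly), trained on a uniform random,
   seeded subset of ROI voxels, labels as sampled (no rebalancing).
   Library default subset size is 10 000; the phantom experiments use
   2 000 because a 48³ study pools only ~6–8 k ROI voxels per hemisphere.
   Hyperparameters (C, γ) default to fixed values (10, 0.1) in the
   experiment driver; leave-one-group-out tuning is available, with mean
   held-out foreground Dice as the selection criterion (matching the
   evaluation metric; the tuning objective is otherwise an open choice)
   and ties broken toward smallest C then smallest γ. Prediction decides
   by the sign of the margin; voxels outside both ROIs are background; in
   ROI overlaps the larger decision value wins (a deterministic rule for
   a case the phantoms never produce).

## Evaluation

Per subject: Dice per structure, averaged left/right. Volumes are voxel
counts × voxel volume. Bland–Altman bias is mean(a−b) with limits
bias ± 1.96·SD (population SD); each structure contributes one point.
Method differences use the two-sided Wilcoxon signed-rank test on
per-subject mean Dice (exact null for n ≤ 25 without ties, normal
approximation otherwise; zero differences dropped; all-zero differences
reported as a flagged, non-significant degenerate case). Dice of two
empty masks is defined as 1.0 (perfect agreement on absence). Comparison
summaries mark the best method and every method not significantly worse.

## Synthetic phantoms

**What they emulate.** A brain-sized ellipsoid with CSF shell, gray ring
and white core, plus two lateralized ellipsoidal target structures with
seeded position/size jitter and a smooth random deformation (~0.8 voxel).
A scanner model renders an anatomy as: per-tissue means → monotone gamma
remap → smooth multiplicative bias field → Gaussian PSF blur → additive
Gaussian noise, in that order. Presets: `reference` (means bg 0.02 /
CSF 0.20 / gray 0.50 / white 0.80 / structure 0.62, γ=1, 5 % bias, 1 mm
PSF, noise SD 0.03), `harp_like` (a mild gap: slightly shifted means,
γ=1.1, 10 % bias) and `rss_like` (a severe gap: inverted contrast —
CSF 0.85 / gray 0.50 / white 0.22 / structure 0.38 — γ=1.6, 20 % bias,
1.5 mm PSF, noise SD 0.05). The structure means sit between gray and
white with a contrast of roughly 2–4× the noise SD after blur: visible
but not trivial, as for medial-temporal structures in T1 images.
"Registered" atlases are training label volumes warped by a smooth
random field of ~1.5 voxels, standing in for residual non-rigid
registration error (registration itself is upstream of this package).

**Default study.** 3 labeled training subjects (scanner A), 3 labeled
test subjects (scanner B), 2 unlabeled rescan pairs, 48³ voxels at 1 mm —
sizes chosen so the full comparison runs in seconds while every pipeline
stage operates at realistic per-image voxel counts (~35 k brain voxels).
The rescan-reproducibility experiments use 5 pairs, segmenting each pair
subject with an FST fitted on the *other* pairs (leave-one-subject-out).

**Seeding.** Everything is a pure function of (config, master_seed): each
anatomy, render and atlas warp draws from a named `SeedSequence` spawned
as (master_seed, role, subject index, scanner key). The scanner key is a
digest of the acquisition parameters, so distinct scanner models get
independent noise while two identical models produce identical
acquisitions — which is what makes the same-scanner reduction exact
rather than approximate.

**What passing does not show.** The phantoms have no partial-volume
mixtures beyond PSF blur, no anatomy-correlated bias fields, no
registration error on the rescan pairs, no pathology, and Gaussian noise
instead of Rician. Results demonstrate the method's internal correctness
and its qualitative behavior under controlled appearance gaps — not
expected Dice levels on clinical data.

## Known limitations

- The FST requires same-subject pairs across the two protocols;
  different-subject pairs are out of scope (anatomy differences would
  leave many voxels without a true correspondence).
- `svm_fst_intensity` (transform intensity only, recompute the other
  features) is included as a comparison method and is expected to
  underperform the full FST: the intensity map is not smooth in image
  space, so features derived from the transformed image can be far from
  genuine target features.
- Correspondence uses all joint-mask voxels; optional seeded subsampling
  exists only through building the tables on a reduced mask.
- With the small phantom test sets (n = 3 subjects), the signed-rank test
  has no power (minimum two-sided p = 0.25), so summary bolding typically
  marks all methods; it becomes informative at realistic subject counts.
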