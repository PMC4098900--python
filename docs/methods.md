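# Methods

This note documents the models, algorithms and numerical choices behind
`radrobust`, and what the synthetic study can and cannot say about real
data.

## Study design

Per tumor, one intensity volume and eleven segmentations: five
independent "manual" delineations and six "semi-automatic" ones (three
observers, each running seeded GrowCut twice). Feature reproducibility
is quantified per feature across segmentation sets:

* manual inter-observer set (k = 5) — two-way mixed ICC, absolute agreement;
* two semi-automatic inter-observer sets (k = 3 each, one run per
  observer) — same ICC model, the two sets averaged per feature;
* three intra-observer pairs (k = 2 runs) — one-way ICC, averaged.

Absolute agreement is deliberate for the inter-observer sets: a rater
who systematically over-segments should be penalized, not normalized
away. For intra-observer pairs the "raters" are algorithm restarts with
no meaningful column identity, hence the one-way model.

## Tumor phantoms

A phantom is a sphere of radius R (6–10 mm across tumors) with
`spiculation_count` Gaussian surface bumps of amplitude 0.8–2 mm and
angular half-width 0.35 rad, a core intensity of 0–100 HU on a −300 HU
background, a partial-volume boundary ramp (Gaussian blur of the
core/background step, FWHM 2.5 mm), and spatially correlated texture
(Gaussian-filtered white noise, correlation length 2–4.5 mm, SD
10–30 HU) so texture features genuinely vary between tumors — without
between-tumor variance the ICC numerator would be empty. The grid is
44×44×28 voxels at 1×1×2 mm, the slice-direction anisotropy typical of
thoracic CT.

Two deliberate departures from a naive "lung lesion on air" phantom:

* the background sits at −300 HU rather than −800 HU. With an extreme
  background, the fixed-bin discretization (anchored at the in-mask
  minimum) becomes hypersensitive to single boundary voxels: one rim
  voxel in or out moves the anchor by several bins and destabilizes
  every gray-level-dependent feature for *both* observer groups. A
  moderate background keeps that instability at a realistic level while
  preserving strong lesion contrast;
* the boundary ramp is what gives GrowCut genuine run-to-run
  variability. On a hard step edge the automaton reproduces the same
  boundary for any reasonable stroke placement and the semi-automatic
  arm of the study degenerates to zero variance.

## Observer models

**Manual.** The truth boundary is displaced by a smooth random field:
mask = {x : sdf(x) ≤ d(x) + b}, where sdf is the signed Euclidean
distance transform of the truth (mm, negative inside), d is
Gaussian-filtered white noise rescaled to SD `boundary_jitter_sd`
(default 0.6 mm) with correlation length equal to the contour-smoothing
FWHM, and b is a per-observer systematic bias drawn once per study
(SD 0.3 mm) — an observer's generous or tight style is consistent
across tumors. The contour is then smoothed (Gaussian blur of the
indicator, re-threshold at 0.5, FWHM 3 mm), modelling the way hand
contours iron out fine surface detail. Implementing the displacement on
the distance transform rather than on a spherical parameterization of
the surface keeps the model well-defined for spiculated, non-star-convex
shapes while giving the same variance control.

**Semi-automatic.** Foreground strokes (4 short straight strokes) are
placed uniformly at random inside the surface eroded by 20% of the
effective radius; background marks are placed on a shell 1–3 erosion
margins outside the surface, one near each of 14 jittered directions
(axes and diagonals), mimicking a user marking around the tumor.
GrowCut then runs with ROI margin 2 voxels and an iteration cap of 500
(non-convergence raises), followed by largest-component island removal.
The observer's systematic bias shifts the stroke margins (SD 0.15 mm).

Under these defaults, manual inter-observer pairwise Dice is ≈0.90 and
semi-automatic ≈0.99, and the study-level orderings come out as
configured: semi-automatic inter-observer ICC above manual, and
intra-observer ICC highest. No overlap statistics exist to calibrate
against, so the defaults were chosen once to produce that qualitative
ordering at plausible magnitudes and are exposed in `StudyConfig`.

## GrowCut

Standard competitive cellular automaton. Strength of seeded voxels is 1;
neighbour q conquers p iff `g(|C_p − C_q|)·θ_q > θ_p`,
`g(x) = 1 − x/max_diff`, where `max_diff` is the intensity range over
the ROI, fixed before iterating so the attack rule does not drift.
Design choices:

* 26-connectivity (consistent with the texture neighborhood),
  configurable to 6;
* synchronous updates from the previous state with a fixed neighbour
  visiting order — fully deterministic, earlier offsets win ties;
* seeded voxels are never conquered;
* the ROI is the convex hull of the seeds plus a margin. The hull is
  taken over the 8 cube corners of each boundary seed voxel, so single
  voxels and straight strokes (rank-deficient point sets) still span a
  valid hull;
* iteration stops at a full fixed point (no label *and* no strength
  change). Strengths are non-decreasing and drawn from the finite set of
  path products of g-factors, so this terminates; stopping only on label
  stability could let a strength update enable a label flip one sweep
  later, which would break idempotence at convergence.

## Feature definitions

Fixed bin width (default 25 HU) anchored at the in-mask minimum:
`level = 1 + floor((I − min)/width)`. A fixed width keeps one gray-level
step physically comparable across tumors, which a fixed bin *count*
would not.

First-order (15): energy, entropy, kurtosis, maximum, mean, mean
absolute deviation, median, median absolute deviation, minimum, range,
root mean square, skewness, standard deviation, uniformity, variance.
Moments are population moments; kurtosis is the non-excess m4/m2²;
entropy and uniformity use the same discretization as the texture
matrices (one discretization pass, consistent L). Degenerate inputs
(single voxel, zero spread) yield NaN, never a silent zero.

Shape (8): volume, mesh surface area A, A/V, compactness 1
`V/(√π·A^{3/2})`, compactness 2 `36πV²/A³`, spherical disproportion
`A/(4πR²)`, sphericity `π^{1/3}(6V)^{2/3}/A`, maximum 3D diameter
(largest pairwise surface-voxel-center distance, computed on the convex
hull of the boundary voxels). The surface mesh is marching cubes at the
0.5 level of the binary indicator *lightly smoothed* (σ = 0.8 voxel):
meshing the raw binary grid overestimates a digitized sphere's area by
≈8%, while after smoothing the r = 20 sphere meshes to within 0.1% of
4πr². The cost is rounded corners on small objects; a voxel-face area
mode is available via `surface_mode="voxel"`.

Texture (33): 22 GLCM features and 11 GLRLM features, computed per
direction and averaged arithmetically over the 13 directions (never
from a pooled matrix); directions on which a feature is undefined are
skipped. GLCMs are symmetric (pairs counted in both orders) and
normalized; GLRLM entry (g, r) counts maximal runs, broken at the mask
boundary, and run percentage divides by the in-mask voxel count. Where
several formula variants circulate, this package uses: homogeneity 1
with |i−j|, homogeneity 2 with (i−j)²; IDMN/IDN normalized by L; sum
variance centred on the sum average; GLCM variance centred on the
marginal mean; entropies in bits. All matrix features are verified
against naive triple-loop recomputation to 1e-10.

## Statistics

ICC estimators are plain ANOVA mean-square ratios (verified against
explicit sum-of-squares loops to 1e-10). Raw estimates can be negative;
they are clamped to [0, 1] for reporting and classification but the raw
value is preserved in `ICCResult`. Features undefined for a tumor are
dropped row-wise per feature, with the count logged — not imputed. An
all-constant ratings matrix yields an undefined-ICC sentinel, reported
as "unclassified".

The Wilcoxon rank-sum test uses exact enumeration for combined n ≤ 20
without ties and the tie-corrected normal approximation otherwise
(`scipy.stats.mannwhitneyu` backend); the comparison of per-feature ICC
vectors is unpaired, exactly as the study design prescribes, with a
paired signed-rank variant available for sensitivity analysis. No
multiple-testing correction is applied anywhere, by design.

Z-score normalization for the range analysis is per tumor-feature over
its 11 segmentation values (the default); a pooled per-feature mode
exists because the normalization reference is genuinely ambiguous, and
the report records which mode produced it. Zero-spread tumor-features
get z = 0 and are flagged.

## Problem sizes and runtime

Default study: 20 tumors × 11 segmentations on 44×44×28 grids. One full
in-memory study runs in ≈25 s on one CPU; the replicated experiment
(`ordering_replicates`, 20 studies) in ≈8 minutes. Tests use scaled-down
studies (1–4 tumors) except the replicate experiment itself.

## Limitations

* Phantoms are blurred spiculated spheres with stationary Gaussian
  texture; real tumors have non-stationary texture, pleural attachment,
  vessels and cavitation, all of which make both segmentation arms
  harder in ways the generator does not model.
* The manual-observer model reduces human contouring to a smooth random
  boundary displacement plus bias; it has no slice-wise anisotropy of
  attention, no window/level effects, no anatomical priors.
* Passing the qualitative ordering here shows the pipeline measures what
  it claims under controlled conditions — it does not certify effect
  sizes on patient data, and the patient-level ICC values from the
  original cohort are not reproducible from synthetic phantoms.
* No PET information, no DICOM, no wavelet/filtered feature variants,
  no 2D slice-wise features.
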