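# radrobust

Quantifying how robust radiomic features are to the way a tumor is
segmented: manual slice-by-slice delineation versus semi-automatic
GrowCut region growing.

## The problem

Radiomics pipelines reduce a 3D tumor image to a vector of quantitative
descriptors — intensity statistics, shape measures, texture features —
which then feed prognostic or predictive models. Every one of those
numbers depends on the segmented volume of interest, and manual tumor
delineation is notoriously variable between observers. This package
implements, end to end, a study design for asking: *if several observers
segment the same tumors, how reproducible is each feature, and does a
semi-automatic segmentation make the features more reproducible than
manual contouring?*

Because the original patient CT scans behind this design are not
redistributable, the package ships a first-class synthetic data module:
spiculated 3D tumor phantoms with CT-like intensities and anisotropic
voxel spacing, plus simulated observers. Per tumor it produces 5
"manual" masks (independent smooth boundary perturbations with
per-observer systematic bias) and 6 "semi-automatic" masks (3 observers
× 2 GrowCut runs from randomized seed strokes), with manual
inter-observer variability configured larger than semi-automatic
run-to-run variability.

## What is implemented

* **GrowCut** — competitive region-growing cellular automaton. A voxel
  `p` with strength θ_p is conquered by neighbour `q` iff
  `g(|C_p − C_q|)·θ_q > θ_p` with `g(x) = 1 − x/max_diff`, inside an ROI
  built as the convex hull of the user strokes plus a margin; synchronous
  updates, deterministic tie-breaks, island removal afterwards.
* **56 radiomic features** — 15 first-order intensity statistics, 8
  3D shape descriptors (mesh surface area, sphericity, compactness, ...),
  and 33 texture features (22 from gray-level co-occurrence matrices, 11
  from gray-level run-length matrices), computed per direction over the
  13 symmetric directions of the 26-neighborhood at distance 1 and
  averaged, after fixed-bin-width discretization (default 25 HU).
* **Reproducibility statistics** — intraclass correlation from ANOVA
  mean squares: two-way mixed-effects absolute agreement
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` for
  inter-observer sets, one-way `ICC = (MSR − MSW)/(MSR + (k−1)MSW)` for
  intra-observer run pairs; classification into high (ICC ≥ 0.8), medium
  (0.8 > ICC ≥ 0.5) and low (ICC < 0.5) reproducibility; two-sided
  Wilcoxon rank-sum comparisons; and Z-score-normalized feature-range
  analysis across the 11 segmentations of each tumor.

The statistical surface follows the model/results idiom:
`ReproducibilityStudy(feature_table).fit()` returns a
`ReproducibilityResults` with the per-feature ICC tables, group
summaries, classification counts, comparison tests and a `summary()`
report.

## Worked example

```python
from radrobust import StudyConfig
from radrobust.pipeline import run_study

report = run_study(StudyConfig(n_tumors=20, master_seed=5), out_dir="study_out")
print(report.results.summary())
```

prints (exact numbers depend on the master seed):

```
Reproducibility of radiomic features
======================================
manual inter-observer ICC                     0.65 +/- 0.31
semi-auto inter-observer ICC (avg of sets)    0.84 +/- 0.24
semi-auto intra-observer ICC (avg of pairs)   0.90 +/- 0.15
...
features with higher semi-auto ICC: 51/56
rank-sum manual vs semi-auto ICC: p = ...
z-normalized range comparison (manual vs semi-auto):
  range  p = ...
```

Reading: features extracted from the semi-automatic segmentations agree
better across observers (higher mean ICC) and spread over a
significantly smaller normalized range than the manually delineated
ones; repeated GrowCut runs by the same observer are the most
reproducible of all. `study_out/` holds every intermediate — volumes and
masks (NRRD), the manifest, the 56-column feature CSV, the per-feature
ICC table and the JSON report — so each stage can be re-run and every
reported number recomputed.

A command-line interface covers the same stages:

```bash
radrobust run-study --out study_out --seed 5
radrobust simulate --out data --seed 1
radrobust segment --volume v.nrrd --seeds s.nrrd --out mask.nrrd
radrobust extract --volume v.nrrd --mask mask.nrrd --out features.csv
radrobust compare --features features.csv --out analysis
```

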