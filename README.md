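# hippovol

Structural-MRI feature extraction and classification for early detection of
Alzheimer's disease (AD), built around two kinds of atrophy markers that are
measurable on a single spatially normalized coronal T1 slice:

* **Tissue volumetry** — grey matter (GM), white matter (WM) and
  cerebrospinal fluid (CSF) pixel counts obtained by intensity
  thresholding. GM is described by a threshold range `[lo, hi]`: pixels
  with `f(i,j) < lo` are CSF, `lo <= f(i,j) <= hi` are GM, `f(i,j) > hi`
  are WM, and `Volume_X = Σ_slices Σ_i Σ_j [f(i,j) ∈ class X]`.
* **Hippocampal area** — the hippocampus shrinks in the earliest disease
  stages. In a 498×498 normalized coronal slice the left and right
  hippocampi fall inside fixed rectangles, (130, 300)–(225, 360) and
  (280, 300)–(375, 360) (column, row; half-open). Each ROI is binarized at
  `lo`, cleaned by morphological opening keeping the largest object,
  trimmed to that object's bounding box, and the GM-range pixels of the
  retained object are counted as the hippocampal area.

The five features (GM/WM/CSF volumes, left/right hippocampal areas) feed
three base classifiers — an RBF-kernel SVM (C, γ tuned by inner CV), a
2×3 multilayer perceptron (learning rate 0.3) and a pruned univariate
decision tree (confidence factor 0.25) — combined by majority voting:

    ensemble(x) = +1 (AD)   if  Σ_i [clf_i(x) = +1] > n/2
                  −1 (ctl)  otherwise

Evaluation is stratified 10-fold cross-validation reporting accuracy,
specificity (controls) and sensitivity (patients) as percentages.

Because real cohort data (e.g. OASIS) cannot be bundled, the package ships
a **phantom generator**: synthetic skull-stripped coronal slices with three
tissue intensity classes, elliptical hippocampi inside the standard ROIs, a
tunable atrophy factor, Gaussian noise and an optional bias field — with
exact ground truth, so every stage is testable without downloads. It is
intended for researchers and students prototyping ROI-based neuroimaging
classification pipelines.

## Worked example

```python
import pandas as pd
from hippovol import (PhantomSpec, CohortSpec, generate_slice, generate_cohort,
                      estimate_thresh, crossvalidate, FeatureTable)
from hippovol.pipeline import extract_features

# one AD-like phantom (30% atrophy, noise sd 8)
img, truth = generate_slice(PhantomSpec(noise_sd=8.0, atrophy=0.3), seed=42)
print(extract_features(img))
# {'vol_gm': 28193, 'vol_wm': 106489, 'vol_csf': 31514,
#  'left_area': 373, 'right_area': 373, 'thresh_lo': 84.6, 'thresh_hi': 139.4}
print(truth.hippo_left_area, truth.hippo_right_area)   # 373 373  (exact recovery)

# a small cohort, end to end
cohort = generate_cohort(CohortSpec(n_ad=15, n_control=15, seed=0))
rows = [{"subject_id": f"sub-{i:04d}", **extract_features(im), "label": tr.class_label}
        for i, (im, tr) in enumerate(cohort)]
report = crossvalidate(FeatureTable(pd.DataFrame(rows), subset="left"), k=10, seed=0)
print(report.summary())
```

```
Stratified 10-fold cross-validation (subset='left', seed=0)
classifier      ACC%    SPE%    SEN%   tp   fn   tn   fp
svm           100.00   100.0   100.0   15    0   15    0
mlp           100.00   100.0   100.0   15    0   15    0
tree          100.00   100.0   100.0   15    0   15    0
ensemble      100.00   100.0   100.0   15    0   15    0
```

The extracted `left_area`/`right_area` are hippocampal cross-sections in
pixels (here equal to the painted ground truth); `vol_gm` etc. are tissue
pixel counts of the slice; the report rows are pooled confusion counts and
derived metrics per classifier. With the default cohort settings the AD
group's hippocampal areas are far smaller than the controls', so all
classifiers separate the groups perfectly at this sample size.

The same flow is available from the shell:

```bash
hippovol simulate --n-ad 37 --n-control 48 --seed 0 --out cohort/
hippovol run --input cohort/ --out results/ --subset left --k 10 --seed 0
hippovol extract --input cohort/sub-0000.png --out areas.csv
```

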