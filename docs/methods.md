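# Methods

## Scope and assumptions

The pipeline operates on single 2D coronal slices that are already
spatially normalized (Talairach-like frame, 498×498 convention),
bias-corrected and skull-stripped; those preprocessing steps are the
domain of external tools (FSL, BrainSuite) and are deliberately out of
scope. A hook for user-supplied preprocessed images exists in the readers
(`io.read_slice_png`, `io.read_nifti_slice` with `slice_axis`/
`slice_index`), and the only in-scope preprocessing is motion correction
by averaging repeat scans, which assumes the scans are pre-aligned.

Coronal slices are used because they are perpendicular to the long axis of
the hippocampus, so a cross-sectional area is a meaningful size measure.
Which coronal slice of a 3D acquisition to quantify is a study design
choice the package leaves to configuration (`slice_index`); the phantom
sidesteps it by generating one slice per subject.

## Tissue segmentation

Grey matter is described by a closed intensity range `[lo, hi]`; CSF is
strictly below, WM strictly above. This is the only self-consistent
reading of a *range-valued* threshold combined with `<`, `==`, `>`
semantics; the boundary convention (GM inclusive on both ends) is fixed
and documented here rather than configurable.

When no range is given it is estimated per slice as the two cut points of
a three-class between-class-variance maximization (multi-Otsu,
`skimage.filters.threshold_multiotsu`, 256-bin histogram) over in-mask
intensities. A histogram with fewer than three distinct values raises
`ThresholdEstimationError` advising a manual range. Pixels of intensity
exactly 0 are treated as non-brain when no explicit mask is supplied —
the convention of skull-stripped images and of the phantom. A global
(fixed) range can be passed instead via `PipelineConfig.thresh`.

Volumes are raw pixel counts summed over slices (`TissueVolumes.scaled`
multiplies by a voxel volume for physical units). Single-slice input is
valid; multi-slice summation is just a longer list.

## Hippocampus extraction

Per side: ROI crop → binarize at `lo` (tissue vs CSF/background) →
morphological opening (disk, radius 1 by default) → keep the largest
8-connected component (ties broken by the smallest top-left bounding-box
corner, so the choice is deterministic) → crop to the component's bounding
box expanded by a 2 px margin, clipped to the ROI, suppressing
non-component pixels → count the component's pixels that fall in the GM
range. The GM range doubles as the hippocampus separator because the
hippocampus is a GM structure surrounded by CSF: "high intensity" relative
to its CSF surround means GM-range intensity. The opening radius and
margin are configurable (`HippocampusConfig`).

ROI coordinates are read as (column, row), 0-based, half-open
`[x1, x2) × [y1, y2)`. For non-498 images the rectangles scale
proportionally with round-half-up; both rectangles can be overridden.

Degenerate inputs degrade gracefully: an ROI that is empty after opening
yields area 0 with a logged warning, never an exception, and per-subject
failures in the umbrella pipeline exclude the subject with a warning.

## Classification

Features may be any of eight named subsets (each feature alone, the three
volumes, the two areas, or all five). Base classifiers (scikit-learn):

* **SVM** — RBF kernel; C ∈ {0.1, 1, 10, 100}, γ ∈ {0.001, 0.01, 0.1, 1}
  chosen by 3-fold stratified grid search *inside each training fold*.
* **MLP** — 2 hidden layers × 3 neurons, SGD with learning rate 0.3,
  momentum 0.2, up to 500 epochs, seeded initialization. Non-convergence
  is logged, not fatal.
* **Decision tree** — entropy criterion with cost-complexity pruning.
  There is no exact C4.5 (gain ratio + pessimistic pruning) in
  scikit-learn, so the C4.5-style confidence factor cf ∈ (0, 0.5] is
  mapped monotonically onto pruning strength, `ccp_alpha =
  0.02·(0.5/cf − 1)`: cf = 0.5 disables pruning and the conventional
  cf = 0.25 gives α = 0.02. The contract kept is "a pruned univariate
  decision tree"; the pruning mechanism differs from C4.5's.

Features are z-scored inside each model's pipeline (training-fold
statistics only) by default — RBF kernels on raw pixel-count scales are
otherwise degenerate. The ensemble votes per subject; +1 (AD) needs a
strict majority, so a tie at an even number of voters returns −1
(control), the literal "otherwise" branch of the voting rule.

Cross-validation is stratified k-fold (default 10) with a seeded shuffle;
k is reduced to the smallest class size (≥ 2) with a warning when a class
is too small. Test predictions are pooled over folds into one confusion
matrix per classifier (micro-averaging); per-fold macro-averaging is the
other defensible choice but pooling keeps the counts interpretable at
small n. Sensitivity/specificity are reported as missing when their
denominator is zero.

## The phantom

`PhantomSpec` paints a circular brain (radius 230 px in the 498 frame):
CSF rim (12 px), cortical GM band (30 px), WM interior, with default
intensities CSF 60 / GM 110 / WM 170 on a 0–255-like scale — well-ordered
with comfortable margins, as the threshold model assumes. Each hemisphere
gets an elliptical GM-intensity hippocampus (semi-axes 20×12 px) centred
in its standard ROI, sitting in a CSF-intensity moat painted over the ROI
rectangle expanded by 6 px. The moat-fills-the-ROI choice makes the
hippocampus the only above-threshold object inside the ROI, mirroring real
coronal anatomy at hippocampal level where the ROI interior is dominated
by temporal-horn CSF; a thin ring would leave WM corner fragments that
could out-size a strongly atrophied hippocampus and break the
largest-object rule in a way real images do not.

Atrophy a ∈ [0, 1) multiplies the hippocampal semi-axes and the GM band
thickness by (1 − a): smaller hippocampi and less grey matter, the
structural signature the classifier exploits. Noise is additive Gaussian
(sd 8 by default) inside the brain only; the optional bias field is
`1 + A·cos(πx/w)·cos(πy/h)`, a smooth multiplicative stand-in for MRI
intensity inhomogeneity. Ground truth records the noiseless label map and
the exact painted ellipse pixel counts.

Cohorts draw per-subject atrophy from truncated normals on [0, 1):
AD mean 0.35, control mean 0.05, sd 0.05 by default (37 AD / 48
controls). These defaults produce a hippocampal-area separation of roughly
6 pooled standard deviations — a strongly atrophic, cleanly labelled
cohort. All generators are pure functions of (spec, seed); per-subject
seeds derive from the cohort seed via `numpy.random.SeedSequence`.

**What the phantom does not emulate:** anatomical shape variability,
partial-volume mixing at tissue boundaries, Rician noise statistics,
registration error, or inter-subject ROI placement error. Passing tests
therefore validate the *operators* (thresholding, morphology, voting, CV
bookkeeping) and their composition under controlled noise — not clinical
performance on real MRI, where tissue overlap and segmentation error make
discrimination much harder.

## Numerical choices

* Painted and measured ellipse membership both use the closed inequality
  `((x−cx)/a)² + ((y−cy)/b)² ≤ 1` on the integer pixel lattice.
* Noiseless phantoms give *exact* area recovery because a solid discrete
  ellipse of these sizes is invariant under opening with a radius-1 disk;
  recovery error grows continuously with noise sd.
* Multi-Otsu cuts are bin edges; with well-separated classes the closed-GM
  convention classifies the class means correctly regardless of the exact
  bin position.
* `average_scans` intersects brain masks; members without a mask count as
  all-brain.
* Problem sizes in the test suite and acceptance script (20-seed recovery
  runs, 10 phantoms per atrophy level, an 85-subject cohort, a 200-subject
  null table) were chosen as the smallest sizes at which the binomial /
  sampling error bounds quoted in the tests are meaningful.

## Known limitations

* The fixed-rectangle ROI presumes accurate spatial normalization; no
  atlas-based or deformable hippocampus segmentation is attempted.
* The decision tree is a CART-style approximation of C4.5 (see above).
* Volumes are per-slice pixel counts unless the caller supplies multiple
  slices and a voxel size; no parcellated volumetry or cortical thickness.
* Classification quality claims hold for the phantom's idealized contrast;
  on real data the same code measures, but does not guarantee, separation.
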