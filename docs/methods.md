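# Methods

## The model

`felgrim` treats automated Feline Grimace Scale (FGS) assessment as three
independent components: (1) localisation of 37 facial landmarks on a frontal
cat face, (2) reduction of the landmark configuration to 35 similarity-
invariant geometric descriptors, and (3) prediction of FGS scores from those
descriptors with gradient-boosted trees. Each component runs without the
others: descriptors need only an annotation, scoring needs only rater tables,
and landmark evaluation needs only coordinate files.

### Landmark schema

Landmarks are indexed 1–37 (1-based everywhere), in pixel coordinates with
the origin at the image top-left and y increasing downward. Four role sets
are fixed by the scale's published methodology: rotation landmarks
{13, 14, 17, 18} (two per eye; their per-eye centroids define the eye line),
crop landmarks {3, 10, 29, 30, 31, 32, 36, 37}, the normalisation pair
(33, 34) (nose wings), and the ten landmarks excluded from NRMSEw
{6, 7, 27–32, 36, 37}. The full anatomical table behind the numbering is not
recoverable from the published text, so the package ships a canonical
allocation chosen to satisfy every stated constraint — ears 1–8, cheeks and
jaw/chin {9, 10, 35, 36, 37}, whisker field {11, 12, 27–32}, eyes 13–20,
muzzle {21–26, 33, 34} (AU counts 8/8/8/8/5) — and accepts any user schema
that passes the same invariants. This allocation is an explicit stand-in; the
schema object, not the code, is the source of truth.

### Preprocessing

Alignment rotates by the negative signed eye-line angle (positive when the
right eye group sits lower, range (−180°, 180°]), crops to the crop-set
bounding box expanded by a margin fraction (default 0.10), grows the box
further if needed so that all 37 landmarks stay inside (keeping every
landmark outranks face framing), and resizes to the output size (default
224×224). Rotation is about the image centre, which keeps raster and
landmark transforms identical. Alignment is idempotent to sub-pixel level.

Edge filters use 3×3 kernels with reflect padding: the 4-neighbour Laplacian
[[0,1,0],[1,−4,1],[0,1,0]]; bilateral smoothing (3-px neighbourhood, colour
and spatial sigmas of 100 on the 0–255 scale) before the Laplacian;
Prewitt/Sobel as 0.5·|vertical| + 0.5·|horizontal| mask responses (the
published weighting of the two derived images is unstated; equal weights are
the neutral choice). Outputs are rescaled to [0, 255] unless raw responses
are requested.

Augmentation draws every parameter uniformly from its printed range
(probability distributions were not published): rotation from [3°, 19°] or
[341°, 357°] with probability ½ each, shear in (−0.16, 0.18), a flip
(left–right, rotate −90°, rotate −270°) applied with probability 0.5 (the
flip frequency is likewise unpublished), contrast (0.6–2), sharpness
(0.4–8), brightness (0.7–1.6), colour balance (0.2–3.5) and Gaussian blur
radius (1.05–2.9). Geometric draws act on raster and landmarks through one
affine; colour draws act on the raster only. Face crops are accepted only if
the (image-clipped) box area strictly exceeds 0.4 of the original image
area, then resized back to the original size. Detector internals are out of
scope: any callable returning (x, y, w, h) serves as a face-box provider,
and whole-image and landmark-bounding-box providers ship as defaults.

### Geometric descriptors

Three kinds: unsigned angles in degrees (mean over (vertex, arm, arm)
triples), ratios of mean inter-landmark distances, and ratios of mean
quadrilateral shoelace areas. Every descriptor is therefore invariant under
translation, rotation, uniform scaling and reflection of the annotation
(verified to 1e-9 over random similarity transforms). The canonical registry
has 35 descriptors split 10/5/8/5/7 across ear position / orbital tightening /
muzzle tension / whiskers change / head position, with left/right homologous
parts averaged; orbital descriptors are angles, the rest mostly distance
ratios normalised by the cheek width (9–10) or nose width (33–34), plus two
area ratios for head position. The exact published landmark sets per
descriptor are in unavailable supplementary material, so the canonical
registry is authored to match every stated constraint and alternative
registries load from YAML without code changes. Excluding the whiskers AU
leaves 30 descriptors, head position 28, both 23.

### Scoring and aggregation

Total score = Σ(scored AUs) / (2 · n_scored); missing AUs shrink the
denominator. Binarisation is inclusive (painful iff score ≥ threshold); the
threshold is always explicit, defaulting to 0.39 for scale semantics with
0.4 as the model-label convention — both published values are kept verbatim.
Multi-rater aggregation: AND/OR on binarised labels, mean/max/min on ratios,
mode/max/min on ordinal AU scores. Mode ties resolve to the lowest tied
score (deterministic and conservative — it never overcalls pain);
`tie="highest"` flips this.

### Prediction models

All three tasks use gradient-boosted trees behind scikit-learn-style
estimators, tuned by exhaustive grid search over five hyperparameters with
shuffled 5-fold cross-validation (seeded; binary folds fall back to
stratification if a fold loses a class). The published grid values are not
printed; the shipped default is trees {100, 300}, learning rate
{0.05, 0.1, 0.3}, L1 weight {0, 0.5, 1}, depth {3, 5}, row subsample
{0.8, 1.0}, column subsample {0.8, 1.0} — fully configurable. The CV metric
is accuracy for binary and negative MSE otherwise. Binary models weight the
positive class by negatives/positives, computed per training fold and for
the final refit. Ordinal models are 3-class softmax boosted trees with MSE
between predicted and true class integers (matching how ordinal errors are
reported); a cumulative-link formulation would also fit but is not the
default.

Recursive feature elimination is backward with step 1, dropping the lowest
gain-importance feature, scoring each subset by shuffled 4-fold CV and
keeping the best-scoring subset (ties go to the smaller subset). For binary
tasks the subset criterion is negative log-loss rather than accuracy: a
continuous criterion distinguishes nested subsets that tie on the quantised
accuracy scale, which materially improves rejection of pure-noise features.
Boruta runs `n_trials` rounds (default 20): each round appends an
independently permuted shadow copy of every feature, fits the booster,
computes per-feature mean |SHAP| attributions via the exact tree-SHAP path
algorithm built into the boosting backend, z-scores them within the round,
and scores a hit for each real feature exceeding the maximum shadow z-score.
Features whose hit counts beat the 50% chance level on a one-sided binomial
test (α = 0.05) are relevant. Both selectors are deterministic under a fixed
seed.

PCA for visualising the descriptor covariance structure standardises
features to zero mean/unit variance first and drops zero-variance columns
with a warning.

### Landmark-error metrics and the reference network

NRMSE is the mean over images and included landmarks of the Euclidean
prediction error divided by that image's ground-truth nose-wing distance
(33–34), ×100. The printed formula is a mean normalised distance — there is
no square root of a mean of squares — and it is implemented exactly as
printed under its conventional name. NRMSEw restricts to the 27 landmarks
outside the published exclusion set; per-AU values restrict to one AU, and
the count-weighted mean of disjoint subsets recomposes the overall value
exactly. The metric is invariant under a similarity transform applied
jointly to predictions and truths. Whether alignment-frame errors should be
normalised by the pre- or post-alignment nose distance is not fixed by the
text; we normalise in whatever coordinate frame is being evaluated.

The reference network is a deliberately small CNN written directly in NumPy
(im2col convolutions with analytic gradients, Adam, MSE on coordinates
normalised by image size): three stride-2 3×3 conv/ReLU blocks of 8/16/32
channels, an optional parallel block (symmetric 3×3+1×1, asymmetric
1×3+3×1, or hybrid kernels, 'same' padding, channel-concatenated), a
global-average-pooling or flatten head, up to two hidden dense layers, and a
74-wide output (37 x/y pairs). The output bias is initialised to the mean
training configuration, so an untrained-head network already matches the
constant-configuration baseline and training strictly refines it. Defaults:
batch 32, learning rate 3e-3, early stopping on validation loss with
patience 5. Training is deterministic under a fixed seed on fixed hardware.
Large pretrained backbones are deliberately out of scope; anything with
`predict(images) -> annotations` plugs into the same evaluation.

## The synthetic generator

No deposited dataset exists, so the generator is a first-class, tested
module that emulates what the pipeline assumes about real data. A canonical
frontal face template (authored coordinates in a 224×224 frame, not
measured from cats) is deformed linearly in each AU's latent intensity
u ∈ [0, 1]: ears rotate outward and lower (tips most), eyelids close toward
the eye axis (aperture 16 px → 4 px across the range), muzzle landmarks
compress 25% toward their centroid, whisker pads straighten and advance
downward, and head landmarks lower relative to the eyes. Each AU has a
designated primary descriptor that responds monotonically to its intensity.
Isotropic Gaussian annotation noise (default σ = 1.5 px, a realistic
annotation jitter at this face scale) and a random similarity nuisance
transform (rotation ±15°, scale 0.85–1.2, translation ±20 px) complete a
sample; both the observed and the noise-only aligned configuration are
returned.

Painful and non-painful groups draw per-AU intensities from truncated
normals (mean 0.8, sd 0.15 vs mean 0.12, sd 0.08; prevalence 0.5 by
default) — separable but overlapping at default noise, which is the
calibration substrate for the performance checks. Raters discretise
intensity at thresholds ⅓ and ⅔ into true levels 0/1/2 and then err through
a confusion matrix (end levels: 0.8 correct / 0.15 adjacent / 0.05 two-off;
the middle level has two adjacent neighbours and no two-off cell, so its row
is 0.1/0.8/0.1). Three raters per image by default. The rasteriser draws
head ellipse, ear triangles, eye ellipses, nose polygon, mouth/jaw lines and
whisker polylines directly from the landmark coordinates, so rendered
features move with the annotation; rendering is deterministic.

What the generator does **not** emulate: photographic appearance (fur,
breed, coat colour, lighting), occlusion, off-frontal pose, detector
failures, or rater biases that correlate across AUs or raters. Passing
performance bounds on this substrate therefore demonstrates that the
pipeline's machinery — descriptors, aggregation, training, evaluation — is
correct and well-calibrated on data with the assumed statistical structure;
it does not certify real-photograph accuracy.

## Numerical choices and degenerate inputs

* Angles clamp their cosine into [−1, 1] before `acos`; coincident
  vertex/arm points raise a degenerate-geometry error naming the descriptor.
* Zero ratio denominators and a zero nose-wing distance (which would break
  NRMSE and nose-normalised descriptors) raise errors naming the descriptor
  or image; annotation validation reports them without raising.
* Degenerate quadrilaterals have area 0 by the shoelace formula, without
  error.
* All randomness flows through seeded `numpy.random.Generator` objects;
  identical seeds give bit-identical datasets, augmentations, searches and
  training runs.
* The `.txt` annotation dialect round-trips coordinates exactly (floats are
  written with `repr`).

## Problem sizes

Test-suite and acceptance computations use desk-scale sizes chosen to
exercise the full pipeline: 1200 synthetic faces (1000 train / 200 held
out) for the prediction tasks, 600-sample planted-feature datasets for
selection recovery, and 500 training faces at 64×64 for the reference
network, which beats the constant-configuration baseline within 30 epochs.
The experiment-grid orchestrator accepts any sizes; the published study
operated on 3447 annotated photographs, which the synthetic substrate does
not attempt to match in scale or realism.

## Known limitations

* The canonical landmark allocation and descriptor definitions are authored
  stand-ins constrained by the published role sets and counts, not the
  (unavailable) supplementary anatomical tables.
* Ordinal models ignore order during fitting (softmax over three classes);
  only the error metric is order-aware.
* The reference CNN is a correctness- and procedure-level stand-in for
  production landmark detectors; its NRMSE on rendered faces is not
  comparable to photograph-trained backbones.
* Haar-cascade face detection is interface-only; no detector ships.
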