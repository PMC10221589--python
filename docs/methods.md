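# Methods

`liverscan` classifies liver ultrasound frames into the 11 standardized
scan locations (SL, ST, RSPV, RSLT, LD, RSHV, GBL, EBL, RIA, RIP, LK)
from the outputs of two semantic-segmentation backends: an *organ* model
(background, liver, kidney, gallbladder) and a *vessel* model
(background, vessel).  This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## Features from segmentation artifacts

Each frame yields, per backend, a `SegmentationArtifact`: the grayscale
image, the hard class map, pre-activation mask logits `P` (N x H x W),
per-segment query embeddings `Q` (C_Q x N, one query per class), the
encoder/FPN feature map `F` (C_F x H_F x W_F) and per-query class
scores (N x (N+1)).  Four feature families are derived:

* **Image features** `G_i = mean_{h,w} F_{i,h,w}` — global average
  pooling per channel.
* **Query embeddings and class scores**, flattened as-is.  Whether the
  class scores are logits or probabilities is backend-dependent; they
  are stored raw and consumed as-is.
* **Geometric features** `V ∈ R^{(N-1)x10}`: per non-background class,
  `[T, L_x, L_y, S, λ1, λ2, v1x, v1y, v2x, v2y]` — a detection tag,
  the mask centroid in raw pixel units, the area fraction
  `|C| / (H·W)`, and the eigenvalues/unit eigenvectors of the 2x2
  covariance matrix of the mask's pixel coordinates (population 1/n
  normalization, pixel² units).  Undetected classes yield all-zero
  rows.  The covariance eigenstructure is a standard shape-PCA
  morphology descriptor; an optional flag normalizes centroids by
  (W, H) and eigenvalues by W·H (default off — raw units).
  Eigenvector signs are fixed (largest-magnitude component positive,
  ties toward the first component); a repeated eigenvalue returns the
  canonical basis.  Argmax ties in the hard class map break toward the
  lowest class index.  These conventions are arbitrary but frozen and
  tested: the descriptors must be reproducible byte-for-byte.

## Hierarchical classification

Level 1 maps each frame to one of 8 regions from **organ features
only**: six locations are distinguishable from organ layout alone;
{ST, RSPV, RSHV} (right lobe, vessel-defined) and {SL, EBL}
(longitudinal views) are collapsed into two group classes.  Routing is
strictly feed-forward: a level-1 error cannot be corrected downstream,
and the final label always lies in the fiber of the level-1 decision.

**Group {ST, RSPV, RSHV}.** Sub-step 1 trains an MLP on liver-restricted
organ features (geometric rows limited to the liver class; the
restriction is configurable) concatenated with the full vessel feature
vector.  Training frames it classifies correctly *on the training set*
are "clear"; the rest are ambiguous.  A triplet encoder is fitted on
clear frames with the squared-distance hinge
`L(a,p,n) = max(|a-p|² - |a-n|² + α, 0)`, α = 1, using online
batch-hard mining (hardest positive and hardest negative within each
minibatch).  Clear embeddings are projected to 2-D with t-SNE
(perplexity 30, reduced automatically when data are few; fixed seed), a
uniform 10x10 grid is laid over the projection's bounding box (cells
half-open except the last row/column), and one clear point is sampled
uniformly from every occupied cell.  These reference points — stored
with their 64-d embeddings — classify queries by 3-nearest-neighbor
majority vote (Euclidean; vote ties fall to the single nearest
neighbor, distance ties to insertion order).  At inference *every*
group-1 frame goes through the KNN; sub-step 1 exists to define clear
data.  (Confidence-thresholded routing, where only low-confidence
frames take the KNN path, is available as a config option.)  The
clear-data definition uses training-set correctness rather than
out-of-fold predictions; this is logged so users can switch.

**Group {SL, EBL}.** The vessel model's mask logits are rectified with
a ReLU (not a sigmoid — negative responses are discarded but
low-confidence positives, i.e. faint vessels the hard segmentation
missed, are kept) and stacked with the vessel-masked image intensities
into an H x W x 3 image: (masked intensity, background prediction,
vessel prediction).  The image is bilinearly resized (default side 224;
the pipeline default for desk-scale runs is 32) and min-max normalized
per channel (a constant channel maps to zeros; whether to normalize
jointly or per channel was open — per channel chosen).  The classifier
is a backbone + MLP head; the default desk-scale backbone is a coarse
average-pooled map plus per-channel photometric statistics (mean, std,
max, quartiles and occupancy of non-zero pixels).  The statistics carry
the echogenicity of the segmented vessel relative to the channel's
dynamic range — the property that actually separates SL from EBL —
and are stable across subjects, where finely-resolved positional
features are not.  Any callable mapping the preprocessed raster to a
feature vector can replace the backbone (a large pretrained CNN in a
full-fidelity deployment; bundling one is out of scope).

**Non-hierarchical ablation.** One MLP over the concatenated organ +
vessel feature vectors for all 11 labels, same optimizer and stopping.

## Optimization

All classification heads are two fully connected layers (hidden width
256, configurable) trained with cross-entropy, AdamW at learning rate
1e-4 (weight decay 0.01), batch size 64, and early stopping with
patience 10 on validation loss; the epoch cap is 500 and exists as a
safety net (early stopping is the intended termination).  Inputs are
standardized with training-set statistics.

Early-stopping validation is **subject-held-out**: one whole training
subject is set aside whenever at least three subjects carry every
class, falling back to a stratified random split otherwise.  Validation
on a within-subject split lets a network keep improving by memorizing
subject-specific appearance; that both inflates held-in performance and
collapses the clear/ambiguous partition (nearly every training frame
ends up "clear"), which defeats the group-1 design.

## The triplet encoder at desk scale

The encoder is three layers (batch normalization + leaky ReLU, slope
0.2, after the hidden layers) to a 64-d embedding.  Its training set —
the clear subset of one fold's training subjects — is small, and an
unconstrained metric net drives the mined loss to zero by memorizing
those subjects, ruining the embedding for new ones.  Three measures
keep it honest:

* a projection front end onto the leading 64 principal axes of the
  standardized features (unwhitened — whitening amplifies trailing
  noise directions and was measurably harmful);
* a zero-initialized final layer plus a skip connection from the
  projected input, so the encoder *starts exactly at the PCA metric*
  and learns a residual refinement; the untrained state participates in
  model selection;
* early stopping (patience 10) on the batch-hard loss of a held-out
  subject's clear frames, with the best state restored.

Encoder learning rate is 1e-3 with weight decay 0.05 (the optimization
recipe above is stated for the classification heads; the encoder's was
an open choice).  Embeddings are L2-normalized before KNN, making the
vote effectively cosine-based; margins are computed on unnormalized
embeddings during training.

## Synthetic study conditions

The generator emulates, per scan location: organ presence probabilities
and elliptical geometry (centroid, area fraction, eccentricity,
orientation — fraction-of-image units), vessel strokes as quadratic
Bezier branches (count, curvature, length, width, echogenicity), mask
logits as Gaussian-blurred signed-distance maps (so ReLU vs sigmoid
behavior meets realistic negative values), and label-conditional
Gaussian query embeddings / feature maps.  Subjects perturb geometry
and embeddings through deterministic per-subject offsets, so
subject-wise cross-validation is a real generalization test.  Rasters
default to 128x128 with C_Q = C_F = 32 (configurable); production
images are larger, but the statistical structure, not resolution, is
what the pipeline consumes.

Within-group confusability is controlled by `ambiguity_overlap`: each
group-1/group-2 frame draws a partner class in its group and a mixing
weight t ~ U(0, overlap), pulling its vessel geometry, embeddings and
feature map toward the partner's, with noise growing in t.  This
emulates probe drift: a frame labeled one view increasingly resembles a
neighboring view, and past t = 0.5 is effectively mislabeled from the
features' standpoint.  That asymmetry — corrupted supervised training
versus a curated clear set — is precisely what the reference-point KNN
exploits.  Vessel *echogenicity* is deliberately not mixed: echo
texture survives when segmentation-derived features blur, which is what
the SL/EBL image branch relies on.  What the generator does **not**
emulate: speckle physics, attenuation/shadowing, probe-motion kinematics
(morphological interpolation between frames stands in), or anatomical
covariation between organs; passing benchmarks here demonstrates that
the pipeline machinery works under the stated statistical structure,
not clinical performance.

Benchmark conditions (fixed once): the recovery study uses the
separable spec set (overlap 0) with 50 frames per location over 5
subjects, 3 training / 2 held-out; the ambiguity study uses overlap
0.6 with 40 frames per location, 5 training seeds, each averaged over
3 of the 10 subject folds.  These sizes keep a full study within
minutes on one CPU while leaving the comparisons statistically
meaningful.

## Evaluation

Subject-wise splits assign whole subjects to train or test; with 5
subjects and 3 training, all C(5,3) = 10 folds are enumerated in
deterministic order.  Metrics are per-class precision, recall and F1
with unweighted macro averages ("average F1" is macro, and labeled as
such; support-weighting was the alternative).  Zero-denominator
precision/recall is defined as 0 and flagged.  Comparisons between
modes (hierarchical, non-hierarchical, sub-step 1, sub-step 2) run each
mode over folds x seeds and report mean ± sd macro-F1 with directional
verdicts; a failed cell is recorded and the comparison proceeds.

## Determinism

Every stochastic step — generation, initialization, minibatch order,
validation splits, t-SNE, reference sampling — draws from a named seed,
and artifact bundles are written with fixed dataset order, little-endian
float32 payloads and timestamp tracking disabled, so a rerun with the
same config produces byte-identical manifests, bundles, prediction CSVs
and metrics JSON.  Artifact tensors are held in float32 in memory for
the same reason.

## Known limitations

* The clear/ambiguous partition inherits any bias of sub-step 1; with
  very small groups a label can end up with no clear samples, which is
  a hard error (`DegenerateReferenceError`) rather than a silent
  fallback.
* t-SNE is recomputed per fold; reference sets from different folds are
  not comparable.
* The grid cells of the reference selection are axis-aligned in t-SNE
  coordinates, which are themselves seed-dependent; only the *set* of
  selected references is meaningful, not cell identities across runs.
* The desk-scale image backbone is a stand-in; absolute SL/EBL accuracy
  with a real CNN on real images is not addressed here.
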