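# Methods

## Problem and model

Microcalcifications (MCs) are sub-millimetre calcium deposits that appear
in mammograms as small, locally bright blobs; clusters of them can be an
early sign of breast cancer. `mcseg` implements a two-stage, patch-based
convolutional approach to find and delineate them:

1. **Detector** — a binary CNN screening overlapped N×N tiles of the
   mammogram for the presence of any MC.
2. **Segmentator** — a binary CNN classifying the central pixel of an
   N×N patch as lesion or background; applied to every foreground pixel
   of the tiles the detector flags, it produces the per-pixel MC mask.
3. **Cluster analysis** — connected components of the mask are the MC
   objects; a sliding 1 cm² window marks a cluster wherever strictly more
   than 5 distinct MC centroids co-occur, the standard radiological
   density rule.

The two stages trade compute for specificity: Otsu thresholding removes
the (large) image background from all further evaluation, the detector
cheaply discards most remaining tiles, and only flagged regions-of-
interest pay for per-pixel classification.

### Architecture

Both networks share one architecture: six 3×3 stride-1 convolutions,
with a 2×2 max-pool (floor division on odd sides) after the first and
second, then fully connected layers of 64 and 2 units. ReLU follows
every convolution and the 64-unit layer; batch normalization follows
each ReLU (inference uses running statistics); 50% dropout regularizes
the 64-unit layer; weights use He initialization. Padding is selectable:
*same* preserves the spatial side; *valid* shrinks it by 2 per
convolution, so a 49×49 patch contracts to a 2×2 map entering the first
dense layer (`feature_map_side(49, "valid") == 2`; 29×29 under-runs the
valid path and is rejected). The class posterior is the softmax of the
two output scores, and training minimizes categorical cross-entropy.
Decision rule at inference: positive iff the positive-class posterior
exceeds 0.5; an exact tie goes to the negative class, favouring
specificity.

The CNN stack (im2col convolution, pooling, batch norm, dropout, dense,
Adam) is implemented directly on NumPy with analytic backpropagation;
the test suite validates every parameter group against central-difference
numerical gradients, and the layer-size recurrence against instantiated
forward passes.

Unstated architecture details were fixed as: ReLU activations (implied
by He initialization), batch norm after the activation, per-image input
standardization (zero mean, unit variance), and default filter counts
(16, 16, 32, 32, 64, 64) — all exposed in `NetworkConfig`.

### Patch taxonomy and sampling

Windows are classified from the ground-truth mask:

| class | rule |
|-------|------|
| C1 | central pixel belongs to an MC |
| C2 | center is background, nearest MC pixel within ≤ 3 px (Euclidean) |
| C3 | an MC lies in the window, but farther than 3 px from the center |
| C4 | no MC anywhere in the window |

The detector's positive label is C1∪C2∪C3; the segmentator's is C1.
The C2 radius metric is Euclidean with the 1–2 px shell folded in
(configurable `c2_radius_px`), making the four classes exhaustive.
Border windows are completed by symmetric reflection (edge pixel
included), chosen so that window extraction agrees bit-exactly with the
`scipy.ndimage` boundary mode used by the vectorized whole-image
classifier. Patch records (coordinates + class) live in an indexed
SQLite table; pixels are re-read from the images at sampling time.
Minibatches are exactly half positive / half negative — not merely on
average — drawn uniformly within each pool (without replacement inside a
batch, with replacement across batches) and given a random dihedral
(rotation/flip) augmentation, which fixes the center pixel of an
odd-sided patch and therefore preserves the class.

### Training

Adam at initial learning rate 1e-3, minibatch size 256 (study runs use
128, see below). Validation loss is evaluated every `eval_every` steps;
after `plateau_patience` consecutive non-improving evaluations the
learning rate is halved (automating what would otherwise be a manual
plateau judgement; default patience 5), and after `early_stop_patience`
non-improving evaluations training stops and the weights at the best
validation loss are restored. All randomness (draws, augmentations,
dropout) derives from the schedule seed; runs are bit-reproducible.

### Inference

Tiling uses stride N − floor(N/2) (25 for N = 49), i.e. consecutive
tiles overlap by floor(N/2) pixels, with a final tile clamped flush to
each image edge so no pixel escapes screening. The overlap makes the
overwhelming majority of pixels visible to the detector in at least two
tiles per axis (exception: a 1-px lattice at stride period, an
unavoidable parity effect of odd N). Within flagged tiles, every Otsu-
foreground pixel is classified exactly once (union semantics over
overlapping tiles); pixels in flagged tiles but outside the foreground
are left negative, consistent with excluding background from all
evaluation.

## Synthetic phantoms

Clinical mammogram datasets with per-pixel MC annotation are rarely
shareable, so the package ships a phantom generator that emulates the
*statistics that matter to a patch classifier*, not anatomy:

* breast region: a half-ellipse flush against one image edge with a
  few-pixel smoothed boundary (reproducing a tissue-to-background
  transition zone, a known source of false positives);
* tissue: a Gaussian-smoothed random field (correlation length
  `tissue_texture_scale`, default 8 px) around a mean level of 0.45;
* MCs: star-shaped blobs whose outline radius is perturbed by a
  band-limited angular function (`mc_shape_irregularity` 0 → circular,
  1 → strongly irregular), with a ~1.5 px soft intensity shoulder
  beyond the mask boundary emulating partial-volume blur; peak added
  intensity is `mc_contrast_range` (default 0.3–0.9) times the local
  tissue intensity;
* optional white noise (`noise_sigma`, default 0.01) mimicking noisier
  digitized film;
* optional spatial clustering of lesions around seed points.

Placement is rejection-sampled with a minimum separation so the mask has
exactly `n_mcs` connected components; failure after bounded retries
raises a placement error. Images are floats in [0, 1], written
losslessly as 16-bit TIFF/PNG; masks as 8-bit PNG. Everything is
bit-deterministic given the seed.

What the phantoms do **not** model: projective tissue superposition,
scanner-specific noise spectra, benign look-alikes (vascular
calcification, dense glandular islands), or realistic breast anatomy.
Passing the end-to-end tests therefore demonstrates that the pipeline's
machinery — taxonomy, sampling, training, tiling, per-pixel inference,
metrics — is correct and trainable, not that the trained weights would
transfer to clinical images.

## Metrics

* **Per-class patch error** (%) for C1–C4 under each network's label
  mapping, plus an overall accuracy on a balanced pool. Whether that
  pool should be balanced per binary label or per four-way class is
  ambiguous in the protocol this follows, so both are computed.
* **Pixel accuracy and FPR** (FP/(FP+TN)) over two domains: all pixels
  (headline; dominated by background true negatives) and Otsu foreground
  only (stricter).
* **Lesionwise recall**: the fraction of true MC components touched by
  at least one predicted pixel — boundary-pixel mistakes do not count a
  lesion as missed.
* **Cluster regions**: merged unions of qualifying 1 cm² windows; an MC
  is attributed to a region iff its centroid lies inside the union (not
  the union's bounding box). The ">5 per cm²" threshold is strict and
  configurable; window step defaults to 25 px for speed, with step 1 as
  the exhaustive reference that coarser steps can only under-detect
  against.

## Study problem sizes

`run_synthetic_study` is the package's reproducible end-to-end
experiment, sized for a single CPU core: 16 train + 4 validation
phantoms of 128×128 px (8 MCs each, diameters 2–11 px), patch side 29
with same padding (valid padding is impossible at N = 29), filter banks
(8, 8, 16, 16, 16, 16), per-class record cap 1250 (~5,000 training
patches), minibatch 128, 220/260 Adam steps for detector/segmentator,
and 10 held-out test phantoms. Under these conditions the pipeline
reaches lesionwise recall ≈ 0.99–1.0 with all-pixel FPR ≈ 0.4% across
seeds, and the per-class error tables reproduce the qualitative
signature expected of the taxonomy: C3 (peripheral lesion) is the
detector's hardest class and C2 (near-center lesion border) the
segmentator's — the ambiguous limit cases between positive and negative
labels. Patch side, padding, filters and step counts are all arguments,
so larger configurations (e.g. N = 49) run unchanged when more compute
is available.

## Numerical choices and edge cases

* Softmax uses max-subtraction; cross-entropy clamps log at 1e-12.
* Max-pooling crops odd sides (floor), matching the printed 49→2
  valid-path arithmetic (ceil would give 3).
* Batch-norm epsilon 1e-5, running-stat momentum 0.1.
* Constant images are rejected by both Otsu thresholding and per-image
  normalization (no split / zero variance).
* An image smaller than the patch side cannot be tiled and is rejected.
* A cluster-analysis image smaller than the 1 cm window is scanned with
  a single window anchored at the origin.
* Chi-square goodness-of-fit (α = 0.01, 10⁴ draws) verifies uniform
  within-pool sampling; determinism contracts are asserted bit-exactly.

## Known limitations

* NumPy training is single-core and orders of magnitude slower than a
  GPU framework; the defaults here are sized accordingly.
* The segmentator evaluates one forward pass per pixel; a fully
  convolutional reformulation would be faster but is out of scope.
* Phantom realism as discussed above: results on phantoms bound the
  machinery, not clinical performance.
* Early stopping monitors a fixed validation patch set; with very small
  validation pools the loss estimate is noisy and the plateau rule can
  fire early.
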