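# Methods

This note documents the models, the synthetic study conditions, the numerical
choices, and the known limitations of `convrules`.

## Problem setting

A binary image classifier `M = h ∘ g` is interpreted through the kernels of
its last convolutional layer.  `g` maps an image to `k_l` post-ReLU
activation maps (one per kernel); `h` is everything after that layer.  The
package extracts a symbolic surrogate of `M`, grounds its symbols in
anatomical regions, and measures how much each kernel group contributes to
the decision.

## Quantization

Kernel norms are plain L1 norms of the activation maps, with no
normalization by map size.  Thresholds are per-kernel arithmetic means over
the *training* split and are frozen: held-out data is always binarized
against training thresholds.  Binarization is strictly `a > θ`; the tie
`a = θ` yields the negative literal.  Display codes (`AA`, `AB`, …) are
stable two-letter labels assigned by kernel index.

## Rule extraction

Trees are grown greedily over the ±1 literal columns, choosing at each node
the kernel that minimizes the weighted Gini impurity of the children.
Implementation choices:

- depth cap 3 (three literals per rule body) — deeper trees add fidelity
  only marginally and stop being readable;
- no kernel repeats along a path; ties between equal-Gini kernels break to
  the lowest kernel index, so builds are deterministic;
- minimum leaf size 2; a split must strictly reduce impurity;
- trees are induced against the CNN's predictions (fidelity-first); accuracy
  against labels is reported, never optimized;
- pruning is reduced-error pruning on a held-out fold (by default the last
  20% of the training split, stratified by class): a subtree collapses to
  its majority leaf whenever held-out misclassifications do not increase,
  bottom-up in one pass (which reaches the fixed point).

A rule set is the exhaustive, mutually exclusive set of root-to-leaf paths;
`apply_rules` verifies the partition property on every input table.
Interventions re-induce the tree under an allow/deny-constrained kernel
vocabulary and report side-by-side against the unconstrained baseline.

## Concept assignment

The activated image region of a kernel on one image is computed as follows:
bilinearly upsample the map to image resolution; box-filter it with a width
of `image_size // 4` (an estimate of one unit's receptive field, so a
sharply peaked map still claims the image area that drives it); threshold at
half of the peak value (FWHM support); keep the connected component
containing the peak; take its tight bounding box, grown to at least the
footprint width (shifting inward at image borders, where the support would
otherwise be clipped).  Raw percentile thresholding (the 95th percentile of
the upsampled map) is available via parameters.  These choices matter: a
bounding box over *all* supra-threshold pixels is inflated by secondary
activations, and sparse maps otherwise produce boxes far smaller than any
region, capping IOU below the hit threshold for perfectly region-locked
kernels.

A hit is IOU > 0.5 between that box and a region's ground-truth box; hit
rates aggregate over the whole split, counting silent images as misses.  A
kernel is assigned the region with the highest hit rate when that rate
exceeds 0.70; kernels with no region above 0.70, or more than two, are
uninterpretable.  Raising the IOU threshold can only lower hit rates
(monotonicity, tested).

## Ablation experiments

Muting replaces a kernel's maps with zeros between `g` and `h`; activating a
set mutes its complement (an identity that is tested on random subsets).
Four experiments: incremental activation of region groups against
size-matched random subsets of uninterpretable kernels (100 replicates,
sampled without replacement); muting one region's kernels together with all
uninterpretable kernels against the uninterpretable-only reference; an
exhaustive ranking of region-group combinations of a given size (capped at
5000 evaluations); and a random-muting curve over muted fractions 10–90%
(20 replicates).  Accuracies are against ground-truth labels on the training
split by default.  Feature maps are extracted once per experiment and masks
are applied to the cached maps, which is exact because `g` does not depend
on the mask.

## Radiomics

Crops are discretized per crop by min–max scaling into 32 equal bins
(constant crops map to level 1).  GLCM joint entropy uses distance 1, the
four undirected directions, symmetric co-occurrence counts and log base 2,
averaged over directions.  GLRLM gray-level and run-length non-uniformities
are computed per direction from maximal runs and averaged.  First-order MAD
and RMS use raw intensities in [0, 1], not the discretized levels.
Associations with kernel norms are Pearson correlations with a fitted line;
zero-variance inputs leave the correlation undefined (NaN) rather than
raising.

## The phantom: what it emulates and what it does not

The generator emulates frontal chest radiographs for pleural-effusion
detection at desk scale: 64×64 images, nine named regions (T, UM, CS, LC,
RC, LH, RH, LCA, RCA) on a flush 3×3 grid, 200 images per class for
training and 40 per class held out (matching a 400-image training study).
Each region carries a sinusoidal carrier with a region-specific orientation
(stride-4-permuted so neighbors differ strongly) and one of two spatial
frequencies.  Class signal lives in CS and UM: in positive images both
carriers are attenuated toward a mean amplitude of 0.16 (healthy: 0.35 ± 15%
jitter), with anti-correlated severity shares (Dirichlet, concentration
0.35, scale jitter ±30%) — the disease burden splits unevenly between the
two sites, so neither region alone classifies perfectly and the model must
attend to both, as a radiologist integrates findings across sites.  Decoy
regions keep a class-independent texture whose amplitude varies per image
over (0.02, 0.15); this is deliberate: if "a low-texture patch exists
somewhere" only ever occurred in diseased images, a classifier could learn a
spatially unlocalizable obscurity detector, which no region-based concept
could ever explain.  Fill level and pixel noise are identical across classes
for the same reason.

What the phantom does **not** emulate: anatomy, intensity calibration,
patient variability, label noise, multi-disease overlap, or detector error
in the region boxes (boxes are exact by construction; optional ±2 px jitter
exists for robustness checks).  Passing tests on the phantom therefore show
that the pipeline's mechanics — quantization, rule induction, concept
geometry, masking — behave correctly and that concept recovery works when
localized class evidence exists; they do not certify performance on real
radiographs.

## The built-in CNN

Three conv blocks (5×5, 3×3, 3×3; 8/12/16 channels; max-pool after the
first two), so the 16-kernel feature layer keeps a 16×16 grid on 64×64
inputs; the head is global pooling plus a linear layer.  Everything is
float64 NumPy with explicit seeding — training is bit-reproducible.  Three
training choices are load-bearing for interpretability and stand in for the
activation-sparsity training that large radiology CNNs in this line of work
rely on:

- **Global max pooling** in the head: with average pooling a kernel that
  additively mixes several regions' energies is as useful as two pure
  kernels, and mixed kernels cannot be assigned a concept.  Under max
  pooling a mixed kernel's contribution is dominated by whichever region is
  currently structured, which destroys its class information — so training
  itself favors selective, localizable kernels.
- **Activation L1** (weight 0.05 on the mean feature-map activation):
  concentrates each kernel's response spatially and drives constant or
  diffuse channels toward zero, leaving genuinely unused kernels for the
  uninterpretable pool.
- **Head re-fit under random muting**: after convolutional training the
  linear head alone is re-trained on frozen pooled features while channels
  are zeroed at random per-sample rates (up to 0.95, unscaled — exactly the
  masking applied at inference).  Drop probability is reduced for
  consistently active channels, and a lasso on each channel's differential
  weight (class-1 minus class-0) zeroes the decision influence of channels
  without class evidence.  The result degrades gracefully under kernel
  muting, emulating the redundancy of much larger networks, without touching
  what the kernels learned.

The class encoding is fixed: 0 = healthy, 1 = effusion-like; sensitivity is
recall of class 1.  Training raises an error with diagnostics if validation
accuracy ends below 0.7.

## Numerical and interface choices

- One canonical image representation: floats in [0, 1]; gray-level
  discretization happens only inside radiomics.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces every
  artifact byte-for-byte, including the run-directory files.
- Degenerate inputs: empty literal tables, all-denied vocabularies, missing
  region boxes, zero-variance correlation inputs and out-of-range kernel ids
  raise informative errors; an empty pruning fold skips pruning with a
  warning.
- Run directories carry a manifest with the config hash; the what-if entry
  point refuses to operate on a bundle whose hash does not match.

## Known limitations

- The head re-fit trades a small amount of full-model margin for muting
  robustness; on hard phantoms the post-re-fit accuracy can dip slightly
  below the pre-re-fit one.
- Concept recovery is stochastic in the training seed: with 16 kernels and
  only two informative regions, some seeds produce one or two
  discriminative kernels whose activated area never matches a single region
  box, and occasionally the near-zero-hit-rate kernel pool still contains
  class information (the interpretable-vs-noise rule-set contrast then
  ties rather than separates).
- The exhaustive combination ranking is capped; beyond the cap the caller
  must restrict the group set.
- Only binary classification is supported; the masking and rule machinery
  generalizes, but sensitivity/specificity reporting assumes two classes.
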