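# Methods

This note records the models, conventions and design choices behind
`morphoscreen`, in the spirit of a package methods appendix. It states no
empirical numbers beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Pipeline model

The pipeline assumes a plate imager producing one grayscale brightfield
frame per well per hour. Classification is *patch-based*: a frame is never
scored as a whole; instead disjoint 224 × 224 tiles are classified
independently and the frame-level decision is a vote. This makes the
classifier robust to frames containing mixtures (e.g. a dying focus
surrounded by healthy cells) and yields an interpretable per-image
composition — the classification score vector c with entries
c_i = #{j : f(p_j) = i} / M over the frame's M patches. Because the entries
are integer counts over M, the package stores them as exact rationals;
`ScoreVector.fractions` sums to 1 identically, not merely to floating
tolerance. The image call is argmax c with ties broken toward the lowest
index in the fixed label order `('apo','aut','fer','hea','nec')` — a
declared convention, since a majority-vote tie has no canonical winner.

### Patch grid

The native frame geometry is 1408 × 1040 px. The default grid is 4 rows ×
4 columns of disjoint 224-px tiles: rows are four contiguous bands
vertically centered (top margin 72 px); columns are four bands equally
spaced across the width (margins 103 px, gaps 102 px). Sixteen patches per
frame reproduces the bookkeeping identities 64 frames → 1024 patches and
22 frames → 352 patches per class. For non-native geometries
`PatchGridSpec.tiling` fits the maximal number of disjoint tiles per axis
with evenly distributed slack. Coordinates are 0-based, row-major,
top-left origin.

### Intensity handling

Frames live in a floating [0, 1] range; file writers quantize to 16-bit.
Before the network, each patch is min-max scaled to [0, 1] and then
standardized with the backbone's fixed mean 0.5 / SD 0.25. Per-patch
min-max (rather than per-frame) makes patches insensitive to illumination
gradients at the cost of amplifying noise in empty patches; the simulator's
illumination-gradient parameter exists precisely to exercise this.

## The classifier

### Backbone

`micro_cnn` is a compact multi-scale convolutional backbone designed for
deterministic CPU training: a parameter-free 4 × 4 average-pool stem, three
conv–relu(–maxpool) stages (12, 24, 32 channels), global mean+max pooling
of *all three* stages concatenated into a 136-dimensional descriptor, and a
dense suffix 136 → 64 → 48 → 5. Pooling statistics of several depths keep
the descriptor informative even with randomly initialized, frozen filters
(random convolutional features act as a fixed texture bank), which is what
makes head-only training effective without pretrained weights. Pretrained
weights can be supplied via a checkpoint (`pretrained_path`); they are an
optional capability, not a requirement.

### Transfer-learning semantics

Parameters form an ordered group list `(conv1, conv2, conv3, fc1, fc2,
head)`. `num_train_layers = k` unfreezes exactly the last k groups; the
default 3 trains the dense suffix only. Frozen groups are never passed to
the optimizer, and `TrainingResults.frozen_params_unchanged()` verifies
bit-identity against the pre-training snapshot. When every convolutional
group is frozen, backbone features are computed once per dataset and
cached — training cost then scales with the 136-d features, not the
pixels. Full backpropagation through the convolutions (validated against
central-difference gradients in the test suite) runs only when k > 3.

A fixed feature standardization (per-dimension mean/SD of the *training*
features) sits between backbone and head. It is set once at the start of
`fit` and never updated afterwards; it carries no trainable parameters and
is stored in the checkpoint.

### Schedule

Defaults: batch 100, up to 50 epochs, early-stopping patience 25 on the
validation cross-entropy, Adam, initial learning rate 1e-4 multiplied by
0.95 every 5 epochs (`lr = lr0 · (1 − 0.05)^⌊epoch/5⌋`; the multiplicative
reading of "5% each five epochs" was chosen over a linear one), best-epoch
weights restored. An epoch is one full pass over the training patches; the
rate changes at epoch boundaries.

`TrainingConfig.cpu_protocol` is the package's fast schedule for head-only
training from random initialization: ≤ 10 epochs at initial rate 1e-3.
The 1e-4 default suits long fine-tuning of a pretrained backbone; a fresh
dense head trained for only a few hundred Adam updates needs the larger
step. The acceptance script and the end-to-end tests use this protocol at
the full dataset size (108 frames/class, 64/22/22, 16-patch grid).

### Determinism

All randomness flows through seeded `numpy` generators: scene rendering
(one splitmix-mixed seed per frame), split shuffling, weight
initialization, batch order. There is no threading nondeterminism in the
pure-numpy network, so identical config + data + seed reproduce identical
histories, weights, and byte-identical result files on a fixed platform —
checked end-to-end by hashing CSV/JSON outputs of two CLI runs.

## The morphology simulator

The generator renders what a texture classifier needs to see, not optics.
Each class composes soft-edged primitives on a noisy background
(default level 0.55) with an optional linear illumination ramp:

| class | rendering | rationale |
|---|---|---|
| apo | cluster of small bright discs with dark halos | apoptotic-body accumulation |
| fer | large smooth bright disc, thin dark rim | ballooning |
| nec | medium disc with harmonic radial raggedness, no satellites | blebbing without bodies |
| aut | thin long ellipse with small dark interior discs | spindle + vacuoles |
| hea | faint elongated ellipses | adherent low-contrast cells |

Defaults (60 cells per native frame, size 36 ± 8 px, noise SD 0.02,
gradient 0.08) were fixed once so the five classes are visually and
statistically distinct — a separability test verifies that a linear
classifier on simple patch statistics beats the 20% chance level by a wide
margin, which is what makes the end-to-end learning test meaningful.
Cell centers are rejection-sampled with a minimum separation so object
counts match ground truth (verified against a connected-component oracle).

What the simulator does **not** emulate: phase optics, debris, confluency
gradients, death-mode kinetics (frames are static per requested hour), or
the intra-class heterogeneity of real cultures. Passing tests therefore
demonstrate that the pipeline's machinery — bookkeeping, training
mechanics, aggregation, evaluation — is correct and that the classifier
can learn five distinct textures; they do not certify accuracy on real
microscopy, whose difficulty is dominated by biological variability the
generator deliberately omits.

## Screen aggregation

One frame per (well, hour); duplicate acquisitions are an error.
Time-courses mark missing hours explicitly rather than interpolating. The
screen report emits one record per (compound, concentration, report hour)
plus a per-compound *headline*: the modal call across concentrations at
that hour, ties resolved to the call of the highest concentration (the
concentration a screener would inspect). This reduction is a declared
package convention — a single-label-per-drug summary admits several
defensible rules. Vehicle wells called healthy are reported as Healthy
controls; a healthy call under treatment likewise reports Healthy (no
effect). The simulated screen assigns each compound one induced morphotype
at every concentration and hour; concentration–response and kinetics are
out of scope.

## Evaluation conventions

Metrics are one-vs-rest per class. Zero denominators (a class absent from
both truth and predictions) return 0 with a `zero_division` flag rather
than NaN. Reports state their granularity (`patch` or `image`) explicitly,
since patch-level and call-level supports differ by the patches-per-frame
factor. The Jaccard–F1 identity J = F/(2 − F) and the partition identity
TP + FP + TN + FN = N are enforced as invariants in the tests.

## Problem sizes

The test suite and acceptance script run the full study conditions for
training and evaluation (540 frames, 8 640 patches) and a complete
384-well × 24-hour screen; small-geometry frames (224 × 224, one patch)
are used for the per-well screen frames so the plate-scale plumbing runs
end-to-end through the trained model in minutes on one CPU. The unit
suites use 10 frames per class. These sizes are the package's chosen
defaults for its reference runs.

## Known limitations

- No pretrained-backbone zoo; transfer learning starts from the package's
  own deterministic initialization unless a checkpoint is supplied.
- No overlapping/strided inference, no augmentation, no dose–response
  fitting — all declared non-goals.
- The simulator's phenotype realism is heuristic; no intensity statistics
  of real brightfield cultures are available to calibrate against.
- Synthetic class distinctness means reported synthetic accuracies are an
  upper bound on what comparable real data would yield.
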