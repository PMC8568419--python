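# Methods

## Problem and model

The package segments the paravertebral muscle groups (bilateral psoas,
quadratus lumborum, paraspinal muscle) on single axial CT slices at the
L3/L4 level. Segmentation is binary: muscle foreground vs everything else.
The reference label for training is not the manual ROI itself but the ROI
restricted to the skeletal-muscle attenuation window,

    gt(x) = roi(x) AND (−29 HU ≤ img(x) ≤ +150 HU),

with both bounds inclusive — the standard body-composition convention for
skeletal muscle. The network therefore learns the expert's delineation
*after* HU filtering; it does not threshold HU at inference time.

The network is a U-Net: L encoder levels, each two same-padded 3×3
convolutions with LeakyReLU (negative slope 0.01), with 2×2/stride-2 max
pooling between levels; the number of filters at level i is

    n_base · 2^(i−1),  i = 1 … L.

The decoder mirrors the encoder with 2×2/stride-2 transposed convolutions
and concatenation of the matching encoder feature map, ending in a 1×1
convolution to two channels and a per-pixel softmax. The predicted mask is
the channel argmax; an exact tie goes to background, which makes untrained
or degenerate networks err conservatively. Inputs must be square with side
divisible by 2^(L−1) so pooling is exact; this is validated at forward
time.

The engine is plain numpy: convolutions are evaluated as im2col + BLAS
matrix products, the backward pass is analytic (the input gradient of a
same-padded convolution is the same-padded convolution with the spatially
flipped, channel-transposed kernel), and every layer is verified against
central finite differences in the test suite. Batch normalization exists
behind a config flag but is off by default. Weights are He-uniform
initialized from a seeded generator.

### Numerical choices

- Input normalization: fixed linear map from HU ∈ [−1024, +1024] to [0, 1],
  clipped outside. Dataset-independent, so a trained network is portable
  across cohorts without recalibration; raw-HU input to `predict` is
  rejected rather than silently rescaled.
- Loss: pixel-wise categorical cross-entropy over the softmax channels.
  The validation metric (foreground mIOU) is deliberately a different
  quantity, so early stopping measures segmentation quality, not the loss.
- The softmax cross-entropy backward flushes gradient entries below 1e-20
  to exact zero. Once the model is confident, off-class probabilities
  underflow into float32 subnormals, and subnormal arithmetic is an order
  of magnitude slower on x86; entries this small are far below Adam's
  update resolution, so the flush changes timing, not results.
- Argmax ties: `np.argmax` returns the first maximum, i.e. class 0
  (background).

## Training policy

Adam at learning rate 1e-4 (default), batch size 4, up to 1000 epochs.
After every epoch the foreground mIOU is computed on the un-augmented
validation slices. Early stopping halts after 100 epochs without a strict
improvement (min-delta 0); after 100 non-improving epochs the learning rate
is multiplied by 0.1 and the decay counter restarts. The returned model is
the checkpoint with the best validation mIOU, and the recorded
learning-rate trace is non-increasing by construction. Data order, weight
init and augmentation are all seeded, so a run is a pure function of
(data, config).

Train and validation sets must be patient-disjoint; the trainer checks the
patient ids and refuses leaking inputs.

## CT-aware augmentation

One augmentation draws dx, dy ~ U(−0.05, +0.05) (fraction of the image
side), hflip ~ Bernoulli(0.5) and angle ~ U(−20°, +20°), emulating patient
positioning variation. The maps compose in the fixed order flip → rotate
(about the pixel-grid center) → shift, collapsed into a single affine so
the image is resampled once: bilinear with air fill (−1000 HU) for the
image, nearest-neighbor with zero fill for the mask. Identity parameters
short-circuit to a bit-exact copy. Expansion by factor k keeps each
original plus (k−1) sampled copies — the study convention ×5 maps 616
training slices to 3080 — and records per-copy provenance so any copy can
be reproduced bit-exactly from its source and parameters.

Augmentation is applied offline to the already-HU-filtered ground truth
(materialized set, not per-epoch sampling); the transformed mask is not
re-filtered against the transformed image.

## Synthetic phantoms

Each phantom is an elliptical body (fat interior, mean −100 HU) on an air
background (−1000 HU), a vertebral body plus spinous process in bone HU
(mean +700), and six muscle compartments: psoas as rotated ellipses beside
the vertebra, quadratus lumborum as small lateral ellipses, paraspinal
muscle as posterior crescents (ellipse differences). Muscle HU are
N(50, 15²) plus global acquisition noise N(0, 10²), so essentially all
muscle pixels fall inside [−29, +150]; the geometry is mirror-symmetric
about the vertebral column in the nominal (unjittered) case. HU are
rounded to integers, stored int16, written as DICOM (RescaleSlope 1,
RescaleIntercept 0) or 16-bit PNG with calibration recorded in a manifest.

A cohort draws one uniform ±10% jitter vector per patient (compartment
centers and axes), shared by that patient's slices (default 4); slices of
one patient differ only by noise. This makes patient-level splitting
meaningful: slices of the same patient are highly correlated, as in real
cohorts.

What the phantoms do **not** emulate: vertebral morphology, contrast-agent
kinetics, scanner artifacts (beam hardening, rings), inter-organ soft
tissue variety, muscle-boundary fuzziness. Passing the phantom benchmarks
demonstrates that the pipeline's mechanics (labeling, splitting,
augmentation, optimization, scoring) are correct and that the network can
learn shape-from-context at realistic HU contrast; it does not certify
clinical accuracy on patient CT.

## Evaluation

The headline metric is the foreground Jaccard index per image, averaged
over the evaluation set (what the field calls mIOU in the two-class
setting). When prediction and reference are both empty the score is 1.0 —
perfect agreement on an empty slice is not penalized; this convention
matters for per-image averages and is applied uniformly. A two-class
(background + foreground) average exists behind a flag but is not the
headline. Per-image sd is across images. Confusion overlays color TP
white, FN green, FP red, TN black, and their pixel counts agree with the
confusion counts used by the metric.

Holdout cross-validation repeats 3 rounds; each round draws a fresh seeded
patient-level 6:2:2 split (round-half-up for train and val counts,
remainder to test — 256 patients give 154/51/51; for very small cohorts the
larger partition shrinks so the test set is never empty), trains every grid
model from scratch, and scores that round's test set. Final score per model
is the unweighted mean of the 3 round means; the selected model maximizes
the final mean with lower across-round sd as tie-break. All per-model seeds
derive from the round seed and grid position, so the report is bit-for-bit
reproducible.

## Problem sizes used in the shipped checks

The real study scale (512×512, n_base 16/32, depth 5, 1000 epochs) is not
exercised end to end in tests; counts and formulas are checked exactly at
that scale, while learning is demonstrated on a scaled-down surrogate
chosen to keep a full run on one CPU core in minutes:

- Surrogate training: 40 phantom patients × 4 slices at 128×128, 6:2:2
  split (96/32/32 slices), ×5-augmented training set (480 slices), n_base 8,
  depth 4, batch 4, 12 epochs at lr 1e-3. At this epoch budget the
  default lr 1e-4 is too slow to converge (full-scale runs converge in
  hundreds of epochs); 1e-3 is the surrogate's rate, not the library
  default. Held-out foreground mIOU ≈ 0.92–0.96 across seeds.
- Direction check: training thinned to 10 patients at 64×64 (n_base 4,
  depth 3, 10 epochs), with vs without ×5 augmentation, 3 seeded
  repetitions.
- CV harness: 8 patients at 32×32, grid {n_base 2, 4} × {DA, no-DA},
  3 rounds, 25 epochs.

## Known limitations

- The numpy engine is single-device and unbatched beyond BLAS threading;
  full 512×512 training at depth 5 is possible but slow (hours, not
  minutes).
- Binary head only; multi-class body composition (fat, bone) is out of
  scope.
- 2-D slices only; no volumetric context, no automatic L3/L4 slice
  selection.
- The both-empty = 1.0 Jaccard convention inflates averages on datasets
  with many empty reference slices; report the per-image distribution when
  that matters.
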