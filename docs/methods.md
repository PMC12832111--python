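# Methods

## Problem and model

`methylgan` predicts DNA N6-methyladenine (6mA) sites from fixed-length,
site-centered sequence windows: each input is a 41-bp window over
{A, C, G, T} whose central base (0-based index 20) is an adenine, labeled 1
if that adenine is methylated and 0 otherwise.  Windows are one-hot encoded
as 4 × 41 binary matrices (rows A, C, G, T; every column sums to 1).

The method is a two-stage *feature-synthesis fine-tuning* procedure:

1. **Stage 1 — base classifier.**  A convolutional network of five blocks
   (valid 1-D cross-correlation along the sequence, LeakyReLU, dropout),
   two fully connected hidden layers and a sigmoid output is trained with
   binary cross-entropy and Adam.  After every epoch the validation ROC-AUC
   is computed; a checkpoint is kept only on strict improvement, training
   stops after a patience budget without improvement, and the best
   checkpoint (not the last epoch) is returned.
2. **Stage 2 — feature synthesis and fine-tuning.**  The post-activation
   output of conv block 3 is flattened channel-major into feature vectors.
   One Wasserstein GAN with gradient penalty (WGAN-GP) is trained per class
   on those vectors; generator checkpoints are captured on a fixed epoch
   interval.  Each checkpoint is scored by a classifier two-sample test
   (CTST): real features labeled 1 and generated features labeled 0 are
   pooled, and a 1-nearest-neighbour classifier under leave-one-out
   cross-validation reports its accuracy; the checkpoint whose accuracy is
   closest to 0.5 (most indistinguishable) is selected, ties going to the
   earliest epoch.  Synthetic vectors from the selected generators — as many
   per class as that class's validation count — are reshaped back to
   (channels, positions) maps and injected at the block-3 output, and the
   network suffix (blocks 4–5 and the dense head) is fine-tuned with blocks
   1–3 frozen (weights and biases bit-identical before and after).
   Validation and test metrics always use real records only.

Both the stage-1 model and the fine-tuned model are evaluated on the same
held-out test records with Sen, Spe, Acc, MCC (threshold 0.5, score ≥
threshold predicts positive; MCC defined as 0 when a denominator factor
vanishes) and ROC-AUC, so the effect of fine-tuning reads off as a paired
comparison.

## Numerical core

No deep-learning framework is used.  `methylgan.autodiff` is a small
vectorized reverse-mode automatic-differentiation engine over NumPy arrays
(float64 throughout).  Dense operations express their backward pass in the
engine's own tensor operations, so gradients are differentiable again —
this supplies the second-order term of the WGAN-GP critic update, where the
loss contains ‖∇ₓD(x̂)‖₂ at interpolates x̂ = εx_real + (1−ε)x_fake.  The
1-D convolution is first-order only (the penalty path never crosses a
convolution) and the engine refuses to build a higher-order graph through
it.  Gradients were verified against central finite differences (first and
second order) and the convolution against a nested-loop oracle; these
checks are part of the test suite.

## Parameters that matter

Stage-1 architecture (the reference configuration): filter counts
(32, 64, 128, 128, 128), kernel height 5 spanning all incoming channels,
dropout 0.3 per block, LeakyReLU slope 0.01, FC widths (128, 32); Adam
lr 1e-3, batch 64, patience 10 within 100 epochs.  For CPU-minute
experiments and the test suite a *compact* variant — filters
(8, 16, 16, 16, 16), FC (32, 16), patience 5 within 30 epochs — is the
default in the pipeline; at the simulated-data scale below it performs at
the reference architecture's level in a fraction of the time.

WGAN-GP: gradient-penalty coefficient λ = 10, five critic updates per
generator update, Adam lr 1e-4 with betas (0, 0.9) — the standard WGAN-GP
recipe.  Generator and critic are 3-layer MLPs (LeakyReLU 0.2 hidden,
linear output; post-LeakyReLU features are unbounded reals, so the
generator output is deliberately unsquashed).  Checkpoints default to every
200 epochs over 2000; the desk-scale pipeline uses every 50 over 200.  An
epoch is one full shuffled pass over the real rows of one class.

Fine-tuning: Adam lr 1e-4 (an order below stage 1, preserving the learned
representation), frozen prefix = 3 conv blocks = the extraction depth; the
pipeline enforces that equality so synthetic maps enter the network exactly
where real features leave it.  Dropout stays active only in the unfrozen
blocks.  Real and synthetic rows are shuffled into the same minibatches.

Splitting: stratified per class — floor(n/10) to test, then
floor(remainder/9) to validation, rest to train; deterministic given the
split seed.  A single master seed fans out to named per-stage streams
(split, stage-1, per-class GANs, synthetic sampling, fine-tuning), all
recorded in the run report.

## The synthetic-data generator

`simulate` plants a width-9 position weight matrix (PWM), centered on the
site, into otherwise uniform-background sequence.  Negatives are pure
background.  Both classes have 'A' forced at the center — as in the real
benchmark, where negatives are unmethylated adenines — so the central base
carries no label information and a classifier must learn the flanking
motif.  A `strength` parameter in [0, 1] mixes the PWM with background
column-wise; at 0 the two classes are identically distributed, which the
tests exploit as a null case.

The default PWM puts 0.9 of each flanking column's mass on a fixed
consensus base.  This value was chosen from a likelihood-ratio ceiling
analysis: the Bayes-optimal AUC of the generative model at strength 0.8 is
≈ 0.986 with consensus mass 0.9, leaving realistic headroom for a trained
network, whereas softer motifs (e.g. mass 0.7, Bayes ceiling ≈ 0.93) cannot
support the near-ceiling discrimination the end-to-end checks probe.

What the simulator does *not* emulate: real 6mA sequence statistics (k-mer
composition, GC content, known methylation motifs such as GAGG),
position-dependent background, or class imbalance.  Passing tests therefore
demonstrate that the pipeline's machinery — encoding, training, synthesis,
selection, freezing, evaluation — behaves correctly on data of the
benchmark's shape and difficulty, not that any particular accuracy will be
attained on biological data.

## Problem sizes used by the tests and the acceptance script

End-to-end runs use 1000 + 1000 simulated 41-bp records at strength 0.8
(split 1600 / 200 / 200), the compact architecture, 200 GAN epochs with
checkpoints every 50, and ≤ 15 fine-tuning epochs; one run takes roughly
half a CPU-minute.  The GAN-convergence check uses 256 two-dimensional
Gaussian feature vectors for 1000 epochs.  CTST calibration uses 200 + 200
standard-normal points averaged over 20 seeds.  These sizes are the
package's desk-scale defaults; all of them are plain configuration and
scale up unchanged.

## Numerical and design choices

- Convolution is implemented as written in the field's usual component form
  (cross-correlation, no kernel flip); kernels span the full channel axis.
- Feature flattening is channel-major: map element (c, p) ↔ flat index
  c · positions + p; `reshape_to_layer` is its exact inverse, and a test
  pins the ordering.
- CTST distances are Euclidean; nearest-neighbour ties break to the lowest
  row index; the pooled synthetic sample is sized to the real sample for a
  balanced test.  The CTST reuses the rows the GAN trained on — at
  desk scale there is no held-out feature set to spare, and the selection
  only ranks checkpoints relative to one another.
- AUC uses the Mann–Whitney convention (ties count one half), identical to
  trapezoidal ROC integration; scikit-learn supplies ROC/AUC while the
  confusion-matrix metrics are computed directly from their definitions.
- The stage-1 loss is binary cross-entropy computed from logits via
  log-sigmoid for numerical stability.
- Early-stopping "improvement" is strictly greater validation AUC; ties do
  not refresh the checkpoint, so the first epoch attaining the maximum wins.
- Degenerate inputs fail loudly: ambiguity codes, ragged lengths,
  single-class validation sets, mixed-class GAN input, mismatched layer
  shapes and empty CTST inputs all raise.

## Known limitations

- Edge positions have no translation redundancy under valid convolution:
  with kernels ≥ 3 and a few hundred training records, a label carried by a
  single terminal position is memorized rather than generalized (train AUC
  1.0, validation near chance).  The separability sanity test therefore
  uses a position-wise (kernel-1) configuration.  Benchmark-like signals —
  motifs straddling the well-covered center — do not hit this regime.
- The WGAN-GP at desk scale (hundreds of rows, a few hundred epochs)
  produces features that remain CTST-distinguishable from real ones
  (accuracy ≫ 0.5); checkpoint selection still ranks checkpoints, and
  fine-tuning is validated as non-degrading rather than improving by a
  fixed margin.
- Training is CPU-bound, single-threaded NumPy; the full-width architecture
  on the real benchmark (≈ 40k records) is hours of CPU, not minutes, and
  is exposed but not exercised by the tests.
- `conv1d` supports first-order differentiation only; architectures that
  would place a convolution inside the gradient-penalty path are rejected.
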