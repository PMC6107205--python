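# Methods

## Scoring model

The pipeline treats histological scoring as ordinal classification followed
by probabilistic interpolation. Each 512×512-px tile (0.44 µm/px) receives a
softmax probability vector over the scheme's score classes plus an *ignore*
class. Scoring proceeds in three steps:

1. **Ignore gate.** A tile is excluded iff the ignore probability is the
   *strictly* largest component. A tie between the ignore mass and the best
   score class scores the tile — "not the largest" is read strictly, and the
   tie case is covered by a dedicated test. Gating on the argmax rather than
   a fixed threshold means borderline tiles still contribute whenever any
   score class is at least as plausible as the ignore interpretation.
2. **Renormalization.** The score-class probabilities are divided by their
   sum, removing the ignore mass. This makes the score invariant to how much
   probability leaked into the ignore component: scaling the score classes by
   (1−ε) and adding ignore mass ε leaves the score exactly unchanged, an
   algebraic identity the suite asserts to 1e-12.
3. **Weighted sum.** The continuous score is `A = Σ wᵢ p̃ᵢ` with weights
   (0, 1, 3, 5, 7) for the Ashcroft scheme and (0, 1, 2, 3) for inflammation.
   `A` is therefore a convex combination of the class weights and always lies
   inside the weight range; when the classifier is undecided between two
   classes the score interpolates monotonically between their weights.

The slide score is the arithmetic mean of `A` over non-ignored tiles. Because
`A` is linear in the renormalized probabilities, averaging tile scores equals
scoring the averaged renormalized vectors; the suite asserts this, so the
choice between the two aggregation orders is immaterial. A slide whose tiles
are all ignored yields a typed all-ignored result rather than a numeric mean.

## Tiling

Slides are downscaled by area averaging (BOX resampling; a 50% reduction of
a 20x scan approximates 10x optical sampling) and cut into a non-overlapping
grid anchored at (0,0); right/bottom remainders smaller than one tile are
dropped, not padded, because partial tiles would distort the cell-count and
area-fraction semantics the classes encode. Coordinates are 0-based
row-major (row, col) and are carried through scoring so maps reassemble
exactly. Blank-glass prefiltering (mean luminance > 0.95) exists as an
opt-in optimization but is off by default: non-scorable content is the
ignore class's job, keeping one mechanism responsible.

## Dataset handling

Training tiles live in one folder per class, named by the label. The
train/validation split is a global random 90/10 draw, reproducible per seed;
after the draw, any class with ≥2 items missing from one partition gets one
item swapped in (with a compensating swap back) so both partitions cover
every adequately represented class. A stratified per-class split is available
via a flag. Class imbalance is corrected by oversampling with replacement up
to the largest class — the simplest policy consistent with balancing, and it
never fabricates labels since every emitted item references an original file.

Augmentation applies only to training items: rotation uniform in [−45°, 45°]
with reflection filling (constant fill would introduce borders the classifier
could exploit), vertical flip with probability 0.5 (a deterministic
always-flip would merely relabel orientation), then resize to the model
input. Validation tiles are only resized.

## Classifier backends

The production recipe is transfer learning: an ImageNet-pretrained
convolutional backbone whose classification layer is replaced by a fresh
softmax head of width 6 (Ashcroft) or 5 (inflammation), fine-tuned on all
layers. Constructing it requires a deep-learning framework with pretrained
weights; in their absence `build_model("transfer_backbone", ...)` raises an
explicit error directing users to `small_cnn`.

`small_cnn` is a compact convolutional network implemented on numpy with
full backpropagation: three 3×3 conv blocks (8, 16, 32 channels, each
ReLU + 2×2 max-pool), global average pooling and a dense softmax head,
32-px inputs normalized to [−1, 1]. It exists so that training, scheduling,
scoring and evaluation can be exercised end-to-end on a CPU in seconds; it
is not intended to match a pretrained backbone on real tissue.

Optimization is SGD with momentum (default 0.9) and categorical
cross-entropy (implied by the softmax output). The plateau schedule is a pure
function of the validation-loss sequence: "did not reduce" means no new
strict minimum; after `patience` (3) consecutive non-improving epochs the
learning rate is multiplied by `factor` (1/5), floored at 1e-7, and the
counter resets (also on improvement). The best-validation-loss weights are
retained. Training stops early once the rate sits at the floor with no
improvement for 2×patience epochs. Defaults follow the fine-tuning recipe
(initial lr 0.5e-4); `TrainConfig.desk_scale()` raises the initial rate to
0.02 because a from-scratch network needs a much larger step than a
fine-tuned pretrained one. Batch size defaults to 32 (configurable).

## Synthetic tile generator

The generator produces Masson-trichrome-like caricatures, not photorealistic
histology. All morphology constants live in one `GeneratorParams` table:

| parameter | default | meaning |
|---|---|---|
| collagen table | {0: 0.02, 1: 0.08, 3: 0.25, 5: 0.50, 7: 0.85} | collagen fraction of tissue per Ashcroft class |
| collagen jitter | sd 0.01, clipped ±0.02 | per-tile variation, preserving class order |
| blob radius | 4–8 px at 512 px, scaled, min 2 px | nucleus-like blob size |
| airspace fraction | 0.35 | alveolar lumina share of the tile |
| palette | pink parenchyma, blue collagen, dark-purple nuclei, pale glass | trichrome approximation |

Fibrosis tiles draw a smooth random collagen field thresholded so the blue
texture occupies the requested fraction of tissue area; inflammation tiles
place exactly `cell_count` non-overlapping dark blobs (dispersed by default,
clustered via a flag, since the within-tile spatial distribution of
inflammatory cells is a free choice); ignore tiles mix two styles 50/50
(near-blank glass; large pale fat-like lobules with thin rims) to emulate
heterogeneous non-alveolar content. Rendering is a pure function of
(spec, seed): identical inputs give bit-identical images.

By construction a trivial feature separates the classes — blue-dominant
pixel fraction orders the fibrosis classes linearly, and connected-component
counting recovers blob counts exactly. Passing tests on this data therefore
demonstrates that the *pipeline machinery* (data handling, optimization,
aggregation, evaluation) is correct and learnable at desk scale; it says
nothing about accuracy on real tissue, where class boundaries are genuinely
ambiguous, staining varies between batches, and ignore content is far more
diverse.

## Desk-scale problem sizes

Suite experiments use 96-px tiles (the generator's minimum that still
carries morphology is 64 px) and 32-px CNN inputs. The end-to-end recovery
experiment trains on 60 tiles/class and scores 30 virtual slides of 4×4
tiles with graded ground-truth burden; the data-amount curve trains subsets
of {25, 50, 100, 200} tiles at a matched 12-epoch budget, 3 replicate seeds
per size, averaged. These sizes were chosen so the full suite runs in a
couple of minutes on one CPU while every stage still operates far from
degenerate regimes.

## Evaluation choices

Confusion matrices are row-normalized (rows: reference; columns: predicted);
zero-support rows are kept as all-zero and flagged so matrices from
different runs stay conformable. The adjacent-error statistic is computed on
the score classes only (errors into the ignore class are a different failure
mode) as the fraction of off-diagonal counts with |rank difference| = 1 in
weight order; a matrix with no off-diagonal mass returns an explicit
sentinel rather than a conventional 1.0. The expert comparison is OLS of
automated on expert scores with 5%/95% percentile-bootstrap intervals (2,000
paired resamples, seeded; analytic t-intervals via a flag) — the interval
method behind published fit uncertainties is rarely stated, and the
percentile bootstrap makes the fewest distributional assumptions. The
data-amount curve fits a Michaelis–Menten-like saturation
`A(n) = A_∞ · n/(n + k)` by default, with exponential saturation
`A_∞(1 − e^(−n/τ))` selectable; the true functional form is empirical, so
both are offered and the self-consistency of the fit is what the suite
checks.

## Numerical conventions

Probability vectors must sum to 1 within 1e-6 (softmax outputs); the
renormalized vector sums to 1 within 1e-9; the aggregation is checked
against an independent plain-Python oracle to 1e-12. Scores are written to
CSV at 3 decimals, full precision in JSON. The end-to-end pipeline fans a
single root seed out to per-stage seeds via SHA-256, so any stage can be
reproduced in isolation.

## Known limitations

- The transfer backbone is a contract plus an explicit unavailability error
  wherever pretrained weights cannot be loaded; fine-tuning at production
  scale requires a GPU deep-learning stack.
- The generator does not model staining variability, compression artifacts,
  tissue folds, or the gradual morphological continuum between adjacent
  Ashcroft grades; real-data adjacent-class ambiguity is therefore
  under-represented.
- The whole-slide reader handles single-resolution TIFF/PNG rasters;
  pyramidal scanner formats need prior conversion.
- The inflammation scheme counts cells irrespective of type; distinguishing
  inflammatory-cell subtypes is out of scope.
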