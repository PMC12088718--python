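# Methods

`milcta` implements a weakly supervised pipeline for detecting significant
coronary artery stenosis (≥50% luminal obstruction) from stacks of curved
multiplanar reformation (CMR) slices. A patient contributes a variable number
of slices but only one label per artery, derived from the radiological
report; the pipeline therefore treats each patient as a *bag* of slice
*instances* (multi-instance learning, MIL) under the clinical assumption that
a diseased artery shows its lesion on at least one reformation slice.

## Labels and splits

Stenosis is graded on the ordinal scale none / minimal (1–24%) / mild
(25–49%) / moderate (50–69%) / severe (70–99%) / total occlusion (100%). The
artery-level grade is the maximum over evaluated segments (1–15), and the
binary target is grade ≥ moderate. Splits are random 70/15/15 partitions *at
the patient level* — a patient with several bags never crosses splits — and
are stratified by the binary label. Test and validation counts per class use
round-half-up of `n_class × 0.15`; with the published artery totals
(776/311, 694/130, 600/93) this allocation reproduces the published per-split
positive counts (47/47/217, 20/20, 14/14). The published experiment is
repeated over five independent splits with consecutive seeds; all aggregate
metrics are means over the five test sets with a t-based 95% CI
(`mean ± t₀.₉₇₅,₄ · sd/√5`; a normal interval is selectable).

## Preprocessing

Each slice (a 2-D Hounsfield-unit grid) is windowed into five clinically
chosen HU ranges — (−150,−50), (−50,50), (50,130), (130,400), (400,1000) —
covering fat, soft plaque, fibrous tissue, contrast lumen and calcification.
Each window is clipped and mapped linearly to [0,1], filtered with 3×3 Sobel
kernels (reflect padding), and the gradient magnitude is divided by the
analytic bound 4√2 so that all windows share one scale; per-image scaling
would distort the subsequent pointwise-maximum fusion across windows. The
fused edge map is thresholded (default 0.25), an 8-pixel border frame is
zeroed (burned-in annotation text sits at the borders), connected components
smaller than 20 pixels are removed (strictly below: a 20-pixel object
survives), and the remaining components are ranked by the mean of min–max
normalized area, major axis length and perimeter. The top two components are
retained, the fused map is masked by them, and the result is resized
(aspect-preserving, zero-padded) to the model input size.

The edge threshold default of 0.25 is a noise-floor choice: with the
generator's σ = 15 HU noise, the Sobel response of pure noise inside an
80–100 HU-wide window is ≈ 0.13 of the 4√2 bound, so a threshold below that
floods the mask; 0.25 suppresses noise (speckle survival ≈ 2.5%, removed by
the small-object filter) while true step edges of vessel wall and plaque
(≈ 0.3–0.7) pass. The threshold, window list, connectivity (8), border
margin, kept-component count and output size are all configurable.

## Model

Bags hold exactly 36 processed slices in acquisition order. Patients with
more slices contribute `ceil(n/36)` bags; a short (or only) chunk is padded
by cycling the patient's own slices from the start, with padded entries
flagged. The network is:

1. a shared convolutional encoder applied per slice. The desk default
   (`small_cnn`) is a stack of stride-2 3×3 conv/ReLU blocks followed by
   global average *and* maximum pooling (concatenated) and a linear
   projection to the embedding; the max channel keeps a single small lesion
   visible in the slice embedding instead of being averaged away. A
   VGG16-shaped encoder (`vgg16_style`) is available for externally supplied
   pretrained weights; its first 15 sequential layers (convolutions and
   pooling counted alike) are frozen by default.
2. additive sinusoidal positional encoding of the in-bag index, so that
   order information survives the permutation-invariant attention.
3. one pre-norm multi-head self-attention block (4 heads, residual). The
   output projection is zero-initialized, so the block starts as the
   identity and learns to mix context.
4. gated attention pooling: `score_i = w·(tanh(V h_i) ⊙ σ(U h_i))`,
   attention = softmax(scores), bag embedding = Σ attention·h. The attention
   weights are the per-slice relevance scores reported to the user.
5. a dense → ReLU → dropout(0.2) → dense → sigmoid head on the bag
   embedding.

Patient-level probability is the maximum over the patient's bag
probabilities. Case attention assigns each original slice the maximum
attention over all its occurrences (replication never inflates a slice) and
renormalizes to sum to one per case.

## Training

Class-weighted binary cross-entropy (`w_c = N/(2·N_c)`), ADAM, learning-rate
reduction on validation plateau (factor 0.2, patience 5), early stopping
(patience 7) with best-weight restoration, and per-slice zoom/shift
augmentation (±10%); rotation is structurally unsupported — requesting it is
a hard configuration error — because it would scramble what the positional
encoding represents. The estimator default learning rate is 1e-4, the
reference fine-tuning setting; the bundled experiment configuration trains
the small encoder end-to-end and uses 1e-3, the conventional choice for a
from-scratch small CNN.

Two training devices matter at the ~100-bag scale of the bundled experiment:

**Surrogate pretraining.** The reference protocol relies on transfer
learning: encoder features that already separate generic structures, so the
attention stage only has to learn *which* slices matter. Trained from
scratch, attention pooling provides no per-instance credit assignment and
the encoder reliably collapses to the constant predictor (we verified that
the same encoder reaches slice-level AUC ≈ 0.97 under direct supervision on
identical inputs). The package therefore pretrains the encoder (seconds of
compute) on a procedurally generated pretext corpus: sparse edge-style
images of a random curvilinear outline, half of which contain one small
compact blob outline. The pretext task — "is there a focal structure on the
curvilinear structure?" — uses no patient data and no cohort labels and
plays the role ImageNet initialization plays in the reference protocol.
Disable with `pretrain="none"`.

**Context dropout.** With self-attention mixing lesion evidence into every
instance, the bag objective admits solutions whose pooling attention
concentrates on *normal* slices (anti-aligned, seed-dependent). During
training the MHA context branch is therefore dropped per bag with
probability `context_dropout` (stochastic depth): without the mixed-context
shortcut the prediction must be recoverable from instance-local features,
which anchors attention to the evidence-carrying slices. The bundled
experiment uses 0.7.

All randomness (initialization, shuffling, augmentation, dropout, splits,
cohort generation) derives from explicit seeds; inference runs in
deterministic eval mode.

## Synthetic cohort

Clinical CCTA data cannot be shared, so the generator emulates the relevant
image statistics on a 96×96 (configurable, default 192×192) grid: smooth
soft-tissue background around −30 HU clipped to [−120, 60]; a quadratic
Bézier vessel band (width 6–12 px) at ≈ 380–460 HU; on plaque-bearing
slices either a calcified plaque (compact ellipse ≥ 25 px at 750–900 HU
adjacent to the band — deliberately above the 20-px removal filter) or a
soft plaque (ellipse at 0–30 HU indenting the band, i.e. local lumen
narrowing detectable by the sub-130 HU windows); thin separated high-HU
strokes near the border imitating burned-in text; additive Gaussian noise
with σ = 15 HU. A positive patient has exactly `plaque_slices_per_positive`
(default 3 — a lesion is typically visible from several reformation angles)
plaque slices; a negative patient has none, so the patient label is the OR
over slice truths. Slice counts are uniform on the configured range
(default 6–144, matching the reported spread).

What the generator does *not* emulate: real CMR anatomy (myocardium,
branching vessels, bones), scanner physics (beam hardening, partial volume),
variable contrast timing, obstructing tissue, and label noise from report
extraction. Passing the synthetic recovery bars therefore validates the
*mechanism* — weak-label key-instance detection with interpretable
attention — not clinical performance.

## Evaluation

AUC-ROC (Mann–Whitney; ties count ½), Brier score (mean squared error of
the probability), equal-width 10-bin calibration tables with empty bins
dropped (fewer positives naturally yield fewer occupied bins), and a
threshold sweep over 0.01–0.50 in steps of 0.01 reporting sensitivity,
specificity, precision and F-score (precision and F are undefined, reported
as NaN, when nothing is predicted positive; ties at the threshold predict
positive). All evaluation is at the patient level.

## Problem sizes

The bundled experiment uses a 120-patient cohort (prevalence 0.4, 12–40
slices per patient, ≈ 3200 slices), 48×48 processed slices, a two-block
(8, 16)-channel encoder with 64-dimensional embeddings, batches of 8 bags
and at most 30 epochs per repeat — sizes chosen so the full five-repeat
experiment plus a five-repeat shuffled-label null completes in minutes on a
single CPU core. With these conditions the five-repeat mean patient-level
test AUC is ≈ 1.0, the argmax-attention slice of a positive test case is a
true plaque slice in ≈ 97% of cases, and the shuffled-label null sits near
chance.

## Known limitations

- The numerical core is a small reverse-mode autodiff engine written for
  exactly the operations this network needs; it is single-threaded numpy
  and not a general-purpose deep-learning runtime.
- `vgg16_style` reproduces the layer layout and freezing convention but
  ships no pretrained weights; nothing in the test surface depends on them.
- The file-based pipeline entry (DICOM/PNG input directories) covers
  reading, preprocessing and bagging; the bundled end-to-end experiment
  runs on the synthetic cohort.
- Whether the reference pipeline normalized windows linearly or by
  histogram is unstated; linear clipping is assumed. The component-ranking
  weights, kept-component count and text-removal mechanism are likewise
  unstated and exposed as configuration with the defaults above.
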