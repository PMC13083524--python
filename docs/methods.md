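# Methods

## Model

One patient contributes a bag of image patches and a bag of gene-set
expression features; the label lives at the patient level only.  The
classifier is trained end to end: cross-entropy gradients reach the patch
encoder through the attention aggregators.  Two components sit outside the
joint optimization by design — the upstream selection of significant gene
sets and the gene-set autoencoder — because both are unsupervised
preprocessing whose outputs are fixed inputs to the classifier.

### Patch encoder

A truncated MobileNetV4-style feature extractor: a 3×3 stride-2 stem, UIB
(universal inverted bottleneck) blocks, and a 1×1 high-channel head whose
global average pool is the patch feature vector.  Each UIB is
[optional depthwise 3×3] → 1×1 expansion → [optional depthwise 3×3] →
1×1 linear projection, every convolution followed by a batch-norm affine
pair; ReLU activations (a rectifier is required for APoZ to be
meaningful).  A block is *removable* exactly when it is stride 1 with equal
in/out channels, i.e. shape-neutral, so deleting it cannot break channel
chaining.

The reference configuration is pinned so that the closed-form parameter
count (convolution kernels + normalization affine terms; convolutions
carry no bias) hits the reference budgets exactly:

| stage | spec | params |
|---|---|---|
| stem | 3→16, 3×3/2 | 464 |
| down 1 | UIB 16→24, e=2, pre+mid dw | 1,920 |
| removables | 4 × UIB 24→24, e=2, mid dw | 11,904 |
| down 2 | UIB 24→64, e=2, pre+mid dw | 5,240 |
| removables | 3 × UIB 64→64, e=2, mid dw | 54,528 |
| down 3 | UIB 64→96, e=4, pre+mid dw | 45,184 |
| removables | 3 × UIB 96→96, e=2, mid dw | 118,656 |
| head | 1×1 96→1052 | 103,096 |

Total 340,992; after deleting the ten removables and APoZ-pruning the head
from 1052 to 164 channels, 68,880 (a 79.8% reduction).  The reference
totals constrain but do not determine the architecture; this configuration
is one consistent reconstruction, and the module treats it as a pinned
constant.  APoZ is computed per channel over a seeded calibration batch of
synthetic patches (default 256) as the fraction of post-ReLU entries equal
to zero; pruning is budgeted (keep the `k` lowest-APoZ channels, ties by
channel index) rather than thresholded, so parameter targets can be met
exactly.  Batch statistics are always the current bag's, making the
forward pass a deterministic function of the bag.

### Aggregation

Both branches are two pre-norm residual attention layers over a class
token plus instance tokens, with the final class token (after layer norm)
as the bag vector.

* **Nyström attention.** Full self-attention rows are approximated with
  `m` segment-mean landmarks (default 8) and a 6-iteration Newton–Schulz
  pseudo-inverse of the landmark kernel.  When `m >= n` the exact dense
  attention is computed instead.  The fixed-iteration pseudo-inverse also
  acts as a regularizer: the landmark kernel is often ill-conditioned and
  its exact pseudo-inverse amplifies noise.
* **PPEG.** Between the two image-branch layers, instance tokens are laid
  out on their ⌈√N⌉×⌈√N⌉ grid (padded by repeating leading tokens) and
  receive the sum of depthwise 3×3, 5×5 and 7×7 convolutions, residually.
  The convolutions are **zero-initialized**: the branch starts symmetric
  (identical tokens ⇒ uniform attention) and acquires grid structure only
  through training.  The gene branch has no PPEG and no padding and is
  therefore permutation-invariant over gene sets; it uses exact attention
  up to 64 tokens and Nyström landmarks beyond, since set counts from real
  enrichment analyses can reach the hundreds.
* **Cross-attention.** Single-query multi-head attention: the aggregated
  gene vector queries the image instance tokens and vice versa.  With the
  two self-attention vectors this yields four D-vectors, concatenated into
  a single linear classifier (ablation flags reduce this to two vectors or
  to one single-modality vector).
* **Exported attention weights** are the *exact* head-averaged softmax row
  of the class token (or cross query) in the final attention layer,
  restricted to real (non-padded) instances and renormalized.  The Nyström
  approximation is used for the full-sequence outputs only; its
  reconstructed rows can dip below zero and are never exported.

### Gene-set features

Counts → TPM (per patient, length-normalized to a 10⁶ total) → log2(·+1)
→ per-gene z-score across patients → per-set rows zero-padded to the
maximum set size with a binary mask → shared autoencoder
P→256→D→256→P with tanh units, trained by Adam on the masked MSE
Σ mask⊙(x−x̂)² / Σ mask (one global normalizer, not per-row).  The encoder
input is multiplied by the mask, so padded positions influence neither the
latent, the loss, nor any gradient — perturbing them leaves the training
trajectory bit-identical.  The per-gene z-score exists because log-TPM
values (≈0–20) saturate tanh units; it is linear per gene and preserves
class shifts.  The latent dimension D equals the image feature dimension
(reference 164; desk-scale studies use 32).  GO- and KEGG-derived sets are
processed independently, never merged.

### Training and evaluation

Adam (β 0.9/0.999), one patient bag per step, cross-entropy; default desk
scale lr 1e-3 for 15 epochs — small-scale sweeps showed results
insensitive to lr in [3e-4, 1e-3], and 1e-3 converges within the short
schedule.  Optional decoupled weight decay and a frozen-backbone flag
exist for ablations.  Splits: stratified 80/20 train/test plus stratified
five-fold partitions of the train portion, seeded.  Metrics: sensitivity,
specificity and F1 at the argmax threshold with a config-declared positive
class; ROC-AUC (equivalent to concordant-pair counting with ties at ½) and
PR-AUC by monotone-interpolated precision (p(r) = max precision at recall
≥ r, integrated stepwise — never below the step-wise average precision).
Fold-level model comparisons use the two-sided paired t-test (df = n−1),
raising on zero-variance differences rather than returning NaN.

### Attention significance

Per-patient gene-set attention rows (renormalized to sum 1) are compared
between label groups per set with the Mann–Whitney U test — exact
enumeration when both groups are small (<8) and tie-free, tie-corrected
normal approximation otherwise — then Benjamini–Hochberg FDR (chosen as
the standard step-up procedure), significant at adjusted p < 0.01.  Each
significant set gets a label-permutation check: statistic = |difference in
group mean attention|, p = (1 + #{permuted ≥ observed}) / (n_perm + 1)
with n_perm = 999 by default.  Because each attention row is a
composition (sums to 1), a between-class shift cannot touch a single set
in isolation; the forced-shift generator used in validation moves weight
*within* k ≥ 2 designated sets so that exactly those k differ.

### Tiling

Non-overlapping 256×256 grid (desk scale 64×64), row-major, partial edge
tiles dropped (fixed tensor shapes).  One Otsu threshold per slide — the
level maximizing between-class histogram variance, returned as the
boundary t+0.5 so "strictly below threshold" selects exactly the dark
class; a constant slide raises a degenerate-histogram error and is treated
as all background.  A patch is valid when its dark-pixel fraction strictly
exceeds 0.90.  Every patient contributes the cohort-minimum number of
valid patches (optionally capped, e.g. at the reference budget of 64);
selection is deterministic top-by-tissue-fraction with (row, col)
tie-break, with a seeded uniform alternative.

## Synthetic data

The generator emulates the two inputs at desk scale.  Slides: white
background (intensity ≈245) with dark elliptical tissue blobs (≈120,
Gaussian noise) grown to a target coverage of 0.5; fully-tissue tiles
carry dark spots whose count depends on the class (2 vs 10 per signal
tile, 6 in non-signal tiles), with a configurable signal-tile fraction.
Expression: negative-binomial counts (variance μ + φμ², φ = 0.1) with
log-normal per-gene means; member genes of designated DE sets have means
scaled by 2^lfc (default lfc = 1) in class 1.  The emitted adjusted-p
table marks the DE sets directly from the known assignment — differential
expression and enrichment testing are upstream tools, out of scope here.
Default study conditions: 40 patients per class, 512×512 slides, 16
patches of 64×64 px per bag, 10 gene sets of 20–60 genes over 800 genes,
3 DE sets.

The end-to-end recovery study passes the significance filter at α = 1.0 so
that all ten sets (three shifted, seven null) enter the model: the null
sets act as negative controls for the attention analysis, which would be
vacuous if only shifted sets were modeled.

What the generator does **not** emulate: real histology texture, stain
variation, magnification pyramids, correlated gene–image noise, set
overlap, and batch effects.  Passing tests therefore demonstrate that the
mechanics (tiling, budgeting, masking, attention, statistics, determinism)
are correct and that the architecture can learn a planted multimodal
signal — not that the model reaches any particular accuracy on real
cohorts.

## Numerical choices and degenerate inputs

* float32 for all network math; float64 for statistics and metrics.
* Attention/linear projections use uniform(±1/√fan_in) init; convolutions
  use ReLU-gain normal init.  The cooler linear init keeps attention
  logits trainable at start — with ReLU-gain init the softmax saturates
  and the branches memorize instead of generalizing.
* Otsu ties resolve to the lowest level; APoZ pruning ties to the lowest
  channel index; top-patch ties to the lowest (row, col).
* Zero-variance paired differences, empty groups, all-zero masks, constant
  slides, patients with zero valid patches, and missing modalities raise
  typed errors naming the offender rather than propagating NaN.
* All randomness flows through seeded `numpy.random.Generator` instances;
  identical config + seed reproduces metrics and significance CSVs byte
  for byte.

## Problem sizes used in validation

The shipped studies run 80-patient cohorts with 16-patch bags of 64×64 px,
feature dimension 32, 2 heads, 2 layers per branch, 8 landmarks, 15
training epochs, autoencoder 50 epochs — chosen as the smallest
configuration on which the planted signal is comfortably recoverable and
results are stable across seeds.  The pinned 164-dimensional reference
encoder is exercised structurally (parameter accounting, pruning,
shape/gradient contracts) rather than trained in the studies.

## Known limitations

* The reference backbone is a reconstruction constrained only by the
  reference parameter budgets; variant, truncation point and head width
  are otherwise underdetermined.
* Nyström approximation quality on short sequences is modest (the
  landmark kernel is noisy); the implementation falls back to dense
  attention when landmarks ≥ sequence length.
* Batch statistics (rather than running moments) make per-bag inference
  deterministic but mean single-patch inference is not supported.
* The permutation test reuses the trained model's attention values; it
  validates label association, not causal importance.
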