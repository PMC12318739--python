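# Methods

## Problem and model

The package classifies pulmonary nodules as benign or malignant from two
modalities per nodule: a 32×32×32 voxel CT cube `C` (1 mm isotropic,
intensity-windowed) and a 9×4 matrix `S` of structured radiographic
attributes (nine attributes × four radiologist readers).

The network (a dual cross-attention fusion classifier) is:

1. **Structured branch.** Each attribute row of `S` (a 4-vector of reader
   ratings) is embedded by two stacked linear maps with a single trailing
   ReLU: `S_emb = ReLU((S·W1 + b1)·W2 + b2)` with `W1 ∈ ℝ^{4×32}`,
   `W2 ∈ ℝ^{32×256}`, giving 9 tokens of width 256, then encoded by a
   six-block transformer encoder (`S_enc`, 9×256).
2. **Image branch.** The cube is split into its 32 axial slices; a single
   shared convolution with a full-slice 32×32 kernel, stride 32 and 256
   output channels maps each slice to one token (implemented as a linear map
   on the flattened slice — the identical computation), then a second
   six-block transformer encoder (`C_enc`, 32×256).
3. **Dual cross-attention.** Two independent single-head scaled dot-product
   attentions with learned Q/K/V projections (256×256, no bias, no output
   projection, scale `1/√256`): one uses image queries over structured
   keys/values (output `S_CA`, 32×256), the other structured queries over
   image keys/values (`C_CA`, 9×256). The subscript follows the key/value
   modality. There is no residual connection around cross-attention; layer
   norm and pooling are applied directly downstream.
4. **Pooling and head.** Each attended sequence is layer-normalized per
   token and mean-pooled over tokens to a 256-vector; the two pooled
   vectors are concatenated (structured first) into `V ∈ ℝ^{512}` and a
   single linear layer yields benign/malignant logits; training minimizes
   softmax cross-entropy. Benign = 0 = negative, malignant = 1 = positive.

The structured-embedding formula as commonly printed
(`W1·S` with `W1 ∈ ℝ^{4×32}` against a 9×4 `S`) is dimensionally
inconsistent; the row-wise right-multiplication `S·W1` used here is the
only reading consistent with the stated weight shapes.

### Choices where the architecture description is silent

* **Transformer block internals:** pre-norm blocks, 8 self-attention heads,
  feed-forward width 4×d with GELU, dropout 0.1, a final layer norm after
  the stack. All exposed in `ModelConfig`; these are this implementation's
  defaults, not protocol facts.
* **Positional information:** learnable positional embeddings added to both
  token sequences before encoding (slice order and attribute identity are
  meaningful); switchable off.
* **Token-axis pooling** (not feature-axis): the only reading that yields
  256-vectors and hence a 512-dim concatenation under a 2-class linear head.
* **Input scaling:** structured ratings are affinely rescaled to [0,1] per
  attribute using the *fixed* ordinal ranges (subtlety 1–5, internal
  structure 1–4, calcification 1–6, sphericity/margin/lobulation/
  spiculation/texture 1–5, diameter clipped to 0–40 mm) — never data
  statistics, so folds stay independent.
* **Initialization:** uniform fan-in scaling (`U(±1/√fan_in)`) from one
  seeded generator per model; all randomness (init, dropout, shuffling,
  folds) flows through explicit seeds, no global state.

### Ablation switches

`structured_only` / `image_only` drop the other branch and classify the
single pooled 256-vector; `no_transformer` replaces both encoders with the
identity (embeddings and positional terms remain); `no_cross_attention`
pools `S_enc`/`C_enc` directly and concatenates.

## Cohort construction

From LIDC-IDRI-style per-reader annotations: keep nodules ≥ 3 mm in
diameter with annotations from ≥ 3 readers (both thresholds inclusive).
The label is the mean malignancy score over present readers rounded to the
nearest integer — 1–2 benign, 4–5 malignant, 3 excluded. A missing fourth
reader's attribute is imputed as the rounded mean of the three present
values, clamped to the attribute's ordinal range; with ≥ 2 readers missing
an attribute the module raises rather than guessing (the 3-of-4 case is
the only one defined). Diameter is a per-nodule quantity and is replicated
across the four reader columns to complete the 9×4 matrix. Rounding ties
(.5) go half-up by default — one documented rule applied uniformly to
labels and imputation; half-even is available as a config option because
the tie rule silently changes cohort membership. Reader columns are sorted
by reader id, the imputed reader always in column four, so matrices are
deterministic across runs. "Consensus annotations from at least three
radiologists" is implemented as a reader *count*, not score agreement.

## CT preprocessing

Volumes are resampled to 1×1×1 mm (trilinear, output shape =
round(shape × spacing)), a 32³ window is cropped around the voxel nearest
to the annotated centre (mm → voxel by nearest-voxel rounding, 0-based
(z,y,x) indices), out-of-bounds voxels are padded with air (−1000 HU) and
flagged, and intensities are clipped to the lung window [−1000, 400] HU
and mapped affinely to [0,1]. Resampling precedes extraction; the window
bounds, interpolation order and pad value are config.

## Training protocol

Reference settings: 30 epochs, batch size 100, learning rate 5e-4, weight
decay 1e-3, five-fold cross-validation with every fold serving as the test
set once, final-epoch weights (no validation split, no early stopping).
The optimizer is AdamW — weight decay is named by the protocol and AdamW is
the standard decoupled formulation; Adam and SGD are config options. Folds
are stratified by label by default so each fold preserves the global class
ratio within one sample; a plain random partition is available. Per-fold
metrics are averaged arithmetically; pooled-confusion-matrix metrics are
reported alongside. Metrics with zero denominators are reported as
NaN/undefined, never as 0.

## Synthetic data generator

The generator stands in for the preprocessed real cohort (default size 684
samples at the real prevalence 330/684 malignant). Benign cubes are smooth
soft spheres (radius 6 mm, edge softness 0.8 mm, background 0.15, nodule
intensity 0.55, additive Gaussian noise σ = 0.05); malignant cubes grow the
radius by up to 3 mm and add six radial spiculation spikes plus a low-order
boundary irregularity. Ratings use class-conditional latent means with
malignant shifts on spiculation (+2), lobulation (+2), margin (−1.8) and
diameter (+8 mm), per-reader Gaussian jitter of 0.7 ordinal steps, rounded
and clamped to the ordinal ranges.

Every class difference is scaled by one separation knob δ ∈ [0, 1] *and* a
per-sample, per-modality attenuation drawn uniformly from [0.15, 1]. The
attenuations are independent between the cube and the ratings, so either
modality alone has genuinely ambiguous cases that the other modality often
resolves — this is what makes the multimodal-versus-unimodal comparison
meaningful rather than trivially saturated. δ = 0 zeroes every class
difference, giving a null dataset whose class-conditional distributions are
identical. The generator does not attempt radiologically realistic texture,
scanner noise spectra, or the real LIDC attribute correlations; passing
tests demonstrate that the pipeline learns and evaluates correctly, not
that the architecture's accuracy on real CT data is reproduced.

## Numerical core

No GPU framework is used: the network runs on a small in-repo reverse-mode
automatic-differentiation engine over float64 numpy arrays (broadcasting
arithmetic, batched matmul with a collapsed-gemm fast path, fused softmax /
layer-norm / cross-entropy primitives with closed-form gradients).
Gradients are validated against central finite differences, and each core
operation against explicit-loop brute-force oracles at 1e-6 in the tests.
Layer-norm epsilon is 1e-5; softmax and cross-entropy are max-shifted for
stability.

## Problem sizes used in tests and the acceptance script

Full-protocol training on a real-size cohort is not part of the test
suite; the suite uses desk-scale problem sizes chosen as standard practice
for CI-style verification of a research pipeline:

* overfit-capacity check: the full architecture (6 blocks, width 256) on
  20 samples, up to 200 epochs;
* cross-validation checks: 300 samples, a reduced model (2 blocks, width
  64) and 10 epochs, with batch size 30 and learning rate 3e-3 — the batch
  and rate are scaled to the smaller model and dataset so the run performs
  a meaningful number of optimization steps per fold;
* the same reduced setup for the δ = 0 null control and the
  structured-only/image-only ablation comparison.

## Known limitations

* Real LIDC-IDRI reproduction (cohort counts and headline accuracies)
  requires downloading the dataset and full-scale training; only the
  machinery is provided, not the numbers.
* The XML reader covers the common reading-session layout (characteristics
  per unblinded read); diameter and centre come from an external nodule
  list, as they are not part of the XML characteristics.
* Imputation with two or more missing readers is undefined and raises.
* The float64 CPU implementation is deliberately simple; it is fast enough
  for the desk-scale protocol, not for full-scale training.
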