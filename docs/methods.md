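# Methods

This note records what the package computes, the assumptions behind it,
and the design choices made where the design was genuinely open.

## Texture encoding and suppression

The encoding layer treats the backbone's `W×H×C` feature map as a bag of
`N = W·H` descriptors and aggregates residuals against `K` learnable
codewords with soft-assignment weights `softmax_j(−s_j‖r_ij‖²)`. The
result is orderless by construction: any permutation of the descriptors
yields the same `K×C` encoding, which is the property that makes the
representation suitable for dispersed fine-grained texture rather than
localised objects.

Suppression multiplies, per channel, the single maximal entry of the
encoding by `λ ∈ (0,1]`. Decisions taken here:

- **Tie-break.** If several codewords attain a channel's maximum, only the
  first (lowest codeword index) is suppressed. Ties have measure zero for
  learned real-valued encodings; fixing the rule keeps the "exactly one
  entry per channel" contract testable.
- **Signed maximum.** The maximum is over raw signed values, not
  magnitudes — the literal reading of "the maximum". Suppressing the
  largest-|·| entry instead is a defensible alternative; it is not what
  this package does.
- **Applied at training and inference.** Restricting suppression to
  training would make the representation seen by the classifier differ
  between phases for no benefit.
- **Smoothing factors are unconstrained** (the weight formula is
  well-defined for any real `s_k`), initialised U(0,1); codewords are
  initialised U(−1/√K, 1/√K), the usual dictionary-layer scale. Weights
  are computed with a per-descriptor log-sum-exp shift.

## Losses

- **Ordinal label distribution.** Profusion levels are unit-spaced
  integers 0…C−1; the ground-truth distribution for level `t` is
  `softmax_j(−|t−j|)`. It is maximal at `t`, strictly decaying with
  ordinal distance, and mirror-symmetric — the properties the tests pin.
- **Reweighted KL.** The divergence `Σ_j y_j ln(y_j/p_j)` is scaled by
  `1/π_t`, the inverse empirical frequency of the true level in the
  training split (computed once per split, not per batch). The loss is
  non-negative and zero only at `p = y`; `0·ln 0 ≡ 0`. A negated variant
  of this expression would be a quantity to maximise, which contradicts
  its role as an information-loss measure, so the non-negative form is
  used.
- **Supervised contrastive loss.** Implemented in the
  log-of-ratio-of-sums ("in") form: each anchor contributes
  `−log(Σ_pos e^{sim/τ} / Σ_all e^{sim/τ})`, class-averaged by `|M_c|`.
  The per-positive-pair ("out") form from the wider contrastive-learning
  literature is available as `supcon_variant="out"`. Similarity is cosine;
  embeddings are L2-normalised so it reduces to a dot product. Classes
  with a single member in a batch have no positive and are skipped with a
  warning; the label-balanced batch sampler (at least two samples per
  present class) makes this rare in practice.
- **Combination.** `L = α·ℓ_sup + β·ℓ_kl`, defaults α = β = 0.5, τ = 0.1.

## Network

An 18-layer residual backbone (no global pooling) feeds a 1×1
channel-reduction convolution, the encoding layer, L2 normalisation and a
fully connected head. For 256-px inputs the shapes are
8×8×512 → 8×8×256 → (8 codewords × 256) → 2048 → 4. Choices:

- **Grayscale replication.** Radiographs are single-channel; inputs are
  replicated to three channels so the standard 7×7 stem applies.
- **Flatten, not pool.** The `K×C` encoding is flattened to `K·C` before
  normalisation and classification; summing over codewords would discard
  the per-codeword structure, and nothing in the architecture table
  requires it.
- **One embedding.** The contrastive embedding and the classifier input
  are the same L2-normalised vector; no separate projection head.
- **Random initialisation.** No pretrained weights are required or
  downloaded; all randomness is fixed by the config seed.
- **Small backbone.** A `small` variant (halved widths 32…256, reduced
  channels 128, 64-px inputs) exists so the reference experiments run in
  minutes on one CPU. The layer layout is identical.

The layers are implemented directly on numpy arrays with hand-derived
backpropagation (im2col convolutions so the inner products run in BLAS);
gradient correctness is pinned by central-finite-difference tests at
relative error < 1e-4 on float64 instances. After the training loop the
batch-norm running statistics are recalibrated by one pass over the
unaugmented training data with frozen weights: momentum-tracked estimates
lag the rapidly changing batch statistics of a short run, and the
recalibration makes evaluation-mode behaviour consistent with the final
weights.

Training uses Adam. The full-scale defaults follow the protocol the
architecture was designed under (lr 1e-4, batch 16, 300 epochs, horizontal
flip and ±10° rotation augmentation, five-fold cross-validation); the
desk-scale experiments below use lr 1e-3, appropriate for a 30-epoch run
of the small model.

## Staging rules

The decision table is implemented with precedence III → II → I → Normal:

| Stage | Condition |
|---|---|
| III | level 3 in ≥ 5 zones **and** aggregation |
| II | level ≥ 2 in ≥ 5 zones, **or** level 3 in ≥ 4 zones |
| I | level ≥ 1 in ≥ 2 zones |
| Normal | otherwise |

The published count phrases are internally inconsistent (the Normal row
covers only "one subregion" while Stage I asks for "more than two", which
would leave two-zone profiles unclassifiable); the completion above is
exhaustive and monotone — raising any level or setting the aggregation
flag never lowers the stage — which the tests verify by enumerating all
8192 profiles. Counts are cumulative over higher levels because profusion
is ordinal. Aggregation (coalescence into a large opacity) is an input
flag; detecting it is out of scope.

The subregion splitter cuts each lung's bounding box into three
equal-height bands (integer thirds, 0-based half-open boxes), crops each
band to the mask's bounding box, zeroes background outside the mask and
resizes to the tile size. The exact zone geometry of the clinical
protocol is not numerically specified anywhere; equal thirds is the
simplest faithful reading. The patient's right lung is the image-left
component (radiographic convention). A single merged mask component is
split at the image midline; a mask missing one lung raises an error
naming the absent side.

## Synthetic benchmark

The generator emulates exactly the statistical structure the method
assumes, and nothing more:

- **Signal.** `n` isotropic Gaussian blobs ("rounded opacities") at
  uniform positions, with `n` drawn per level from
  (0–2, 8–16, 24–48, 64–128) on 256-px tiles — ranges chosen so adjacent
  levels overlap in appearance but are separable, the regime where ordinal
  label distributions should help.
- **Distractors.** Bright oblique bands (rib/clavicle surrogates) drawn
  from the same distribution at every level, so any classifier signal
  from them is spurious — the property the suppression strategy targets.
- **Background.** Smoothed Gaussian noise.

For other tile sizes, counts scale with the linear factor and radii with
its square root (for 64-px tiles: counts (0–1, 2–4, 6–12, 16–32), radii
1–3 px), keeping blobs resolvable. Each sample owns a random stream
derived from (seed, index), so datasets are bit-reproducible and
order-independent. An imbalance option apportions a total count by given
proportions (largest remainder) to exercise the class reweighting.

What the benchmark does **not** model: radiographic physics (scatter,
exposure), anatomy beyond rectangular lung fields, opacity shape
diversity, or inter-reader label noise. Passing the synthetic experiments
therefore demonstrates that the pipeline learns ordinal dispersed-texture
structure under controlled conditions — not clinical performance.

## Reference experiment

The desk-scale experiment (`pneumotex.experiments`) trains the small
backbone on 64-px tiles, 100 training and 25 held-out tiles per level
(data seed fixed, training seed varied), 30 epochs, α = β = 0.5, τ = 0.1,
K = 8, λ = 0.2, lr 1e-3. These sizes were chosen as the smallest
configuration in which the four levels remain confusable yet learnable.
The acceptance bar — held-out accuracy ≥ 0.7 with mean absolute level
error < 0.5 on at least two of three training seeds — sits far above the
0.25 chance level while leaving room for seed variance. The staging
agreement check assembles random six-zone profiles from held-out tiles and
compares the stage implied by predicted levels with the stage implied by
true levels.

## Numerical notes and limitations

- float32 parameters and activations in the network; float64 in the
  functional encoding/loss surface and all oracles.
- Softmax-style computations use log-sum-exp shifts throughout.
- Argmax ties (prediction, suppression) break toward the lowest index.
- The balanced batch sampler draws classes in pairs, cycling per-class
  pools; with fewer than two samples of a class overall, that class can
  appear once in a batch and is then skipped by the contrastive term.
- Training on one CPU is the intended regime; there is no GPU path, no
  mixed precision, and no multi-worker data loading.
- Cross-validation utilities are stratified and seeded; folds with a
  class smaller than k warn and fall back to best-effort stratification.
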