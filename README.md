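# pneumotex

Texture-encoding profusion grading and GBZ70-2015 staging of
pneumoconiosis chest radiographs.

## The problem

Pneumoconiosis staging rests on grading the *profusion* of small rounded
opacities — an ordinal level 0–3 — separately in six lung zones
(right/left × upper/middle/lower), then aggregating the six levels into a
final stage (Normal, I, II, III) under the GBZ70-2015 decision table.
The opacities are fine-grained textures dispersed over the whole zone, so
a plain CNN, which preserves spatial arrangement, is a poor fit: the
relevant statistic is global and orderless, and salient anatomy (ribs,
clavicles) easily dominates the learned features.

`pneumotex` implements the full pipeline for researchers working on
automated staging: a residual texture-encoding layer with channel-wise
suppression, ordinal label-distribution training with class reweighting,
supervised contrastive representation learning, the subregion/staging
protocol, and a seeded synthetic benchmark so everything is testable
without clinical data.

## The model

A feature map `X ∈ R^{W×H×C}` is treated as `N = W·H` descriptors `x_i`.
Against `K` learnable codewords `d_j` with smoothing factors `s_j`:

    r_ij = x_i − d_j
    ω_ij = exp(−s_j‖r_ij‖²) / Σ_k exp(−s_k‖r_ik‖²)
    e_j  = Σ_i ω_ij r_ij

giving an orderless `K×C` encoding `E`. Suppression damps the per-channel
maximum: `Ẽ_l = P_l ∘ E_l` with `P_lj = λ` where `E_lj = max(E_l)` and 1
elsewhere (`λ ∈ (0,1]`; `λ = 0.2` by default), so no single salient
structure can monopolise a channel.

Training minimises `L = α·ℓ_sup + β·ℓ_kl` (α = β = 0.5):

- `ℓ_sup` — supervised contrastive loss over the L2-normalised flattened
  encodings at temperature τ = 0.1;
- `ℓ_kl` — KL divergence between the predicted softmax and the ordinal
  ground-truth distribution `y_j ∝ exp(−|t−j|)`, scaled by the inverse
  training frequency `1/π_t` of the true level.

At test time the predicted level is the argmax of the predicted
distribution; six per-zone levels plus an aggregation flag are mapped to
the final stage by the decision table in `pneumotex.staging`.

## Worked example

```python
import numpy as np
from pneumotex import ProfusionClassifier, SyntheticParams, ProfusionProfile, final_stage
from pneumotex.synthetic import generate_arrays

params = SyntheticParams().scaled(64)          # 64-px tiles for a quick run
X, y, _ = generate_arrays(50, params, seed=0)  # 200 tiles, 50 per level
X_train, y_train, X_test, y_test = X[:160], y[:160], X[160:], y[160:]

clf = ProfusionClassifier(epochs=15, random_state=0)
clf.fit(X_train, y_train)
pred = clf.predict(X_test)
print("held-out accuracy:", round((pred == y_test).mean(), 3))
print("mean |level error|:", round(np.abs(pred - y_test).mean(), 3))

profile = ProfusionProfile(dict(zip(("RU","RM","RL","LU","LM","LL"), pred[:6])))
result = final_stage(profile)
print("stage:", result.stage, "|", result.triggered_rule)
```

Output:

```
held-out accuracy: 0.725
mean |level error|: 0.275
stage: I | profusion level 1 or higher in at least two subregions
```

The accuracy is over four ordinal levels (chance 0.25) after a deliberately
short 15-epoch run; the mean absolute level error shows the mistakes that
remain are almost all between adjacent levels. A longer run at the
reference experiment size (below) reaches ≈0.88.

The same model is available from the shell: `pneumotex generate`,
`pneumotex train`, `pneumotex evaluate`, `pneumotex encode`, and
`pneumotex stage` (see `pneumotex --help`).

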