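# frn3d

Binary classification of volumetric brain images (e.g. gray-matter density
maps from structural MRI) by **feature-map reconstruction**: a 3D residual
convolutional network extracts a spatial feature map from each volume, and a
closed-form ridge-regression head classifies a query by how well each class's
pooled support features can reconstruct it. The approach keeps the full
spatial feature grid — no global pooling — so localized, subtle group
differences (the typical signature of psychiatric conditions such as major
depressive disorder) are preserved through the classification stage.

## The model

A single-channel volume `x` passes through four stacked 3D residual modules
(two conv + batch-norm + ReLU layers each, with identity or 1×1×1-projected
skips; no pooling before the first block) and emerges as a feature map
`Q ∈ R^{r×d}`: `d`-channel feature vectors at `r` surviving spatial
locations. For each class `c`, the feature-map rows of its `k` support
images are pooled into `S_c ∈ R^{kr×d}`. The query is reconstructed from
each pool by ridge regression, solved in closed form:

    W̄   = Q S_cᵀ (S_c S_cᵀ + λI)⁻¹          (the unique minimiser of
                                              ‖Q − W S_c‖² + λ‖W‖²)
    Q̄_c = ρ W̄ S_c
    ⟨Q, Q̄_c⟩ = (1/r) ‖Q − Q̄_c‖²

and class probabilities are a softmax over the negative distances,
`P(y=c|x) ∝ exp(−γ ⟨Q, Q̄_c⟩)`. The head has exactly three learned scalars,
parameterized for positivity as

    λ = (kr/d) e^α,   ρ = e^β,   γ = e^g,        α = β = g = 0 initially.

Training is episodic (k support + q query subjects per class per step) and
minimises query cross-entropy plus `0.03 ×` an auxiliary loss
`Σ_{i≠j} ‖Ŝ_i Ŝ_jᵀ‖²` that pushes row-normalised support features of
different classes toward orthogonality. The schedule is SGD (momentum 0.9),
learning rate 0.01, weight decay 0.001, 100 epochs, with the rate cut ×0.1
after 10 epochs without validation-loss improvement, under stratified
fivefold cross-validation.

Since clinical cohorts of this kind are private, the package ships a
synthetic-cohort generator (`frn3d.synthetic`) producing brain-like volumes
with a known localized class effect, which makes every stage — and the whole
pipeline — testable.

## Worked example

```python
import numpy as np
from frn3d import (SyntheticConfig, generate_cohort, BackboneConfig,
                   TrainConfig, train_model)

cohort = generate_cohort(SyntheticConfig(
    shape=(32, 32, 32), n_per_class=30, effect_size=5.0, seed=7))
backbone_cfg = BackboneConfig(block_channels=(4, 8, 8, 16),
                              downsample_per_block=(True, True, True, True))
train_cfg = TrainConfig(epochs=15, episodes_per_epoch=6,
                        k_support=3, q_query=2, folds=5, seed=7)
models, results = train_model(cohort, train_cfg, backbone_cfg, folds_to_run=[0])
rep = results[0].report
print(f"held-out accuracy  {rep.accuracy:.3f}")
print(f"held-out recall    {rep.recall:.3f}")
print(f"held-out AUC       {rep.auc:.3f}")
head = models[0].head
print(f"learned head scalars: alpha={float(head.alpha.data):+.4f}, "
      f"beta={float(head.beta.data):+.4f}, gamma={float(np.exp(head.log_gamma.data)):.4f}")
```

prints (~20 s on one CPU core):

```
held-out accuracy  1.000
held-out recall    1.000
held-out AUC       1.000
learned head scalars: alpha=+0.0281, beta=-0.0473, gamma=1.1042
```

The cohort carries a strong localized effect (5 noise SDs inside a few
spherical regions), so a converged model should separate the 12 held-out
subjects perfectly; with `effect_size=0.0` the same pipeline stays at chance
level. The head scalars moving off zero shows that the ridge penalty,
recalibration and temperature are genuinely trained.

The same pipeline is available from the shell:

```
frn3d simulate sim.yaml --out cohort/      # NIfTI volumes + manifest.tsv
frn3d train train.yaml                     # cross-validated run directory
frn3d evaluate RUN_DIR cohort/manifest.tsv
frn3d predict RUN_DIR cohort/sub-pat-000.nii.gz
```

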