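# Methods

## Model

The classifier has two parts.

**Feature extractor.** A four-block 3D residual network maps a single-channel
volume to a spatial feature map. Each block is two k×k×k convolutions
(default k=3, shape-preserving padding k//2), each followed by batch
normalisation and a rectifier, with an identity skip connection; when the
block changes channel count or resolution the skip is a 1×1×1 convolution
(stride matching the block) plus batch norm. There is no pooling before the
first block — the volume enters the residual stack directly — and no global
pooling after the last: the output grid of shape (D′, H′, W′) with d
channels is flattened row-major over (depth, height, width) into the r×d
feature map Q, r = D′·H′·W′. The unpadded stride-1 convolution arithmetic
(h−k+1, w−k+1, d−k+1, n) is exposed separately (`conv3d_output_shape`) and a
tested shape law guarantees the instantiated network obeys the composed
per-layer arithmetic.

**Reconstruction head.** Support feature maps of class c are pooled row-wise
into S_c (kr×d). A query map is reconstructed per class by ridge regression
W̄ = Q S_cᵀ(S_c S_cᵀ + λI)⁻¹, recalibrated as Q̄_c = ρ W̄ S_c, and scored by
the deflated squared error ⟨Q, Q̄_c⟩ = ‖Q − Q̄_c‖²/r; probabilities are
softmax(−γ·distance). λ = (kr/d)e^α, ρ = e^β and γ = e^g are the head's only
parameters, initialised at α = β = g = 0 (λ = kr/d, ρ = γ = 1). The prose
around the penalty in the source method description suggests a 1/(kr)
scaling; the printed formula λ = (kr/d)e^α is the self-consistent one and is
what is implemented.

**Loss.** Query cross-entropy on the class-1 posterior (probabilities
clamped at 1e−12 before logs) plus 0.03 × the inter-class orthogonality
penalty Σ_{i≠j}‖Ŝ_i Ŝ_jᵀ‖², where Ŝ row-normalises each pool onto the unit
sphere. The double sum runs over ordered pairs, so each unordered pair
counts twice — implemented literally. The positive class is the patient
group throughout, which fixes the orientation of recall.

## Training protocol

Episodic: each step samples, without replacement within the episode,
k_support support and q_query query subjects per class from the training
split; the episode batch passes through the backbone once (batch-norm batch
statistics are computed over the whole episode). How supports are drawn
during supervised training is genuinely open; episodic resampling is the
choice here because the head requires a support pool at every step. At
evaluation time the support bank is the full training split of each class
(k = class size) — the most information-preserving reading of pooling "all"
support features.

Optimiser: SGD with momentum 0.9 — the schedule names only the learning rate
(0.01) and weight decay (0.001), and SGD is the convention for residual
networks. Weight decay applies to backbone parameters only; decaying the
head's log-scale scalars would fight the (kr/d) calibration of λ. The
learning rate is multiplied by 0.1 when the validation loss has not made a
new minimum for 10 consecutive epochs (the counter resets on improvement and
after a drop). Validation loss is the cross-entropy of the held-out split
classified against the full-training-split support bank, i.e. the same
protocol as final evaluation. Non-finite training loss aborts with a
diagnostic rather than continuing silently.

Cross-validation is stratified k-fold (default 5) via scikit-learn's
splitter; each fold trains a fresh backbone and head. All randomness — cohort
generation, initialisation, fold shuffling, episode sampling — flows from
integer seeds through named NumPy generators; repeated runs are bit-identical
on CPU.

## Numerical choices

- All model arithmetic runs in float64. The ridge solves use Cholesky
  factorisation of the Gram matrix plus λI; no explicit inverse is formed
  anywhere. The kr×kr system is solved when kr ≤ d and the d×d system
  otherwise; the two forms are algebraically identical (push-through
  identity) and their agreement is a tested invariant at 1e−8.
- The positive-definite solve's gradient is computed from the same
  factorisation (adjoints A⁻¹G and the symmetrised −A⁻¹G Xᵀ).
- Softmaxes subtract the row maximum before exponentiation.
- Classification ties break toward the lower class index (first argmin).
- Gaussian smoothing uses per-axis SD = FWHM/(voxel·2.3548), "nearest"
  boundary, kernel truncated at 6 SD (the common 4-SD truncation clips
  ~1e−4 of the mass, which visibly breaks linearity/semigroup identities).
  The smoothing FWHM is not dictated by the method; the default is 8 mm,
  the common convention for gray-matter maps, and it is configurable.
- Down-sampling to a cube is trilinear over the voxel-center field of view:
  exact on affine intensity profiles, idempotent on an already-cubic
  isotropic grid. Smoothing is applied before down-sampling (the order is
  not dictated; smooth-then-resample is the anti-aliasing order).
- Batch norm: eps 1e−5, running-stat momentum 0.1; evaluation mode uses the
  running statistics, which keeps inference deterministic and local (the
  receptive-field test relies on this).
- Convolution weights: He-normal initialisation, seeded; biases are omitted
  in conv layers (batch norm absorbs them).

## Synthetic cohorts

The generator emulates preprocessed gray-matter-density cohorts: an
axis-aligned ellipsoidal "brain" mask (30–70% of each axis), a smooth
baseline texture (white noise Gaussian-filtered at `smoothness_fwhm_vox`,
rescaled to unit SD), an additive class effect of `effect_size × noise_sd`
inside `n_effect_regions` spheres of radius `region_radius_vox` whose
centers are drawn once per cohort (group-level spatial consistency), and
independent voxel noise of SD `noise_sd`. Labels: 0 control, 1 patient.
`effect_size = 0` is an exact null — the label then enters the generative
process nowhere.

Defaults (effect 3 SD, 4 regions of radius 4, smoothness FWHM 6 voxels, 34
subjects per class) are conventions chosen to be plausible for group-level
gray-matter differences, not estimates from any dataset: no quantitative
effect geometry is available for the clinical cohorts this emulates. What
passing tests show is therefore that the pipeline recovers a localized
additive signal of stated size and stays at chance under the null — not
that it attains any particular accuracy on real patients. Real sMRI
features the generator does not model: anatomical structure and its
covariance, registration error, scanner bias fields, site effects,
age/sex confounds.

## Study sizes

The end-to-end studies (test suite and `scripts/acceptance.py`) use
32³-voxel cohorts of 30 subjects per class, a narrow backbone
(4, 8, 8, 16 channels, stride 2 in every block → r = 8, d = 16), 15 epochs
of 6 episodes, and a subset of the five folds (one held-out fold per seed
for the effect cohorts, two for the null) — sizes chosen so the full
pipeline, not a shortcut, runs comfortably on a single CPU core. The
paper-scale path (64³ input, 16–128 channels, 100 epochs, all five folds)
is the same code under the default configurations.

## Known limitations

- The reconstruction head is implemented for binary cohorts end-to-end;
  the head algebra itself is class-count agnostic but the training loop and
  metrics assume two classes.
- No data augmentation, no GPU path, no mixed precision.
- The block template (two convs per block, projection skips) is one
  faithful reading of the four-module residual extractor; exact layer
  counts/filter widths of the original are not recoverable and are exposed
  as configuration instead.
- Checkpoints store raw parameter arrays (NumPy `.npz`); they are tied to
  the architecture configuration recorded alongside them.
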