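# Methods

This note documents the models, simulation design, numerical choices and
known limitations of `neurocode`.

## The conversion problem

Two subjects viewing the same kind of stimuli represent shared content in
idiosyncratic voxel spaces. Neural code conversion learns a map
Φ : ℝᵐ → ℝⁿ from a source subject's activity pattern to the target's voxel
space. The package implements two training objectives:

- **Content loss** (the method of interest). With a frozen per-layer feature
  decoder (W_l, b_l) belonging to the *target*, the converter minimizes

  L(Φ) = Σᵢ Σₗ η_l ‖v_il − (W_l Φ(x_i) + b_l)‖², η_l = 1/‖v_il‖²,

  over the source's training stimuli. η is computed per sample and per layer
  on the units included in the current iteration (a per-layer-average
  variant is available via `weighting="per_layer_average"`). No target brain
  responses appear anywhere in the objective; the API enforces this by not
  accepting them.

- **Brain loss** (paired baseline). A linear map minimizing
  Σᵢ ‖y_i − (M x_i + c)‖² + λ‖M‖²_F on paired responses to shared stimuli,
  solved in closed form on centered data (bias unpenalized). λ defaults to
  generalized (leave-one-out) cross-validation over a log grid 10⁻²…10⁴.
  A pairwise orthogonal Procrustes transformation (centering + orthogonal
  matrix from the SVD of the cross-covariance; reflections permitted) is a
  second paired baseline.

### Converter architectures

The default converter is a two-hidden-layer MLP with instance normalization
and ReLU; each hidden layer has ⌈m/2⌉ units. Variants: a purely affine
"linear MLP" (three stacked linear layers, collapsible to a single (M, c)),
and a residual MLP adding three residual blocks of the hidden width.
Instance normalization standardizes each sample by its own mean/variance
across units, so single-sample and batched conversion agree by construction.

Two deliberate numerical choices, both absent from the loss definition but
important in practice:

- **Near-zero output initialization.** The frozen decoder constrains Φ(x)
  only within the row space of the stacked (W_l); voxel directions outside it
  receive no gradient. Initializing the output layer near zero leaves those
  directions at zero — a minimum-norm inductive bias analogous to ridge
  shrinkage — instead of at random values, which would add uninformative
  noise to every converted pattern.
- **Per-sample-mean gradients.** The reported loss trajectory is the sum
  over training samples, but optimizer steps use the gradient of the mean,
  so step sizes are independent of the training-set size. Without this,
  training at larger N oscillates with Adam's default step size.

### Training schedule

Each of 1,024 iterations draws one feature map (channel) per convolutional
layer uniformly at random and decodes all of its units; fully connected
layers are decoded in full every iteration. One Adam step
(lr 10⁻³, β = 0.9/0.999) is taken per iteration on the full training set
restricted to the sampled units. Training is deterministic given
(data, config, seed). Converters can consume trial-level responses
(default) or repetition averages (`trial_level=False`).

## Feature decoding

Per-layer ridge regression predicts stimulus features from voxel patterns.
Voxels and features are z-scored with training statistics; per layer, voxels
are ranked by their maximum absolute Pearson correlation with any of that
layer's units and the top 500 are kept (clipped with a warning when fewer
exist); the ridge penalty defaults to 100. Selection is per layer, not per
unit, keeping one weight matrix per layer. Constant voxels get unit sd, score
zero, and are never selected; constant feature units get zero weights and
their mean as bias. The fitted decoder is an affine map, so converter
training can differentiate through it. Note the default penalty of 100 is
calibrated to noisy responses; noiseless parameter-recovery experiments use a
small penalty (≤1), since shrinkage otherwise caps attainable accuracy.

## The virtual world

- **Stimuli.** Procedural 32×32 RGB composites (disks, squares, gratings,
  wedges over colored backgrounds) organized into categories with
  within-category jitter; train/test splits can be category-disjoint. The
  default world has 200 training and 50 test stimuli in 10 categories.
- **Content space.** A seeded differentiable extractor: three 3×3/stride-2
  convolution stages (8, 16, 16 channels) plus a 64-unit dense layer.
  Features are taken before rectification; rectified values propagate. A
  patch-embedding extractor (4×4 patches, two dense stages) provides a
  second, differently parameterized feature family for cross-feature-space
  generalization experiments.
- **Subjects.** Each voxel reads a random 10% of the mid-level convolutional
  layer's flattened units with Gaussian weights (the mid-level choice keeps
  both lower and higher layers only partially linearly decodable, so
  layer-wise comparisons are non-degenerate). Encoding rows are scaled so
  the stimulus-driven response has unit sd over the training stimuli; with
  Gaussian repetition noise of sd σ, the expected between-repetition profile
  correlation is 1/(1+σ²), which the simulation reproduces. The default
  "moderate SNR" condition is σ = 1 with 3 training and 5 test repetitions.
- **Sites.** Inter-site rosters are subjects tagged with different dataset
  ids; nothing forces stimulus sharing across sites.

What the simulation deliberately omits: hemodynamics, temporal
autocorrelation, session drift, ROI structure, and realistic inter-subject
topography statistics (the sparse-Gaussian ensemble is a modeling choice,
exposed as configuration). Passing tests therefore demonstrate the
*machinery* — optimization, metrics, statistics — under a linear encoding
model with i.i.d. noise, not performance on real fMRI data.

## Evaluation

- **Noise ceilings.** Pattern ceiling per stimulus: mean over repetition
  pairs of the across-voxel correlation between the two repetitions; profile
  ceiling per voxel: the analogous across-stimuli correlation. Exclusion
  threshold: the 99th percentile of a seeded random-pair null — repetition
  responses to mismatched stimuli (pattern) and mismatched voxel pairings
  (profile), 10,000 draws each. Raw correlations are divided by ceilings;
  excluded or non-positive-ceiling items become missing, never zero.
  Ceilings apply only to conversion metrics; decoding analyses retain all
  voxels. Normalized values can exceed 1 when the converter's output is less
  noisy than the repetitions the ceiling was estimated from. Ceilings use
  single-repetition pairs (not split-half averages).
- **Identification.** Each item is compared against all S−1 alternatives
  from the same test set (S×(S−1) comparisons; 50 items → 2,450); correct
  when the candidate correlates more with its own true feature vector; ties
  count 0.5 (unbiased under exchangeability); zero-variance candidates score
  0.5 on all comparisons and are flagged. Workbench experiments run
  identification per feature layer and average per-item accuracies across
  layers.
- **Group statistics.** Pair-level means are dyadic (pairs sharing a subject
  are dependent), so group means and 95% CIs come from a bootstrap that
  resamples source IDs and target IDs separately (1,000 replicates),
  drops same-ID pairs, and truncates/fills each replicate to the original
  sample size; empty replicates are redrawn and logged.

## Image reconstruction

A generator latent z (by default the pixels themselves, clipped to [0, 1])
is optimized so the extractor's features of the generated image match a
target feature stack:

z* = argmin_z L_mse + λ_tex L_tex + λ_str L_str

with γ_l = 1/‖u_l‖² layer weighting in the feature MSE, and structure/texture
terms built from per-channel spatial means, variances and cross-covariances
of convolutional feature maps (dense layers enter only the MSE). ε = 10⁻⁶
stabilizes the ratios; α_l = β_l = 1/L over included spatial layers;
λ_tex = λ_str = 1 by default. Optimization is SGD with momentum
(lr 0.1, momentum 0.9, 200 iterations); the lowest-loss iterate is returned,
so the result never regresses below the initialization. The deep-generator
prior is out of scope; the interface accepts any generator with a
differentiable `generate_tensor`, and a seeded toy dense decoder is provided.

## Simulation scale and capacity

Default experiment scale — 3-subject rosters, 250 voxels, 200/50 stimuli,
3/5 repetitions — completes a full conversion experiment in a few minutes on
one CPU. At this scale the default nonlinear MLP (≈125 hidden units
trained on ≈200 samples) memorizes its training set and converts nothing
discriminative, so workbench experiments default to the linear content MLP;
the nonlinear and residual variants remain available and are the right
choice when training data are plentiful relative to converter capacity.
Similarly, converter capacity, decoder penalties and training-set ladders
(default 25/50/100/200) are scaled-down analogues of much larger published
designs.

## Reproducibility

Every stochastic stage (world generation, subject draws, sessions, converter
training, bootstrap, reconstruction) takes an explicit seed; experiment
configs are hashable and serialized into run manifests, and generation is
bit-reproducible from (config, seeds).
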