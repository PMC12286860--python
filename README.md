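# neurocode

Content-loss **neural code conversion** between simulated fMRI subjects:
mapping one subject's multivoxel activity patterns into another subject's
voxel space *without any shared stimuli or paired brain data*, plus the
surrounding machinery — ridge feature decoding, noise-ceiling-normalized
evaluation, pairwise identification, dyadic bootstrap statistics, and
feature-inversion image reconstruction with structure/texture losses.

## Who this is for

Functional alignment methods usually need paired data: the same stimuli shown
to both subjects, so that a mapping between their brains can be regressed
directly. The content-loss approach removes that requirement. A converter
Φ : ℝᵐ → ℝⁿ from a source subject's m voxels to a target subject's n voxels
is trained so that the *target's* pre-trained feature decoder, applied to the
converted pattern, reproduces the true stimulus features of the *source's*
stimuli:

```
L(Φ) = Σᵢ Σₗ ηₗ ‖ v_il − (W_l Φ(x_i) + b_l) ‖²,     ηₗ = 1 / ‖v_il‖²
```

where `x_i` is the source's activity for stimulus i, `v_il` its true
layer-l feature vector, and `(W_l, b_l)` the target's frozen per-layer ridge
decoder. Only source-side responses and stimulus features enter the loss;
the training API does not even accept target responses. Baselines with paired
data are provided for comparison: a ridge-regularized linear map trained on
shared-stimulus responses ("brain loss", `‖y_i − (M x_i + c)‖² + λ‖M‖²_F`)
and pairwise orthogonal Procrustes.

Everything runs on **virtual subjects**: a procedurally generated stimulus
world with category-based train/test splits, a small differentiable
hierarchical feature extractor as the shared content space, and per-subject
random sparse linear voxel encodings with controlled repetition noise. No
fMRI downloads, no pretrained network weights; published unit-count
arithmetic for VGG19 / AlexNet / CLIP-ViT is included for dimension
validation only.

## Worked example

Convert one simulated subject's activity into another's voxel space with no
paired data, and evaluate against the target's measured responses:

```python
import neurocode as nc

# simulated world: 200 train / 50 test stimuli over 10 categories
world = nc.make_stimulus_world(rng_seed=0, n_train=200, n_test=50, n_categories=10)
source = nc.make_virtual_subject(1, world, n_voxels=250, noise_sd=1.0, subject_id="sub01")
target = nc.make_virtual_subject(2, world, n_voxels=250, noise_sd=1.0, subject_id="sub02")

# target decoder from the target's own training responses
tgt_train = nc.simulate_session(target, world.train, n_repetitions=3, rng_seed=10)
decoder = nc.fit_feature_decoder(tgt_train, world.train.features)

# content-loss converter: source data + target decoder, no paired responses
src_train = nc.simulate_session(source, world.train, n_repetitions=3, rng_seed=11)
config = nc.ContentTrainingConfig(kind="content_mlp_linear", rng_seed=0, trial_level=False)
converter = nc.train_content_converter(
    nc.average_repetitions(src_train), world.train.features, decoder, config)

# evaluate on held-out test stimuli against the target's measured activity
src_test = nc.simulate_session(source, world.test, n_repetitions=5, rng_seed=12)
tgt_test = nc.simulate_session(target, world.test, n_repetitions=5, rng_seed=13)
ceiling = nc.estimate_noise_ceiling(tgt_test, rng_seed=0)
converted = nc.convert(converter, nc.average_repetitions(src_test).mean_pattern())
table = nc.conversion_accuracy(converted, tgt_test, ceiling, pair="sub01->sub02")
print("normalized pattern r :", round(table[table.metric == "pattern_mean"].value.iloc[0], 3))
print("normalized profile r :", round(table[table.metric == "profile_mean"].value.iloc[0], 3))

decoded = nc.decode_features(decoder, converted)
acc = nc.decoding_accuracy(decoded, world.test.features)
for layer, vals in acc.items():
    print(f"decoding pattern r ({layer}):", round(vals["pattern_mean"], 3))
ident = nc.pairwise_identification(decoded.flat("conv2"), world.test.features.flat("conv2"))
print("identification (conv2):", round(ident["mean"], 3), "over", ident["n_comparisons"], "comparisons")
```

Output:

```
normalized pattern r : 0.994
normalized profile r : 1.144
decoding pattern r (conv1): 0.924
decoding pattern r (conv2): 0.979
decoding pattern r (conv3): 0.98
decoding pattern r (fc4): 0.977
identification (conv2): 0.808 over 2450 comparisons
```

The converted activity correlates with the target's measured voxel patterns
essentially at the noise ceiling (normalized pattern r ≈ 1; profile values can
exceed 1 because the converter's output is noise-free while the ceiling is
estimated from noisy repetitions). Features decoded from the converted
activity identify the correct stimulus among 49 alternatives 81% of the time
(chance 50%).

Higher-level experiment runners (`run_within_individual`,
`run_conversion_experiment`, `run_training_size_ladder`,
`run_cross_decoder_generalization`) reproduce whole pipeline shapes over
subject rosters and emit tidy metric tables with dyadic-bootstrap group
summaries. A `neurocode` CLI wraps the same functionality
(`simulate`, `train-decoder`, `train-converter`, `convert`, `evaluate`,
`reconstruct`, `run-experiment`, `report`).

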