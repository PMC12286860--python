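"""End-to-end experiment runner on virtual subjects.

Reproduces the pipeline shapes of the real studies — within-individual
decoding, pairwise conversion (content-loss without shared stimuli vs
brain-loss with shared stimuli), inter-site rosters, converter training-size
ladders and cross-feature-space generalization — at simulation scale, with
every stage seeded and all metrics emitted as tidy tables.

Converter training here consumes repetition-averaged responses and the
default roster is three subjects of 250 voxels on a 200/50-stimulus world;
these are the package's simulation-scale study conditions (see the methods
note), chosen so a full experiment runs in minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .conversion import (
    ContentTrainingConfig,
    train_brain_loss_converter,
    train_content_converter,
    convert,
)
from .evaluation import (
    conversion_accuracy,
    dyadic_bootstrap,
    enumerate_conversion_pairs,
    estimate_noise_ceiling,
    pairwise_identification,
)
from .feature_decoding import decode_features, decoding_accuracy, fit_feature_decoder
from .feature_world import FeatureStack, ToyConvExtractor, ToyPatchExtractor
from .virtual_subjects import (
    StimulusSet,
    average_repetitions,
    make_stimulus_world,
    make_virtual_subject,
    simulate_session,
    split_source_target_nonoverlapping,
)

__all__ = [
    "ExperimentConfig",
    "run_within_individual",
    "run_conversion_experiment",
    "run_training_size_ladder",
    "run_cross_decoder_generalization",
]


@dataclass
class ExperimentConfig:
    # stimulus world
    n_train: int = 200
    n_test: int = 50
    n_categories: int = 10
    image_size: int = 32
    category_disjoint: bool = True
    # subjects: (dataset_id, n_subjects) per simulated site
    rosters: tuple = (("dsA", 3),)
    n_voxels: int = 250
    noise_sd: float = 1.0
    encoding_layer: str = "conv2"
    encoding_density: float = 0.1
    n_repetitions_train: int = 3
    n_repetitions_test: int = 5
    # feature decoder
    n_voxels_select: int = 500
    ridge_penalty: float = 100.0
    # converter
    converter_kind: str = "content_mlp_linear"  # capacity matched to simulation scale
    n_iterations: int = 1024
    learning_rate: float = 1e-3
    weighting: str = "per_sample"
    trial_level: bool = False  # averaged responses at simulation scale
    nonoverlapping: bool = False  # True trains content converters on category-disjoint halves
    with_brain_baseline: bool = True
    # evaluation
    scope: str = "within_dataset"
    ladder: tuple = (12, 25, 50, 100)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "rosters" in d:
            d["rosters"] = tuple(tuple(r) for r in d["rosters"])
        if "ladder" in d:
            d["ladder"] = tuple(d["ladder"])
        return cls(**d)


def _content_config(config: ExperimentConfig, seed: int) -> ContentTrainingConfig:
    return ContentTrainingConfig(
        n_iterations=config.n_iterations,
        kind=config.converter_kind,
        learning_rate=config.learning_rate,
        weighting=config.weighting,
        trial_level=config.trial_level,
        rng_seed=seed,
    )


class _Bench:
    """Shared simulated state (world, subjects, cached sessions/decoders)."""

    def __init__(self, config: ExperimentConfig, extractor: ToyConvExtractor | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.extractor = extractor or ToyConvExtractor(seed=0, input_size=config.image_size)
        self.world = make_stimulus_world(
            int(rng.integers(2**31)),
            n_train=config.n_train,
            n_test=config.n_test,
            n_categories=config.n_categories,
            image_size=config.image_size,
            category_disjoint=config.category_disjoint,
            extractor=self.extractor,
        )
        self.subjects = []
        for ds_id, count in config.rosters:
            for _ in range(count):
                self.subjects.append(
                    make_virtual_subject(
                        int(rng.integers(2**31)),
                        self.world,
                        n_voxels=config.n_voxels,
                        noise_sd=config.noise_sd,
                        dataset_id=ds_id,
                        encoding_layer=config.encoding_layer,
                        density=config.encoding_density,
                    )
                )
        self.by_id = {s.subject_id: s for s in self.subjects}
        if config.nonoverlapping:
            self.source_half, self.target_half = split_source_target_nonoverlapping(
                self.world, int(rng.integers(2**31))
            )
        else:
            self.source_half = self.target_half = self.world.train
        self._rng = rng
        self._cache: dict = {}

    def seed(self) -> int:
        return int(self._rng.integers(2**31))

    def session(self, subject_id: str, stimuli: StimulusSet, reps: int, tag: str):
        key = ("sess", subject_id, tag)
        if key not in self._cache:
            self._cache[key] = simulate_session(
                self.by_id[subject_id], stimuli, reps, self.seed(), split=tag
            )
        return self._cache[key]

    def decoder(self, subject_id: str, stimuli: StimulusSet, tag: str = "tgt"):
        key = ("dec", subject_id, tag)
        if key not in self._cache:
            sess = self.session(subject_id, stimuli, self.config.n_repetitions_train, f"train-{tag}")
            self._cache[key] = fit_feature_decoder(
                sess,
                stimuli.features,
                n_voxels_select=self.config.n_voxels_select,
                ridge_penalty=self.config.ridge_penalty,
            )
        return self._cache[key]


def _identification_accuracies(decoded: FeatureStack, true: FeatureStack) -> np.ndarray:
    """Per-item identification accuracy, averaged over feature layers.

    Identification is run separately per layer (as the published analyses do)
    and the per-item accuracies are then averaged across layers.
    """
    return np.mean(
        [
            pairwise_identification(decoded.flat(n), true.flat(n))["accuracies"]
            for n in decoded.layer_order
        ],
        axis=0,
    )


def _identification_from_features(decoded: FeatureStack, true: FeatureStack) -> float:
    return float(_identification_accuracies(decoded, true).mean())


def run_within_individual(config: ExperimentConfig) -> pd.DataFrame:
    """Standard within-individual decoding: decoder trained and tested on one subject."""
    bench = _Bench(config)
    rows = []
    test = bench.world.test
    for sub in bench.subjects:
        dec = bench.decoder(sub.subject_id, bench.world.train, tag="within")
        test_sess = bench.session(sub.subject_id, test, config.n_repetitions_test, "test")
        decoded = decode_features(dec, average_repetitions(test_sess).mean_pattern())
        acc = decoding_accuracy(decoded, test.features)
        for layer, vals in acc.items():
            rows.append((sub.subject_id, layer, "decoding_pattern", vals["pattern_mean"]))
            rows.append((sub.subject_id, layer, "decoding_profile", vals["profile_mean"]))
        rows.append(
            (sub.subject_id, "all", "identification", _identification_from_features(decoded, test.features))
        )
    return pd.DataFrame(rows, columns=["subject", "layer", "metric", "value"])


def run_conversion_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Pairwise conversion with content-loss (and optionally brain-loss) converters.

    Content converters are trained on the source subject's responses to the
    source stimulus half against the target subject's decoder (trained on the
    disjoint target half) — no shared stimuli. Brain-loss converters use the
    paired repetition-averaged responses of both subjects to the full
    training set. Held-out test responses are converted, compared against the
    target's measured test activity under noise-ceiling normalization, and
    decoded for feature/identification metrics.
    """
    bench = _Bench(config)
    roster = [(s.subject_id, s.dataset_id) for s in bench.subjects]
    grid = enumerate_conversion_pairs(roster, config.scope)
    test = bench.world.test
    rows = []
    for src_id, tgt_id, src_ds, tgt_ds in grid.pairs:
        pair = f"{src_id}->{tgt_id}"
        dec = bench.decoder(tgt_id, bench.target_half)
        src_train = bench.session(src_id, bench.source_half, config.n_repetitions_train, "train-src")
        src_test = bench.session(src_id, test, config.n_repetitions_test, "test")
        tgt_test = bench.session(tgt_id, test, config.n_repetitions_test, "test")
        ceiling = estimate_noise_ceiling(tgt_test, rng_seed=config.seed)
        src_pattern = average_repetitions(src_test).mean_pattern()
        converters = {}
        cc = train_content_converter(
            src_train, bench.source_half.features, dec, _content_config(config, config.seed)
        )
        converters["content"] = cc
        if config.with_brain_baseline:
            pair_src = bench.session(src_id, bench.world.train, config.n_repetitions_train, "paired")
            pair_tgt = bench.session(tgt_id, bench.world.train, config.n_repetitions_train, "paired")
            converters["brain"] = train_brain_loss_converter(
                pair_src.mean_pattern(), pair_tgt.mean_pattern()
            )
        for name, conv in converters.items():
            converted = convert(conv, src_pattern)
            table = conversion_accuracy(converted, tgt_test, ceiling, pair=pair)
            for metric in ("pattern_mean", "profile_mean"):
                val = table.loc[table.metric == metric, "value"].iloc[0]
                rows.append((pair, src_id, tgt_id, name, f"conversion_{metric}", val))
            decoded = decode_features(dec, converted)
            acc = decoding_accuracy(decoded, test.features)
            dec_pattern = np.nanmean([v["pattern_mean"] for v in acc.values()])
            rows.append((pair, src_id, tgt_id, name, "decoding_pattern_mean", dec_pattern))
            rows.append(
                (pair, src_id, tgt_id, name, "identification",
                 _identification_from_features(decoded, test.features))
            )
    df = pd.DataFrame(
        rows, columns=["pair", "source", "target", "converter", "metric", "value"]
    )
    # dyadic bootstrap group summaries where the roster allows them
    summaries = []
    for (conv_name, metric), sub in df.groupby(["converter", "metric"]):
        vals = {(r.source, r.target): r.value for r in sub.itertuples()}
        if len({s for s, _ in vals}) >= 2 and len({t for _, t in vals}) >= 2:
            ci = dyadic_bootstrap(vals, rng_seed=config.seed)
            summaries.append(
                ("group", "", "", conv_name, f"{metric}_group", ci.mean)
            )
            summaries.append(("group", "", "", conv_name, f"{metric}_ci_low", ci.lower))
            summaries.append(("group", "", "", conv_name, f"{metric}_ci_high", ci.upper))
    if summaries:
        df = pd.concat(
            [df, pd.DataFrame(summaries, columns=df.columns)], ignore_index=True
        )
    return df


def run_training_size_ladder(config: ExperimentConfig) -> pd.DataFrame:
    """Identification accuracy of one pair's content conversion vs training-set size."""
    bench = _Bench(config)
    if len(bench.subjects) < 2:
        raise ValueError("ladder experiment needs at least 2 subjects")
    src, tgt = bench.subjects[0], bench.subjects[1]
    dec = bench.decoder(tgt.subject_id, bench.target_half)
    test = bench.world.test
    src_test = bench.session(src.subject_id, test, config.n_repetitions_test, "test")
    src_pattern = average_repetitions(src_test).mean_pattern()
    n_avail = len(bench.source_half.stimulus_ids)
    order = np.random.default_rng(config.seed).permutation(n_avail)
    rows = []
    for size in config.ladder:
        size = min(size, n_avail)
        subset_mask = np.zeros(n_avail, dtype=bool)
        subset_mask[order[:size]] = True
        stimuli = bench.source_half.subset(subset_mask)
        sess = simulate_session(src, stimuli, config.n_repetitions_train, bench.seed())
        conv = train_content_converter(
            sess, stimuli.features, dec, _content_config(config, config.seed)
        )
        decoded = decode_features(dec, convert(conv, src_pattern))
        accs = _identification_accuracies(decoded, test.features)
        rows.append((size, float(accs.mean()), float(accs.std() / np.sqrt(len(accs)))))
    return pd.DataFrame(rows, columns=["n_train", "identification", "se"])


def run_cross_decoder_generalization(config: ExperimentConfig) -> pd.DataFrame:
    """Converter trained against feature space A, evaluated with a decoder for space B.

    The converted activity is decoded with the target's extractor-B decoder
    and compared with the target's own within-individual extractor-B
    decoding; a shuffled-stimulus control (converter trained on permuted
    source features) provides the negative reference.
    """
    bench = _Bench(config)
    if len(bench.subjects) < 2:
        raise ValueError("cross-decoder experiment needs at least 2 subjects")
    src, tgt = bench.subjects[0], bench.subjects[1]
    ext_b = ToyPatchExtractor(seed=100, input_size=config.image_size)
    test = bench.world.test
    feats_b_test = ext_b.extract(test.images, list(test.stimulus_ids))
    feats_b_tgt_half = ext_b.extract(
        bench.target_half.images, list(bench.target_half.stimulus_ids)
    )
    dec_a = bench.decoder(tgt.subject_id, bench.target_half)
    tgt_train = bench.session(
        tgt.subject_id, bench.target_half, config.n_repetitions_train, "train-tgt"
    )
    dec_b = fit_feature_decoder(
        tgt_train, feats_b_tgt_half,
        n_voxels_select=config.n_voxels_select, ridge_penalty=config.ridge_penalty,
    )
    src_train = bench.session(src.subject_id, bench.source_half, config.n_repetitions_train, "train-src")
    src_test = bench.session(src.subject_id, test, config.n_repetitions_test, "test")
    tgt_test = bench.session(tgt.subject_id, test, config.n_repetitions_test, "test")
    src_pattern = average_repetitions(src_test).mean_pattern()
    conv = train_content_converter(
        src_train, bench.source_half.features, dec_a, _content_config(config, config.seed)
    )
    rows = []
    decoded_cross = decode_features(dec_b, convert(conv, src_pattern))
    acc_cross = decoding_accuracy(decoded_cross, feats_b_test)
    decoded_within = decode_features(dec_b, average_repetitions(tgt_test).mean_pattern())
    acc_within = decoding_accuracy(decoded_within, feats_b_test)
    for layer in feats_b_test.layer_order:
        rows.append(("cross_decoder", layer, acc_cross[layer]["pattern_mean"]))
        rows.append(("within", layer, acc_within[layer]["pattern_mean"]))
    # shuffled-stimulus negative control
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(bench.source_half.stimulus_ids))
    shuffled = bench.source_half.features.subset(perm)
    shuffled.stimulus_ids = list(bench.source_half.stimulus_ids)
    conv_sh = train_content_converter(
        src_train, shuffled, dec_a, _content_config(config, config.seed)
    )
    decoded_sh = decode_features(dec_b, convert(conv_sh, src_pattern))
    acc_sh = decoding_accuracy(decoded_sh, feats_b_test)
    for layer in feats_b_test.layer_order:
        rows.append(("shuffled_control", layer, acc_sh[layer]["pattern_mean"]))
    return pd.DataFrame(rows, columns=["condition", "layer", "value"])
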