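"""Simulated stimulus worlds and virtual fMRI subjects.

A stimulus world is a set of procedurally drawn images organized into
categories with train/test splits (optionally category-disjoint, mirroring
natural-image datasets whose test categories never appear in training). A
virtual subject is a fixed linear readout ("encoding") from a designated
layer of the shared feature hierarchy into its own idiosyncratic voxel space,
plus i.i.d. Gaussian repetition noise. Two subjects therefore share latent
stimulus content but have unrelated functional topographies — the situation
neural code conversion is meant to bridge.

Encoding rows are scaled so each voxel's stimulus-driven response has unit
standard deviation over the world's training stimuli; ``noise_sd`` is then
directly interpretable as the inverse of the per-trial SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .feature_world import FeatureStack, ToyConvExtractor

__all__ = [
    "StimulusSet",
    "VirtualSubject",
    "ResponseDataset",
    "make_stimulus_world",
    "make_virtual_subject",
    "simulate_session",
    "split_source_target_nonoverlapping",
    "average_repetitions",
]

DEFAULT_ENCODING_LAYER = "conv2"
MAX_VOXELS = 100_000


@dataclass
class StimulusSet:
    stimulus_ids: list[str]
    categories: np.ndarray  # (n,) integer category label per stimulus
    images: np.ndarray  # (n, H, W, C) in [0, 1]
    features: FeatureStack
    split: np.ndarray  # (n,) 'train' | 'test'

    def __post_init__(self):
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("stimulus ids must be unique")

    def _mask(self, tag: str) -> np.ndarray:
        return np.asarray(self.split) == tag

    def subset(self, mask: np.ndarray) -> "StimulusSet":
        idx = np.flatnonzero(mask)
        return StimulusSet(
            [self.stimulus_ids[i] for i in idx],
            self.categories[idx],
            self.images[idx],
            self.features.subset(idx),
            self.split[idx],
        )

    @property
    def train(self) -> "StimulusSet":
        return self.subset(self._mask("train"))

    @property
    def test(self) -> "StimulusSet":
        return self.subset(self._mask("test"))


@dataclass
class VirtualSubject:
    subject_id: str
    dataset_id: str
    encoding: np.ndarray  # (n_voxels, feature_dim)
    bias: np.ndarray  # (n_voxels,)
    noise_sd: float
    encoding_layer: str = DEFAULT_ENCODING_LAYER
    roi: np.ndarray | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_vox, dim = self.encoding.shape
        if n_vox <= dim and np.linalg.matrix_rank(self.encoding) < n_vox:
            raise ValueError("encoding matrix is rank deficient")

    @property
    def n_voxels(self) -> int:
        return self.encoding.shape[0]

    def clean_responses(self, features: FeatureStack) -> np.ndarray:
        """Noise-free responses (stimuli, voxels) for a feature stack."""
        f = features.flat(self.encoding_layer)
        return f @ self.encoding.T + self.bias


@dataclass
class ResponseDataset:
    subject_id: str
    stimulus_ids: list[str]
    responses: np.ndarray  # (stimuli, repetitions, voxels)
    split: str = "train"
    dataset_id: str = ""

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (stimuli, repetitions, voxels)")
        if self.responses.shape[0] != len(self.stimulus_ids):
            raise ValueError("stimulus count mismatch between ids and responses")

    @property
    def n_repetitions(self) -> int:
        return self.responses.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[2]

    def mean_pattern(self) -> np.ndarray:
        """Repetition-averaged (stimuli, voxels) activity."""
        return self.responses.mean(axis=1)

    def trials(self) -> tuple[np.ndarray, list[str]]:
        """Trial-level (stimuli*reps, voxels) activity with per-trial stimulus ids."""
        s, r, v = self.responses.shape
        ids = [sid for sid in self.stimulus_ids for _ in range(r)]
        return self.responses.reshape(s * r, v), ids


# ---------------------------------------------------------------------------
# Procedural stimulus drawing
# ---------------------------------------------------------------------------


def _draw_image(rng: np.random.Generator, category_params: dict, size: int) -> np.ndarray:
    """One colored geometric composite with within-category jitter."""
    bg = category_params["bg"]
    fg = category_params["fg"]
    kind = category_params["kind"]
    img = np.empty((size, size, 3))
    img[:] = bg
    yy, xx = np.mgrid[0:size, 0:size] / size
    cx = category_params["cx"] + rng.uniform(-0.1, 0.1)
    cy = category_params["cy"] + rng.uniform(-0.1, 0.1)
    r = category_params["scale"] * (1 + rng.uniform(-0.2, 0.2))
    if kind == 0:  # disk
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
    elif kind == 1:  # square
        mask = (np.abs(xx - cx) < r) & (np.abs(yy - cy) < r)
    elif kind == 2:  # stripes
        phase = rng.uniform(0, 2 * np.pi)
        freq = category_params["freq"]
        mask = np.sin(2 * np.pi * freq * (xx * category_params["ux"] + yy * category_params["uy"]) + phase) > 0
    else:  # diagonal wedge
        mask = (xx - cx) + (yy - cy) * category_params["slope"] > 0
    img[mask] = fg
    # smooth gradient overlay gives gradual within-category variation
    grad = 0.15 * rng.uniform(-1, 1) * (xx + yy)[..., None]
    return np.clip(img + grad, 0.0, 1.0)


def _category_params(rng: np.random.Generator, n_categories: int) -> list[dict]:
    params = []
    for c in range(n_categories):
        params.append(
            {
                "kind": c % 4,
                "bg": rng.uniform(0, 1, size=3),
                "fg": rng.uniform(0, 1, size=3),
                "cx": rng.uniform(0.3, 0.7),
                "cy": rng.uniform(0.3, 0.7),
                "scale": rng.uniform(0.15, 0.3),
                "freq": rng.integers(2, 6),
                "ux": rng.uniform(0.3, 1.0),
                "uy": rng.uniform(0.3, 1.0),
                "slope": rng.uniform(0.5, 2.0),
            }
        )
    return params


def make_stimulus_world(
    rng_seed: int,
    n_train: int = 200,
    n_test: int = 50,
    n_categories: int = 10,
    image_size: int = 32,
    category_disjoint: bool = True,
    extractor: ToyConvExtractor | None = None,
) -> StimulusSet:
    """Generate a seeded stimulus world with ground-truth features attached.

    With ``category_disjoint`` the test stimuli come from categories never
    seen in training. Stimuli are allocated to categories round-robin so
    per-category counts are as even as possible.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    if category_disjoint and n_categories < 2:
        raise ValueError("category-disjoint splits need at least 2 categories")
    rng = np.random.default_rng(rng_seed)
    params = _category_params(rng, n_categories)
    cats = np.arange(n_categories)
    if category_disjoint:
        rng.shuffle(cats)
        n_test_cats = max(1, min(n_categories - 1, round(n_categories * n_test / (n_train + n_test))))
        test_cats, train_cats = cats[:n_test_cats], cats[n_test_cats:]
    else:
        train_cats = test_cats = cats
    train_assign = np.array([train_cats[i % len(train_cats)] for i in range(n_train)])
    test_assign = np.array([test_cats[i % len(test_cats)] for i in range(n_test)])
    categories = np.concatenate([train_assign, test_assign])
    split = np.array(["train"] * n_train + ["test"] * n_test)
    images = np.stack(
        [_draw_image(rng, params[c], image_size) for c in categories]
    )
    ids = [f"stim{i:05d}" for i in range(n_train + n_test)]
    if extractor is None:
        extractor = ToyConvExtractor(seed=0, input_size=image_size)
    features = extractor.extract(images, ids)
    return StimulusSet(ids, categories, images, features, split)


def make_virtual_subject(
    rng_seed: int,
    world: StimulusSet,
    n_voxels: int = 300,
    noise_sd: float = 1.0,
    dataset_id: str = "sim",
    subject_id: str | None = None,
    encoding_layer: str = DEFAULT_ENCODING_LAYER,
    density: float = 0.1,
) -> VirtualSubject:
    """Draw a subject's sparse-Gaussian voxel encoding over the world's features.

    Each voxel reads a random ``density`` fraction of the encoding layer's
    flattened units with Gaussian weights; rows are rescaled to unit
    stimulus-driven standard deviation over the training stimuli. Subjects
    drawn with different seeds share the content space but have uncorrelated
    topographies.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if n_voxels > MAX_VOXELS:
        raise ValueError(f"n_voxels exceeds the configured maximum ({MAX_VOXELS})")
    rng = np.random.default_rng(rng_seed)
    feats = world.train.features.flat(encoding_layer)
    dim = feats.shape[1]
    n_read = max(1, int(round(density * dim)))
    enc = np.zeros((n_voxels, dim))
    for v in range(n_voxels):
        idx = rng.choice(dim, size=n_read, replace=False)
        enc[v, idx] = rng.standard_normal(n_read)
    drive = feats @ enc.T  # (train stimuli, voxels)
    sd = drive.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    enc /= sd[:, None]
    bias = rng.standard_normal(n_voxels) * 0.1
    if subject_id is None:
        subject_id = f"sub{rng_seed:03d}"
    return VirtualSubject(subject_id, dataset_id, enc, bias, noise_sd, encoding_layer)


def simulate_session(
    subject: VirtualSubject,
    stimuli: StimulusSet,
    n_repetitions: int = 1,
    rng_seed: int = 0,
    split: str = "train",
) -> ResponseDataset:
    """Simulate repeated measurements: encoding + bias + i.i.d. Gaussian noise."""
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(rng_seed)
    clean = subject.clean_responses(stimuli.features)  # (S, V)
    noise = rng.standard_normal((clean.shape[0], n_repetitions, clean.shape[1])) * subject.noise_sd
    responses = clean[:, None, :] + noise
    return ResponseDataset(
        subject.subject_id, list(stimuli.stimulus_ids), responses, split, subject.dataset_id
    )


def split_source_target_nonoverlapping(
    world: StimulusSet, rng_seed: int = 0
) -> tuple[StimulusSet, StimulusSet]:
    """Split the training stimuli into two category-disjoint halves.

    Emulates the no-shared-stimuli condition: the source subject's training
    stimuli and the target subject's training stimuli come from disjoint
    categories, and their union is the original training set.
    """
    train = world.train
    cats = np.unique(train.categories)
    if len(cats) < 2:
        raise ValueError("need at least 2 training categories to split")
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(cats)
    half = len(cats) // 2
    src_cats = set(cats[:half].tolist())
    src_mask = np.array([c in src_cats for c in train.categories])
    return train.subset(src_mask), train.subset(~src_mask)


def average_repetitions(dataset: ResponseDataset) -> ResponseDataset:
    """Collapse repetitions to a single per-stimulus mean pseudo-repetition."""
    return replace(dataset, responses=dataset.mean_pattern()[:, None, :])
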