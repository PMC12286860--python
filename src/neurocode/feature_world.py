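"""Hierarchical content representations for virtual-subject experiments.

The real analyses this package emulates use deep network features (VGG19,
AlexNet, CLIP-ViT) as the shared "content space" linking stimuli and brain
activity. Here that role is played by small, seeded, fully differentiable
extractors: a convolutional hierarchy (:class:`ToyConvExtractor`) and a
patch-embedding variant (:class:`ToyPatchExtractor`) with a deliberately
different parameterization, so that cross-feature-space generalization can be
exercised. Unit-count arithmetic for the published architectures is provided
separately (:func:`layer_unit_count`) for dimension validation.

Feature values are taken *before* rectification wherever a nonlinearity
exists; the rectified values propagate to the next stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "LayerSpec",
    "FeatureStack",
    "ToyConvExtractor",
    "ToyPatchExtractor",
    "GeneratorModel",
    "extract_features",
    "layer_unit_count",
    "architecture_layers",
    "generate",
]


@dataclass(frozen=True)
class LayerSpec:
    """Geometry of one feature layer: unit_count == height * width * channels."""

    name: str
    kind: str  # convolutional | fully_connected | patch_embedding | token_block
    height: int
    width: int
    channels: int

    def __post_init__(self):
        for f in ("height", "width", "channels"):
            if getattr(self, f) < 1:
                raise ValueError(f"LayerSpec.{f} must be a positive integer")

    @property
    def unit_count(self) -> int:
        return self.height * self.width * self.channels


class FeatureStack:
    """Per-layer stimulus feature arrays sharing one stimulus index.

    Convolutional layers are stored as ``(stimulus, channels, height, width)``,
    fully connected layers as ``(stimulus, units)``. Flattening is
    channel-major, matching the layer's :class:`LayerSpec`.
    """

    def __init__(self, specs: list[LayerSpec], arrays: dict[str, np.ndarray], stimulus_ids: list[str]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.specs = {s.name: s for s in specs}
        self.layer_order = names
        self.stimulus_ids = list(stimulus_ids)
        self.arrays: dict[str, np.ndarray] = {}
        n = len(self.stimulus_ids)
        for name in names:
            arr = np.asarray(arrays[name], dtype=np.float64)
            spec = self.specs[name]
            expected = (
                (n, spec.unit_count)
                if spec.kind == "fully_connected"
                else (n, spec.channels, spec.height, spec.width)
            )
            if arr.shape != expected:
                raise ValueError(f"layer {name!r}: expected shape {expected}, got {arr.shape}")
            self.arrays[name] = arr

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    def flat(self, layer: str) -> np.ndarray:
        """Features of one layer as (stimuli, unit_count), channel-major."""
        return self.arrays[layer].reshape(self.n_stimuli, -1)

    def subset(self, indices: np.ndarray) -> "FeatureStack":
        ids = [self.stimulus_ids[i] for i in indices]
        return FeatureStack(
            list(self.specs.values()), {k: v[indices] for k, v in self.arrays.items()}, ids
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureStack)
            and self.layer_order == other.layer_order
            and self.stimulus_ids == other.stimulus_ids
            and all(np.array_equal(self.arrays[k], other.arrays[k]) for k in self.layer_order)
        )


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class ToyConvExtractor:
    """Seeded differentiable convolutional hierarchy.

    Default: three 3x3/stride-2 convolutional stages (8, 16, 16 channels) on
    32x32x3 input, followed by one dense layer of 64 units. Small enough for
    seconds-scale optimization, deep enough that multi-layer losses and
    graded layer-wise decodability are non-degenerate.
    """

    def __init__(
        self,
        seed: int = 0,
        input_size: int = 32,
        channels: tuple[int, ...] = (8, 16, 16),
        dense_units: int = 64,
        in_channels: int = 3,
    ):
        self.seed = seed
        self.input_size = input_size
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        self.layer_specs: list[LayerSpec] = []
        c_in, size = in_channels, input_size
        for i, c_out in enumerate(channels):
            self.conv_w.append(Tensor(_he(rng, (c_out, c_in, 3, 3), c_in * 9)))
            self.conv_b.append(Tensor(np.zeros(c_out)))
            size = (size + 2 * 1 - 3) // 2 + 1  # kernel 3, stride 2, pad 1
            self.layer_specs.append(LayerSpec(f"conv{i + 1}", "convolutional", size, size, c_out))
            c_in = c_out
        flat_dim = c_in * size * size
        self.fc_w = Tensor(_he(rng, (flat_dim, dense_units), flat_dim))
        self.fc_b = Tensor(np.zeros(dense_units))
        self.layer_specs.append(
            LayerSpec(f"fc{len(channels) + 1}", "fully_connected", 1, 1, dense_units)
        )
        self.layer_order = [s.name for s in self.layer_specs]

    def forward_tensors(self, images: Tensor) -> dict[str, Tensor]:
        """Pre-rectification features per layer for an (N, C, H, W) image tensor."""
        n = images.shape[0]
        feats: dict[str, Tensor] = {}
        h = images
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            pre = conv2d(h, w, b, stride=2, padding=1)
            feats[f"conv{i + 1}"] = pre
            h = pre.relu()
        feats[self.layer_order[-1]] = h.reshape(n, -1) @ self.fc_w + self.fc_b
        return feats

    def extract(self, images: np.ndarray, stimulus_ids: list[str] | None = None) -> FeatureStack:
        return extract_features(self, images, stimulus_ids)


class ToyPatchExtractor:
    """Patch-embedding extractor with a different parameterization.

    One non-overlapping 4x4 patch embedding (16 channels) followed by two
    dense stages (128, then 64 units). Shares the input geometry of
    :class:`ToyConvExtractor` but a disjoint random parameter draw and a
    different layer structure, standing in for a second feature family.
    """

    def __init__(self, seed: int = 100, input_size: int = 32, in_channels: int = 3):
        self.seed = seed
        self.input_size = input_size
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        tokens = input_size // 4
        self.patch_w = Tensor(_he(rng, (16, in_channels, 4, 4), in_channels * 16))
        self.patch_b = Tensor(np.zeros(16))
        flat = 16 * tokens * tokens
        self.fc1_w = Tensor(_he(rng, (flat, 128), flat))
        self.fc1_b = Tensor(np.zeros(128))
        self.fc2_w = Tensor(_he(rng, (128, 64), 128))
        self.fc2_b = Tensor(np.zeros(64))
        self.layer_specs = [
            LayerSpec("patch1", "patch_embedding", tokens, tokens, 16),
            LayerSpec("fc2", "fully_connected", 1, 1, 128),
            LayerSpec("fc3", "fully_connected", 1, 1, 64),
        ]
        self.layer_order = [s.name for s in self.layer_specs]

    def forward_tensors(self, images: Tensor) -> dict[str, Tensor]:
        n = images.shape[0]
        pre = conv2d(images, self.patch_w, self.patch_b, stride=4, padding=0)
        h = pre.relu().reshape(n, -1)
        f1 = h @ self.fc1_w + self.fc1_b
        f2 = f1.relu() @ self.fc2_w + self.fc2_b
        return {"patch1": pre, "fc2": f1, "fc3": f2}

    def extract(self, images: np.ndarray, stimulus_ids: list[str] | None = None) -> FeatureStack:
        return extract_features(self, images, stimulus_ids)


def extract_features(model, images: np.ndarray, stimulus_ids: list[str] | None = None) -> FeatureStack:
    """Run the extractor on an (N, H, W, C) image batch in [0, 1].

    Returns a :class:`FeatureStack` with one array per layer; batch order is
    preserved and identical inputs produce identical feature rows.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    n, h, w, c = images.shape
    if h != model.input_size or w != model.input_size:
        raise ValueError(
            f"image size {h}x{w} does not match extractor input size "
            f"{model.input_size}x{model.input_size}"
        )
    if c != model.in_channels:
        raise ValueError(f"image has {c} channels, extractor expects {model.in_channels}")
    feats = model.forward_tensors(Tensor(images.transpose(0, 3, 1, 2)))
    if stimulus_ids is None:
        stimulus_ids = [str(i) for i in range(n)]
    return FeatureStack(model.layer_specs, {k: v.data for k, v in feats.items()}, stimulus_ids)


# ---------------------------------------------------------------------------
# Published architecture shape arithmetic (for dimension validation only; no
# weights are ever loaded).
# ---------------------------------------------------------------------------


def _vgg19_layers(input_size: int) -> list[LayerSpec]:
    specs = []
    blocks = [(1, 2, 64), (2, 2, 128), (3, 4, 256), (4, 4, 512), (5, 4, 512)]
    size = input_size
    for block, n_convs, ch in blocks:
        for i in range(1, n_convs + 1):
            specs.append(LayerSpec(f"conv{block}_{i}", "convolutional", size, size, ch))
        size //= 2  # 2x2/stride-2 max pool after each block
    specs += [
        LayerSpec("fc6", "fully_connected", 1, 1, 4096),
        LayerSpec("fc7", "fully_connected", 1, 1, 4096),
        LayerSpec("fc8", "fully_connected", 1, 1, 1000),
    ]
    return specs


def _alexnet_layers(input_size: int) -> list[LayerSpec]:
    # The Caffe bvlc_alexnet reference crops 224 inputs to 227, which is the
    # geometry that yields the published 55x55 first-layer map; we follow it
    # rather than silently convolving at 224.
    size = 227 if input_size == 224 else input_size
    s1 = (size - 11) // 4 + 1  # conv1: 11x11, stride 4, no pad
    p1 = (s1 - 3) // 2 + 1  # 3x3/stride-2 max pool
    s2 = p1  # conv2: 5x5, pad 2
    p2 = (s2 - 3) // 2 + 1
    s345 = p2  # conv3-5: 3x3, pad 1
    return [
        LayerSpec("conv1", "convolutional", s1, s1, 96),
        LayerSpec("conv2", "convolutional", s2, s2, 256),
        LayerSpec("conv3", "convolutional", s345, s345, 384),
        LayerSpec("conv4", "convolutional", s345, s345, 384),
        LayerSpec("conv5", "convolutional", s345, s345, 256),
        LayerSpec("fc6", "fully_connected", 1, 1, 4096),
        LayerSpec("fc7", "fully_connected", 1, 1, 4096),
        LayerSpec("fc8", "fully_connected", 1, 1, 1000),
    ]


def _clip_vit_b32_layers(input_size: int) -> list[LayerSpec]:
    tokens = input_size // 32  # 32x32 patch embedding, stride 32
    width = 768
    specs = [LayerSpec("conv1", "patch_embedding", tokens, tokens, width)]
    for i in range(12):
        # class token + patch tokens, each of transformer width
        specs.append(LayerSpec(f"block{i}", "token_block", tokens * tokens + 1, 1, width))
    specs.append(LayerSpec("ln_post", "fully_connected", 1, 1, width))
    specs.append(LayerSpec("model_output", "fully_connected", 1, 1, 512))
    return specs


_ARCH_TABLES = {
    "vgg19": _vgg19_layers,
    "alexnet": _alexnet_layers,
    "clip_vit_b32": _clip_vit_b32_layers,
}

_ALIASES = {"fc6": "fc6", "fc7": "fc7", "fc8": "fc8"}


def architecture_layers(architecture: str, input_size: int = 224) -> list[LayerSpec]:
    """Layer geometry table for a published architecture."""
    try:
        return _ARCH_TABLES[architecture](input_size)
    except KeyError:
        raise KeyError(
            f"unknown architecture {architecture!r}; valid: {sorted(_ARCH_TABLES)}"
        ) from None


def layer_unit_count(architecture: str, layer_name: str, input_size: int = 224) -> int:
    """Unit count P*Q*K of a named layer from standard shape arithmetic."""
    specs = {s.name.lower(): s for s in architecture_layers(architecture, input_size)}
    key = layer_name.lower()
    if key not in specs:
        raise KeyError(
            f"unknown layer {layer_name!r} for {architecture}; valid: {sorted(specs)}"
        )
    return specs[key].unit_count


# ---------------------------------------------------------------------------
# Generator abstraction for image reconstruction
# ---------------------------------------------------------------------------


@dataclass
class GeneratorModel:
    """Maps a latent vector z to an image in [0, 1].

    ``identity_pixels`` (default) treats z as the pixels themselves, clipped
    to the valid range — direct pixel-space optimization. ``toy_decoder`` is a
    seeded random dense map from a low-dimensional latent through a sigmoid.
    """

    mode: str = "identity_pixels"
    image_size: int = 32
    channels: int = 3
    latent_dim: int | None = None
    seed: int = 0
    _w: Tensor = field(default=None, repr=False, compare=False)
    _b: Tensor = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n_pix = self.channels * self.image_size**2
        if self.mode == "identity_pixels":
            self.latent_dim = n_pix
        elif self.mode == "toy_decoder":
            if self.latent_dim is None:
                self.latent_dim = 64
            rng = np.random.default_rng(self.seed)
            self._w = Tensor(_he(rng, (self.latent_dim, n_pix), self.latent_dim))
            self._b = Tensor(np.zeros(n_pix))
        else:
            raise ValueError(f"unknown generator mode {self.mode!r}")

    def generate_tensor(self, z: Tensor) -> Tensor:
        """Differentiable image (1, C, H, W) from a latent tensor of shape (latent_dim,)."""
        if z.data.size != self.latent_dim:
            raise ValueError(f"latent length {z.data.size} != expected {self.latent_dim}")
        c, s = self.channels, self.image_size
        if self.mode == "identity_pixels":
            return z.reshape(1, c, s, s).clip(0.0, 1.0)
        return (z.reshape(1, -1) @ self._w + self._b).sigmoid().reshape(1, c, s, s)


def generate(model: GeneratorModel, z: np.ndarray) -> np.ndarray:
    """Image (H, W, C) in [0, 1] from a latent vector."""
    img = model.generate_tensor(Tensor(np.asarray(z, dtype=np.float64)))
    return img.data[0].transpose(1, 2, 0)
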