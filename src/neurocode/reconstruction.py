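"""Feature-inversion image reconstruction with structure/texture losses.

An image is reconstructed from a (decoded) feature stack by optimizing a
generator latent z so that the extractor's features of the generated image
match the target features:

    z* = argmin_z  L_mse(z) + lambda_tex L_tex(z) + lambda_str L_str(z)

L_mse is the layer-weighted feature MSE with gamma_l = 1/||u_l||^2. The
texture and structure terms are DISTS-style similarities built from
per-channel spatial means, variances and cross-covariances of convolutional
feature maps (dense layers contribute to the MSE term only). Optimization is
stochastic gradient descent with momentum, 200 iterations by default; the
iterate with the lowest total loss is returned, so the result is never worse
than the initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import SGD, Tensor
from .feature_world import FeatureStack, GeneratorModel

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "feature_mse_loss",
    "channel_stats",
    "texture_loss",
    "structure_loss",
    "reconstruct_image",
]

_SPATIAL_KINDS = ("convolutional", "patch_embedding")


@dataclass
class ReconstructionConfig:
    lambda_tex: float = 1.0
    lambda_str: float = 1.0
    alpha: dict[str, float] | None = None  # per-layer texture weights; default 1/L_conv
    beta: dict[str, float] | None = None  # per-layer structure weights; default 1/L_conv
    epsilon: float = 1e-6
    learning_rate: float = 0.1
    momentum: float = 0.9
    n_iterations: int = 200
    rng_seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.n_iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.lambda_tex < 0 or self.lambda_str < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class ReconstructionResult:
    image: np.ndarray  # (H, W, C) in [0, 1]
    z: np.ndarray
    trajectory: dict[str, np.ndarray]  # total/mse/tex/str per iteration
    rng_seed: int
    config: ReconstructionConfig = field(repr=False, default=None)


def _gamma(u_flat: np.ndarray) -> float:
    sq = float((u_flat**2).sum())
    return 0.0 if sq == 0 else 1.0 / sq


def feature_mse_loss(predicted: FeatureStack, target: FeatureStack) -> float:
    """Sum over layers of gamma_l ||predicted_l - u_l||^2, gamma_l = 1/||u_l||^2."""
    if predicted.layer_order != target.layer_order:
        raise ValueError("layer mismatch")
    total = 0.0
    for name in target.layer_order:
        u = target.flat(name)
        d = predicted.flat(name)
        total += _gamma(u) * float(((d - u) ** 2).sum())
    return total


def channel_stats(u: np.ndarray, uhat: np.ndarray | None = None):
    """Spatial per-channel statistics of a (K, P, Q) feature map.

    Returns (means, variances) or, when a second map is given,
    (means_u, vars_u, cross_covariance(u, uhat)).
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 3:
        raise ValueError("feature map must be (channels, height, width)")
    mu = u.mean(axis=(1, 2))
    var = ((u - mu[:, None, None]) ** 2).mean(axis=(1, 2))
    if uhat is None:
        return mu, var
    uhat = np.asarray(uhat, dtype=np.float64)
    mu2 = uhat.mean(axis=(1, 2))
    cross = (u * uhat).mean(axis=(1, 2)) - mu * mu2
    return mu, var, cross


def _spatial_layers(stack: FeatureStack) -> list[str]:
    return [n for n in stack.layer_order if stack.specs[n].kind in _SPATIAL_KINDS]


def _default_weights(layers: list[str], given: dict[str, float] | None) -> dict[str, float]:
    if given is not None:
        return given
    L = max(len(layers), 1)
    return {n: 1.0 / L for n in layers}


def texture_loss(
    u: FeatureStack, uhat: FeatureStack, alpha: dict[str, float] | None = None, epsilon: float = 1e-6
) -> float:
    """DISTS texture term: negative mean per-channel spatial-mean similarity."""
    layers = _spatial_layers(u)
    alpha = _default_weights(layers, alpha)
    total = 0.0
    for name in layers:
        mu_u, _ = channel_stats(u.arrays[name][0])
        mu_h, _ = channel_stats(uhat.arrays[name][0])
        ratio = (mu_u * mu_h + epsilon) / (mu_u**2 + mu_h**2 + epsilon)
        total -= alpha[name] * float(ratio.mean())
    return total


def structure_loss(
    u: FeatureStack, uhat: FeatureStack, beta: dict[str, float] | None = None, epsilon: float = 1e-6
) -> float:
    """DISTS structure term: negative mean per-channel normalized cross-covariance."""
    layers = _spatial_layers(u)
    beta = _default_weights(layers, beta)
    total = 0.0
    for name in layers:
        mu_u, var_u, cross = channel_stats(u.arrays[name][0], uhat.arrays[name][0])
        _, var_h = channel_stats(uhat.arrays[name][0])
        ratio = (cross + epsilon) / (var_u + var_h + epsilon)
        total -= beta[name] * float(ratio.mean())
    return total


def _loss_tensors(feats, target: FeatureStack, config: ReconstructionConfig):
    """Differentiable (mse, tex, str) loss tensors from extractor feature tensors."""
    eps = config.epsilon
    spatial = _spatial_layers(target)
    alpha = _default_weights(spatial, config.alpha)
    beta = _default_weights(spatial, config.beta)
    mse = None
    tex = None
    stru = None
    for name in target.layer_order:
        u_flat = target.flat(name)[0]
        f = feats[name]
        g = _gamma(u_flat)
        n = f.data.shape[0]
        term = ((f.reshape(n, -1) - u_flat) ** 2.0).sum() * g
        mse = term if mse is None else mse + term
        if name in spatial and (config.lambda_tex > 0 or config.lambda_str > 0):
            u = target.arrays[name][0]
            K = u.shape[0]
            mu_u, var_u = channel_stats(u)
            mu_f = f.mean(axis=(2, 3))  # (1, K)
            t_ratio = (mu_f * mu_u + eps) / (mu_f**2.0 + mu_u**2.0 + eps)
            t_term = t_ratio.sum() * (-alpha[name] / K)
            tex = t_term if tex is None else tex + t_term
            mu_f_keep = f.mean(axis=(2, 3), keepdims=True)
            var_f = ((f - mu_f_keep) ** 2.0).mean(axis=(2, 3))
            cross = (f * u[None]).mean(axis=(2, 3)) - mu_f * mu_u
            s_ratio = (cross + eps) / (var_f + var_u + eps)
            s_term = s_ratio.sum() * (-beta[name] / K)
            stru = s_term if stru is None else stru + s_term
    zero = Tensor(0.0)
    return mse, tex if tex is not None else zero, stru if stru is not None else zero


def reconstruct_image(
    decoded: FeatureStack,
    extractor,
    generator: GeneratorModel | None = None,
    config: ReconstructionConfig | None = None,
    z_init: np.ndarray | None = None,
) -> ReconstructionResult:
    """Optimize a generator latent so extracted features match ``decoded``.

    ``decoded`` must hold a single stimulus whose layers are a subset of the
    extractor's. Returns the lowest-loss iterate with the per-component loss
    trajectory.
    """
    config = config or ReconstructionConfig()
    if generator is None:
        generator = GeneratorModel(
            "identity_pixels", image_size=extractor.input_size, channels=extractor.in_channels
        )
    missing = set(decoded.layer_order) - set(extractor.layer_order)
    if missing:
        raise ValueError(f"layers {sorted(missing)} not produced by the extractor")
    rng = np.random.default_rng(config.rng_seed)
    if z_init is None:
        z_init = rng.uniform(0.0, 1.0, size=generator.latent_dim)
    z = Tensor(np.asarray(z_init, dtype=np.float64).copy(), requires_grad=True)
    opt = SGD([z], lr=config.learning_rate, momentum=config.momentum)
    traj = {k: np.empty(config.n_iterations) for k in ("total", "mse", "tex", "str")}
    best_loss, best_z = np.inf, z.data.copy()
    for it in range(config.n_iterations):
        img = generator.generate_tensor(z)
        feats = extractor.forward_tensors(img)
        mse, tex, stru = _loss_tensors(feats, decoded, config)
        total = mse + config.lambda_tex * tex + config.lambda_str * stru
        val = total.item()
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite reconstruction loss at iteration {it}: "
                f"mse={mse.item()}, tex={tex.item()}, str={stru.item()}"
            )
        traj["total"][it] = val
        traj["mse"][it] = mse.item()
        traj["tex"][it] = tex.item()
        traj["str"][it] = stru.item()
        if val < best_loss:
            best_loss, best_z = val, z.data.copy()
        opt.zero_grad()
        total.backward()
        opt.step()
    image = generator.generate_tensor(Tensor(best_z)).data[0].transpose(1, 2, 0)
    return ReconstructionResult(image, best_z, traj, config.rng_seed, config)
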