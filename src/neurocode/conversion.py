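"""Neural code converters: content-loss MLPs and paired-data baselines.

The content-loss converter maps a source subject's voxel pattern into a
target subject's voxel space *without any paired brain data*: it is trained
so that the target's frozen feature decoder, applied to the converted
pattern, reproduces the true stimulus features of the source's stimuli,

    L(Phi) = sum_i sum_l eta_l || v_il - (W_l Phi(x_i) + b_l) ||^2,

with eta_l = 1 / ||v_il||^2 weighting each layer's contribution per sample.
Training is iterative with a stochastic decoding schedule: in each iteration
one feature map (channel) is drawn per convolutional layer and all of its
units are decoded, while fully connected layers are decoded in full; 1,024
iterations are used by default so every unit participates.

Baselines: the brain-loss converter, a ridge-regularized linear map fit on
paired responses to shared stimuli, and a pairwise orthogonal Procrustes
transformation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from sklearn.linear_model import Ridge, RidgeCV

from .autodiff import Adam, Tensor, instance_norm
from .feature_decoding import FeatureDecoder, decode_layer_tensor
from .feature_world import FeatureStack, LayerSpec
from .virtual_subjects import ResponseDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Converter",
    "ContentTrainingConfig",
    "content_loss",
    "sample_units_for_iteration",
    "train_content_converter",
    "train_brain_loss_converter",
    "train_procrustes_converter",
    "convert",
    "collapse_linear_mlp",
]

MLP_KINDS = ("content_mlp_nonlinear", "content_mlp_linear", "content_mlp_residual")


class _MLP:
    """Converter network; hidden width is half the input width (rounded up)."""

    def __init__(self, kind: str, m: int, n: int, rng: np.random.Generator):
        self.kind = kind
        self.m, self.n = m, n
        h = math.ceil(m / 2)
        self.h = h

        def lin(din, dout, scale=1.0):
            w = Tensor(
                rng.standard_normal((din, dout)) * (scale * np.sqrt(2.0 / din)),
                requires_grad=True,
            )
            b = Tensor(np.zeros(dout), requires_grad=True)
            return w, b

        def norm():
            return (
                Tensor(np.ones(h), requires_grad=True),
                Tensor(np.zeros(h), requires_grad=True),
            )

        self.lin1 = lin(m, h)
        self.lin2 = lin(h, h)
        # near-zero output init: voxel directions the frozen decoder does not
        # constrain stay at zero instead of random junk (minimum-norm bias)
        self.lin3 = lin(h, n, scale=0.01)
        self.norms = [norm(), norm()] if kind != "content_mlp_linear" else []
        self.res = []
        if kind == "content_mlp_residual":
            for _ in range(3):
                self.res.append((lin(h, h), norm()))

    def params(self) -> list[Tensor]:
        ps = [*self.lin1, *self.lin2, *self.lin3]
        for g, b in self.norms:
            ps += [g, b]
        for (w, b), (g, gb) in self.res:
            ps += [w, b, g, gb]
        return ps

    def forward(self, x: Tensor) -> Tensor:
        if self.kind == "content_mlp_linear":
            h = x @ self.lin1[0] + self.lin1[1]
            h = h @ self.lin2[0] + self.lin2[1]
            return h @ self.lin3[0] + self.lin3[1]
        h = x @ self.lin1[0] + self.lin1[1]
        h = instance_norm(h, *self.norms[0]).relu()
        h = h @ self.lin2[0] + self.lin2[1]
        h = instance_norm(h, *self.norms[1]).relu()
        for (w, b), (g, gb) in self.res:
            h = h + instance_norm(h @ w + b, g, gb).relu()
        return h @ self.lin3[0] + self.lin3[1]


@dataclass
class ContentTrainingConfig:
    n_iterations: int = 1024
    kind: str = "content_mlp_nonlinear"
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    weighting: str = "per_sample"  # or "per_layer_average"
    trial_level: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("iteration count must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.kind not in MLP_KINDS:
            raise ValueError(f"unknown converter kind {self.kind!r}; valid: {MLP_KINDS}")


@dataclass
class Converter:
    kind: str
    m: int
    n: int
    mlp: _MLP | None = None
    M: np.ndarray | None = None
    c: np.ndarray | None = None
    R: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    loss_trajectory: np.ndarray | None = None
    rng_seed: int | None = None
    config: dict = field(default_factory=dict)


def _eta(v_sub: np.ndarray, weighting: str) -> np.ndarray:
    """Per-sample layer weights 1/||v_il||^2 on the included units."""
    sq = (v_sub**2).sum(axis=1)
    if weighting == "per_layer_average":
        mean_sq = sq.mean()
        return np.full(len(sq), 0.0 if mean_sq == 0 else 1.0 / mean_sq)
    with np.errstate(divide="ignore"):
        eta = np.where(sq > 0, 1.0 / np.where(sq > 0, sq, 1.0), 0.0)
    return eta


def content_loss(
    decoded: FeatureStack,
    true: FeatureStack,
    weighting: str = "per_sample",
    unit_subsets: dict[str, np.ndarray] | None = None,
) -> tuple[float, dict[str, float]]:
    """Eq.-style content loss with a per-layer breakdown.

    ``unit_subsets`` restricts each layer to an index set (flattened,
    channel-major); the weighting is computed on the included units only.
    """
    if decoded.layer_order != true.layer_order:
        raise ValueError("layer mismatch between decoded and true stacks")
    per_layer: dict[str, float] = {}
    for name in true.layer_order:
        d, v = decoded.flat(name), true.flat(name)
        if unit_subsets is not None:
            idx = np.asarray(unit_subsets.get(name, []), dtype=int)
            if idx.size == 0:
                logger.info("layer %s: empty unit subset, contributes 0", name)
                per_layer[name] = 0.0
                continue
            d, v = d[:, idx], v[:, idx]
        eta = _eta(v, weighting)
        per_layer[name] = float((eta * ((v - d) ** 2).sum(axis=1)).sum())
    return sum(per_layer.values()), per_layer


def sample_units_for_iteration(
    layer_specs: list[LayerSpec], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One random feature map per convolutional layer; dense layers in full."""
    subsets = {}
    for spec in layer_specs:
        if spec.kind == "fully_connected":
            subsets[spec.name] = np.arange(spec.unit_count)
        else:
            k = int(rng.integers(spec.channels))
            pq = spec.height * spec.width
            subsets[spec.name] = np.arange(k * pq, (k + 1) * pq)
    return subsets


def train_content_converter(
    source_train: ResponseDataset,
    source_features: FeatureStack,
    target_decoder: FeatureDecoder,
    config: ContentTrainingConfig | None = None,
) -> Converter:
    """Train a content-loss converter; no target brain responses are used.

    The target decoder is frozen; gradients flow through its affine decode
    into the converter parameters. One Adam step is taken per iteration on
    the full training set restricted to the iteration's sampled units.
    """
    config = config or ContentTrainingConfig()
    if source_train.stimulus_ids != source_features.stimulus_ids:
        order = {sid: i for i, sid in enumerate(source_features.stimulus_ids)}
        try:
            idx = np.array([order[sid] for sid in source_train.stimulus_ids])
        except KeyError as e:
            raise ValueError(f"stimulus id {e} missing from source features") from None
        source_features = source_features.subset(idx)
    dec_layers = set(target_decoder.layer_order)
    feat_layers = set(source_features.layer_order)
    if not dec_layers <= feat_layers:
        raise ValueError(
            f"decoder layers {sorted(dec_layers - feat_layers)} missing from source features"
        )
    specs = [s for s in target_decoder.specs]
    if config.trial_level:
        X, _ = source_train.trials()
        reps = source_train.n_repetitions
        V = {s.name: np.repeat(source_features.flat(s.name), reps, axis=0) for s in specs}
    else:
        X = source_train.mean_pattern()
        V = {s.name: source_features.flat(s.name) for s in specs}
    m, n = X.shape[1], target_decoder.n_voxels
    rng = np.random.default_rng(config.rng_seed)
    mlp = _MLP(config.kind, m, n, rng)
    opt = Adam(mlp.params(), lr=config.learning_rate, betas=config.betas)
    trajectory = np.empty(config.n_iterations)
    xt = Tensor(X)
    for it in range(config.n_iterations):
        subsets = sample_units_for_iteration(specs, rng)
        phi = mlp.forward(xt)
        loss = None
        for spec in specs:
            idx = subsets[spec.name]
            v_sub = V[spec.name][:, idx]
            eta = _eta(v_sub, config.weighting)
            d = decode_layer_tensor(target_decoder, phi, spec.name, idx)
            term = (((d - v_sub) ** 2.0).sum(axis=1, keepdims=False) * eta).sum()
            loss = term if loss is None else loss + term
        val = loss.item()
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite content loss ({val}) at iteration {it}")
        trajectory[it] = val
        opt.zero_grad()
        # gradient of the per-sample mean: step size independent of N
        loss.backward(np.float64(1.0 / X.shape[0]))
        opt.step()
    return Converter(
        config.kind,
        m,
        n,
        mlp=mlp,
        loss_trajectory=trajectory,
        rng_seed=config.rng_seed,
        config=vars(config).copy(),
    )


def train_brain_loss_converter(
    paired_source: np.ndarray,
    paired_target: np.ndarray,
    ridge_penalty: float | str = "gcv",
) -> Converter:
    """Ridge-regularized linear converter fit on paired (shared-stimulus) data.

    Minimizes sum_i ||y_i - (M x_i + c)||^2 + lambda ||M||_F^2 with the bias
    unpenalized (fit on centered data). ``ridge_penalty='gcv'`` selects the
    penalty by generalized (leave-one-out) cross-validation over a log grid
    from 1e-2 to 1e4.
    """
    X = np.asarray(paired_source, dtype=np.float64)
    Y = np.asarray(paired_target, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"paired sample counts differ: {X.shape[0]} vs {Y.shape[0]}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 paired samples")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    if ridge_penalty == "gcv":
        model = RidgeCV(alphas=np.logspace(-2, 4, 13), fit_intercept=False)
    else:
        model = Ridge(alpha=float(ridge_penalty), fit_intercept=False)
    model.fit(Xc, Yc)
    M = np.atleast_2d(model.coef_)
    c = y_mean - M @ x_mean
    return Converter("brain_ridge", X.shape[1], Y.shape[1], M=M, c=c)


def train_procrustes_converter(
    paired_source: np.ndarray, paired_target: np.ndarray, pad: bool = False
) -> Converter:
    """Orthogonal Procrustes baseline: centering plus a rotation/reflection.

    Requires equal voxel counts unless ``pad`` zero-pads the smaller space.
    """
    X = np.asarray(paired_source, dtype=np.float64)
    Y = np.asarray(paired_target, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("paired sample counts differ")
    m, n = X.shape[1], Y.shape[1]
    if m != n:
        if not pad:
            raise ValueError(
                f"Procrustes needs equal voxel counts (got {m} and {n}); enable pad=True"
            )
        d = max(m, n)
        X = np.pad(X, ((0, 0), (0, d - m)))
        Y = np.pad(Y, ((0, 0), (0, d - n)))
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    R, _ = orthogonal_procrustes(X - x_mean, Y - y_mean)
    return Converter("procrustes", m, n, R=R, x_mean=x_mean, y_mean=y_mean)


def convert(converter: Converter, responses: np.ndarray) -> np.ndarray:
    """Apply a trained converter to (stimuli, m) activity; returns (stimuli, n)."""
    X = np.asarray(responses, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None]
    if X.shape[1] != converter.m:
        raise ValueError(f"voxel-count mismatch: converter expects {converter.m}, got {X.shape[1]}")
    if converter.kind in MLP_KINDS:
        out = converter.mlp.forward(Tensor(X)).data
    elif converter.kind == "brain_ridge":
        out = X @ converter.M.T + converter.c
    elif converter.kind == "procrustes":
        Xp = X
        d = converter.R.shape[0]
        if converter.m < d:
            Xp = np.pad(X, ((0, 0), (0, d - converter.m)))
        out = ((Xp - converter.x_mean) @ converter.R + converter.y_mean)[:, : converter.n]
    else:
        raise ValueError(f"unknown converter kind {converter.kind!r}")
    return out[0] if single else out


def collapse_linear_mlp(converter: Converter) -> tuple[np.ndarray, np.ndarray]:
    """Compose a linear MLP converter into its equivalent (M, c)."""
    if converter.kind != "content_mlp_linear":
        raise ValueError("only linear MLP converters are affine-collapsible")
    mlp = converter.mlp
    M = mlp.lin1[0].data @ mlp.lin2[0].data @ mlp.lin3[0].data
    c = (mlp.lin1[1].data @ mlp.lin2[0].data + mlp.lin2[1].data) @ mlp.lin3[0].data + mlp.lin3[1].data
    return M.T, c
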