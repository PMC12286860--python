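"""Per-layer ridge-regression feature decoders.

A feature decoder predicts the stimulus's hierarchical feature values from a
voxel activity pattern. Training follows the standard visual feature-decoding
recipe: voxel responses and feature values are z-scored with training
statistics, voxels are ranked per layer by their highest absolute Pearson
correlation with any of that layer's units, the top 500 (by default) are
kept, and a ridge solution with penalty 100 is fit per layer. The fitted
decoder applies as an affine map, so it can sit (frozen) inside converter
training and gradients flow through it.

Voxel selection is per layer, not per unit: one selected voxel set per layer,
scored by each voxel's maximum |r| over the layer's units, keeping a single
weight matrix per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from ._stats import cross_correlation, pearson_cols, pearson_rows
from .autodiff import Tensor
from .feature_world import FeatureStack, LayerSpec
from .virtual_subjects import ResponseDataset

logger = logging.getLogger(__name__)

__all__ = ["FeatureDecoder", "fit_feature_decoder", "decode_features", "decoding_accuracy"]


@dataclass
class _LayerDecoder:
    weights: np.ndarray  # (units, n_selected) in z-scored spaces
    selected: np.ndarray  # voxel indices into the full voxel space
    feat_mean: np.ndarray  # (units,)
    feat_sd: np.ndarray  # (units,) with constant units carrying sd=1, weight row 0


@dataclass
class FeatureDecoder:
    specs: list[LayerSpec]
    layers: dict[str, _LayerDecoder]
    vox_mean: np.ndarray
    vox_sd: np.ndarray  # constant voxels carry sd=1 and are never selected
    ridge_penalty: float
    n_voxels_select: int
    extractor_tag: str = ""

    @property
    def layer_order(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def n_voxels(self) -> int:
        return len(self.vox_mean)

    def bias(self, layer: str) -> np.ndarray:
        """Effective bias b_l of the affine decoder in raw feature units."""
        return self.layers[layer].feat_mean

    def weight_matrix(self, layer: str) -> np.ndarray:
        """Effective W_l mapping raw (selected, z-scored) voxels to raw features."""
        ld = self.layers[layer]
        return ld.weights * ld.feat_sd[:, None]


def fit_feature_decoder(
    train_responses: ResponseDataset,
    train_features: FeatureStack,
    n_voxels_select: int = 500,
    ridge_penalty: float = 100.0,
    extractor_tag: str = "",
) -> FeatureDecoder:
    """Fit per-layer ridge decoders from trial-level responses to features."""
    if train_responses.stimulus_ids != train_features.stimulus_ids:
        order = {sid: i for i, sid in enumerate(train_features.stimulus_ids)}
        try:
            idx = np.array([order[sid] for sid in train_responses.stimulus_ids])
        except KeyError as e:
            raise ValueError(f"stimulus id {e} missing from features") from None
        train_features = train_features.subset(idx)
    X_trials, trial_ids = train_responses.trials()
    n_rep = train_responses.n_repetitions
    if len(train_responses.stimulus_ids) < 2:
        raise ValueError("need at least 2 training stimuli")
    vox_mean = X_trials.mean(axis=0)
    vox_sd = X_trials.std(axis=0, ddof=0)
    constant_vox = vox_sd == 0
    vox_sd = np.where(constant_vox, 1.0, vox_sd)
    Xz = (X_trials - vox_mean) / vox_sd
    n_sel = min(n_voxels_select, Xz.shape[1])
    if n_sel < n_voxels_select:
        logger.warning(
            "n_voxels_select=%d exceeds available voxels (%d); clipped", n_voxels_select, Xz.shape[1]
        )
    layers: dict[str, _LayerDecoder] = {}
    for name in train_features.layer_order:
        Y = np.repeat(train_features.flat(name), n_rep, axis=0)
        feat_mean = Y.mean(axis=0)
        feat_sd = Y.std(axis=0, ddof=0)
        constant_unit = feat_sd == 0
        feat_sd = np.where(constant_unit, 1.0, feat_sd)
        Yz = (Y - feat_mean) / feat_sd
        r = cross_correlation(X_trials, Y)  # (voxels, units)
        r = np.nan_to_num(r, nan=0.0)  # constant voxels/units score 0
        score = np.abs(r).max(axis=1)
        score[constant_vox] = 0.0
        selected = np.sort(np.argsort(score)[::-1][:n_sel])
        model = Ridge(alpha=ridge_penalty, fit_intercept=False)
        model.fit(Xz[:, selected], Yz)
        W = model.coef_  # (units, n_sel)
        W[constant_unit] = 0.0
        layers[name] = _LayerDecoder(W, selected, feat_mean, feat_sd)
    return FeatureDecoder(
        list(train_features.specs.values()),
        layers,
        vox_mean,
        vox_sd,
        ridge_penalty,
        n_sel,
        extractor_tag,
    )


def decode_layer_tensor(
    decoder: FeatureDecoder, x: Tensor, layer: str, unit_idx: np.ndarray | None = None
) -> Tensor:
    """Differentiable decode of one layer from raw voxel patterns (S, V).

    Returns de-normalized feature values (S, units) — restricted to
    ``unit_idx`` if given — with gradients flowing back to ``x``.
    """
    ld = decoder.layers[layer]
    xz = (x - decoder.vox_mean) * (1.0 / decoder.vox_sd)
    xsel = xz.gather_cols(ld.selected)
    if unit_idx is None:
        W, mu, sd = ld.weights, ld.feat_mean, ld.feat_sd
    else:
        W, mu, sd = ld.weights[unit_idx], ld.feat_mean[unit_idx], ld.feat_sd[unit_idx]
    return (xsel @ W.T) * sd + mu


def decode_features(decoder: FeatureDecoder, responses: np.ndarray) -> FeatureStack:
    """Decode all layers from an activity matrix (stimuli, voxels)."""
    responses = np.asarray(responses, dtype=np.float64)
    if responses.ndim == 1:
        responses = responses[None]
    if responses.shape[1] != decoder.n_voxels:
        raise ValueError(
            f"voxel-count mismatch: decoder expects {decoder.n_voxels}, got {responses.shape[1]}"
        )
    n = responses.shape[0]
    arrays = {}
    for spec in decoder.specs:
        flat = decode_layer_tensor(decoder, Tensor(responses), spec.name).data
        if spec.kind == "fully_connected":
            arrays[spec.name] = flat
        else:
            arrays[spec.name] = flat.reshape(n, spec.channels, spec.height, spec.width)
    return FeatureStack(decoder.specs, arrays, [str(i) for i in range(n)])


def decoding_accuracy(decoded: FeatureStack, true: FeatureStack) -> dict[str, dict]:
    """Pattern and profile correlations per layer.

    Pattern r: per test stimulus, across a layer's units. Profile r: per
    unit, across all test stimuli (undefined and excluded when fewer than 3
    stimuli). Layer means ignore undefined (NaN) entries.
    """
    if decoded.layer_order != true.layer_order:
        raise ValueError("layer mismatch between decoded and true feature stacks")
    if len(decoded.stimulus_ids) != len(true.stimulus_ids):
        raise ValueError("stimulus count mismatch")
    out = {}
    n_stim = true.n_stimuli
    for name in true.layer_order:
        d, t = decoded.flat(name), true.flat(name)
        pattern = pearson_rows(d, t)
        if n_stim >= 3:
            profile = pearson_cols(d, t)
        else:
            profile = np.full(d.shape[1], np.nan)
        out[name] = {
            "pattern": pattern,
            "profile": profile,
            "pattern_mean": np.nanmean(pattern) if np.any(np.isfinite(pattern)) else np.nan,
            "profile_mean": np.nanmean(profile) if np.any(np.isfinite(profile)) else np.nan,
        }
    return out
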