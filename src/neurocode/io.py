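"""HDF5/NPZ/PNG serialization for datasets, features, decoders and converters."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .conversion import MLP_KINDS, Converter, _MLP
from .feature_decoding import FeatureDecoder, _LayerDecoder
from .feature_world import FeatureStack, LayerSpec
from .virtual_subjects import ResponseDataset, StimulusSet

__all__ = [
    "save_response_dataset",
    "load_response_dataset",
    "save_feature_stack",
    "load_feature_stack",
    "save_decoder",
    "load_decoder",
    "save_converter",
    "load_converter",
    "save_stimulus_set",
    "load_images",
]


def _is_npz(path) -> bool:
    return str(path).endswith(".npz")


def save_response_dataset(path, ds: ResponseDataset) -> None:
    if _is_npz(path):
        np.savez(
            path,
            responses=ds.responses,
            stimulus_ids=np.array(ds.stimulus_ids),
            subject_id=ds.subject_id,
            dataset_id=ds.dataset_id,
            split=ds.split,
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=ds.responses)
        f.create_dataset("stimulus_ids", data=np.array(ds.stimulus_ids, dtype="S"))
        f.attrs["subject_id"] = ds.subject_id
        f.attrs["dataset_id"] = ds.dataset_id
        f.attrs["split"] = ds.split


def load_response_dataset(path) -> ResponseDataset:
    if _is_npz(path):
        z = np.load(path, allow_pickle=False)
        return ResponseDataset(
            str(z["subject_id"]),
            [str(s) for s in z["stimulus_ids"]],
            z["responses"],
            str(z["split"]),
            str(z["dataset_id"]),
        )
    with h5py.File(path, "r") as f:
        return ResponseDataset(
            f.attrs["subject_id"],
            [s.decode() for s in f["stimulus_ids"][()]],
            f["responses"][()],
            f.attrs["split"],
            f.attrs["dataset_id"],
        )


def _specs_json(specs: list[LayerSpec]) -> str:
    return json.dumps(
        [[s.name, s.kind, s.height, s.width, s.channels] for s in specs]
    )


def _specs_from_json(text: str) -> list[LayerSpec]:
    return [LayerSpec(*row) for row in json.loads(text)]


def save_feature_stack(path, stack: FeatureStack) -> None:
    if _is_npz(path):
        np.savez(
            path,
            _specs=_specs_json(list(stack.specs.values())),
            _stimulus_ids=np.array(stack.stimulus_ids),
            **stack.arrays,
        )
        return
    with h5py.File(path, "w") as f:
        for name, arr in stack.arrays.items():
            f.create_dataset(name, data=arr)
        f.attrs["specs"] = _specs_json(list(stack.specs.values()))
        f.attrs["stimulus_ids"] = json.dumps(stack.stimulus_ids)


def load_feature_stack(path) -> FeatureStack:
    if _is_npz(path):
        z = np.load(path, allow_pickle=False)
        specs = _specs_from_json(str(z["_specs"]))
        ids = [str(s) for s in z["_stimulus_ids"]]
        return FeatureStack(specs, {s.name: z[s.name] for s in specs}, ids)
    with h5py.File(path, "r") as f:
        specs = _specs_from_json(f.attrs["specs"])
        ids = json.loads(f.attrs["stimulus_ids"])
        return FeatureStack(specs, {s.name: f[s.name][()] for s in specs}, ids)


def save_decoder(path, dec: FeatureDecoder) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["specs"] = _specs_json(dec.specs)
        f.attrs["ridge_penalty"] = dec.ridge_penalty
        f.attrs["n_voxels_select"] = dec.n_voxels_select
        f.attrs["extractor_tag"] = dec.extractor_tag
        f.create_dataset("vox_mean", data=dec.vox_mean)
        f.create_dataset("vox_sd", data=dec.vox_sd)
        for name, ld in dec.layers.items():
            g = f.create_group(f"layer/{name}")
            g.create_dataset("weights", data=ld.weights)
            g.create_dataset("selected", data=ld.selected)
            g.create_dataset("feat_mean", data=ld.feat_mean)
            g.create_dataset("feat_sd", data=ld.feat_sd)


def load_decoder(path) -> FeatureDecoder:
    with h5py.File(path, "r") as f:
        specs = _specs_from_json(f.attrs["specs"])
        layers = {}
        for name in f["layer"]:
            g = f[f"layer/{name}"]
            layers[name] = _LayerDecoder(
                g["weights"][()], g["selected"][()], g["feat_mean"][()], g["feat_sd"][()]
            )
        return FeatureDecoder(
            specs,
            layers,
            f["vox_mean"][()],
            f["vox_sd"][()],
            float(f.attrs["ridge_penalty"]),
            int(f.attrs["n_voxels_select"]),
            f.attrs["extractor_tag"],
        )


def save_converter(path, conv: Converter) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = conv.kind
        f.attrs["m"] = conv.m
        f.attrs["n"] = conv.n
        f.attrs["config"] = json.dumps(conv.config, default=str)
        if conv.rng_seed is not None:
            f.attrs["rng_seed"] = conv.rng_seed
        if conv.loss_trajectory is not None:
            f.create_dataset("loss_trajectory", data=conv.loss_trajectory)
        if conv.kind in MLP_KINDS:
            for i, p in enumerate(conv.mlp.params()):
                f.create_dataset(f"param/{i:03d}", data=p.data)
        for name in ("M", "c", "R", "x_mean", "y_mean"):
            val = getattr(conv, name)
            if val is not None:
                f.create_dataset(name, data=val)


def load_converter(path) -> Converter:
    with h5py.File(path, "r") as f:
        kind, m, n = f.attrs["kind"], int(f.attrs["m"]), int(f.attrs["n"])
        conv = Converter(kind, m, n, config=json.loads(f.attrs["config"]))
        if "rng_seed" in f.attrs:
            conv.rng_seed = int(f.attrs["rng_seed"])
        if "loss_trajectory" in f:
            conv.loss_trajectory = f["loss_trajectory"][()]
        if kind in MLP_KINDS:
            mlp = _MLP(kind, m, n, np.random.default_rng(0))
            for i, p in enumerate(mlp.params()):
                p.data = f[f"param/{i:03d}"][()]
            conv.mlp = mlp
        for name in ("M", "c", "R", "x_mean", "y_mean"):
            if name in f:
                setattr(conv, name, f[name][()])
        return conv


def save_stimulus_set(directory, world: StimulusSet) -> None:
    """PNG per stimulus plus a metadata CSV and the ground-truth features."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, img in zip(world.stimulus_ids, world.images):
        Image.fromarray((np.clip(img, 0, 1) * 255).astype(np.uint8)).save(directory / f"{sid}.png")
    pd.DataFrame(
        {"id": world.stimulus_ids, "category": world.categories, "split": world.split}
    ).to_csv(directory / "metadata.csv", index=False)
    save_feature_stack(directory / "features.h5", world.features)


def load_images(directory, ids: list[str]) -> np.ndarray:
    """Read PNGs back as an (N, H, W, C) float batch in [0, 1]."""
    directory = Path(directory)
    return np.stack(
        [np.asarray(Image.open(directory / f"{sid}.png"), dtype=np.float64) / 255.0 for sid in ids]
    )
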