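"""Content-loss converters and paired baselines."""

import numpy as np
import pytest

import neurocode as nc
from neurocode._stats import pearson_rows
from neurocode.conversion import collapse_linear_mlp, _MLP
from neurocode.feature_world import FeatureStack, LayerSpec


def _stack(arrays_by_layer, ids):
    specs, arrays = [], {}
    for name, arr in arrays_by_layer.items():
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim == 2:
            specs.append(LayerSpec(name, "fully_connected", 1, 1, arr.shape[1]))
        else:
            specs.append(LayerSpec(name, "convolutional", arr.shape[2], arr.shape[3], arr.shape[1]))
        arrays[name] = arr
    return FeatureStack(specs, arrays, ids)


# ---------------------------------------------------------------- content loss
def test_content_loss_zero_when_equal(rng):
    ids = ["a", "b"]
    s = _stack({"fc": rng.standard_normal((2, 5))}, ids)
    total, per = nc.content_loss(s, s)
    assert total == 0.0 and per == {"fc": 0.0}


def test_content_loss_forced_value():
    # one layer, one sample, v=(3,4), d=(0,0), eta=1/25 -> loss 1
    ids = ["a"]
    v = _stack({"fc": [[3.0, 4.0]]}, ids)
    d = _stack({"fc": [[0.0, 0.0]]}, ids)
    total, _ = nc.content_loss(d, v)
    assert total == pytest.approx(1.0)


def test_content_loss_matches_nested_loop_oracle(rng):
    ids = [f"s{i}" for i in range(3)]
    v = _stack({"conv": rng.standard_normal((3, 2, 2, 2)), "fc": rng.standard_normal((3, 4))}, ids)
    d = _stack({"conv": rng.standard_normal((3, 2, 2, 2)), "fc": rng.standard_normal((3, 4))}, ids)
    total, per = nc.content_loss(d, v)
    expected = {}
    for name in v.layer_order:
        acc = 0.0
        for i in range(3):
            vv, dd = v.flat(name)[i], d.flat(name)[i]
            acc += ((vv - dd) ** 2).sum() / (vv**2).sum()
        expected[name] = acc
    for name, val in expected.items():
        assert per[name] == pytest.approx(val, rel=1e-12)
    assert total == pytest.approx(sum(expected.values()), rel=1e-12)


# ------------------------------------------------------------- unit sampling
def test_sample_units_rules(rng):
    specs = [
        LayerSpec("conv", "convolutional", 2, 2, 1),
        LayerSpec("fc", "fully_connected", 1, 1, 64),
    ]
    sub = nc.sample_units_for_iteration(specs, np.random.default_rng(0))
    np.testing.assert_array_equal(sub["conv"], np.arange(4))  # single channel, always chosen
    np.testing.assert_array_equal(sub["fc"], np.arange(64))  # dense: all units


def test_sample_units_channel_frequencies_uniform():
    spec = [LayerSpec("conv", "convolutional", 2, 2, 3)]
    gen = np.random.default_rng(1)
    counts = np.zeros(3)
    for _ in range(3000):
        idx = nc.sample_units_for_iteration(spec, gen)["conv"]
        counts[idx[0] // 4] += 1
    freqs = counts / 3000
    assert np.all(np.abs(freqs - 1 / 3) < 0.03)


# ------------------------------------------------------ brain-loss converter
def test_brain_ridge_identity_when_target_equals_source(rng):
    X = rng.standard_normal((12, 6))
    conv = nc.train_brain_loss_converter(X, X, ridge_penalty=0.0)
    np.testing.assert_allclose(conv.M, np.eye(6), atol=1e-8)
    np.testing.assert_allclose(conv.c, 0.0, atol=1e-8)


def test_brain_ridge_huge_penalty_collapses_to_means(rng):
    X = rng.standard_normal((15, 4))
    Y = rng.standard_normal((15, 3)) + 2.0
    conv = nc.train_brain_loss_converter(X, Y, ridge_penalty=1e12)
    assert np.linalg.norm(conv.M) < 1e-6
    np.testing.assert_allclose(conv.c, Y.mean(0), atol=1e-6)


def test_brain_ridge_matches_normal_equation_oracle(rng):
    X = rng.standard_normal((6, 3))
    Y = rng.standard_normal((6, 2))
    lam = 1.0
    conv = nc.train_brain_loss_converter(X, Y, ridge_penalty=lam)
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    M = (np.linalg.solve(Xc.T @ Xc + lam * np.eye(3), Xc.T @ Yc)).T
    np.testing.assert_allclose(conv.M, M, atol=1e-10)
    np.testing.assert_allclose(conv.c, Y.mean(0) - M @ X.mean(0), atol=1e-10)


def test_brain_ridge_shape_mismatch(rng):
    with pytest.raises(ValueError, match="sample counts"):
        nc.train_brain_loss_converter(rng.standard_normal((5, 3)), rng.standard_normal((4, 3)))


# -------------------------------------------------------------- Procrustes
def test_procrustes_recovers_planted_rotation(rng):
    X = rng.standard_normal((40, 5))
    q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
    Y = X @ q
    conv = nc.train_procrustes_converter(X, Y)
    np.testing.assert_allclose(conv.R, q, atol=1e-6)
    np.testing.assert_allclose(conv.R.T @ conv.R, np.eye(5), atol=1e-8)
    np.testing.assert_allclose(nc.convert(conv, X), Y, atol=1e-8)


def test_procrustes_identity_and_reflection(rng):
    X = rng.standard_normal((30, 4))
    conv = nc.train_procrustes_converter(X, X)
    np.testing.assert_allclose(conv.R, np.eye(4), atol=1e-8)
    # reflections allowed: unconstrained orthogonal solution is at least as good
    refl = np.diag([1.0, 1.0, 1.0, -1.0])
    Y = (X - X.mean(0)) @ refl
    conv = nc.train_procrustes_converter(X, Y)
    resid_free = np.linalg.norm(nc.convert(conv, X) - Y)
    u, _, vt = np.linalg.svd((X - X.mean(0)).T @ Y)
    d = np.ones(4)
    d[-1] = np.sign(np.linalg.det(u @ vt))
    R_rot = u @ np.diag(d) @ vt  # rotation-only (det +1) alternative
    resid_rot = np.linalg.norm((X - X.mean(0)) @ R_rot - Y)
    assert resid_free <= resid_rot + 1e-10


def test_procrustes_dimension_mismatch_requires_padding(rng):
    X, Y = rng.standard_normal((10, 4)), rng.standard_normal((10, 3))
    with pytest.raises(ValueError, match="pad"):
        nc.train_procrustes_converter(X, Y)
    conv = nc.train_procrustes_converter(X, Y, pad=True)
    assert nc.convert(conv, X).shape == (10, 3)


# ------------------------------------------------------------ MLP mechanics
def test_convert_trivial_and_batch_independence(rng):
    conv = nc.Converter("brain_ridge", 4, 4, M=np.eye(4), c=np.zeros(4))
    X = rng.standard_normal((5, 4))
    np.testing.assert_array_equal(nc.convert(conv, X), X)
    mlp = nc.Converter("content_mlp_nonlinear", 6, 3, mlp=_MLP("content_mlp_nonlinear", 6, 3, rng))
    batch = rng.standard_normal((10, 6))
    one = nc.convert(mlp, batch[4])
    np.testing.assert_allclose(nc.convert(mlp, batch)[4], one, atol=1e-12)
    with pytest.raises(ValueError, match="mismatch"):
        nc.convert(mlp, rng.standard_normal((2, 5)))


def test_linear_mlp_collapses_to_single_affine_map(rng):
    mlp = nc.Converter("content_mlp_linear", 5, 4, mlp=_MLP("content_mlp_linear", 5, 4, rng))
    M, c = collapse_linear_mlp(mlp)
    X = rng.standard_normal((7, 5))
    np.testing.assert_allclose(nc.convert(mlp, X), X @ M.T + c, atol=1e-10)


def test_nonlinear_hidden_width_is_half_input():
    mlp = _MLP("content_mlp_nonlinear", 9, 4, np.random.default_rng(0))
    assert mlp.h == 5  # ceil(9/2)


# ----------------------------------------------------- content training
@pytest.fixture(scope="module")
def trained_content():
    world = nc.make_stimulus_world(1, n_train=60, n_test=15, n_categories=6)
    sub = nc.make_virtual_subject(2, world, n_voxels=80, noise_sd=0.0)
    sess = nc.simulate_session(sub, world.train, 1, 3)
    dec = nc.fit_feature_decoder(sess, world.train.features, n_voxels_select=80, ridge_penalty=1.0)
    cfg = nc.ContentTrainingConfig(n_iterations=1024, kind="content_mlp_linear", rng_seed=0)
    conv = nc.train_content_converter(sess, world.train.features, dec, cfg)
    return world, sub, sess, dec, cfg, conv


def test_content_training_reduces_loss_nearly_fully(trained_content):
    """Noiseless linear world: training drives the content loss below 1% of the start."""
    *_, conv = trained_content
    traj = conv.loss_trajectory
    assert traj.min() < 0.01 * traj[0]
    assert traj[-1] < 0.02 * traj[0]  # per-iteration channel sampling jitters the tail


def test_content_training_smoothed_trajectory_nonincreasing(trained_content):
    *_, conv = trained_content
    traj = conv.loss_trajectory
    k = 50
    smooth = np.convolve(traj, np.ones(k) / k, mode="valid")
    assert np.all(np.diff(smooth) <= np.abs(smooth[:-1]) * 0.05 + 1e-9)


def test_content_training_seed_determinism(trained_content):
    world, sub, sess, dec, cfg, conv = trained_content
    again = nc.train_content_converter(sess, world.train.features, dec, cfg)
    for a, b in zip(conv.mlp.params(), again.mlp.params()):
        np.testing.assert_array_equal(a.data, b.data)


def test_content_training_never_touches_target_responses(trained_content):
    """The API takes no target responses: the trained map depends only on
    source data, source features and the frozen decoder."""
    world, sub, sess, dec, cfg, conv = trained_content
    assert conv.config["kind"] == "content_mlp_linear"
    assert conv.loss_trajectory.shape == (cfg.n_iterations,)


def test_content_converter_residual_kind_runs(trained_content):
    world, sub, sess, dec, _, _ = trained_content
    cfg = nc.ContentTrainingConfig(n_iterations=8, kind="content_mlp_residual", rng_seed=1)
    conv = nc.train_content_converter(sess, world.train.features, dec, cfg)
    out = nc.convert(conv, sess.mean_pattern())
    assert out.shape == (60, 80) and np.all(np.isfinite(out))


def test_content_feature_recovery_improves_with_iterations(trained_content):
    """Composed with the frozen decoder, converted activity reproduces the
    stimulus features increasingly well as training proceeds."""
    world, sub, sess, dec, _, _ = trained_content
    r2s = []
    for iters in (16, 128, 384):
        cfg = nc.ContentTrainingConfig(n_iterations=iters, kind="content_mlp_linear", rng_seed=0)
        conv = nc.train_content_converter(sess, world.train.features, dec, cfg)
        decoded = nc.decode_features(dec, nc.convert(conv, sess.mean_pattern()))
        d = decoded.flat("conv2")
        t = world.train.features.flat("conv2")
        r2s.append(1 - ((d - t) ** 2).sum() / ((t - t.mean(0)) ** 2).sum())
    assert r2s[0] <= r2s[1] + 0.02 and r2s[1] <= r2s[2] + 0.02
    assert r2s[-1] > 0.9


def test_content_config_validation():
    with pytest.raises(ValueError):
        nc.ContentTrainingConfig(n_iterations=0)
    with pytest.raises(ValueError):
        nc.ContentTrainingConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        nc.ContentTrainingConfig(kind="vit")
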