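"""Noise ceilings, conversion metrics, identification, pair grids, bootstrap."""

import itertools

import numpy as np
import pytest

import neurocode as nc


# ------------------------------------------------------------- noise ceiling
def test_ceiling_one_for_identical_repetitions(rng):
    base = rng.standard_normal((10, 1, 20))
    ds = nc.ResponseDataset("s", [f"i{k}" for k in range(10)], np.repeat(base, 3, axis=1))
    ceil = nc.estimate_noise_ceiling(ds, rng_seed=0)
    np.testing.assert_allclose(ceil.pattern, 1.0, atol=1e-12)
    np.testing.assert_allclose(ceil.profile, 1.0, atol=1e-12)
    assert ceil.excluded_stimuli.size == 0


def test_ceiling_minus_one_for_sign_flipped_repetitions(rng):
    base = rng.standard_normal((6, 1, 15))
    resp = np.concatenate([base, -base], axis=1)
    ceil = nc.estimate_noise_ceiling(
        nc.ResponseDataset("s", [f"i{k}" for k in range(6)], resp), rng_seed=0
    )
    np.testing.assert_allclose(ceil.pattern, -1.0, atol=1e-12)


def test_ceiling_matches_brute_force_pair_average(rng):
    resp = rng.standard_normal((5, 4, 8))
    ds = nc.ResponseDataset("s", [f"i{k}" for k in range(5)], resp)
    ceil = nc.estimate_noise_ceiling(ds, rng_seed=1)
    for i in range(5):
        vals = [
            np.corrcoef(resp[i, a], resp[i, b])[0, 1]
            for a, b in itertools.combinations(range(4), 2)
        ]
        assert ceil.pattern[i] == pytest.approx(np.mean(vals), rel=1e-10)
    for v in range(8):
        vals = [
            np.corrcoef(resp[:, a, v], resp[:, b, v])[0, 1]
            for a, b in itertools.combinations(range(4), 2)
        ]
        assert ceil.profile[v] == pytest.approx(np.mean(vals), rel=1e-10)


def test_ceiling_tracks_snr_formula():
    # train stimuli: the encoding is normalized to unit signal sd on these
    world = nc.make_stimulus_world(2, n_train=200, n_test=10, n_categories=8)
    sub = nc.make_virtual_subject(3, world, n_voxels=60, noise_sd=1.0)
    ds = nc.simulate_session(sub, world.train, 3, rng_seed=0)
    ceil = nc.estimate_noise_ceiling(ds, rng_seed=0)
    assert abs(np.nanmean(ceil.profile) - 0.5) < 0.05  # sigma_s^2/(sigma_s^2+sigma_n^2)


def test_ceiling_monotone_in_noise():
    world = nc.make_stimulus_world(2, n_train=50, n_test=60, n_categories=8)
    means = []
    for noise in (2.0, 1.0, 0.5, 0.0):
        sub = nc.make_virtual_subject(4, world, n_voxels=50, noise_sd=noise)
        ds = nc.simulate_session(sub, world.test, 3, rng_seed=1)
        means.append(np.nanmean(nc.estimate_noise_ceiling(ds, rng_seed=0).profile))
    assert all(a < b for a, b in zip(means, means[1:]))
    assert means[-1] == pytest.approx(1.0, abs=1e-9)


def test_ceiling_requires_repetitions(rng):
    ds = nc.ResponseDataset("s", ["a", "b"], rng.standard_normal((2, 1, 5)))
    with pytest.raises(ValueError, match="repetitions"):
        nc.estimate_noise_ceiling(ds)


# ------------------------------------------------------- conversion accuracy
def test_conversion_accuracy_division_contract(rng):
    resp = rng.standard_normal((4, 2, 6))
    ds = nc.ResponseDataset("s", [f"i{k}" for k in range(4)], resp)
    ceil = nc.NoiseCeiling(
        pattern=np.full(4, 0.9), profile=np.full(6, 0.9), pattern_threshold=0.0, profile_threshold=0.0
    )
    table = nc.conversion_accuracy(ds.mean_pattern(), ds, ceil)
    pat = table[table.metric == "pattern"].value.to_numpy()
    np.testing.assert_allclose(pat, 1 / 0.9, atol=1e-10)  # raw r = 1 against itself
    mean = table[table.metric == "pattern_mean"].value.iloc[0]
    assert mean == pytest.approx(1 / 0.9)


def test_conversion_accuracy_matches_loop_oracle(rng):
    conv = rng.standard_normal((5, 6))
    resp = rng.standard_normal((5, 3, 6))
    ds = nc.ResponseDataset("s", [f"i{k}" for k in range(5)], resp)
    table = nc.conversion_accuracy(conv, ds, ceiling=None)
    avg = resp.mean(axis=1)
    for i in range(5):
        expected = np.corrcoef(conv[i], avg[i])[0, 1]
        got = table[(table.metric == "pattern") & (table.item == f"i{i}")].value.iloc[0]
        assert got == pytest.approx(expected, rel=1e-10)
    for v in range(6):
        expected = np.corrcoef(conv[:, v], avg[:, v])[0, 1]
        got = table[(table.metric == "profile") & (table.item == f"voxel{v}")].value.iloc[0]
        assert got == pytest.approx(expected, rel=1e-10)


def test_excluded_items_missing_not_zero(rng):
    resp = rng.standard_normal((4, 2, 5))
    ds = nc.ResponseDataset("s", [f"i{k}" for k in range(4)], resp)
    ceil = nc.NoiseCeiling(
        pattern=np.array([0.9, 0.05, 0.9, -0.2]),
        profile=np.full(5, 0.9),
        pattern_threshold=0.1,
        profile_threshold=0.0,
    )
    table = nc.conversion_accuracy(ds.mean_pattern(), ds, ceil)
    vals = table[table.metric == "pattern"].set_index("item").value
    assert np.isnan(vals["i1"]) and np.isnan(vals["i3"])  # excluded / non-positive
    assert np.isfinite(table[table.metric == "pattern_mean"].value.iloc[0])


def test_normalization_removes_snr_dependence():
    """A perfect converter scores ~1 after ceiling normalization despite noise."""
    world = nc.make_stimulus_world(6, n_train=50, n_test=60, n_categories=8)
    sub = nc.make_virtual_subject(5, world, n_voxels=80, noise_sd=1.0)
    clean = sub.clean_responses(world.test.features)
    ds = nc.simulate_session(sub, world.test, 4, rng_seed=2)
    ceil = nc.estimate_noise_ceiling(ds, rng_seed=0)
    table = nc.conversion_accuracy(clean, ds, ceil)
    # single-repetition-pair ceilings bound r(clean, 4-rep average) slightly
    # above the ceiling itself, so normalized scores land just above 1
    assert table[table.metric == "pattern_mean"].value.iloc[0] == pytest.approx(1.0, abs=0.15)


# ------------------------------------------------------------ identification
def test_identification_perfect_and_comparison_counts(rng):
    feats = rng.standard_normal((50, 30))
    out = nc.pairwise_identification(feats, feats)
    assert out["mean"] == 1.0
    assert out["n_comparisons"] == 2450
    assert nc.pairwise_identification(rng.standard_normal((100, 10)), rng.standard_normal((100, 10)))[
        "n_comparisons"
    ] == 9900


def test_identification_brute_force_three_items():
    true = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.3, 0.3, 1.0]])
    cand = np.array([[0.9, 0.1, 0.0], [1.0, 0.0, 0.1], [0.2, 0.3, 1.1]])  # row 1 engineered to fail
    out = nc.pairwise_identification(cand, true)
    expected = []
    for i in range(3):
        wins = 0.0
        ri = np.array([np.corrcoef(cand[i], true[j])[0, 1] for j in range(3)])
        for j in range(3):
            if j == i:
                continue
            wins += 1.0 if ri[i] > ri[j] else (0.5 if ri[i] == ri[j] else 0.0)
        expected.append(wins / 2)
    np.testing.assert_allclose(out["accuracies"], expected, atol=1e-12)


def test_identification_zero_variance_row_counts_half(rng):
    cand = rng.standard_normal((4, 6))
    cand[2] = 3.14
    out = nc.pairwise_identification(cand, rng.standard_normal((4, 6)))
    assert out["accuracies"][2] == 0.5
    assert 2 in out["degenerate_items"]


def test_identification_affine_invariance(rng):
    cand = rng.standard_normal((12, 9))
    true = rng.standard_normal((12, 9))
    base = nc.pairwise_identification(cand, true)["accuracies"]
    shifted = nc.pairwise_identification(2.5 * cand - 7.0, true)["accuracies"]
    np.testing.assert_allclose(base, shifted, atol=1e-12)


# ----------------------------------------------------------------- pair grid
def test_pair_grid_printed_counts():
    deeprecon = [(f"d{i}", "deeprecon") for i in range(5)]
    things = [(f"t{i}", "things") for i in range(3)]
    nsd = [(f"n{i}", "nsd") for i in range(4)]
    assert len(nc.enumerate_conversion_pairs(deeprecon, "within_dataset")) == 20
    roster = deeprecon + things + nsd
    assert len(nc.enumerate_conversion_pairs(roster, "inter_site")) == 94
    within = nc.enumerate_conversion_pairs(roster, "within_dataset")
    inter = nc.enumerate_conversion_pairs(roster, "inter_site")
    allp = nc.enumerate_conversion_pairs(roster, "all")
    assert len(allp) == len(within) + len(inter)
    assert len(nc.enumerate_conversion_pairs([("solo", "x")], "all")) == 0
    for s, t, sd, td in inter.pairs:
        assert sd != td and s != t


# ------------------------------------------------------------------ bootstrap
def _grid_values(rng, ns, nt, const=None):
    vals = {}
    for i in range(ns):
        for j in range(nt):
            if f"s{i}" != f"t{j}":
                vals[(f"s{i}", f"t{j}")] = const if const is not None else rng.standard_normal()
    return vals


def test_bootstrap_constant_values(rng):
    vals = _grid_values(rng, 3, 3, const=0.7)
    ci = nc.dyadic_bootstrap(vals, n_replicates=200, rng_seed=0)
    assert ci.mean == pytest.approx(0.7)
    assert ci.lower == pytest.approx(0.7) and ci.upper == pytest.approx(0.7)


def test_bootstrap_two_seed_stability(rng):
    """CI endpoints agree across independent seeds on a small dyadic grid."""
    shared = {
        (f"s{i}", f"t{j}"): 0.5 + 0.05 * (i - j) for i in range(3) for j in range(3)
    }
    a = nc.dyadic_bootstrap(shared, n_replicates=2000, rng_seed=1)
    b = nc.dyadic_bootstrap(shared, n_replicates=2000, rng_seed=99)
    assert abs(a.lower - b.lower) < 0.01 and abs(a.upper - b.upper) < 0.01
    assert a.lower <= a.mean <= a.upper


def test_bootstrap_never_pairs_same_id():
    # ids shared between sources and targets; exclusion must drop (x, x)
    vals = {(s, t): 1.0 for s in "abc" for t in "abc" if s != t}
    ci = nc.dyadic_bootstrap(vals, n_replicates=100, rng_seed=3)
    assert ci.mean == pytest.approx(1.0)  # any same-id pair would carry no value anyway


def test_bootstrap_ci_width_shrinks_with_dispersion(rng):
    tight = {k: 0.5 + 0.001 * v for k, v in zip(_grid_values(rng, 4, 4), rng.standard_normal(100))}
    wide = {k: 0.5 + 0.3 * v for k, v in zip(_grid_values(rng, 4, 4), rng.standard_normal(100))}
    ci_t = nc.dyadic_bootstrap(tight, n_replicates=500, rng_seed=0)
    ci_w = nc.dyadic_bootstrap(wide, n_replicates=500, rng_seed=0)
    assert (ci_t.upper - ci_t.lower) < (ci_w.upper - ci_w.lower)


def test_bootstrap_coverage_on_synthetic_dyads():
    """Percentile CI covers the true mean at close to nominal rate."""
    nominal = 0.95
    hits = 0
    n_sim = 60
    for s in range(n_sim):
        g = np.random.default_rng(1000 + s)
        vals = {
            (f"s{i}", f"t{j}"): 0.4 + g.normal(scale=0.1)
            for i in range(4)
            for j in range(4)
        }
        ci = nc.dyadic_bootstrap(vals, n_replicates=300, rng_seed=s)
        if ci.lower <= 0.4 <= ci.upper:
            hits += 1
    assert hits / n_sim >= nominal - 0.05 - 2 * np.sqrt(nominal * 0.05 / n_sim)


def test_bootstrap_requires_two_ids():
    with pytest.raises(ValueError, match="distinct"):
        nc.dyadic_bootstrap({("a", "b"): 1.0})
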