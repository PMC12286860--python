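"""Conversion-accuracy metrics, identification analysis and group statistics.

Conversion accuracy is measured by pattern correlation (across voxels, per
test stimulus) and profile correlation (across test stimuli, per voxel)
between converted and measured activity, each normalized by a noise ceiling
estimated from correlations between repeated responses to identical stimuli.
Stimuli or voxels whose ceiling falls below the 99th percentile of a
random-pair null distribution are excluded from conversion metrics (and only
from conversion metrics — decoding analyses retain all voxels).

Pairwise identification treats each test item against every other test item
as the false alternative; chance is 50%. Group summaries over subject pairs
use a dyadic bootstrap that resamples source and target subject identities
separately, honoring the dependence among pairs sharing a subject.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import pearson_rows
from .virtual_subjects import ResponseDataset

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseCeiling",
    "PairGrid",
    "BootstrapCI",
    "estimate_noise_ceiling",
    "conversion_accuracy",
    "pairwise_identification",
    "enumerate_conversion_pairs",
    "dyadic_bootstrap",
]


@dataclass
class NoiseCeiling:
    pattern: np.ndarray  # per-stimulus ceilings
    profile: np.ndarray  # per-voxel ceilings
    pattern_threshold: float
    profile_threshold: float
    excluded_stimuli: np.ndarray = field(default=None)
    excluded_voxels: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.excluded_stimuli is None:
            self.excluded_stimuli = np.flatnonzero(self.pattern < self.pattern_threshold)
        if self.excluded_voxels is None:
            self.excluded_voxels = np.flatnonzero(self.profile < self.profile_threshold)


@dataclass
class PairGrid:
    pairs: list[tuple[str, str, str, str]]  # (src_subject, tgt_subject, src_dataset, tgt_dataset)
    scope: str

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class BootstrapCI:
    mean: float
    lower: float
    upper: float
    confidence: float
    n_replicates: int
    rng_seed: int


def estimate_noise_ceiling(
    test_responses: ResponseDataset,
    n_null_draws: int = 10_000,
    percentile: float = 99.0,
    rng_seed: int = 0,
) -> NoiseCeiling:
    """Noise ceilings from correlations between repeated responses.

    Pattern ceiling per stimulus: mean over repetition pairs of the
    across-voxel correlation between the two repetitions. Profile ceiling per
    voxel: mean over repetition pairs of the across-stimuli correlation of
    that voxel's two response sequences. The exclusion threshold is the
    ``percentile``-th percentile of a seeded random-pair null — repetition
    responses to mismatched stimuli (pattern) and mismatched voxel pairings
    (profile).
    """
    resp = test_responses.responses  # (S, R, V)
    S, R, V = resp.shape
    if R < 2:
        raise ValueError(
            "noise-ceiling estimation needs >= 2 repetitions per stimulus; "
            "skip normalization for single-repetition data"
        )
    rep_pairs = list(itertools.combinations(range(R), 2))
    pattern = np.zeros(S)
    for a, b in rep_pairs:
        pattern += pearson_rows(resp[:, a, :], resp[:, b, :])
    pattern /= len(rep_pairs)
    profile = np.zeros(V)
    for a, b in rep_pairs:
        profile += pearson_rows(resp[:, a, :].T, resp[:, b, :].T)
    profile /= len(rep_pairs)

    rng = np.random.default_rng(rng_seed)
    i = rng.integers(S, size=n_null_draws)
    j = rng.integers(S, size=n_null_draws)
    resample = i == j
    while resample.any():
        j[resample] = rng.integers(S, size=resample.sum())
        resample = i == j
    ra, rb = rng.integers(R, size=n_null_draws), rng.integers(R, size=n_null_draws)
    null_pattern = pearson_rows(resp[i, ra, :], resp[j, rb, :])
    v = rng.integers(V, size=n_null_draws)
    w = rng.integers(V, size=n_null_draws)
    resample = v == w
    while resample.any():
        w[resample] = rng.integers(V, size=resample.sum())
        resample = v == w
    null_profile = pearson_rows(resp[:, 0, :][:, v].T, resp[:, -1, :][:, w].T)
    return NoiseCeiling(
        pattern,
        profile,
        float(np.nanpercentile(null_pattern, percentile)),
        float(np.nanpercentile(null_profile, percentile)),
    )


def conversion_accuracy(
    converted: np.ndarray,
    measured: ResponseDataset,
    ceiling: NoiseCeiling | None = None,
    pair: str = "",
    roi: str = "VC",
) -> pd.DataFrame:
    """Normalized pattern/profile correlation between converted and measured activity.

    ``measured`` is repetition-averaged internally. Raw correlations are
    divided by their noise ceilings; excluded or non-positive-ceiling items
    are flagged missing and dropped from the means. Returns a tidy table with
    per-item rows plus ``*_mean`` summary rows.
    """
    target = measured.mean_pattern()
    converted = np.asarray(converted, dtype=np.float64)
    if converted.shape != target.shape:
        raise ValueError(f"shape mismatch: converted {converted.shape} vs measured {target.shape}")
    raw_pattern = pearson_rows(converted, target)
    raw_profile = pearson_rows(converted.T, target.T)
    if ceiling is not None:
        pat_ceil = ceiling.pattern.copy()
        prof_ceil = ceiling.profile.copy()
        pat_ceil[ceiling.excluded_stimuli] = np.nan
        prof_ceil[ceiling.excluded_voxels] = np.nan
        bad_p = np.flatnonzero(np.nan_to_num(pat_ceil, nan=1.0) <= 0)
        bad_v = np.flatnonzero(np.nan_to_num(prof_ceil, nan=1.0) <= 0)
        if bad_p.size or bad_v.size:
            logger.warning(
                "non-positive noise ceilings for %d stimuli / %d voxels; flagged missing",
                bad_p.size,
                bad_v.size,
            )
        pat_ceil[bad_p] = np.nan
        prof_ceil[bad_v] = np.nan
        norm_pattern = raw_pattern / pat_ceil
        norm_profile = raw_profile / prof_ceil
    else:
        norm_pattern, norm_profile = raw_pattern, raw_profile
    rows = []
    for i, (r, sid) in enumerate(zip(norm_pattern, measured.stimulus_ids)):
        rows.append((pair, roi, "pattern", sid, r))
    for v, r in enumerate(norm_profile):
        rows.append((pair, roi, "profile", f"voxel{v}", r))
    rows.append((pair, roi, "pattern_mean", "", np.nanmean(norm_pattern)))
    rows.append((pair, roi, "profile_mean", "", np.nanmean(norm_profile)))
    return pd.DataFrame(rows, columns=["pair", "roi", "metric", "item", "value"])


def pairwise_identification(
    candidate_features: np.ndarray, true_features: np.ndarray
) -> dict:
    """Two-alternative identification of each item against all other items.

    For item i the candidate row is correlated with its own true row and with
    each of the S-1 other true rows; a comparison is correct when the former
    is larger, ties count 0.5. A zero-variance candidate row has undefined
    correlations: all of its comparisons count 0.5 and the row is flagged.
    """
    C = np.asarray(candidate_features, dtype=np.float64)
    T = np.asarray(true_features, dtype=np.float64)
    if C.shape != T.shape:
        raise ValueError("candidate and true feature arrays must have the same shape")
    S = C.shape[0]
    if S < 2:
        raise ValueError("identification needs at least 2 items")
    Cc = C - C.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(Cc, axis=1)
    tn = np.linalg.norm(Tc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Cc @ Tc.T) / np.outer(cn, tn)
    degenerate = np.flatnonzero((cn == 0) | ~np.isfinite(cn))
    accuracies = np.empty(S)
    for i in range(S):
        if i in degenerate or np.any(~np.isfinite(corr[i])):
            accuracies[i] = 0.5
            continue
        own = corr[i, i]
        others = np.delete(corr[i], i)
        accuracies[i] = (np.sum(own > others) + 0.5 * np.sum(own == others)) / (S - 1)
    return {
        "accuracies": accuracies,
        "mean": float(accuracies.mean()),
        "n_comparisons": S * (S - 1),
        "degenerate_items": degenerate,
    }


def enumerate_conversion_pairs(
    subjects: list[tuple[str, str]], scope: str = "all"
) -> PairGrid:
    """Ordered source→target pairs of distinct subjects under a scope.

    ``within_dataset`` keeps pairs sharing a dataset id, ``inter_site`` keeps
    pairs whose dataset ids differ, ``all`` keeps both.
    """
    if scope not in ("within_dataset", "inter_site", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    pairs = []
    for (s, sd), (t, td) in itertools.permutations(subjects, 2):
        if s == t:
            continue
        same = sd == td
        if scope == "within_dataset" and not same:
            continue
        if scope == "inter_site" and same:
            continue
        pairs.append((s, t, sd, td))
    return PairGrid(pairs, scope)


def dyadic_bootstrap(
    pair_values: dict[tuple[str, str], float],
    n_replicates: int = 1000,
    confidence: float = 0.95,
    rng_seed: int = 0,
) -> BootstrapCI:
    """Bootstrap mean and CI for dyadic (subject-pair) data.

    Each replicate resamples source IDs and target IDs with replacement,
    forms the crossed pairs, drops pairs whose source and target IDs
    coincide, truncates or fills to the original sample size with observed
    pair values, and takes the mean. The CI comes from the replicate-mean
    percentiles.
    """
    sources = sorted({s for s, _ in pair_values})
    targets = sorted({t for _, t in pair_values})
    if len(sources) < 2 or len(targets) < 2:
        raise ValueError("dyadic bootstrap needs >= 2 distinct source and target IDs")
    n = len(pair_values)
    rng = np.random.default_rng(rng_seed)
    means = np.empty(n_replicates)
    redraws = 0
    for rep in range(n_replicates):
        while True:
            ss = rng.choice(sources, size=len(sources), replace=True)
            tt = rng.choice(targets, size=len(targets), replace=True)
            vals = [
                pair_values[(s, t)]
                for s in ss
                for t in tt
                if s != t and (s, t) in pair_values
            ]
            if vals:
                break
            redraws += 1
        vals = np.asarray(vals)
        rng.shuffle(vals)
        if len(vals) >= n:
            sample = vals[:n]
        else:
            sample = np.concatenate([vals, rng.choice(vals, size=n - len(vals), replace=True)])
        means[rep] = sample.mean()
    if redraws:
        logger.info("dyadic bootstrap redrew %d empty replicates", redraws)
    alpha = 1.0 - confidence
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(float(means.mean()), float(lo), float(hi), confidence, n_replicates, rng_seed)
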