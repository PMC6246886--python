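"""Splits, surrogate constructions, rank-sum statistics, Bonferroni plan."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reachdecode.decoder import DecoderConfig
from reachdecode.evaluation import (
    SplitPlan,
    bonferroni_critical_p,
    compare_distributions,
    comparison_family_size,
    evaluate_fold,
    make_splits,
    rank_sum_test,
    shuffle_pls_rows,
    temporal_surrogate,
)
from reachdecode.kinematics import KinematicFrames
from reachdecode.task import ConfigurationError


# ---------------------------------------------------------------------------
# splits

def test_splits_sizes_partition_determinism():
    ids = np.arange(80)
    plan = SplitPlan(n_repeats=5, seed=3)
    splits = make_splits(ids, plan)
    for train, test in splits:
        assert train.size == 70 and test.size == 10
        assert np.intersect1d(train, test).size == 0
        np.testing.assert_array_equal(np.union1d(train, test), ids)
    splits2 = make_splits(ids, SplitPlan(n_repeats=5, seed=3))
    for (a, b), (c, d) in zip(splits, splits2):
        np.testing.assert_array_equal(a, c)
        np.testing.assert_array_equal(b, d)
    with pytest.raises(ConfigurationError):
        make_splits(np.arange(5), plan)


# ---------------------------------------------------------------------------
# temporal surrogate

def _toy_frames(n_trials=6, frames_per_trial=40, seed=0):
    rng = np.random.default_rng(seed)
    F = n_trials * frames_per_trial
    speed = np.abs(rng.standard_normal(F)).cumsum() % 3.0
    velocity = rng.standard_normal((F, 3))
    return KinematicFrames(
        times=np.arange(F) * 0.05,
        position=np.cumsum(velocity, axis=0) * 0.05,
        velocity=velocity,
        speed=speed,
        trial_id=np.repeat(np.arange(n_trials), frames_per_trial),
        movement=np.zeros(F, dtype=bool),
    )


def test_temporal_surrogate_identity_reproduces_original():
    frames = _toy_frames()
    train = np.arange(6)
    sur = temporal_surrogate(frames, train, seed=0, permutation=train,
                             shifts={t: 0 for t in train})
    np.testing.assert_array_equal(sur.speed, frames.speed)
    np.testing.assert_array_equal(sur.position, frames.position)


def test_temporal_surrogate_preserves_trial_multisets():
    frames = _toy_frames()
    train = np.arange(6)
    sur = temporal_surrogate(frames, train, seed=42)
    # per-trial sorted speed values across the *training set* are a
    # permutation of the originals trial-for-trial (equal-length trials)
    orig = sorted(
        tuple(np.sort(frames.speed[frames.trial_frames(t)])) for t in train
    )
    new = sorted(
        tuple(np.sort(sur.speed[sur.trial_frames(t)])) for t in train
    )
    assert orig == new
    # neural features are untouched by construction (kinematics-only op)


def test_temporal_surrogate_preserves_autocorrelation():
    frames = _toy_frames(n_trials=4, frames_per_trial=100, seed=1)
    train = np.arange(4)

    def lag1(x):
        return np.corrcoef(x[:-1], x[1:])[0, 1]

    sur = temporal_surrogate(frames, train, seed=7)
    rows = np.concatenate([frames.trial_frames(t) for t in train])
    assert abs(lag1(sur.speed[rows]) - lag1(frames.speed[rows])) < 0.05


# ---------------------------------------------------------------------------
# feature-shuffle surrogate

def test_shuffle_pls_rows_identity_and_block_structure():
    rng = np.random.default_rng(2)
    C, F, L = 3, 8, 31
    coef = rng.standard_normal((C * F * L, 4))
    ident = shuffle_pls_rows(coef, (C, F, L), np.arange(C * F))
    np.testing.assert_array_equal(ident, coef)
    perm = rng.permutation(C * F)
    shuf = shuffle_pls_rows(coef, (C, F, L), perm)
    # same multiset of lag-blocks, moved as units
    orig_blocks = {coef.reshape(C * F, L, 4)[i].tobytes() for i in range(C * F)}
    new_blocks = {shuf.reshape(C * F, L, 4)[i].tobytes() for i in range(C * F)}
    assert orig_blocks == new_blocks


# ---------------------------------------------------------------------------
# fold metrics

def test_evaluate_fold_perfect_and_negated():
    from reachdecode.decoder import PredictionResult

    frames = _toy_frames(seed=3)
    rows = np.arange(frames.n_frames)
    perfect = PredictionResult(
        frame_idx=rows, state=np.ones(rows.size, bool),
        speed=frames.speed.copy(), velocity=frames.velocity.copy(),
    )
    m = evaluate_fold(frames, perfect, np.arange(6))
    assert m["speed_r"] == pytest.approx(1.0)
    for k in ("vx_r", "vy_r", "vz_r"):
        assert m[k] == pytest.approx(1.0)
    assert m["targets_hit_pct"] == 100.0

    negated = PredictionResult(
        frame_idx=rows, state=np.ones(rows.size, bool),
        speed=frames.speed.copy(), velocity=-frames.velocity,
    )
    m = evaluate_fold(frames, negated, np.arange(6))
    for k in ("vx_r", "vy_r", "vz_r"):
        assert m[k] == pytest.approx(-1.0)


def test_evaluate_fold_zero_variance_flagged_as_zero():
    from reachdecode.decoder import PredictionResult

    frames = _toy_frames(seed=4)
    rows = np.arange(frames.n_frames)
    flat = PredictionResult(
        frame_idx=rows, state=np.zeros(rows.size, bool),
        speed=np.zeros(rows.size), velocity=np.zeros((rows.size, 3)),
    )
    m = evaluate_fold(frames, flat, np.arange(6))
    assert m["speed_r"] == 0.0 and m["vx_r"] == 0.0


# ---------------------------------------------------------------------------
# rank-sum statistics

def _exact_two_sided_p(x, y):
    """Independent enumeration oracle for the rank-sum p-value."""
    from scipy.stats import rankdata

    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = ranks[:n1].sum()
    stats = [
        ranks[list(c)].sum()
        for c in itertools.combinations(range(len(combined)), n1)
    ]
    stats = np.asarray(stats)
    le = np.mean(stats <= w + 1e-9)
    ge = np.mean(stats >= w - 1e-9)
    return min(1.0, 2.0 * min(le, ge))


def test_rank_sum_textbook_example():
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert res["W"] == 6.0
    assert res["method"] == "exact"
    assert res["p"] == pytest.approx(0.1)


def test_rank_sum_matches_enumeration_for_small_groups():
    rng = np.random.default_rng(5)
    for n1 in (2, 3, 4, 5, 6):
        for n2 in (2, 4, 6):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.uniform(-1, 1)
            res = rank_sum_test(x, y)
            assert res["method"] == "exact"
            assert res["p"] == pytest.approx(_exact_two_sided_p(x, y), abs=1e-12)


def test_rank_sum_normal_approximation_with_ties():
    rng = np.random.default_rng(6)
    x = np.round(rng.standard_normal(40), 1)
    y = np.round(rng.standard_normal(45) + 1.0, 1)
    res = rank_sum_test(x, y)
    assert res["method"] == "normal"
    assert res["p"] < 0.01
    from scipy.stats import ranksums

    ref = ranksums(x, y)
    # same direction, similar magnitude (we add tie/continuity corrections)
    assert np.sign(res["z"]) == np.sign(ref.statistic)
    assert res["z"] == pytest.approx(ref.statistic, abs=0.1)


def test_identical_groups_not_significant():
    res = compare_distributions([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], m=1)
    assert res["p"] > 0.9
    assert not res["significant"]


def test_bonferroni_family_enumeration():
    assert comparison_family_size() == 215
    crit = bonferroni_critical_p()
    assert crit == pytest.approx(0.05 / 215)
    assert float(f"{crit:.2g}") == 0.00023


def test_null_calibration_of_corrected_tests():
    """Identical distributions: almost nothing survives alpha/m."""
    rng = np.random.default_rng(7)
    m = comparison_family_size()
    n_sig = 0
    reps = 200
    for _ in range(reps):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        if compare_distributions(a, b, m=m)["significant"]:
            n_sig += 1
    assert n_sig / reps <= 0.05


@given(st.integers(min_value=0, max_value=10_000))
def test_rank_sum_symmetry(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(5)
    y = rng.standard_normal(7)
    a = rank_sum_test(x, y)
    b = rank_sum_test(y, x)
    assert a["p"] == pytest.approx(b["p"], abs=1e-12)
    assert a["z"] == pytest.approx(-b["z"], abs=1e-9)
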