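"""Lagged design, lag selection, PLS, hierarchical switching, trajectories."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from reachdecode.decoder import (
    LAG_OFFSETS,
    DecoderConfig,
    TrainingError,
    build_lagged_design,
    compose_prediction,
    fit_hierarchical,
    integrate_trajectory,
    predict_hierarchical,
    score_targets_hit,
    select_best_lags,
    train_movement_classifier,
    train_pls,
)
from reachdecode.evaluation import evaluate_fold, make_splits, SplitPlan


# ---------------------------------------------------------------------------
# lagged design

def test_design_column_count_and_shift():
    rng = np.random.default_rng(0)
    values = rng.standard_normal((80, 1, 8)).astype(np.float32)
    design, valid = build_lagged_design(values)
    assert design.shape == (80, 1 * 8 * 31)
    assert valid.sum() == 80 - 20 - 10
    # delta pulse at window 40 appears at frame 50 in the -500 ms column
    values = np.zeros((80, 1, 8), dtype=np.float32)
    values[40, 0, 0] = 1.0
    design, valid = build_lagged_design(values)
    col = 0 * 31 + int(np.flatnonzero(LAG_OFFSETS == -10)[0])
    assert design[50, col] == 1.0
    assert design[40, col] == 0.0
    # constant feature series -> constant columns on valid rows
    values = np.full((80, 1, 8), 2.5, dtype=np.float32)
    design, valid = build_lagged_design(values)
    assert np.all(design[valid] == 2.5)


# ---------------------------------------------------------------------------
# lag selection

def _lagged_speed_world(lag_frames, negate=False, n=400):
    rng = np.random.default_rng(1)
    speed = np.abs(np.cumsum(rng.standard_normal(n)))
    values = np.zeros((n, 1, 8), dtype=np.float32)
    # feature(t) = speed(t - lag): for negative lag the feature leads
    # the kinematics, so the selected lag should equal lag_frames
    shifted = np.roll(speed, lag_frames)
    values[:, 0, 0] = -shifted if negate else shifted
    rng2 = np.random.default_rng(2)
    values[:, 0, 1:] = rng2.standard_normal((n, 7))
    frames = np.arange(25, n - 15)
    return values, speed, frames


def test_select_best_lags_recovers_shift():
    values, speed, frames = _lagged_speed_world(-4)  # -200 ms
    lags, r = select_best_lags(values, speed, frames)
    assert lags[0, 0] == -4
    assert r[0, 0] > 0.99


def test_select_best_lags_uses_absolute_correlation():
    values, speed, frames = _lagged_speed_world(0, negate=True)
    lags, r = select_best_lags(values, speed, frames)
    assert lags[0, 0] == 0
    assert r[0, 0] > 0.99


def test_white_noise_feature_has_low_best_correlation():
    rng = np.random.default_rng(3)
    n = 560
    values = rng.standard_normal((n, 1, 8)).astype(np.float32)
    speed = np.abs(np.sin(np.arange(n) / 15.0))
    frames = np.arange(25, n - 15)  # ~500 usable frames
    _, r = select_best_lags(values, speed, frames)
    assert r.max() < 0.2


# ---------------------------------------------------------------------------
# movement classifier

def _classifier_world(separable=True, n=560, seed=4):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, 2, 8)).astype(np.float32)
    labels = np.zeros(n, dtype=bool)
    labels[rng.random(n) < 0.5] = True
    speed = labels.astype(float) + 0.05 * rng.random(n)
    if separable:
        values[labels, 0, 0] += 4.0
    return values, speed, labels, np.arange(25, n - 15)


def test_classifier_separable_data_high_accuracy():
    values, speed, labels, frames = _classifier_world(True)
    clf = train_movement_classifier(values, speed, labels, frames)
    flat = values.reshape(values.shape[0], -1)
    X = (clf.design(flat, frames) - clf.x_mean) / clf.x_std
    acc = clf.model.score(X, labels[frames].astype(int))
    assert acc >= 0.95


def test_classifier_null_labels_near_chance_cv():
    values, speed, labels, frames = _classifier_world(False)
    clf = train_movement_classifier(values, speed, labels, frames)
    flat = values.reshape(values.shape[0], -1)
    X = (clf.design(flat, frames) - clf.x_mean) / clf.x_std
    # held-out halves: accuracy near 0.5 when labels are independent
    half = frames.size // 2
    from sklearn.linear_model import LogisticRegression

    m = LogisticRegression(solver="saga", C=clf.c_, l1_ratio=clf.l1_ratio_,
                           max_iter=200, tol=1e-2, random_state=0)
    m.fit(X[:half], labels[frames[:half]].astype(int))
    acc = m.score(X[half:], labels[frames[half:]].astype(int))
    assert 0.4 <= acc <= 0.6


def test_classifier_single_class_rejected():
    values, speed, labels, frames = _classifier_world(True)
    labels[:] = True
    with pytest.raises(TrainingError):
        train_movement_classifier(values, speed, labels, frames)


def test_classifier_duplicated_columns_stable():
    values, speed, labels, frames = _classifier_world(True, seed=6)
    clf1 = train_movement_classifier(values, speed, labels, frames)
    dup = np.concatenate([values, values], axis=1)  # duplicate all channels
    clf2 = train_movement_classifier(dup, speed, labels, frames)
    flat1 = values.reshape(values.shape[0], -1)
    flat2 = dup.reshape(dup.shape[0], -1)
    p1 = clf1.predict_proba(flat1, frames)
    p2 = clf2.predict_proba(flat2, frames)
    # regularization keeps the decision function essentially unchanged
    assert np.mean((p1 > 0.5) == (p2 > 0.5)) > 0.97


# ---------------------------------------------------------------------------
# PLS

def test_pls_exact_linear_recovery():
    # zero-mean orthonormal design columns: a 3-column linear map is
    # recovered exactly by three PLS components
    rng = np.random.default_rng(7)
    G = rng.standard_normal((300, 40))
    X, _ = np.linalg.qr(G - G.mean(axis=0))
    B = np.zeros((40, 4))
    B[[3, 11, 25], :] = rng.standard_normal((3, 4))
    Y = X @ B
    model = train_pls(X, Y, cv_folds=7, k_max=3, seed=0)
    pred = model.predict(X.astype(np.float32))
    for j in range(4):
        r = np.corrcoef(pred[:, j], Y[:, j])[0, 1]
        assert r > 0.999


def test_pls_nested_components_on_rank_one_targets():
    # whitened X and exactly rank-1 targets: the first component carries
    # everything, so the 2-component fit equals the 1-component fit
    rng = np.random.default_rng(8)
    G = rng.standard_normal((200, 30))
    X, _ = np.linalg.qr(G - G.mean(axis=0))
    w = rng.standard_normal(30)
    s = X @ w
    Y = np.outer(s, [1.0, -0.5, 2.0, 0.3])
    from reachdecode.decoder import _simpls

    Xc = (X - X.mean(0)).astype(np.float32)
    Yc = Y - Y.mean(0)
    R, Q = _simpls(Xc, Yc, 2)
    pred1 = Xc @ (R[:, :1] @ Q[:, :1].T).astype(np.float32)
    pred2 = Xc @ (R @ Q.T).astype(np.float32)
    assert np.abs(pred1 - pred2).max() < 1e-3 * np.abs(pred2).max()


def test_pls_permuted_targets_near_zero_cv():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((500, 60))
    Y = rng.standard_normal((500, 4))  # independent of X
    model = train_pls(X[:400], Y[:400], cv_folds=7, k_max=5, seed=0)
    pred = model.predict(X[400:].astype(np.float32))
    for j in range(4):
        assert abs(np.corrcoef(pred[:, j], Y[400:, j])[0, 1]) < 0.15


def test_simpls_matches_sklearn_pls():
    """Cross-check against the independent NIPALS implementation.

    PLS1 (single output) is algorithm-independent: SIMPLS and NIPALS
    give identical models; multivariate first components also agree.
    """
    rng = np.random.default_rng(10)
    X = rng.standard_normal((120, 15))
    y = X @ rng.standard_normal(15) + 0.1 * rng.standard_normal(120)
    from reachdecode.decoder import _simpls

    Xc = X - X.mean(0)
    yc = (y - y.mean()).reshape(-1, 1)
    for k in (1, 2, 4):
        R, Q = _simpls(Xc, yc, k)
        mine = (R @ Q.T).ravel()
        sk = PLSRegression(n_components=k, scale=False).fit(X, y)
        theirs = sk.coef_.ravel()
        np.testing.assert_allclose(mine, theirs, rtol=1e-6, atol=1e-10)
    # multivariate: first latent direction agrees
    Y4 = np.column_stack([y, -y + rng.standard_normal(120)])
    Yc = Y4 - Y4.mean(0)
    R, Q = _simpls(Xc, Yc, 1)
    sk = PLSRegression(n_components=1, scale=False).fit(X, Y4)
    np.testing.assert_allclose(
        np.abs(R[:, 0] / np.linalg.norm(R[:, 0])),
        np.abs(sk.x_weights_[:, 0]),
        atol=1e-6,
    )


def test_pls_too_few_frames_rejected():
    with pytest.raises(TrainingError):
        train_pls(np.zeros((4, 3)), np.zeros((4, 4)), cv_folds=7)


# ---------------------------------------------------------------------------
# hierarchical prediction contracts

def test_compose_prediction_renormalization():
    state = np.array([True, True, True])
    move_out = np.array(
        [[2.0, 3.0, 0.0, 0.0],   # raw velocity renormalized to speed 2
         [1.0, 0.0, 0.0, 0.0],   # zero raw velocity stays zero
         [-1.0, 1.0, 1.0, 1.0]]  # negative speed clamps to zero
    )
    rest_out = np.zeros((3, 4))
    pred = compose_prediction(state, move_out, rest_out, np.arange(3))
    np.testing.assert_allclose(pred.velocity[0], [2.0, 0.0, 0.0])
    np.testing.assert_allclose(pred.velocity[1], [0.0, 0.0, 0.0])
    assert pred.speed[2] == 0.0
    np.testing.assert_allclose(pred.velocity[2], 0.0)
    # ||v|| == speed wherever the raw vector was renormalizable
    ok = (pred.speed > 0) & (np.linalg.norm(pred.velocity, axis=1) > 0)
    np.testing.assert_allclose(
        np.linalg.norm(pred.velocity[ok], axis=1), pred.speed[ok]
    )


def test_rest_everywhere_uses_rest_model():
    state = np.zeros(4, dtype=bool)
    move_out = np.full((4, 4), 9.0)
    rest_out = np.tile([0.5, 0.3, 0.0, 0.0], (4, 1))
    pred = compose_prediction(state, move_out, rest_out, np.arange(4))
    np.testing.assert_allclose(pred.speed, 0.5)
    np.testing.assert_allclose(pred.velocity[:, 0], 0.5)


# ---------------------------------------------------------------------------
# trajectories

def test_integrate_trajectory_arithmetic():
    v = np.tile([0.1, 0.1, 0.1], (10, 1))
    traj = integrate_trajectory(v, step_s=0.05)
    np.testing.assert_allclose(traj[-1], [0.05, 0.05, 0.05])


def test_targets_hit_identity_and_chance():
    rng = np.random.default_rng(11)
    disp = rng.standard_normal((40, 3))
    assert score_targets_hit(disp, disp) == 100.0
    # random octants: chance level 12.5% (binomial n=4000)
    a = rng.standard_normal((4000, 3))
    b = rng.standard_normal((4000, 3))
    assert score_targets_hit(a, b) == pytest.approx(12.5, abs=1.75)


# ---------------------------------------------------------------------------
# end-to-end on the shared synthetic world

def test_hierarchical_decoder_recovers_strong_encoding(small_world):
    feats, frames = small_world["features"], small_world["frames"]
    design, valid = small_world["design"], small_world["valid"]
    trial_ids = np.unique(frames.trial_id[frames.trial_id >= 0])
    (train, test), = make_splits(trial_ids, SplitPlan(n_repeats=1, seed=5))
    dec = fit_hierarchical(feats, frames, train, design, valid, DecoderConfig(seed=5))
    test_rows = np.flatnonzero(np.isin(frames.trial_id, test) & valid)
    pred = predict_hierarchical(dec, feats, design, test_rows)
    metrics = evaluate_fold(frames, pred, test)
    assert metrics["speed_r"] >= 0.7
    for k in ("vx_r", "vy_r", "vz_r"):
        assert metrics[k] >= 0.5
    ok = pred.speed > 0
    np.testing.assert_allclose(
        np.linalg.norm(pred.velocity[ok], axis=1), pred.speed[ok], rtol=1e-5
    )


def test_decoder_determinism(small_world):
    feats, frames = small_world["features"], small_world["frames"]
    design, valid = small_world["design"], small_world["valid"]
    trial_ids = np.unique(frames.trial_id[frames.trial_id >= 0])
    (train, _), = make_splits(trial_ids, SplitPlan(n_repeats=1, seed=5))
    cfg = DecoderConfig(seed=9)
    d1 = fit_hierarchical(feats, frames, train, design, valid, cfg)
    d2 = fit_hierarchical(feats, frames, train, design, valid, cfg)
    np.testing.assert_array_equal(d1.movement_model.coef, d2.movement_model.coef)
    np.testing.assert_array_equal(d1.rest_model.coef, d2.rest_model.coef)
    np.testing.assert_array_equal(d1.classifier.model.coef_, d2.classifier.model.coef_)
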