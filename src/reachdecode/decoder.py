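"""Hierarchical movement/rest-switched PLS kinematic decoder.

An elastic-net logistic classifier labels each 50 ms frame movement or
rest from the eight z-scored features per channel, each taken at its
best speed-correlated lag.  Two multivariate PLS regressions — one
trained on movement frames, one on rest frames — map the full lagged
feature design (channels x 8 features x 31 lags, -1000..+500 ms) to
four outputs (speed, Vx, Vy, Vz).  The classifier switches between the
two PLS outputs frame by frame, and the predicted velocity vector is
renormalized to the predicted speed so that ||v|| == speed exactly.

PLS is fit with the SIMPLS algorithm (implemented here rather than via
scikit-learn so that one high-order fit yields the whole nested family
of component counts, which makes sevenfold component-count
cross-validation affordable at this design size; equivalence with
scikit-learn's PLSRegression is enforced by the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .features import FeatureTensor
from .kinematics import KinematicFrames
from .task import ConfigurationError

__all__ = [
    "LAG_OFFSETS",
    "LAG_MS",
    "DecoderConfig",
    "PlsModel",
    "MovementClassifier",
    "HierarchicalDecoder",
    "PredictionResult",
    "TrainingError",
    "build_lagged_design",
    "select_best_lags",
    "train_movement_classifier",
    "train_pls",
    "fit_hierarchical",
    "predict_hierarchical",
    "integrate_trajectory",
    "score_targets_hit",
]

#: Lag grid in frames (50 ms steps): -1000 .. +500 ms; negative lags mean
#: the neural activity leads the kinematics.
LAG_OFFSETS = np.arange(-20, 11)
LAG_MS = LAG_OFFSETS * 50.0
N_LAGS = LAG_OFFSETS.size

OUTPUT_NAMES = ["speed", "vx", "vy", "vz"]


class TrainingError(RuntimeError):
    """Training preconditions violated (single class, too few frames...)."""


@dataclass(frozen=True)
class DecoderConfig:
    """Training hyperparameters.

    ``k_max`` bounds the PLS component search (all counts 1..k_max are
    scored by CV).  ``clf_cv_max_frames`` and ``rest_max_frames`` cap
    the frames used for classifier hyperparameter search and for the
    rest-model fit; they are compute guards for desk-scale runs (seeded
    subsampling; None disables).
    """

    cv_folds: int = 7
    k_max: int = 12
    clf_cs: tuple[float, ...] = (0.05, 0.5, 5.0)
    clf_l1_ratios: tuple[float, ...] = (0.25, 0.75)
    clf_max_iter: int = 200
    clf_cv_max_frames: int | None = 3000
    rest_max_frames: int | None = 5000
    prob_threshold: float = 0.5
    seed: int = 0


@dataclass
class PlsModel:
    """Multivariate SIMPLS regression with a shared latent space."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    x_rotations: np.ndarray   # (p, k) rows-of-X -> scores
    y_loadings: np.ndarray    # (m, k)
    coef: np.ndarray          # (p, m) regression matrix on centered data
    n_components: int
    cv_mse: np.ndarray | None = None  # (k_max,) CV error per component count

    def predict(self, X: np.ndarray, coef_override: np.ndarray | None = None) -> np.ndarray:
        coef = self.coef if coef_override is None else coef_override
        return (X - self.x_mean) @ coef + self.y_mean


@dataclass
class MovementClassifier:
    """Elastic-net logistic movement/rest classifier at per-feature lags."""

    best_lag_frames: np.ndarray  # (C, 8) chosen lag per channel x feature
    best_lag_r: np.ndarray       # (C, 8) |r| at the chosen lag
    x_mean: np.ndarray
    x_std: np.ndarray
    model: LogisticRegression
    c_: float
    l1_ratio_: float

    def design(self, values2d: np.ndarray, frames: np.ndarray) -> np.ndarray:
        """Gather each channel x feature at its chosen lag."""
        C, F = self.best_lag_frames.shape
        X = np.empty((frames.size, C * F), dtype=np.float32)
        flat = values2d  # (W, C*F)
        lags = self.best_lag_frames.ravel()
        for j, lag in enumerate(lags):
            X[:, j] = flat[frames + lag, j]
        return X

    def predict_proba(self, values2d: np.ndarray, frames: np.ndarray) -> np.ndarray:
        X = (self.design(values2d, frames) - self.x_mean) / self.x_std
        return self.model.predict_proba(X)[:, 1]


@dataclass
class HierarchicalDecoder:
    classifier: MovementClassifier
    movement_model: PlsModel
    rest_model: PlsModel
    layout: tuple[int, int, int]          # (channels, features, lags)
    config: DecoderConfig
    prob_threshold: float = 0.5


@dataclass
class PredictionResult:
    frame_idx: np.ndarray     # session frame indices predicted
    state: np.ndarray         # (F,) bool, True = movement
    speed: np.ndarray         # (F,) >= 0
    velocity: np.ndarray      # (F, 3), ||v|| == speed (or 0)


# ---------------------------------------------------------------------------
# lagged design

def build_lagged_design(
    values: np.ndarray, lag_offsets: np.ndarray = LAG_OFFSETS
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix over all session frames.

    Column (c, f, l) of row t holds feature (c, f) at frame t +
    lag_offsets[l].  Rows lacking full lag coverage at the session edges
    are zero-filled and flagged invalid in the returned mask; callers
    must drop them rather than train on fabricated zeros.

    Returns (design (W, C*F*L) float32, valid (W,) bool).
    """
    W, C, F = values.shape
    L = lag_offsets.size
    flat = np.ascontiguousarray(values.reshape(W, C * F), dtype=np.float32)
    design = np.zeros((W, C * F, L), dtype=np.float32)
    for li, lag in enumerate(lag_offsets):
        if lag >= 0:
            design[: W - lag, :, li] = flat[lag:]
        else:
            design[-lag:, :, li] = flat[: W + lag]
    lo = max(0, -int(lag_offsets.min()))
    hi = W - max(0, int(lag_offsets.max()))
    if hi <= lo:
        raise ConfigurationError("no frame has full lag coverage")
    valid = np.zeros(W, dtype=bool)
    valid[lo:hi] = True
    return design.reshape(W, C * F * L), valid


def select_best_lags(
    values: np.ndarray,
    speed: np.ndarray,
    frames: np.ndarray,
    lag_offsets: np.ndarray = LAG_OFFSETS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per channel x feature, the lag maximizing |Pearson r| with speed.

    Ties are broken toward the smallest |lag|, then the negative
    (neural-leads) sign.  Zero-variance features get lag 0 and r = 0,
    with a warning.

    Returns (lags (C, F) in frames, |r| (C, F)).
    """
    W, C, F = values.shape
    flat = values.reshape(W, C * F)
    s = speed[frames]
    s_c = s - s.mean()
    s_ss = float(s_c @ s_c)
    if s_ss <= 0:
        raise TrainingError("speed has no variance on the training frames")

    order = sorted(range(lag_offsets.size), key=lambda i: (abs(lag_offsets[i]), lag_offsets[i] > 0))
    best_r = np.full(C * F, -1.0)
    best_lag = np.zeros(C * F, dtype=int)
    for li in order:
        lag = int(lag_offsets[li])
        X = flat[frames + lag].astype(np.float64)
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc * Xc).sum(axis=0) * s_ss)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(Xc.T @ s_c) / denom
        r = np.nan_to_num(r, nan=0.0)
        better = r > best_r + 1e-15
        best_r[better] = r[better]
        best_lag[better] = lag
    best_r = np.maximum(best_r, 0.0)
    zero_var = best_r == 0.0  # zero-variance features: |r| = 0 at every lag
    if np.any(zero_var):
        warnings.warn("zero-variance feature(s) excluded from lag selection; lag set to 0")
        best_lag[zero_var] = 0
    return best_lag.reshape(C, F), best_r.reshape(C, F)


# ---------------------------------------------------------------------------
# movement classifier

def train_movement_classifier(
    values: np.ndarray,
    speed: np.ndarray,
    labels: np.ndarray,
    frames: np.ndarray,
    cfg: DecoderConfig = DecoderConfig(),
    lag_offsets: np.ndarray = LAG_OFFSETS,
) -> MovementClassifier:
    """Elastic-net logistic regression on best-lag features.

    The (C, l1_ratio) grid is scored by sevenfold cross-validation on
    the training frames (optionally subsampled for speed), then the
    winning pair is refit on all training frames.
    """
    y = labels[frames].astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingError("both movement and rest frames are required")
    lags, lag_r = select_best_lags(values, speed, frames, lag_offsets)

    W, C, F = values.shape
    flat = values.reshape(W, C * F)
    stub = MovementClassifier(
        best_lag_frames=lags, best_lag_r=lag_r,
        x_mean=np.zeros(C * F, np.float32), x_std=np.ones(C * F, np.float32),
        model=None, c_=np.nan, l1_ratio_=np.nan,
    )
    X = stub.design(flat, frames).astype(np.float64)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    rng = np.random.default_rng(cfg.seed)
    cv_idx = np.arange(frames.size)
    if cfg.clf_cv_max_frames is not None and cv_idx.size > cfg.clf_cv_max_frames:
        cv_idx = np.sort(rng.choice(cv_idx, cfg.clf_cv_max_frames, replace=False))
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)

    def make(c, l1):
        return LogisticRegression(
            solver="saga", C=c, l1_ratio=l1,
            max_iter=cfg.clf_max_iter, tol=1e-2, random_state=cfg.seed,
        )

    best = (None, -np.inf)
    for c in cfg.clf_cs:
        for l1 in cfg.clf_l1_ratios:
            accs = []
            for tr, te in kf.split(cv_idx):
                itr, ite = cv_idx[tr], cv_idx[te]
                if len(np.unique(y[itr])) < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = make(c, l1).fit(Xs[itr], y[itr])
                accs.append(m.score(Xs[ite], y[ite]))
            score = float(np.mean(accs)) if accs else -np.inf
            if score > best[1]:
                best = ((c, l1), score)
    if best[0] is None:
        raise TrainingError("classifier cross-validation failed on every fold")
    c, l1 = best[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = make(c, l1).fit(Xs, y)
    return MovementClassifier(
        best_lag_frames=lags, best_lag_r=lag_r,
        x_mean=mu.astype(np.float32), x_std=sd.astype(np.float32),
        model=final, c_=c, l1_ratio_=l1,
    )


# ---------------------------------------------------------------------------
# SIMPLS

def _simpls(X: np.ndarray, Y: np.ndarray, k: int):
    """SIMPLS on centered X (n, p) and Y (n, m).

    Returns rotations R (p, k_eff), y-loadings Q (m, k_eff); the
    coefficient matrix for a-component truncation is R[:, :a] @ Q[:, :a].T.
    """
    n, p = X.shape
    m = Y.shape[1]
    k = min(k, p, n - 1)
    S = (X.T @ Y.astype(X.dtype)).astype(np.float64)
    R = np.zeros((p, k))
    Q = np.zeros((m, k))
    V = np.zeros((p, k))
    for a in range(k):
        # dominant right singular vector of S via the small m x m problem
        evals, evecs = np.linalg.eigh(S.T @ S)
        q = evecs[:, -1]
        r = S @ q
        t = X @ r.astype(X.dtype)
        t = t.astype(np.float64)
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            R, Q, V = R[:, :a], Q[:, :a], V[:, :a]
            break
        t /= normt
        r /= normt
        p_load = (X.T @ t.astype(X.dtype)).astype(np.float64)
        q_load = Y.T @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            R, Q, V = R[:, :a], Q[:, :a], V[:, :a]
            break
        v /= nv
        S -= np.outer(v, v @ S)
        R[:, a], Q[:, a], V[:, a] = r, q_load, v
    return R, Q


def train_pls(
    X: np.ndarray,
    Y: np.ndarray,
    cv_folds: int = 7,
    k_max: int = 15,
    seed: int = 0,
) -> PlsModel:
    """Multivariate PLS with component count chosen by K-fold CV.

    One SIMPLS fit at ``k_max`` per fold scores every nested component
    count at once (SIMPLS components are greedy, so the a-component
    model is a truncation of the k_max-component one); the count with
    the lowest mean validation MSE wins and is refit on all rows.
    """
    X = np.asarray(X, dtype=np.float32)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n = X.shape[0]
    if n < cv_folds:
        raise TrainingError(f"need at least {cv_folds} frames, got {n}")
    k_max = int(min(k_max, X.shape[1], n - max(2, n // cv_folds) - 1))
    k_max = max(k_max, 1)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sse = np.zeros(k_max)
    counts = np.zeros(k_max)
    for tr, te in kf.split(X):
        xm = X[tr].mean(axis=0)
        ym = Y[tr].mean(axis=0)
        R, Q = _simpls(X[tr] - xm, Y[tr] - ym, k_max)
        if R.shape[1] == 0:
            continue
        T_val = (X[te] - xm) @ R.astype(np.float32)  # (n_te, k_eff)
        resid = Y[te] - ym  # running residual vs truncated predictions
        for a in range(R.shape[1]):
            resid = resid - np.outer(T_val[:, a].astype(np.float64), Q[:, a])
            sse[a] += float((resid**2).sum())
            counts[a] += te.size
        # component counts beyond k_eff keep the k_eff error
        for a in range(R.shape[1], k_max):
            sse[a] += float((resid**2).sum())
            counts[a] += te.size
    if counts.min() == 0:
        raise TrainingError("PLS cross-validation produced no components")
    cv_mse = sse / counts
    k_best = int(np.argmin(cv_mse)) + 1

    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    R, Q = _simpls(X - xm, Y - ym, k_best)
    coef = R @ Q.T
    return PlsModel(
        x_mean=xm, y_mean=ym, x_rotations=R, y_loadings=Q,
        coef=coef.astype(np.float64), n_components=R.shape[1], cv_mse=cv_mse,
    )


# ---------------------------------------------------------------------------
# hierarchical fit / predict

def fit_hierarchical(
    features: FeatureTensor,
    frames: KinematicFrames,
    train_trials: np.ndarray,
    design: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    cfg: DecoderConfig = DecoderConfig(),
    classifier: MovementClassifier | None = None,
) -> HierarchicalDecoder:
    """Train classifier + movement/rest PLS models on whole trials.

    Passing ``classifier`` skips classifier training and reuses the
    given one (surrogate models are always gated by the actual
    classifier, so retraining it on surrogate labels would be wasted).
    """
    values = features.values
    W, C, F = values.shape
    if frames.n_frames != W:
        raise ConfigurationError("feature and kinematic frame grids differ")
    if design is None:
        design, valid = build_lagged_design(values)

    in_train = np.isin(frames.trial_id, np.asarray(train_trials))
    rows = np.flatnonzero(in_train & valid)
    if rows.size == 0:
        raise TrainingError("no training frames with full lag coverage")

    clf = classifier
    if clf is None:
        clf = train_movement_classifier(
            values, frames.speed, frames.movement, rows, cfg
        )

    Y = np.column_stack([frames.speed, frames.velocity])
    move_rows = rows[frames.movement[rows]]
    rest_rows = rows[~frames.movement[rows]]
    if move_rows.size < cfg.cv_folds or rest_rows.size < cfg.cv_folds:
        raise TrainingError("too few movement or rest frames to train PLS models")
    if cfg.rest_max_frames is not None and rest_rows.size > cfg.rest_max_frames:
        rng = np.random.default_rng(cfg.seed + 1)
        rest_rows = np.sort(rng.choice(rest_rows, cfg.rest_max_frames, replace=False))

    movement_model = train_pls(
        design[move_rows], Y[move_rows], cfg.cv_folds, cfg.k_max, cfg.seed
    )
    rest_model = train_pls(
        design[rest_rows], Y[rest_rows], cfg.cv_folds, cfg.k_max, cfg.seed
    )
    return HierarchicalDecoder(
        classifier=clf,
        movement_model=movement_model,
        rest_model=rest_model,
        layout=(C, F, N_LAGS),
        config=cfg,
        prob_threshold=cfg.prob_threshold,
    )


def compose_prediction(
    state: np.ndarray,
    move_out: np.ndarray,
    rest_out: np.ndarray,
    frame_idx: np.ndarray,
    speed_for_modulation: np.ndarray | None = None,
) -> PredictionResult:
    """Switch between model outputs and renormalize velocity to speed.

    Negative predicted speed clamps to zero; a zero raw-velocity vector
    stays zero regardless of speed.  ``speed_for_modulation`` lets
    surrogate evaluations scale velocity by the actual model's speed.
    """
    out = np.where(state[:, None], move_out, rest_out)
    speed = np.clip(out[:, 0], 0.0, None)
    v_raw = out[:, 1:4]
    norms = np.linalg.norm(v_raw, axis=1)
    mod = speed if speed_for_modulation is None else np.clip(speed_for_modulation, 0.0, None)
    scale = np.zeros_like(norms)
    ok = norms > 0
    scale[ok] = mod[ok] / norms[ok]
    return PredictionResult(
        frame_idx=frame_idx,
        state=state,
        speed=speed,
        velocity=v_raw * scale[:, None],
    )


def predict_hierarchical(
    decoder: HierarchicalDecoder,
    features: FeatureTensor,
    design: np.ndarray,
    frame_idx: np.ndarray,
    movement_coef: np.ndarray | None = None,
    rest_coef: np.ndarray | None = None,
    speed_for_modulation: np.ndarray | None = None,
) -> PredictionResult:
    """Frame-by-frame hierarchical prediction on the given frames.

    ``movement_coef`` / ``rest_coef`` substitute PLS weight matrices
    (used by the feature-shuffle surrogate); the classifier gating is
    always the decoder's own.
    """
    if decoder.movement_model is None:
        raise TrainingError("decoder is not trained")
    W, C, F = features.values.shape
    flat = features.values.reshape(W, C * F)
    proba = decoder.classifier.predict_proba(flat, frame_idx)
    state = proba > decoder.prob_threshold
    move_out = decoder.movement_model.predict(design[frame_idx], movement_coef)
    rest_out = decoder.rest_model.predict(design[frame_idx], rest_coef)
    return compose_prediction(state, move_out, rest_out, frame_idx, speed_for_modulation)


# ---------------------------------------------------------------------------
# trajectories

def integrate_trajectory(velocity: np.ndarray, step_s: float = 0.05) -> np.ndarray:
    """Cumulative-sum trajectory (relative to the trial start position)."""
    return np.cumsum(np.asarray(velocity, float), axis=0) * step_s


def score_targets_hit(
    actual_disp: np.ndarray, predicted_disp: np.ndarray
) -> float:
    """Percentage of trials whose predicted endpoint falls in the actual
    endpoint's octant (sign agreement on all three axes; chance 12.5%)."""
    actual_disp = np.atleast_2d(actual_disp)
    predicted_disp = np.atleast_2d(predicted_disp)
    if actual_disp.shape != predicted_disp.shape:
        raise ValueError("trajectory endpoint arrays must match")
    hits = np.all(np.sign(actual_disp) == np.sign(predicted_disp), axis=1)
    return 100.0 * float(hits.mean())
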