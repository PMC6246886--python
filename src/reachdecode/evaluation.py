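"""Resampled evaluation, surrogate nulls, cross-arm prediction, statistics.

Decoders are trained on random 7/8-of-trials training sets and scored on
the held-out trials by Pearson correlation between predicted and actual
speed/Vx/Vy/Vz over concatenated test frames, plus the percentage of
trials whose integrated trajectory ends in the correct octant.

Two null constructions calibrate chance:

* temporal surrogate — training-trial order is permuted and each trial's
  kinematics circularly shifted on the frame grid (autocorrelation
  preserved, neural alignment destroyed); a second decoder is trained on
  these surrogate kinematics and tested on the untouched test set.
* feature-shuffle surrogate — the trained PLS weight rows are permuted
  across (channel, feature) blocks, lag structure intact.

In both cases the actual classifier gates movement/rest and the actual
model's predicted speed modulates the surrogate velocity vector, so any
actual-vs-surrogate difference reflects kinematic prediction, not
movement/rest classification.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .decoder import (
    DecoderConfig,
    HierarchicalDecoder,
    PredictionResult,
    build_lagged_design,
    fit_hierarchical,
    predict_hierarchical,
    score_targets_hit,
)
from .features import FeatureTensor
from .kinematics import KinematicFrames, label_movement
from .task import ConfigurationError

__all__ = [
    "SplitPlan",
    "EvaluationResult",
    "make_splits",
    "temporal_surrogate",
    "shuffle_pls_rows",
    "evaluate_fold",
    "evaluate_session",
    "cross_predict",
    "rank_sum_test",
    "compare_distributions",
    "comparison_family_size",
    "bonferroni_critical_p",
]

METRICS = ["speed_r", "vx_r", "vy_r", "vz_r", "targets_hit_pct"]


@dataclass(frozen=True)
class SplitPlan:
    """Whole-trial resampling plan: 7/8 train, 1/8 test, repeated."""

    n_repeats: int = 100
    train_fraction: float = 7.0 / 8.0
    seed: int = 0


def make_splits(trial_ids: np.ndarray, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded independent train/test splits by whole trial."""
    trial_ids = np.asarray(trial_ids)
    n = trial_ids.size
    if n < 8:
        raise ConfigurationError("need at least 8 trials to split")
    n_train = int(round(plan.train_fraction * n))
    if not 0 < n_train < n:
        raise ConfigurationError("train fraction leaves an empty train or test set")
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.n_repeats):
        perm = rng.permutation(trial_ids)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


# ---------------------------------------------------------------------------
# surrogates

def temporal_surrogate(
    frames: KinematicFrames,
    train_trials: np.ndarray,
    seed: int,
    threshold_frac: float = 0.1,
    permutation: np.ndarray | None = None,
    shifts: dict[int, int] | None = None,
) -> KinematicFrames:
    """Permute training-trial kinematics and circularly shift each trial.

    Neural features are untouched; only the kinematic series of the
    training trials are reassigned (trial order permuted) and wrapped by
    a random frame offset, which preserves each trial's kinematic value
    multiset (for equal-length trials) and autocorrelation structure.
    Movement labels are recomputed from the surrogate speed.

    ``permutation`` and ``shifts`` override the random draws (identity
    permutation with zero shifts reproduces the original exactly).
    """
    rng = np.random.default_rng(seed)
    train_trials = np.asarray(train_trials)
    if train_trials.size < 2:
        raise ConfigurationError("temporal surrogate needs >= 2 training trials")
    out = KinematicFrames(
        times=frames.times,
        position=frames.position.copy(),
        velocity=frames.velocity.copy(),
        speed=frames.speed.copy(),
        trial_id=frames.trial_id,
        movement=frames.movement.copy(),
    )
    perm = rng.permutation(train_trials) if permutation is None else np.asarray(permutation)
    for dst, src in zip(train_trials, perm):
        dst_idx = frames.trial_frames(int(dst))
        src_idx = frames.trial_frames(int(src))
        if dst_idx.size == 0 or src_idx.size == 0:
            continue
        shift = int(rng.integers(0, src_idx.size)) if shifts is None else int(shifts.get(int(dst), 0))
        take = src_idx[(np.arange(dst_idx.size) + shift) % src_idx.size]
        out.position[dst_idx] = frames.position[take]
        out.velocity[dst_idx] = frames.velocity[take]
        out.speed[dst_idx] = frames.speed[take]
        out.movement[dst_idx] = label_movement(out.speed[dst_idx], threshold_frac)
    return out


def shuffle_pls_rows(
    coef: np.ndarray, layout: tuple[int, int, int], perm: np.ndarray
) -> np.ndarray:
    """Permute PLS weight rows across (channel, feature) blocks.

    ``perm`` reassigns the C*F blocks; each block's 31 lag rows move
    together, so the lag structure within a block is intact.
    """
    C, F, L = layout
    blocks = coef.reshape(C * F, L, coef.shape[1])
    return blocks[perm].reshape(coef.shape)


# ---------------------------------------------------------------------------
# metrics

def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 when either series has no variance (flagged case)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0 or a.size < 2:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_fold(
    frames: KinematicFrames,
    pred: PredictionResult,
    test_trials: np.ndarray,
    step_s: float = 0.05,
) -> dict:
    """Pearson r per kinematic over concatenated test frames + octant hits."""
    rows = pred.frame_idx
    out = {
        "speed_r": _safe_pearson(frames.speed[rows], pred.speed),
        "vx_r": _safe_pearson(frames.velocity[rows, 0], pred.velocity[:, 0]),
        "vy_r": _safe_pearson(frames.velocity[rows, 1], pred.velocity[:, 1]),
        "vz_r": _safe_pearson(frames.velocity[rows, 2], pred.velocity[:, 2]),
    }
    # actual and predicted trajectories are integrated identically from
    # their velocity series, so discretization cancels in the comparison
    actual_disp, pred_disp = [], []
    pos_in_rows = {int(r): i for i, r in enumerate(rows)}
    for t in np.asarray(test_trials):
        tidx = [pos_in_rows[int(r)] for r in frames.trial_frames(int(t)) if int(r) in pos_in_rows]
        if len(tidx) < 2:
            continue
        tidx = np.asarray(tidx)
        actual_disp.append(frames.velocity[rows[tidx]].sum(axis=0) * step_s)
        pred_disp.append(pred.velocity[tidx].sum(axis=0) * step_s)
    if actual_disp:
        out["targets_hit_pct"] = score_targets_hit(
            np.array(actual_disp), np.array(pred_disp)
        )
    else:
        out["targets_hit_pct"] = np.nan
    return out


# ---------------------------------------------------------------------------
# session-level evaluation

@dataclass
class EvaluationResult:
    """Accuracy table plus the per-repeat decoders and splits."""

    table: pd.DataFrame
    splits: list[tuple[np.ndarray, np.ndarray]]
    decoders: list[HierarchicalDecoder] | None = None

    def condition(self, name: str) -> pd.DataFrame:
        return self.table[self.table["condition"] == name]


def _spawn_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0] % (2**31))


def evaluate_session(
    features: FeatureTensor,
    frames: KinematicFrames,
    plan: SplitPlan,
    cfg: DecoderConfig = DecoderConfig(),
    n_weight_shuffles: int = 100,
    n_temporal: int = 1,
    keep_decoders: bool = True,
    design: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> EvaluationResult:
    """Train/test over all repeats with both surrogate constructions.

    Produces one 'actual' row per repeat, ``n_temporal`` temporal-
    surrogate rows and ``n_weight_shuffles`` feature-shuffle rows per
    repeat.
    """
    if design is None:
        design, valid = build_lagged_design(features.values)
    trial_ids = np.unique(frames.trial_id[frames.trial_id >= 0])
    splits = make_splits(trial_ids, plan)
    step_s = features.step_s

    C, F = features.values.shape[1], features.values.shape[2]
    n_blocks = C * F
    rows_out: list[dict] = []
    decoders: list[HierarchicalDecoder] = []
    for rep, (train, test) in enumerate(splits):
        rep_cfg = replace(cfg, seed=_spawn_seed(plan.seed, rep))
        dec = fit_hierarchical(features, frames, train, design, valid, rep_cfg)
        if keep_decoders:
            decoders.append(dec)
        test_rows = np.flatnonzero(np.isin(frames.trial_id, test) & valid)
        pred = predict_hierarchical(dec, features, design, test_rows)
        rows_out.append(
            {"repeat": rep, "condition": "actual", **evaluate_fold(frames, pred, test, step_s)}
        )

        for k in range(n_temporal):
            sur_frames = temporal_surrogate(
                frames, train, _spawn_seed(plan.seed, rep, 1, k)
            )
            sur_dec = fit_hierarchical(
                features, sur_frames, train, design, valid, rep_cfg,
                classifier=dec.classifier,
            )
            hybrid = HierarchicalDecoder(
                classifier=dec.classifier,
                movement_model=sur_dec.movement_model,
                rest_model=sur_dec.rest_model,
                layout=dec.layout, config=dec.config,
                prob_threshold=dec.prob_threshold,
            )
            sur_pred = predict_hierarchical(
                hybrid, features, design, test_rows,
                speed_for_modulation=pred.speed,
            )
            rows_out.append(
                {"repeat": rep, "condition": "temporal",
                 **evaluate_fold(frames, sur_pred, test, step_s)}
            )

        rng = np.random.default_rng(_spawn_seed(plan.seed, rep, 2))
        for k in range(n_weight_shuffles):
            perm = rng.permutation(n_blocks)
            shuf_pred = predict_hierarchical(
                dec, features, design, test_rows,
                movement_coef=shuffle_pls_rows(dec.movement_model.coef, dec.layout, perm),
                rest_coef=shuffle_pls_rows(dec.rest_model.coef, dec.layout, perm),
                speed_for_modulation=pred.speed,
            )
            rows_out.append(
                {"repeat": rep, "condition": "shuffle",
                 **evaluate_fold(frames, shuf_pred, test, step_s)}
            )

    return EvaluationResult(
        table=pd.DataFrame(rows_out), splits=splits,
        decoders=decoders if keep_decoders else None,
    )


def cross_predict(
    decoders: list[HierarchicalDecoder],
    features_b: FeatureTensor,
    frames_b: KinematicFrames,
    splits_b: list[tuple[np.ndarray, np.ndarray]],
    design_b: np.ndarray | None = None,
    valid_b: np.ndarray | None = None,
    use_full_test: bool = False,
) -> pd.DataFrame:
    """Apply arm-A decoders unchanged to arm-B test folds.

    Training-time lags travel with the decoder (they are baked into its
    design layout and classifier lag table); the arm-B data must share
    the channel/feature layout.  ``use_full_test`` scores every arm-B
    trial instead of only the fold's held-out trials (all arm-B trials
    are unseen by an arm-A decoder; the larger test set tightens the
    chance-level estimate).
    """
    if design_b is None:
        design_b, valid_b = build_lagged_design(features_b.values)
    C, F = features_b.values.shape[1], features_b.values.shape[2]
    all_trials = np.unique(frames_b.trial_id[frames_b.trial_id >= 0])
    rows_out = []
    for rep, (dec, (_, test)) in enumerate(zip(decoders, splits_b)):
        if use_full_test:
            test = all_trials
        if dec.layout[:2] != (C, F):
            raise ConfigurationError("cross-prediction requires identical layouts")
        test_rows = np.flatnonzero(np.isin(frames_b.trial_id, test) & valid_b)
        pred = predict_hierarchical(dec, features_b, design_b, test_rows)
        rows_out.append(
            {"repeat": rep, "condition": "cross",
             **evaluate_fold(frames_b, pred, test, features_b.step_s)}
        )
    return pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# statistics

def rank_sum_test(x, y, exact_max_n: int = 10) -> dict:
    """Two-sided Wilcoxon rank-sum test.

    W is the rank sum of the first sample (average ranks on ties).  The
    p-value comes from exhaustive enumeration when both groups have at
    most ``exact_max_n`` observations, otherwise from the normal
    approximation with tie correction and continuity correction.  The
    z-statistic is reported in both regimes.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ConfigurationError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return {"W": w, "z": 0.0, "p": 1.0, "method": "degenerate"}
    cc = 0.5 * np.sign(w - mean_w)
    z = (w - mean_w - cc) / math.sqrt(var_w)

    if n1 <= exact_max_n and n2 <= exact_max_n:
        count_le = count_ge = total = 0
        for comb in itertools.combinations(range(n), n1):
            ws = ranks[list(comb)].sum()
            total += 1
            if ws <= w + 1e-9:
                count_le += 1
            if ws >= w - 1e-9:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return {"W": w, "z": float(z), "p": float(p), "method": "exact"}
    p = 2.0 * norm.sf(abs(z))
    return {"W": w, "z": float(z), "p": float(min(p, 1.0)), "method": "normal"}


def comparison_family_size(
    n_params: int = 5,
    n_hands: int = 2,
    n_conditions: int = 2,
    n_surrogates: int = 2,
    n_patients: int = 4,
) -> int:
    """Number of planned comparisons in the full analysis.

    Group-level actual-vs-surrogate tests for every parameter, hand,
    true/cross condition and surrogate method; between-hand parameter
    comparisons; true-vs-cross comparisons per hand; and the same
    actual-vs-surrogate family repeated per patient.  The study's plan
    (5 parameters, 2 hands, 2 conditions, 2 surrogates, 4 patients)
    yields 215.
    """
    group = n_params * n_hands * n_conditions * n_surrogates
    between_hands = n_params
    true_vs_cross = n_params * n_hands
    per_patient = n_patients * n_params * n_hands * n_conditions * n_surrogates
    return group + between_hands + true_vs_cross + per_patient


def bonferroni_critical_p(alpha: float = 0.05, m: int | None = None, **kw) -> float:
    if m is None:
        m = comparison_family_size(**kw)
    return alpha / m


def compare_distributions(
    actual, surrogate, m: int = 1, alpha: float = 0.05
) -> dict:
    """Rank-sum comparison with Bonferroni-corrected significance flag."""
    actual = np.asarray(actual, float)
    surrogate = np.asarray(surrogate, float)
    if actual.size < 3 or surrogate.size < 3:
        raise ConfigurationError("need >= 3 samples per group")
    res = rank_sum_test(actual, surrogate)
    critical = alpha / m
    return {
        "median_actual": float(np.median(actual)),
        "median_surrogate": float(np.median(surrogate)),
        **res,
        "m": m,
        "critical_p": critical,
        "significant": bool(res["p"] < critical),
    }
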