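"""Interpreting decoder weights: activation patterns and statistics.

Discriminative weights W of a linear decoder do not measure encoding
strength; the corresponding forward-model (activation) pattern does:

    A = Sigma_X W Sigma_s^{-1}

with Sigma_X the feature covariance and Sigma_s the covariance of the
decoder's extracted outputs (pseudo-inverted when ill-conditioned).
Importance summaries keep the top fraction of |A| (default 25%),
normalize per-channel and per-feature shares of the absolute pattern
mass, and locate each retained channel x feature's peak lag.  A
Gaussian-kernel projection maps per-electrode values onto a 2-D grid.

Movement-related activity statistics (one-sample t per electrode x
feature x window against the Hold-A baseline; two-sample t between
hands) are corrected with Benjamini-Yekutieli FDR, which stays valid
under the positive dependence created by overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task import ConfigurationError

__all__ = [
    "ActivationPattern",
    "compute_activation_patterns",
    "select_top_fraction",
    "summarize_importance",
    "compare_arm_patterns",
    "project_topography",
    "movement_related_stats",
    "active_timecourse_lag",
]


@dataclass
class ActivationPattern:
    """Forward-model pattern per output, shaped like the design layout."""

    A: np.ndarray                   # (p, n_outputs) or reshaped view via .tensor
    layout: tuple[int, int, int]    # (channels, features, lags); lags=1 for classifier
    output_names: list[str]

    def tensor(self) -> np.ndarray:
        C, F, L = self.layout
        return self.A.reshape(C, F, L, -1)


def compute_activation_patterns(
    W: np.ndarray,
    X: np.ndarray,
    layout: tuple[int, int, int],
    output_names: list[str] | None = None,
    rcond: float = 1e-10,
) -> ActivationPattern:
    """A = Sigma_X W Sigma_s^{-1}, from training design X and weights W.

    Computed as Cov(X, s_hat) pinv(Cov(s_hat)) with s_hat = Xc W, which
    is algebraically identical and avoids forming the p x p feature
    covariance.  Works for the multivariate PLS weights (p, 4) and the
    logistic classifier weight vector (p, 1) alike.
    """
    W = np.atleast_2d(np.asarray(W, float))
    if W.shape[0] == 1 and W.shape[1] != 1:
        W = W.T
    X = np.asarray(X)
    n = X.shape[0]
    if n < 2:
        raise ConfigurationError("need >= 2 frames to estimate covariances")
    Xc = X - X.mean(axis=0)
    s_hat = Xc.astype(np.float64) @ W
    cov_xs = (Xc.T @ s_hat.astype(X.dtype)).astype(np.float64) / (n - 1)
    cov_s = np.atleast_2d(np.cov(s_hat.T))
    A = cov_xs @ np.linalg.pinv(cov_s, rcond=rcond)
    if output_names is None:
        output_names = [f"out{i}" for i in range(A.shape[1])]
    return ActivationPattern(A=A, layout=layout, output_names=list(output_names))


def select_top_fraction(A: np.ndarray, fraction: float = 0.25) -> np.ndarray:
    """Indices (into the flattened |A|) of the top-magnitude fraction.

    Ties break by stable (ascending) index order.  The default keeps a
    quarter of the entries, where the skree knee of pattern magnitudes
    sits; configurable.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    mags = np.abs(np.asarray(A, float).ravel())
    if mags.size == 0:
        raise ConfigurationError("empty activation pattern")
    k = max(1, int(round(fraction * mags.size)))
    order = np.argsort(-mags, kind="stable")
    return np.sort(order[:k])


def summarize_importance(
    pattern: ActivationPattern,
    output: int | str = 0,
    fraction: float = 0.25,
    rescale: bool = True,
) -> dict:
    """Channel/feature shares of |A| mass within the top fraction.

    Shares are sums of |A| over the selected set per channel (and per
    feature type) divided by the selected-set total, then min-max
    rescaled to [0, 1] (``rescale=False`` keeps the raw shares, which
    sum to 1).  Also reports the peak |A| lag per selected channel x
    feature.
    """
    if isinstance(output, str):
        output = pattern.output_names.index(output)
    C, F, L = pattern.layout
    absA = np.abs(pattern.tensor()[..., output])  # (C, F, L)
    sel_flat = select_top_fraction(absA, fraction)
    mask = np.zeros(absA.size, dtype=bool)
    mask[sel_flat] = True
    mask = mask.reshape(C, F, L)
    selected = np.where(mask, absA, 0.0)
    total = selected.sum()
    if total <= 0:
        raise ConfigurationError("selected activation mass is zero")

    chan_share = selected.sum(axis=(1, 2)) / total
    feat_share = selected.sum(axis=(0, 2)) / total

    def rescale01(v):
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    peak_lag = np.full((C, F), np.nan)
    cf_selected = mask.any(axis=2)
    for c, f in zip(*np.nonzero(cf_selected)):
        peak_lag[c, f] = int(np.argmax(absA[c, f]))
    return {
        "channel_share": rescale01(chan_share) if rescale else chan_share,
        "feature_share": rescale01(feat_share) if rescale else feat_share,
        "channel_share_raw": chan_share,
        "feature_share_raw": feat_share,
        "peak_lag_index": peak_lag,
        "selected_mask": mask,
    }


def compare_arm_patterns(A_contra: np.ndarray, A_ipsi: np.ndarray) -> dict:
    """Pearson r between |A| vectors of the two arm conditions."""
    a = np.abs(np.asarray(A_contra, float)).ravel()
    b = np.abs(np.asarray(A_ipsi, float)).ravel()
    if a.shape != b.shape:
        raise ConfigurationError("activation patterns must share shape")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n": a.size}


def project_topography(
    coords: np.ndarray,
    values: np.ndarray,
    kernel_sd: float,
    grid_shape: tuple[int, int] = (64, 64),
    margin: float | None = None,
) -> dict:
    """Gaussian-kernel interpolation of electrode values on a 2-D grid.

    map(g) = sum_i v_i K(|g - e_i|) / sum_i K(|g - e_i|): every grid
    value is a convex combination of electrode values, so an isolated
    electrode's location carries exactly its value and the map never
    exceeds the input range.  Coincident electrodes average.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    values = np.asarray(values, float)
    if coords.shape[0] < 1:
        raise ConfigurationError("need at least one electrode")
    if kernel_sd <= 0:
        raise ConfigurationError("kernel_sd must be positive")
    if margin is None:
        margin = 2 * kernel_sd
    x = np.linspace(coords[:, 0].min() - margin, coords[:, 0].max() + margin, grid_shape[1])
    y = np.linspace(coords[:, 1].min() - margin, coords[:, 1].max() + margin, grid_shape[0])
    gx, gy = np.meshgrid(x, y)
    d2 = (gx[..., None] - coords[:, 0]) ** 2 + (gy[..., None] - coords[:, 1]) ** 2
    K = np.exp(-d2 / (2 * kernel_sd**2))
    denom = K.sum(axis=-1)
    denom[denom == 0] = np.finfo(float).tiny
    grid = (K * values).sum(axis=-1) / denom
    return {"grid": grid, "x": x, "y": y}


def movement_related_stats(
    z_by_hand: dict[str, np.ndarray],
    window_times: np.ndarray,
    alpha: float = 0.05,
    fdr_method: str = "fdr_by",
) -> dict:
    """Onset-aligned movement-related activity statistics with FDR.

    ``z_by_hand`` maps hand name -> (trials, electrodes, features,
    windows) tensors of onset-aligned z-scored features.  Per cell a
    one-sample t tests mean z against 0 (the Hold-A baseline); per
    electrode/feature/window a two-sample t compares |z| between hands.
    All p-values are corrected together by Benjamini-Yekutieli step-up
    (valid under the correlation induced by overlapping windows;
    ``fdr_method='fdr_bh'`` opts into plain Benjamini-Hochberg).
    Returns per-cell tables, the percent-active time courses per hand,
    and the between-hand table.
    """
    hands = list(z_by_hand)
    shapes = {z_by_hand[h].shape[1:] for h in hands}
    if len(shapes) != 1:
        raise ConfigurationError("hands must share electrode/feature/window shape")
    E, F, T = shapes.pop()
    if window_times.size != T:
        raise ConfigurationError("window_times length must match the window axis")

    cells = []
    pvals = []
    for h in hands:
        z = np.asarray(z_by_hand[h], float)
        if z.shape[0] < 2:
            raise ConfigurationError("need >= 2 trials per hand")
        mean = z.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat, p = stats.ttest_1samp(z, 0.0, axis=0)
        degenerate = ~np.isfinite(p)
        p = np.where(degenerate, np.nan, p)
        cells.append((h, mean, t_stat, p, degenerate))
        pvals.append(p.ravel())

    between = None
    if len(hands) == 2:
        za, zb = (np.abs(np.asarray(z_by_hand[h], float)) for h in hands)
        with np.errstate(invalid="ignore", divide="ignore"):
            t2, p2 = stats.ttest_ind(za, zb, axis=0)
        p2 = np.where(np.isfinite(p2), p2, np.nan)
        between = (t2, p2)
        pvals.append(p2.ravel())

    allp = np.concatenate(pvals)
    ok = np.isfinite(allp)
    adj = np.full_like(allp, np.nan)
    if ok.any():
        adj[ok] = multipletests(allp[ok], alpha=alpha, method=fdr_method)[1]

    out_tables = {}
    percent_active = {}
    offset = 0
    for h, mean, t_stat, p, degenerate in cells:
        block = adj[offset: offset + p.size].reshape(E, F, T)
        offset += p.size
        sig = np.where(np.isnan(block), False, block < alpha)
        out_tables[h] = pd.DataFrame(
            {
                "electrode": np.repeat(np.arange(E), F * T),
                "feature": np.tile(np.repeat(np.arange(F), T), E),
                "window": np.tile(np.arange(T), E * F),
                "time_s": np.tile(window_times, E * F),
                "mean_z": mean.ravel(),
                "t": t_stat.ravel(),
                "p_adj": block.ravel(),
                "significant": sig.ravel(),
                "degenerate": degenerate.ravel(),
            }
        )
        percent_active[h] = 100.0 * sig.mean(axis=0)  # (F, T) % of electrodes
    result = {
        "tables": out_tables,
        "percent_active": percent_active,
        "window_times": window_times,
    }
    if between is not None:
        t2, p2 = between
        block = adj[offset: offset + p2.size].reshape(E, F, T)
        result["between_hands"] = {
            "t": t2,
            "p_adj": block,
            "significant": np.where(np.isnan(block), False, block < alpha),
        }
    return result


def active_timecourse_lag(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    step_s: float = 0.05,
    max_lag_s: float = 0.5,
) -> dict:
    """Peak lagged correlation between two percent-active time courses.

    Positive lag means ``curve_a`` leads ``curve_b``.  Correlations are
    computed over the overlapping span at each 50 ms lag; a constant
    curve yields r = 0 and a ``degenerate`` flag.
    """
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    if a.size != b.size:
        raise ConfigurationError("curves must have the same length")
    max_shift = int(round(max_lag_s / step_s))
    if a.size <= max_shift:
        raise ConfigurationError("curves shorter than the lag span")
    lags, rs = [], []
    degenerate = False
    for shift in range(-max_shift, max_shift + 1):
        # positive shift: b is a delayed copy of a (a leads)
        if shift >= 0:
            aa, bb = a[: a.size - shift], b[shift:]
        else:
            aa, bb = a[-shift:], b[: b.size + shift]
        if aa.std() == 0 or bb.std() == 0:
            degenerate = True
            r = 0.0
        else:
            r = float(np.corrcoef(aa, bb)[0, 1])
        lags.append(shift * step_s)
        rs.append(r)
    rs = np.asarray(rs)
    best = int(np.argmax(rs))
    return {
        "lags_s": np.asarray(lags),
        "r": rs,
        "peak_r": float(rs[best]),
        "peak_lag_s": float(lags[best]),
        "degenerate": degenerate,
    }
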