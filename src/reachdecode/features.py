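"""Sliding-window spectral features and the local motor potential.

Per channel, power spectra are estimated with an order-75 Burg
(maximum-entropy) autoregressive model in 300 ms windows stepped by
50 ms, evaluated in 2 Hz bins centered 3..253 Hz.  Bin powers are
log-transformed and z-scored against pooled Hold-A baseline windows,
averaged into the seven canonical bands, and z-scored a second time so
that every band has unit baseline variance regardless of how many bins
it contains (this also corrects the 1/f fall-off).  The LMP is the
center value of a second-order Savitzky-Golay (least-squares quadratic)
fit in the same windows, z-scored the same way.

Window bookkeeping is shared by every feature path and by the kinematic
windowing: window w covers samples [w*step, w*step + win), and its
timestamp is the window center, start + win/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._burg import ar_psd, burg_batch
from .bands import BANDS, FEATURE_NAMES
from .task import ConfigurationError

__all__ = [
    "SpectralConfig",
    "FeatureTensor",
    "DegenerateBaselineError",
    "window_starts",
    "window_centers",
    "n_windows",
    "baseline_window_indices",
    "mem_spectrum",
    "sliding_spectrogram",
    "zscore_bins",
    "pool_bands_rezscore",
    "compute_lmp",
    "extract_features",
]

BASELINE_SKIP_S = 0.2  # baseline starts this long after Hold-A onset


class DegenerateBaselineError(ValueError):
    """Baseline windows have zero variance (cannot z-score)."""


class SizingError(ValueError):
    """Signal shorter than one analysis window."""


@dataclass(frozen=True)
class SpectralConfig:
    ar_order: int = 75
    win_ms: float = 300.0
    step_ms: float = 50.0
    bin_start_hz: float = 3.0
    bin_stop_hz: float = 253.0
    bin_step_hz: float = 2.0
    bands: dict = field(default_factory=lambda: dict(BANDS))

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(self.bin_start_hz, self.bin_stop_hz + 1e-9, self.bin_step_hz)

    def win_samples(self, fs: float) -> int:
        return int(round(self.win_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))

    def validate(self, fs: float) -> None:
        if self.win_ms <= self.step_ms:
            raise ConfigurationError("window must be longer than the step")
        if self.ar_order >= self.win_samples(fs):
            raise ConfigurationError("AR order must be below the window sample count")
        for name, (lo, hi) in self.bands.items():
            centers = self.bin_centers
            if np.sum((centers >= lo) & (centers <= hi)) < 1:
                raise ConfigurationError(f"band {name} contains no bin centers")


@dataclass
class FeatureTensor:
    """windows x channels x 8 z-scored features on the 50 ms frame grid."""

    values: np.ndarray        # (n_windows, n_channels, 8)
    times: np.ndarray         # (n_windows,) window-center times, s
    step_s: float
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def n_windows(n_samples: int, win: int, step: int) -> int:
    if n_samples < win:
        raise SizingError("signal shorter than one analysis window")
    return (n_samples - win) // step + 1


def window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    return np.arange(n_windows(n_samples, win, step)) * step


def window_centers(n_samples: int, fs: float, win: int, step: int) -> np.ndarray:
    return (window_starts(n_samples, win, step) + win / 2.0) / fs


def baseline_window_indices(times: np.ndarray, trial_df: pd.DataFrame) -> np.ndarray:
    """Windows whose centers fall in any trial's baseline interval.

    The baseline of a trial runs from 200 ms after Hold-A onset to the
    end of Hold-A; statistics are pooled over all trials of the session.
    """
    mask = np.zeros(times.size, dtype=bool)
    for _, row in trial_df.iterrows():
        mask |= (times >= row["hold_a_on"] + BASELINE_SKIP_S) & (
            times <= row["delay_on"]
        )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ConfigurationError("no baseline windows found")
    return idx


def mem_spectrum(
    window_samples: np.ndarray,
    ar_order: int,
    bin_centers: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Maximum-entropy PSD of one window at the requested bin centers."""
    x = np.asarray(window_samples, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("mem_spectrum expects a single window")
    if x.size <= ar_order:
        raise SizingError("window length must exceed the AR order")
    a, sig = burg_batch(x[None, :], ar_order)
    return ar_psd(a, sig, np.asarray(bin_centers, float), fs)[0]


def _window_view(signal: np.ndarray, win: int, step: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    return sliding_window_view(signal, win)[::step]


def sliding_spectrogram(
    signal: np.ndarray, cfg: SpectralConfig, fs: float
) -> np.ndarray:
    """windows x bins MEM power for one channel."""
    cfg.validate(fs)
    win, step = cfg.win_samples(fs), cfg.step_samples(fs)
    wv = _window_view(np.asarray(signal, np.float64), win, step)
    a, sig = burg_batch(wv, cfg.ar_order)
    return ar_psd(a, sig, cfg.bin_centers, fs)


def zscore_bins(spectrogram: np.ndarray, baseline_idx: np.ndarray) -> np.ndarray:
    """Log-transform then z-score each bin against pooled baseline windows."""
    logp = np.log(spectrogram)
    base = logp[baseline_idx]
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise DegenerateBaselineError("zero baseline SD in at least one bin")
    return (logp - mu) / sd


def pool_bands_rezscore(
    zbins: np.ndarray,
    bin_centers: np.ndarray,
    bands: dict,
    baseline_idx: np.ndarray,
) -> np.ndarray:
    """Average member-bin z-scores per band, then z-score again.

    The second pass guarantees unit baseline variance per band whatever
    the member-bin count, so wide and narrow bands enter the decoder on
    an equal footing.
    """
    cols = []
    for name, (lo, hi) in bands.items():
        members = (bin_centers >= lo) & (bin_centers <= hi)
        if not members.any():
            raise ConfigurationError(f"band {name} has no member bins")
        cols.append(zbins[:, members].mean(axis=1))
    pooled = np.stack(cols, axis=1)
    base = pooled[baseline_idx]
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise DegenerateBaselineError("zero baseline SD in at least one band")
    return (pooled - mu) / sd


def _lmp_center_weights(win: int) -> np.ndarray:
    """Least-squares quadratic fit evaluated at the window-center time.

    The center timestamp convention is start + win/2, i.e. half a sample
    past the middle sample for even window lengths; the quadratic is
    evaluated exactly there.
    """
    u = np.arange(win) - (win / 2.0)
    X = np.stack([np.ones(win), u, u * u], axis=1)
    coef = np.linalg.solve(X.T @ X, X.T)
    return coef[0]  # value of the fitted polynomial at u = 0


def compute_lmp(
    signal: np.ndarray,
    fs: float,
    win_ms: float = 300.0,
    step_ms: float = 50.0,
    baseline_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Savitzky-Golay local motor potential, optionally z-scored.

    Returns the per-window center-evaluated quadratic fit; if
    ``baseline_idx`` is given, the series is z-scored against those
    windows.
    """
    win = int(round(win_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    wv = _window_view(np.asarray(signal, np.float64), win, step)
    lmp = wv @ _lmp_center_weights(win)
    if baseline_idx is None:
        return lmp
    base = lmp[baseline_idx]
    sd = base.std(ddof=0)
    if sd == 0:
        raise DegenerateBaselineError("zero baseline SD in LMP")
    return (lmp - base.mean()) / sd


def extract_features(
    voltages: np.ndarray,
    fs: float,
    trial_df: pd.DataFrame,
    cfg: SpectralConfig | None = None,
) -> FeatureTensor:
    """Full feature tensor for a conditioned multichannel recording.

    Output feature order is the seven bands followed by the LMP; all
    eight are z-scored against the pooled Hold-A baselines, so baseline
    mean is ~0 and SD ~1 per channel and feature.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate(fs)
    C, N = voltages.shape
    win, step = cfg.win_samples(fs), cfg.step_samples(fs)
    times = window_centers(N, fs, win, step)
    baseline_idx = baseline_window_indices(times, trial_df)

    n_feat = len(cfg.bands) + 1
    out = np.empty((times.size, C, n_feat), dtype=np.float32)
    centers = cfg.bin_centers
    for c in range(C):
        spec = sliding_spectrogram(voltages[c], cfg, fs)
        z = zscore_bins(spec, baseline_idx)
        out[:, c, : n_feat - 1] = pool_bands_rezscore(
            z, centers, cfg.bands, baseline_idx
        )
        out[:, c, n_feat - 1] = compute_lmp(
            voltages[c], fs, cfg.win_ms, cfg.step_ms, baseline_idx
        )
    names = list(cfg.bands) + ["lmp"]
    return FeatureTensor(
        values=out, times=times, step_s=cfg.step_ms / 1000.0, feature_names=names
    )
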