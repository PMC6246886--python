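"""Referencing, filtering, and trial segmentation of raw voltages.

Channels are re-referenced to the common average of their reference
group (electrode array / amplifier bank), band-pass filtered 0.1-260 Hz,
and notch filtered at every mains harmonic below 260 Hz.  All filters
are applied forward-backward (zero phase), so conditioned and raw
signals stay time-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, iirnotch, sosfiltfilt, tf2sos

from .task import ConfigurationError

__all__ = [
    "RawRecording",
    "ConditioningConfig",
    "ReferencingError",
    "SegmentationError",
    "common_average_reference",
    "condition_recording",
    "segment_trials",
]


class ReferencingError(ValueError):
    """A reference group has too few channels to form a common average."""


class SegmentationError(ValueError):
    """A trial epoch lies outside the recording."""


@dataclass
class RawRecording:
    """Multichannel voltage block with reference-group bookkeeping."""

    voltages: np.ndarray          # (C, N)
    fs: float
    channel_groups: list[list[int]] | None = None  # partition of retained channels

    def groups(self) -> list[list[int]]:
        if self.channel_groups is None:
            return [list(range(self.voltages.shape[0]))]
        return self.channel_groups


@dataclass
class ConditioningConfig:
    excluded_channels: tuple[int, ...] = ()
    band_hz: tuple[float, float] = (0.1, 260.0)
    notch_base_hz: float = 60.0
    notch_bandwidth_hz: float = 2.0
    notch_max_hz: float = 260.0
    filter_order: int = 4

    def notch_frequencies(self) -> list[float]:
        k = 1
        out = []
        while self.notch_base_hz * k < self.notch_max_hz:
            out.append(self.notch_base_hz * k)
            k += 1
        return out

    def validate(self, fs: float) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi < fs / 2):
            raise ConfigurationError("band edges must satisfy 0 < lo < hi < fs/2")
        if self.notch_base_hz <= 0 or self.notch_bandwidth_hz <= 0:
            raise ConfigurationError("notch parameters must be positive")


def common_average_reference(
    voltages: np.ndarray,
    groups: list[list[int]],
    excluded: tuple[int, ...] = (),
) -> np.ndarray:
    """Subtract the mean of each group's retained channels samplewise.

    Excluded channels neither contribute to the average nor are modified
    meaningfully (they are left as-is; downstream analyses drop them).
    Idempotent: re-applying changes nothing.
    """
    out = voltages.astype(np.float64, copy=True)
    excluded_set = set(excluded)
    for group in groups:
        keep = [c for c in group if c not in excluded_set]
        if len(keep) < 2:
            raise ReferencingError(
                f"reference group {group} has <2 retained channels"
            )
        out[keep] -= out[keep].mean(axis=0, keepdims=True)
    return out


def condition_recording(rec: RawRecording, cfg: ConditioningConfig) -> RawRecording:
    """CAR, zero-phase Butterworth band-pass, then IIR notches."""
    cfg.validate(rec.fs)
    nyq = rec.fs / 2
    v = common_average_reference(rec.voltages, rec.groups(), cfg.excluded_channels)

    lo, hi = cfg.band_hz
    sos = butter(cfg.filter_order, [lo / nyq, hi / nyq], btype="band", output="sos")
    v = sosfiltfilt(sos, v, axis=1)

    for f0 in cfg.notch_frequencies():
        q = f0 / cfg.notch_bandwidth_hz
        b, a = iirnotch(f0, q, fs=rec.fs)
        v = sosfiltfilt(tf2sos(b, a), v, axis=1)

    return RawRecording(
        voltages=v, fs=rec.fs, channel_groups=rec.channel_groups
    )


def segment_trials(
    n_samples: int,
    fs: float,
    trial_df: pd.DataFrame,
) -> pd.DataFrame:
    """Half-open, 0-based sample ranges per trial epoch.

    ``trial_df`` needs columns hold_a_on / delay_on / go_cue / move_end /
    span_end (seconds).  Returns one row per trial with [start, end)
    sample indices for the whole span and for the Hold-A, delay,
    movement and Hold-B epochs.
    """
    cols = [
        "trial_id", "start", "end", "hold_a_start", "hold_a_end",
        "delay_start", "delay_end", "move_start", "move_end",
        "hold_b_start", "hold_b_end",
    ]
    if trial_df.empty:
        return pd.DataFrame(columns=cols)
    s = lambda col: np.round(trial_df[col].to_numpy() * fs).astype(int)
    start, delay_on, go = s("hold_a_on"), s("delay_on"), s("go_cue")
    move_end, end = s("move_end"), s("span_end")
    out = pd.DataFrame(
        {
            "trial_id": trial_df["trial_id"].to_numpy(),
            "start": start,
            "end": end,
            "hold_a_start": start,
            "hold_a_end": delay_on,
            "delay_start": delay_on,
            "delay_end": go,
            "move_start": go,
            "move_end": move_end,
            "hold_b_start": move_end,
            "hold_b_end": end,
        },
        columns=cols,
    )
    if np.any(start < 0) or np.any(end > n_samples):
        raise SegmentationError("trial epoch outside recording extent")
    return out
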