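"""Kinematic processing onto the 50 ms feature frame grid.

Raw hand positions are differentiated (central differences) to velocity
and speed, every kinematic parameter is averaged in the same 300 ms /
50 ms windows used for the neural features, movement onset is the first
frame whose speed exceeds 10% of the trial-specific maximum, and the
same relative threshold produces per-frame movement/rest labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SizingError, window_centers, _window_view

__all__ = [
    "KinematicFrames",
    "OnsetInfo",
    "NoOnsetError",
    "derive_velocity_speed",
    "window_kinematics",
    "detect_onset",
    "label_movement",
    "frame_series",
]

MOVE_THRESHOLD_FRAC = 0.1


class NoOnsetError(ValueError):
    """Speed never rises above zero: no movement onset exists."""


@dataclass
class OnsetInfo:
    onset_frame: int
    max_speed: float
    threshold: float


@dataclass
class KinematicFrames:
    """Session kinematics on the feature frame grid.

    ``trial_id`` is -1 for frames outside any trial's analyzed span
    (return reaches, inter-trial holds); ``movement`` is defined w.r.t.
    each trial's own maximum speed and is False outside trials.
    """

    times: np.ndarray      # (F,)
    position: np.ndarray   # (F, 3)
    velocity: np.ndarray   # (F, 3)
    speed: np.ndarray      # (F,)
    trial_id: np.ndarray   # (F,) int, -1 outside trials
    movement: np.ndarray   # (F,) bool

    @property
    def n_frames(self) -> int:
        return self.times.size

    def trial_frames(self, trial_id: int) -> np.ndarray:
        return np.flatnonzero(self.trial_id == trial_id)


def derive_velocity_speed(position: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference velocity (one-sided at the ends) and speed."""
    position = np.asarray(position, float)
    if position.ndim != 2 or position.shape[1] != 3:
        raise ValueError("position must be (T, 3)")
    if position.shape[0] < 3:
        raise SizingError("need at least 3 samples to differentiate")
    velocity = np.gradient(position, 1.0 / fs, axis=0)
    speed = np.linalg.norm(velocity, axis=1)
    return velocity, speed


def window_kinematics(
    values: np.ndarray, fs: float, win_ms: float = 300.0, step_ms: float = 50.0
) -> np.ndarray:
    """Interval average of a kinematic series in each analysis window.

    Accepts (T,) or (T, D); returns one row per window, aligned with the
    neural feature windows for the same span and sampling rate.  The
    average is trapezoidal over the window interval [start, start+win],
    so a linear signal windows exactly to its value at the window-center
    timestamp (start + win/2); the final window falls back to the plain
    sample mean when the closing sample does not exist.
    """
    values = np.asarray(values, float)
    win = int(round(win_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    n = values.shape[0]
    if n < win:
        raise SizingError("kinematic series shorter than one window")

    def one(x: np.ndarray) -> np.ndarray:
        wv = _window_view(x, win, step)
        starts = np.arange(wv.shape[0]) * step
        out = wv.sum(axis=1)
        ends = starts + win
        has_end = ends < n
        out[has_end] += 0.5 * (x[ends[has_end]] - x[starts[has_end]])
        return out / win

    if values.ndim == 1:
        return one(values)
    return np.stack([one(values[:, d]) for d in range(values.shape[1])], axis=1)


def detect_onset(
    speed_frames: np.ndarray,
    threshold_frac: float = MOVE_THRESHOLD_FRAC,
    override_frame: int | None = None,
) -> OnsetInfo:
    """First frame whose speed exceeds the relative threshold.

    ``override_frame`` is the manual-correction hook: visually confirmed
    onsets can replace the automatic crossing.
    """
    speed_frames = np.asarray(speed_frames, float)
    max_speed = float(speed_frames.max(initial=0.0))
    if max_speed <= 0:
        raise NoOnsetError("all-zero speed; no onset")
    threshold = threshold_frac * max_speed
    if override_frame is not None:
        return OnsetInfo(int(override_frame), max_speed, threshold)
    above = np.flatnonzero(speed_frames > threshold)
    if above.size == 0:
        raise NoOnsetError("speed never exceeds the threshold")
    return OnsetInfo(int(above[0]), max_speed, threshold)


def label_movement(
    speed_frames: np.ndarray, threshold_frac: float = MOVE_THRESHOLD_FRAC
) -> np.ndarray:
    """Movement/rest labels: speed above threshold_frac x trial max."""
    speed_frames = np.asarray(speed_frames, float)
    max_speed = float(speed_frames.max(initial=0.0))
    if max_speed <= 0:
        raise NoOnsetError("all-zero speed; cannot label movement")
    return speed_frames > threshold_frac * max_speed


def frame_series(
    kin_t: np.ndarray,
    kin_position: np.ndarray,
    trial_df: pd.DataFrame,
    kin_fs: float,
    win_ms: float = 300.0,
    step_ms: float = 50.0,
    threshold_frac: float = MOVE_THRESHOLD_FRAC,
) -> KinematicFrames:
    """Window a raw session kinematic record onto the frame grid.

    Velocity and speed are derived on the raw grid first, then every
    parameter is window-averaged; frame times are the window centers
    relative to the same session clock as the neural features.  Frames
    are assigned to the trial whose [hold_a_on, span_end) span contains
    their center; movement labels use each trial's own speed maximum.
    """
    velocity, speed = derive_velocity_speed(kin_position, kin_fs)
    pos_f = window_kinematics(kin_position, kin_fs, win_ms, step_ms)
    vel_f = window_kinematics(velocity, kin_fs, win_ms, step_ms)
    speed_f = window_kinematics(speed, kin_fs, win_ms, step_ms)
    win = int(round(win_ms * kin_fs / 1000.0))
    step = int(round(step_ms * kin_fs / 1000.0))
    times = float(kin_t[0]) + window_centers(kin_position.shape[0], kin_fs, win, step)

    # assign frames to trials in integer grid units: float window-center
    # times jitter at trial boundaries, which would make nominally
    # equal-length trials differ by one frame
    step_s = step_ms / 1000.0
    itimes = np.round(times / step_s).astype(np.int64)
    trial_id = np.full(times.size, -1, dtype=int)
    movement = np.zeros(times.size, dtype=bool)
    for _, row in trial_df.iterrows():
        lo = int(round(row["hold_a_on"] / step_s))
        hi = int(round(row["span_end"] / step_s))
        sel = (itimes >= lo) & (itimes < hi)
        trial_id[sel] = int(row["trial_id"])
        if sel.any():
            movement[sel] = label_movement(speed_f[sel], threshold_frac)
    return KinematicFrames(
        times=times,
        position=pos_f,
        velocity=vel_f,
        speed=speed_f,
        trial_id=trial_id,
        movement=movement,
    )
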