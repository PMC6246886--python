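"""Center-out reach task simulation.

Generates 3D hand kinematics for a center-out reaching task in which a
subject reaches from a central start position to one of eight targets at
the corners of a physical cube (0.5 m edges by default).  Each trial is
structured as a center hold (Hold-A), a planning delay, a point-to-point
reach, and a peripheral hold (Hold-B); trials are concatenated into a
continuous session with a return reach and an inter-trial hold so that
voltage synthesis sees a continuous position signal.

Reaches follow a minimum-jerk (quintic) profile, the standard model for
smooth point-to-point arm movements; its bell-shaped speed profile peaks
at ``15/8 * D / T`` for a reach of amplitude ``D`` and duration ``T``.

Axis convention (kept throughout the package): +x anterior->posterior
toward the subject, +y toward the subject's left, +z downward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialKinematics",
    "CUBE_CORNER_SIGNS",
    "cube_corners",
    "minimum_jerk_position",
    "minimum_jerk_speed",
    "generate_trials",
    "balanced_target_sequence",
]

#: Sign patterns of the eight cube corners, in binary order (z fastest).
CUBE_CORNER_SIGNS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float,
)

MINJERK_PEAK_COEF = 15.0 / 8.0  # peak speed of the quintic profile, in units of D/T


class ConfigurationError(ValueError):
    """Raised for invalid task or analysis configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the simulated center-out session.

    Durations are in seconds, lengths in meters.  ``return_s`` and
    ``iti_s`` (return reach to center and inter-trial hold) are free
    parameters of the simulation: the task protocol does not constrain
    them, but a continuous recording needs them.
    """

    n_trials: int = 80
    cube_edge: float = 0.5
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hold_a_s: float = 1.0
    delay_s: float = 2.0
    move_s: float = 1.0
    hold_b_s: float = 0.5
    return_s: float = 1.0
    iti_s: float = 0.5
    kin_fs: float = 100.0
    jitter_mm: float = 2.0
    jitter_cutoff_hz: float = 2.0
    seed: int = 0

    @property
    def trial_span_s(self) -> float:
        """Duration of the analyzed portion of a trial (Hold-A .. Hold-B)."""
        return self.hold_a_s + self.delay_s + self.move_s + self.hold_b_s

    @property
    def trial_total_s(self) -> float:
        """Full trial duration including return reach and inter-trial hold."""
        return self.trial_span_s + self.return_s + self.iti_s

    def validate(self) -> None:
        durations = (
            self.hold_a_s, self.delay_s, self.move_s,
            self.hold_b_s, self.return_s, self.iti_s,
        )
        if any(d <= 0 for d in durations):
            raise ConfigurationError("all task durations must be > 0")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.cube_edge <= 0:
            raise ConfigurationError("cube_edge must be > 0")
        if self.kin_fs <= 0:
            raise ConfigurationError("kin_fs must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialKinematics:
    """Kinematics of one trial on the raw motion-capture grid.

    ``t`` spans the full trial (including return and inter-trial hold)
    relative to session start; epoch marks give the Hold-A onset, go cue,
    nominal movement onset (= go cue here, the simulated subject has zero
    reaction time unless jitter shifts the threshold crossing), movement
    end, and end of the analyzed span (end of Hold-B).
    """

    trial_id: int
    target_index: int
    t: np.ndarray
    position: np.ndarray  # (T, 3)
    velocity: np.ndarray  # (T, 3)
    speed: np.ndarray     # (T,)
    hold_a_on: float
    delay_on: float
    go_cue: float
    move_on: float
    move_end: float
    span_end: float


def cube_corners(cube_edge: float, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Coordinates of the eight reach targets (corners of the cube)."""
    return np.asarray(center, float) + 0.5 * cube_edge * CUBE_CORNER_SIGNS


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """d/dtau of the normalized profile; peak value is 15/8 at tau = 1/2."""
    tau = np.asarray(tau, float)
    out = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return np.where((tau < 0) | (tau > 1), 0.0, out)


def balanced_target_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random target order with per-corner counts differing by <= 1."""
    reps = int(np.ceil(n_trials / 8))
    seq = np.tile(np.arange(8), reps)[:n_trials]
    rng.shuffle(seq)
    return seq


def _session_position(config: TaskConfig, targets: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Noiseless hand position over the whole session, evaluated at times t."""
    center = np.asarray(config.center, float)
    corners = cube_corners(config.cube_edge, config.center)
    pos = np.empty((t.size, 3))
    total = config.trial_total_s
    trial_idx = np.minimum((t / total).astype(int), len(targets) - 1)
    t_in = t - trial_idx * total
    m_on = config.hold_a_s + config.delay_s
    m_end = m_on + config.move_s
    r_on = m_end + config.hold_b_s
    r_end = r_on + config.return_s
    for k, tgt in enumerate(targets):
        sel = trial_idx == k
        ti = t_in[sel]
        corner = corners[tgt]
        p = np.empty((ti.size, 3))
        # Hold-A + delay at center
        p[:] = center
        moving = (ti >= m_on) & (ti < m_end)
        p[moving] = center + np.outer(
            minimum_jerk_position((ti[moving] - m_on) / config.move_s), corner - center
        )
        holding_b = (ti >= m_end) & (ti < r_on)
        p[holding_b] = corner
        returning = (ti >= r_on) & (ti < r_end)
        p[returning] = corner + np.outer(
            minimum_jerk_position((ti[returning] - r_on) / config.return_s),
            center - corner,
        )
        # after return: at center (inter-trial hold)
        pos[sel] = p
    return pos


def _bandlimited_jitter(
    shape: tuple[int, int], fs: float, cutoff_hz: float, sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow Gaussian positional noise (tracker jitter / postural drift).

    White positional noise would differentiate into unrealistically large
    velocities, so the jitter is low-pass filtered at ``cutoff_hz`` and
    rescaled to the requested positional SD.
    """
    from scipy.signal import butter, filtfilt

    white = rng.standard_normal(shape)
    if cutoff_hz >= fs / 2:
        return sd * white
    b, a = butter(2, cutoff_hz / (fs / 2))
    slow = filtfilt(b, a, white, axis=0)
    scale = slow.std(axis=0, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * slow / scale


def generate_trials(config: TaskConfig, seed: int | None = None) -> list[TrialKinematics]:
    """Simulate one session of center-out reaches.

    Returns one :class:`TrialKinematics` per trial, on a shared session
    time base at ``config.kin_fs``.  Target order is a seeded random
    permutation balanced across the eight corners.  Velocity is the
    analytic derivative where the profile is analytic; with jitter
    enabled, position noise is added first and velocity is obtained by
    central differences of the noisy position so that position, velocity
    and speed remain mutually consistent.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    targets = balanced_target_sequence(config.n_trials, rng)

    total = config.trial_total_s
    n_samples = int(round(config.n_trials * total * config.kin_fs))
    t = np.arange(n_samples) / config.kin_fs
    pos = _session_position(config, targets, t)
    if config.jitter_mm > 0:
        pos = pos + _bandlimited_jitter(
            pos.shape, config.kin_fs, config.jitter_cutoff_hz,
            config.jitter_mm * 1e-3, rng,
        )
    vel = np.gradient(pos, 1.0 / config.kin_fs, axis=0)
    speed = np.linalg.norm(vel, axis=1)

    trials = []
    samples_per_trial = int(round(total * config.kin_fs))
    m_on = config.hold_a_s + config.delay_s
    for k, tgt in enumerate(targets):
        i0 = k * samples_per_trial
        i1 = min(i0 + samples_per_trial, n_samples)
        sl = slice(i0, i1)
        t0 = k * total
        trials.append(
            TrialKinematics(
                trial_id=k,
                target_index=int(tgt),
                t=t[sl],
                position=pos[sl],
                velocity=vel[sl],
                speed=speed[sl],
                hold_a_on=t0,
                delay_on=t0 + config.hold_a_s,
                go_cue=t0 + m_on,
                move_on=t0 + m_on,
                move_end=t0 + m_on + config.move_s,
                span_end=t0 + config.trial_span_s,
            )
        )
    return trials
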