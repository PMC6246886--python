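"""Forward model: synthesize multichannel voltages from reach kinematics.

Each channel is a sum of seven band-limited carriers (amplitude-modulated
narrowband Gaussian noise, so autoregressive spectral estimation sees
realistic spectra rather than line spectra), a slow DC-coupled component
that carries the local motor potential, broadband 1/f ("pink") background
noise, and an optional mains sinusoid.

The encoding is exponential for band amplitudes,

    amp_cb(t) = baseline_cb * exp(w_s * s(t - lag) + w_v . v(t - lag)),

so that window-averaged log band power is linear in speed and velocity —
the regime a linear decoder on log-power z-scores can recover.  The slow
component is linear in the (lagged) kinematics.  Lags follow the decoder
convention: negative lag means neural activity leads the kinematics it
encodes, i.e. the voltage at time t reflects kinematics at t - lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .bands import BANDS, FEATURE_NAMES, N_FEATURES
from .task import (
    CUBE_CORNER_SIGNS,
    ConfigurationError,
    TaskConfig,
    TrialKinematics,
    generate_trials,
)

__all__ = [
    "GroundTruthEncoding",
    "SyntheticDataset",
    "zero_encoding",
    "default_encoding",
    "orthogonal_encoding_pair",
    "synthesize_ecog",
    "simulate_session",
    "make_paired_arm_datasets",
    "trial_table",
]

ECOG_FS = 1200.0
LAG_GRID_MS = 50.0


@dataclass
class GroundTruthEncoding:
    """Known kinematic tuning of every channel x feature, for testing.

    Feature index follows :data:`reachdecode.bands.FEATURE_NAMES`
    (7 bands then LMP).  ``w_s`` and ``w_v`` are speed and velocity
    tuning weights; for bands they act in the log-amplitude domain, for
    the LMP row linearly on the slow potential.  ``lag_ms`` must lie on
    the 50 ms grid in [-1000, 500] ms.
    """

    w_s: np.ndarray          # (C, 8)
    w_v: np.ndarray          # (C, 8, 3)
    lag_ms: np.ndarray       # (C, 8)
    baseline_amp: np.ndarray  # (C, 8); for bands: carrier RMS, for LMP: slow gain
    pink_exponent: float = 2.0
    pink_rms: float = 1.0
    line_freq_hz: float = 60.0
    line_amp: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.w_s.shape[0]

    def validate(self) -> None:
        C = self.n_channels
        if self.w_s.shape != (C, N_FEATURES) or self.lag_ms.shape != (C, N_FEATURES):
            raise ConfigurationError("encoding arrays must be (channels, 8)")
        if self.w_v.shape != (C, N_FEATURES, 3):
            raise ConfigurationError("w_v must be (channels, 8, 3)")
        for arr in (self.w_s, self.w_v, self.lag_ms, self.baseline_amp):
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError("encoding weights must be finite")
        on_grid = np.abs(np.round(self.lag_ms / LAG_GRID_MS) * LAG_GRID_MS - self.lag_ms)
        if np.any(on_grid > 1e-9) or self.lag_ms.min() < -1000 or self.lag_ms.max() > 500:
            raise ConfigurationError("lags must lie on the 50 ms grid in [-1000, 500] ms")

    def flat_weights(self) -> np.ndarray:
        """All tuning weights as one vector (used for orthogonality checks)."""
        return np.concatenate([self.w_s.ravel(), self.w_v.ravel()])


def zero_encoding(n_channels: int) -> GroundTruthEncoding:
    """No kinematic tuning anywhere: the decoder null world."""
    C = n_channels
    enc = GroundTruthEncoding(
        w_s=np.zeros((C, N_FEATURES)),
        w_v=np.zeros((C, N_FEATURES, 3)),
        lag_ms=np.zeros((C, N_FEATURES)),
        baseline_amp=np.ones((C, N_FEATURES)),
    )
    enc.baseline_amp[:, 7] = 0.0
    return enc


def default_encoding(n_channels: int, channels=None) -> GroundTruthEncoding:
    """Strong, physiologically-flavored encoding used as the default world.

    Movement increases high-gamma amplitude and suppresses mu/beta
    (event-related synchronization / desynchronization), and the slow
    potential tracks speed and velocity — the feature profile reported
    for reaching.  Velocity tuning directions vary across channels
    (cycling through the cube-corner directions) so all three components
    are linearly identifiable.  Neural activity leads the kinematics by
    0-100 ms depending on the channel.
    """
    C = n_channels
    enc = zero_encoding(C)
    dirs = CUBE_CORNER_SIGNS / np.sqrt(3.0)
    if channels is None:
        channels = range(C)
    for c in channels:
        u = dirs[c % 8]
        u2 = dirs[(c + 3) % 8]
        lag = -50.0 * (c % 3)
        fidx = {name: i for i, name in enumerate(FEATURE_NAMES)}
        enc.w_s[c, fidx["gamma2"]] = 1.0
        enc.w_v[c, fidx["gamma2"]] = 0.8 * u
        enc.w_s[c, fidx["gamma3"]] = 0.8
        enc.w_v[c, fidx["gamma3"]] = 0.8 * u2
        enc.w_s[c, fidx["beta1"]] = -0.6
        enc.w_s[c, fidx["mu"]] = -0.5
        enc.w_v[c, fidx["beta1"]] = -0.5 * u2
        # alternate the sign/size of slow-potential speed tuning across
        # channels so the common-average reference does not cancel it
        enc.baseline_amp[c, fidx["lmp"]] = 3.0
        enc.w_s[c, fidx["lmp"]] = 0.5 * (1.0, -1.0, 0.6, -0.6)[c % 4]
        enc.w_v[c, fidx["lmp"]] = 1.2 * u
        enc.lag_ms[c, :] = lag
    return enc


def orthogonal_encoding_pair(n_channels: int) -> tuple[GroundTruthEncoding, GroundTruthEncoding]:
    """Two encodings with disjoint band support (orthogonal weights).

    Used to simulate two "arms" whose cortical representations share
    nothing, the negative control for cross-arm prediction.  The second
    arm encodes only in gamma-1 (34-55 Hz) with no slow-potential
    component: that band is untouched by the default encoding and
    spectrally insulated from every band it uses, so neither the
    common-average reference (which mixes channels) nor carrier
    spectral leakage (which couples adjacent bands) can carry arm-B
    kinematics into the features an arm-A decoder relies on.
    """
    enc_a = default_encoding(n_channels)
    enc_b = zero_encoding(n_channels)
    dirs = CUBE_CORNER_SIGNS / np.sqrt(3.0)
    g1 = FEATURE_NAMES.index("gamma1")
    for c in range(n_channels):
        enc_b.w_s[c, g1] = 1.0
        enc_b.w_v[c, g1] = 0.9 * dirs[(c + 2) % 8]
        enc_b.lag_ms[c, :] = -50.0 * ((c + 1) % 3)
    assert float(enc_a.flat_weights() @ enc_b.flat_weights()) == 0.0
    return enc_a, enc_b


@dataclass
class SyntheticDataset:
    """Paired voltages + kinematics + the ground-truth encoding."""

    voltages: np.ndarray       # (C, N) float32, nominal uV
    fs: float
    trials: list[TrialKinematics]
    encoding: GroundTruthEncoding
    config: TaskConfig
    kin_t: np.ndarray          # session kinematic time base (kin_fs)
    kin_position: np.ndarray   # (Tk, 3)
    kin_velocity: np.ndarray   # (Tk, 3)
    kin_speed: np.ndarray      # (Tk,)

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def duration_s(self) -> float:
        return self.voltages.shape[1] / self.fs


def trial_table(trials: list[TrialKinematics]) -> pd.DataFrame:
    """Tabular trial metadata (times in seconds from session start)."""
    return pd.DataFrame(
        {
            "trial_id": [tr.trial_id for tr in trials],
            "target_index": [tr.target_index for tr in trials],
            "hold_a_on": [tr.hold_a_on for tr in trials],
            "delay_on": [tr.delay_on for tr in trials],
            "go_cue": [tr.go_cue for tr in trials],
            "move_on": [tr.move_on for tr in trials],
            "move_end": [tr.move_end for tr in trials],
            "span_end": [tr.span_end for tr in trials],
        }
    )


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    # amplitude shaping: PSD ~ f^-a  =>  |X| ~ f^(-a/2); floor at one bin
    # width so the DC/lowest bins do not blow up
    shape = np.maximum(f, 1.0 / n) ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _band_carrier(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband Gaussian noise carrier."""
    sos = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_ecog(
    trials: list[TrialKinematics],
    encoding: GroundTruthEncoding,
    seed: int,
    config: TaskConfig | None = None,
    ecog_fs: float = ECOG_FS,
) -> SyntheticDataset:
    """Render the session's voltages from kinematics and an encoding."""
    encoding.validate()
    kin_t = np.concatenate([tr.t for tr in trials])
    kin_pos = np.concatenate([tr.position for tr in trials])
    kin_vel = np.concatenate([tr.velocity for tr in trials])
    kin_speed = np.concatenate([tr.speed for tr in trials])

    duration = kin_t[-1] + (kin_t[1] - kin_t[0])
    n = int(round(duration * ecog_fs))
    t = np.arange(n) / ecog_fs

    rng = np.random.default_rng(seed)
    C = encoding.n_channels
    volts = np.zeros((C, n), dtype=np.float64)

    band_edges = list(BANDS.values())
    lmp_idx = N_FEATURES - 1
    for c in range(C):
        acc = np.zeros(n)
        for b, (lo, hi) in enumerate(band_edges):
            carrier = _band_carrier(n, lo, hi, ecog_fs, rng)
            amp = encoding.baseline_amp[c, b]
            if amp == 0.0:
                continue
            if encoding.w_s[c, b] != 0.0 or np.any(encoding.w_v[c, b] != 0.0):
                lag_s = encoding.lag_ms[c, b] / 1000.0
                ts = t - lag_s  # voltage at t encodes kinematics at t - lag
                s = np.interp(ts, kin_t, kin_speed, left=0.0, right=0.0)
                drive = encoding.w_s[c, b] * s
                for ax in range(3):
                    if encoding.w_v[c, b, ax] != 0.0:
                        drive += encoding.w_v[c, b, ax] * np.interp(
                            ts, kin_t, kin_vel[:, ax], left=0.0, right=0.0
                        )
                acc += amp * np.exp(drive) * carrier
            else:
                acc += amp * carrier
        # slow DC-coupled component (carries the LMP)
        g = encoding.baseline_amp[c, lmp_idx]
        if g != 0.0:
            lag_s = encoding.lag_ms[c, lmp_idx] / 1000.0
            ts = t - lag_s
            slow = encoding.w_s[c, lmp_idx] * np.interp(
                ts, kin_t, kin_speed, left=0.0, right=0.0
            )
            for ax in range(3):
                if encoding.w_v[c, lmp_idx, ax] != 0.0:
                    slow += encoding.w_v[c, lmp_idx, ax] * np.interp(
                        ts, kin_t, kin_vel[:, ax], left=0.0, right=0.0
                    )
            acc += g * slow
        if encoding.pink_rms > 0:
            acc += encoding.pink_rms * _pink_noise(n, encoding.pink_exponent, rng)
        if encoding.line_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            acc += encoding.line_amp * np.sin(2 * np.pi * encoding.line_freq_hz * t + phase)
        volts[c] = acc

    return SyntheticDataset(
        voltages=volts.astype(np.float32),
        fs=ecog_fs,
        trials=trials,
        encoding=encoding,
        config=config,
        kin_t=kin_t,
        kin_position=kin_pos,
        kin_velocity=kin_vel,
        kin_speed=kin_speed,
    )


def simulate_session(
    config: TaskConfig,
    encoding: GroundTruthEncoding | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Convenience: trials + voltages in one call (seed drives both)."""
    if seed is None:
        seed = config.seed
    if encoding is None:
        raise ConfigurationError("an encoding is required; use default_encoding(C)")
    ss = np.random.SeedSequence(seed)
    s_kin, s_ecog = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    trials = generate_trials(config, seed=s_kin)
    return synthesize_ecog(trials, encoding, seed=s_ecog, config=config)


def make_paired_arm_datasets(
    config: TaskConfig,
    encoding_contra: GroundTruthEncoding,
    encoding_ipsi: GroundTruthEncoding,
    seed: int,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two independent task realizations (one per arm) with shared noise
    statistics but independent noise draws.

    The two encodings may be identical, overlapping, or orthogonal
    (:func:`orthogonal_encoding_pair`) depending on what the caller wants
    to test about cross-arm transfer.
    """
    if encoding_contra.w_s.shape != encoding_ipsi.w_s.shape:
        raise ConfigurationError("arm encodings must share channel/feature shape")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    contra = simulate_session(config, encoding_contra, seed=seeds[0])
    ipsi = simulate_session(config, encoding_ipsi, seed=seeds[1])
    return contra, ipsi
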