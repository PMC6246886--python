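"""Canonical frequency bands used throughout the package.

Seven bands spanning the motor-relevant spectrum while avoiding mains
harmonics (60/120 Hz fall in the gaps), plus the local motor potential
(LMP) as the eighth feature.
"""

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "mu": (8.0, 12.0),
    "beta1": (12.0, 24.0),
    "beta2": (24.0, 34.0),
    "gamma1": (34.0, 55.0),
    "gamma2": (65.0, 95.0),
    "gamma3": (130.0, 175.0),
}

BAND_NAMES: list[str] = list(BANDS)

#: Feature order of the 8-feature tensors: 7 band powers then LMP.
FEATURE_NAMES: list[str] = BAND_NAMES + ["lmp"]

N_FEATURES = len(FEATURE_NAMES)
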