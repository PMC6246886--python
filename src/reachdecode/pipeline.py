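"""End-to-end orchestration of the analysis stages.

simulate -> condition -> features -> kinematics -> train/evaluate (with
surrogates) -> interpret, with every stochastic stage seeded from the
run configuration and a manifest recording the config hash and output
checksums so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .conditioning import ConditioningConfig, RawRecording, condition_recording
from .decoder import DecoderConfig
from .evaluation import (
    SplitPlan,
    bonferroni_critical_p,
    compare_distributions,
    comparison_family_size,
    evaluate_session,
)
from .features import SpectralConfig, extract_features
from .interpretation import compute_activation_patterns, summarize_importance
from .kinematics import frame_series
from .synth import default_encoding, simulate_session, trial_table, zero_encoding
from .task import ConfigurationError, TaskConfig

__all__ = ["RunConfig", "SCALE_PRESETS", "validate_config", "run_pipeline"]

SCALE_PRESETS = {
    "full": {"n_repeats": 100, "n_weight_shuffles": 100},
    "desk": {"n_repeats": 20, "n_weight_shuffles": 25},
}


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    scale: str = "desk"
    n_channels: int = 16
    encoding: str = "default"          # default | zero
    task: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    conditioning: dict = field(default_factory=dict)
    decoder: dict = field(default_factory=dict)
    train_fraction: float = 7.0 / 8.0
    evaluate: bool = True
    interpret: bool = True
    n_repeats: int | None = None          # override the scale preset
    n_weight_shuffles: int | None = None  # override the scale preset

    @classmethod
    def from_json(cls, path: Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations of a run configuration (empty = runnable)."""
    v: list[str] = []
    if config.scale not in SCALE_PRESETS:
        v.append(f"RunConfig: unknown scale preset {config.scale!r}")
    if config.n_channels < 2:
        v.append("RunConfig: need at least 2 channels for referencing")
    if config.encoding not in ("default", "zero"):
        v.append(f"RunConfig: unknown encoding {config.encoding!r}")
    if not 0 < config.train_fraction < 1:
        v.append("SplitPlan: train fraction must leave a nonempty test set")
    try:
        TaskConfig(**config.task).validate()
    except (ConfigurationError, TypeError) as e:
        v.append(f"TaskConfig: {e}")
    try:
        SpectralConfig(**config.spectral).validate(1200.0)
    except (ConfigurationError, TypeError) as e:
        v.append(f"SpectralConfig: {e}")
    try:
        ConditioningConfig(**config.conditioning).validate(1200.0)
    except (ConfigurationError, TypeError) as e:
        v.append(f"ConditioningConfig: {e}")
    return v


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest dictionary."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": rio.config_hash(config.to_dict()),
        "stages": {},
        "outputs": {},
    }
    try:
        from importlib.metadata import version

        manifest["package_version"] = version("reachdecode")
    except Exception:
        manifest["package_version"] = "unknown"

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    task = TaskConfig(**{"seed": config.seed, **config.task})
    enc = (default_encoding if config.encoding == "default" else zero_encoding)(
        config.n_channels
    )
    with stage("simulate"):
        ds = simulate_session(task, enc, seed=config.seed)
        paths = rio.save_dataset(ds, out / "data")
    trial_df = trial_table(ds.trials)

    with stage("condition"):
        cond = condition_recording(
            RawRecording(ds.voltages.astype(np.float64), ds.fs),
            ConditioningConfig(**config.conditioning),
        )

    with stage("features"):
        feats = extract_features(
            cond.voltages, ds.fs, trial_df, SpectralConfig(**config.spectral)
        )

    with stage("kinematics"):
        frames = frame_series(ds.kin_t, ds.kin_position, trial_df, task.kin_fs)
        n = min(frames.n_frames, feats.n_windows)
        if frames.n_frames != feats.n_windows:  # rounding at the session tail
            feats.values = feats.values[:n]
            feats.times = feats.times[:n]
            for name in ("times", "position", "velocity", "speed", "trial_id", "movement"):
                setattr(frames, name, getattr(frames, name)[:n])
        fr = pd.DataFrame(
            {"t": frames.times, "trial_id": frames.trial_id,
             "speed": frames.speed, "movement": frames.movement.astype(int)}
        )
        fr.to_csv(out / "frames.tsv", sep="\t", index=False)

    result = None
    if config.evaluate:
        with stage("evaluate"):
            preset = SCALE_PRESETS[config.scale]
            plan = SplitPlan(
                n_repeats=config.n_repeats or preset["n_repeats"],
                train_fraction=config.train_fraction,
                seed=config.seed,
            )
            result = evaluate_session(
                feats, frames, plan, DecoderConfig(**config.decoder),
                n_weight_shuffles=config.n_weight_shuffles
                or preset["n_weight_shuffles"],
            )
            result.table.to_csv(out / "accuracy.tsv", sep="\t", index=False)
            m = comparison_family_size()
            stats_rows = []
            for cond_name in ("temporal", "shuffle"):
                for metric in ("speed_r", "vx_r", "vy_r", "vz_r", "targets_hit_pct"):
                    cmp = compare_distributions(
                        result.condition("actual")[metric],
                        result.condition(cond_name)[metric],
                        m=m,
                    )
                    stats_rows.append({"surrogate": cond_name, "metric": metric, **cmp})
            pd.DataFrame(stats_rows).to_csv(out / "stats.tsv", sep="\t", index=False)
            manifest["bonferroni"] = {"m": m, "critical_p": bonferroni_critical_p(m=m)}

    if config.interpret and result is not None and result.decoders:
        with stage("interpret"):
            from .decoder import build_lagged_design

            design, valid = build_lagged_design(feats.values)
            shares = []
            for dec, (train, _) in zip(result.decoders, result.splits):
                rows = np.flatnonzero(np.isin(frames.trial_id, train) & valid)
                move_rows = rows[frames.movement[rows]]
                pat = compute_activation_patterns(
                    dec.movement_model.coef, design[move_rows],
                    dec.layout, ["speed", "vx", "vy", "vz"],
                )
                shares.append(summarize_importance(pat, "speed")["channel_share"])
            imp = pd.DataFrame(
                {"channel": np.arange(config.n_channels),
                 "speed_importance": np.mean(shares, axis=0)}
            )
            imp.to_csv(out / "importance.tsv", sep="\t", index=False)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = rio.file_sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
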