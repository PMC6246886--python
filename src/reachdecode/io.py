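"""Serialization of datasets and results.

Voltages go to ``.npy`` (with a JSON sidecar for rate and channel
bookkeeping), kinematics and trial tables to TSV, configurations and
encodings to JSON.  EDF export is deliberately not provided: no EDF
library is available in the supported stack, and the plain formats here
round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import GroundTruthEncoding, SyntheticDataset, trial_table

__all__ = [
    "save_dataset",
    "load_kinematics_tsv",
    "save_encoding",
    "load_encoding",
    "file_sha256",
    "config_hash",
]


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_encoding(encoding: GroundTruthEncoding, path: Path) -> None:
    payload = {k: v for k, v in dataclasses.asdict(encoding).items()}
    Path(path).write_text(json.dumps(payload, default=_json_default, indent=1))


def load_encoding(path: Path) -> GroundTruthEncoding:
    payload = json.loads(Path(path).read_text())
    arrays = {k: np.asarray(payload.pop(k)) for k in ("w_s", "w_v", "lag_ms", "baseline_amp")}
    return GroundTruthEncoding(**arrays, **payload)


def save_dataset(ds: SyntheticDataset, out_dir: Path) -> dict[str, Path]:
    """Write a synthetic session: voltages, kinematics, trials, encoding."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["voltages"] = out / "voltages.npy"
    np.save(paths["voltages"], ds.voltages)
    meta = {"fs": ds.fs, "n_channels": ds.n_channels,
            "config": ds.config.to_dict() if ds.config else None}
    paths["meta"] = out / "recording.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    kin = pd.DataFrame(
        {"t": ds.kin_t, "x": ds.kin_position[:, 0],
         "y": ds.kin_position[:, 1], "z": ds.kin_position[:, 2]}
    )
    paths["kinematics"] = out / "kinematics.tsv"
    kin.to_csv(paths["kinematics"], sep="\t", index=False)
    paths["trials"] = out / "trials.tsv"
    trial_table(ds.trials).to_csv(paths["trials"], sep="\t", index=False)
    paths["encoding"] = out / "encoding.json"
    save_encoding(ds.encoding, paths["encoding"])
    return paths


def load_kinematics_tsv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (t, x, y, z) TSV back into time and position arrays."""
    df = pd.read_csv(path, sep="\t")
    return df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy()


def file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=_json_default).encode()
    ).hexdigest()[:16]
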