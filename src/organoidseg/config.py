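"""Flat run configuration: one serializable provenance artifact per run.

A 440-launch experiment needs a single file that pins everything the run
depended on — paths, frame size, architecture and strategy selection,
training hyperparameters, classical-method parameters, seed, aggregation
and palette choices.  ``RunConfig`` round-trips through YAML; unknown keys
are rejected rather than silently ignored.
"""

from __future__ import annotations

import hashlib
import json
import os
import platform
from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    """Every field has a documented default; see attribute comments."""

    data_dir: str = "data"          # dataset directory (images/, masks/, manifest.csv)
    out_dir: str = "out"            # run outputs (logs, folds, tables, overlays)
    side: int = 250                 # frame size; 64 is the desk-scale setting
    architecture: str = "munet"     # preset name, see architectures.PRESETS
    strategies: list[str] = field(default_factory=lambda: ["classic"])
    n_originals: int = 40           # originals in the leave-one-out loop
    group_size: int = 40            # augmented items per fold
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 10              # early-stop plateau patience (epochs)
    min_delta: float = 1e-4         # minimum loss improvement counted
    threshold: float = 0.5          # probability binarization threshold
    fixed_threshold: float = 185    # classical threshold, 0-255 scale
    region_threshold: float = 0.2   # region-growing acceptance tolerance
    growth_size: int = 1            # region-growing frontier dilation (px)
    polarity: str = "dark"          # organoid darker ("dark") or brighter
    aggregation: str = "median"     # per-image metric aggregation
    palette: str = "pink-green"     # overlay accent palette
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(out_dir: str | os.PathLike, config: RunConfig) -> str:
    """Drop a reproducibility manifest (config, hash, seed, versions)."""
    import numpy, scipy, skimage  # noqa: PLC0415 — recorded versions

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "config_hash": config.digest(),
                "seed": config.seed,
                "versions": {
                    "python": platform.python_version(),
                    "numpy": numpy.__version__,
                    "scipy": scipy.__version__,
                    "scikit-image": skimage.__version__,
                },
                "note": "training backend is deterministic under the seed",
            },
            fh,
            indent=1,
        )
    return path
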