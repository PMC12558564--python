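"""Pipeline configuration: every threshold and seed, serializable and hashable.

A run is a pure function of its config; the config's SHA-256 hash is embedded
in the run manifest so outputs are auditable. Flags on the CLI override the
config file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # randomness
    seed: int = 1
    # synthetic world
    n_participants: int = 33
    ci_fraction: float = 14 / 33
    days: int = 7
    map_rows: int = 6
    map_cols: int = 6
    jitter_sd_m: float = 3.0
    jitter_corr_s: float = 200.0
    dropout_rate: float = 1 / 300
    spike_rate: float = 1 / 600
    # track pipeline
    mode_threshold: float = 1.39
    band_low: float = 0.30
    min_samples: int = 20
    min_displacement: float = 20.0
    max_gap: float = 2.0
    max_speed: float = 5.0
    max_distance_km: float = 10.0
    smooth_window: int = 3
    # exposure
    buffer_m: float = 1000.0
    cell_m: float = 25.0
    # statistics
    alpha: float = 0.05
    adjust: bool = False
    # artifact handling
    write_streams: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
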