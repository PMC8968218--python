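"""Run configuration: one YAML file drives the whole pipeline.

A master seed deterministically derives one seed per stage (via a stable
hash of ``(master_seed, stage_name)``), so skipping or reordering stages
never silently changes another stage's random stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "stage_seed", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


_PROFILES = {
    # CI-sized: 6 constructs, reduced replicates/iterations
    "test": {
        "simulate": {"n": 1200, "missing_rate": 0.02, "battery": "small"},
        "preprocess": {"m": 2, "iterations": 4},
        "ggm": {"gamma": 0.5, "n_penalties": 40},
        "boot": {"B": 150, "case_drop_B": 20, "case_drop_fracs": [0.25, 0.5, 0.75]},
        "dag": {"sampler": "partition", "iterations": 150_000, "target_samples": 1500},
        "effects": {"focus": ["dissociation", "cad"]},
    },
    # mirrors the published analysis scale
    "full": {
        "simulate": {"n": 6161, "missing_rate": 0.02, "battery": "study"},
        "preprocess": {"m": 5, "iterations": 10},
        "ggm": {"gamma": 0.5, "n_penalties": 100},
        "boot": {"B": 5000, "case_drop_B": 250, "case_drop_fracs": list(
            round(0.05 * k, 2) for k in range(1, 16))},
        "dag": {"sampler": "partition", "iterations": 10_000_000, "target_samples": 50_000},
        "effects": {"focus": ["dissociation", "cad"]},
    },
}


@dataclass
class RunConfig:
    master_seed: int = 1
    profile: str = "test"
    out_dir: str = "results/run"
    data_csv: str | None = None       # external data; otherwise simulate
    data_sidecar: str | None = None
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    ggm: dict = field(default_factory=dict)
    boot: dict = field(default_factory=dict)
    dag: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ConfigError(f"unknown profile {self.profile!r}")
        base = _PROFILES[self.profile]
        for stage in ("simulate", "preprocess", "ggm", "boot", "dag", "effects"):
            merged = dict(base[stage])
            merged.update(getattr(self, stage))
            setattr(self, stage, merged)
        self.validate()

    def validate(self) -> None:
        et = self.effects.get("edge_threshold", 0.50)
        dt = self.effects.get("direction_threshold", 0.90)
        if not 0 < et <= 1 or not 0 < dt <= 1:
            raise ConfigError("thresholds must lie in (0, 1]")
        if dt < et:
            raise ConfigError(
                f"direction_threshold ({dt}) must not be below edge_threshold ({et})"
            )
        if self.dag.get("sampler") not in ("partition", "edge_mh"):
            raise ConfigError(f"unknown sampler {self.dag.get('sampler')!r}")
        if self.preprocess.get("m", 1) < 1:
            raise ConfigError("preprocess.m must be >= 1")
        if self.boot.get("B", 100) < 100:
            raise ConfigError("boot.B must be >= 100")
        if (self.data_csv is None) != (self.data_sidecar is None):
            raise ConfigError("data_csv and data_sidecar must be given together")

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
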