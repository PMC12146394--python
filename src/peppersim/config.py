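"""Run configuration: YAML loading with strict key validation, derived
per-stage seeds, and provenance headers stamped into every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__

__all__ = ["RunConfig", "load_config", "dump_config", "derive_seed", "provenance_header"]

_STOCHASTIC_STAGES = {"synth", "scenario"}


@dataclass
class RunConfig:
    """Validated configuration for a CLI run."""

    stage: str = "simulate"
    params: str | None = None       # registry path, or None for the packaged registry
    accession: str = "PHR18"
    condition: str = "control"
    setting: str = "greenhouse"
    weather: str | None = None      # CSV path, or None to generate
    latitude_band: str = "central"
    years: list[int] = field(default_factory=lambda: [2022])
    management: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    seed: int | None = None
    out: str | None = None
    log_level: str = "INFO"
    force: bool = False

    def __post_init__(self) -> None:
        if self.stage in _STOCHASTIC_STAGES and self.seed is None:
            raise ValueError(
                f"stage {self.stage!r} is stochastic: an integer 'seed' is required"
            )


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}; known keys: {sorted(known)}")
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(seed: int, *keys: int) -> int:
    """Per-stage seed derived from the one config seed; always below 2**31."""
    return int(np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)[0] % (2**31))


def provenance_header(seed: int | None = None, cfg: RunConfig | None = None) -> str:
    parts = [f"peppersim v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg is not None:
        parts.append(f"config_sha={config_hash(cfg)}")
    return " ".join(parts)
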