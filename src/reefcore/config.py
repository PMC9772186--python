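"""Pipeline configuration and run manifest.

The configuration is a flat, typed key-value mapping (YAML on disk) so runs
are diff-friendly and language-agnostic; unknown keys are rejected.  Every
run writes a manifest recording the tool version, a hash of the effective
configuration, checksums of input files, seeds, per-stage record counts and
accumulated warnings — reruns with an identical manifest input block produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "RunManifest", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class PipelineConfig:
    """Flat configuration for an end-to-end run."""

    out_dir: str = "reefcore_out"
    seed: int = 0

    # synthetic cohort
    simulate: bool = True
    n_per_pop: int = 30
    k_lineages: int = 4
    divergence_f: float = 0.3
    n_loci: int = 200
    missing_rate: float = 0.02
    stress_prob_db: float = 0.68
    stress_prob_lb: float = 0.22
    stress_prob_pi: float = 0.17
    stress_prob_rd: float = 0.25

    # densitometry
    window_start: int = 1999
    window_end: int = 2009
    min_thickness_mm: float = 1.0
    z_threshold: float = 2.0

    # thermal
    short_cutoff_h: float = 5.0
    long_cutoff_h: float = 36.0
    filter_order: int = 4

    # popgen
    k_fit: int = 4
    n_restarts: int = 3
    max_iter: int = 300
    n_boot: int = 100

    # external inputs (used when simulate is false)
    profiles_dir: str | None = None
    loggers_dir: str | None = None
    vcf_path: str | None = None
    microsat_path: str | None = None
    metadata_path: str | None = None

    _BOUNDS = {
        "n_per_pop": (2, 10_000),
        "k_lineages": (1, 12),
        "divergence_f": (1e-6, 0.999999),
        "n_loci": (1, 1_000_000),
        "missing_rate": (0.0, 0.99),
        "window_start": (1900, 2100),
        "window_end": (1900, 2100),
        "min_thickness_mm": (1e-6, 1e3),
        "z_threshold": (1e-6, 100),
        "short_cutoff_h": (0.1, 1e4),
        "long_cutoff_h": (0.1, 1e5),
        "filter_order": (1, 16),
        "k_fit": (1, 12),
        "n_restarts": (1, 1000),
        "max_iter": (1, 100_000),
        "n_boot": (0, 100_000),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._BOUNDS.items():
            val = getattr(self, key)
            if not lo <= val <= hi:
                raise ConfigError(f"{key}={val} outside documented bounds [{lo}, {hi}]")
        if self.window_start > self.window_end:
            raise ConfigError("window_start must not exceed window_end")
        if self.short_cutoff_h >= self.long_cutoff_h:
            raise ConfigError("short_cutoff_h must be below long_cutoff_h")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if not f.name.startswith("_")
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @staticmethod
    def checksum(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
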