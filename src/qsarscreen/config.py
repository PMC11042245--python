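"""Run configuration: one YAML file, CLI overrides, provenance fingerprint."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .curation import CurationConfig
from .fingerprints import FingerprintConfig


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serialisable for provenance.

    Precedence is CLI flag > config file > defaults.  The master seed is
    mandatory and every stage derives its own seed from it, so a RunConfig
    fully determines every artifact.
    """

    seed: int = 0
    output_dir: str = "runs/default"
    activity_threshold: float = 7.0
    keep_qualifiers: list[str] = field(default_factory=lambda: ["="])
    fingerprint_radius: int = 3
    fingerprint_bits: int = 512
    cv_k: int = 5
    cv_inner_k: int = 3
    train_fraction: float = 0.9
    screening_mode: str = "threshold"
    screening_threshold: float = 7.0
    screening_top_k: int = 200
    tsne_perplexity: float = 30.0
    tsne_iterations: int = 1000
    model_grids: dict = field(default_factory=dict)
    synthetic_n: int = 400
    synthetic_noise_sd: float = 0.4
    synthetic_active_fraction: float = 0.57

    def curation_config(self) -> CurationConfig:
        return CurationConfig(
            activity_threshold=self.activity_threshold,
            keep_qualifiers=frozenset(self.keep_qualifiers),
        )

    def fingerprint_config(self) -> FingerprintConfig:
        return FingerprintConfig(
            radius=self.fingerprint_radius, n_bits=self.fingerprint_bits
        )

    def fingerprint(self) -> str:
        """Short hash of the full config, embedded in every artifact."""
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["config_fingerprint"] = self.fingerprint()
        return d

    @staticmethod
    def load(path: str | Path | None = None, overrides: dict | None = None) -> "RunConfig":
        data: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text())
            if loaded is not None:
                if not isinstance(loaded, dict):
                    raise ValueError(f"config file {path} must hold a mapping")
                data.update(loaded)
        for key, value in (overrides or {}).items():
            if value is not None:
                data[key] = value
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**data)
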