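"""Run configuration and provenance manifests for the pipeline CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/demo",
    "simulate": {
        "n_aggressive": 3,
        "n_parental": 2,
        "n_ignoring": 1,
        "duration_s": 600.0,
        "n_neurons": 30,
        "frame_rate": 20.0,
        "noise_sd": 1.0,
        "state_shift": -5.0,
        "cohort_n": 126,
        "bleach_tau_s": 300.0,
        "motion_sd": 0.05,
    },
    "behavior": {"pooled_transitions": True},
    "switching": {"ci_level": 0.99},
    "photometry": {"window_s": 20.0, "centred": True},
    "tuning": {"alpha": 0.05, "zscore_window_s": 5.0},
    "population": {
        "k_range": [1, 2, 3, 4, 5, 6],
        "em_iterations": 50,
        "decode_iterations": 50,
        "variance_target": 0.90,
        "usable_threshold": 0.70,
        "overlap_threshold": 0.5,
        "min_episode_s": 2.0,
    },
}


@dataclass
class RunConfig:
    """Structured pipeline configuration with per-module namespaces.

    Round-trips losslessly through YAML; unknown top-level keys are rejected
    so typos fail loudly with the offending key path.
    """

    data: dict = field(default_factory=lambda: _merge(DEFAULT_CONFIG, {}))

    def __post_init__(self) -> None:
        unknown = set(self.data) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"invalid config key(s): {sorted(unknown)}")
        for section, value in self.data.items():
            if isinstance(DEFAULT_CONFIG[section], dict):
                bad = set(value) - set(DEFAULT_CONFIG[section])
                if bad:
                    raise KeyError(
                        f"invalid config key(s): {[f'{section}.{k}' for k in sorted(bad)]}"
                    )
        self.data = _merge(DEFAULT_CONFIG, self.data)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.data["out_dir"])

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        return cls(yaml.safe_load(p.read_text()) or {})

    def section_hash(self, section: str) -> str:
        payload = {
            "seed": self.seed,
            section: self.data.get(section, {}),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        o = override.get(k)
        out[k] = _merge(v, o or {}) if isinstance(v, dict) else (o if k in override else v)
    return out


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, stage: str, cfg: RunConfig, inputs: list, outputs: list) -> Path:
    """Record a stage's provenance: inputs, config hash, seed, output hashes.

    Contains no timestamps, so reruns with identical config and seeds yield
    byte-identical manifests.
    """
    from . import __version__

    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.section_hash(stage if stage in cfg.data else "simulate"),
        "inputs": [str(p) for p in inputs],
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
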