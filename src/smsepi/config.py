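"""Structured pipeline configuration (YAML) and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "write_manifest", "sha256_file"]

_SCHEMA: dict[str, dict] = {
    "phantom": {"n_slices": 4, "grid": 48, "signal_scale": 1.0},
    "coils": {"n_coils": 6, "smoothness": 8.0, "per_slice": True},
    "plan": {
        "n_segments": 4,
        "mb": 4,
        "f": 4,
        "te_list": [9.0, 21.5, 34.0],
        "tr": 261.0,
        "ets": 0.0,
        "n_frames": 3,
        "dead_time": 0.0,
    },
    "acquisition": {"fa": 90.0, "noise_sd": 0.0, "ghost_const": 0.0,
                    "ghost_linear": 0.0},
    "bolus": {
        "enabled": False,
        "t0": 10.0,
        "alpha": 3.0,
        "beta": 2.0,
        "peak_conc": 1.0,
        "r1": 4.0,
        "r2s": 5.0,
        "steady_level": 0.15,
        "recirculation_fraction": 0.15,
        "tissue_delay": 3.0,
        "tissue_mtt": 8.0,
        "vascular_labels": [2],
        "tissue_labels": [1],
    },
    "recon": {"method": 2, "algo": "sg", "policy": "acs111",
              "kernel_size": [5, 5], "lam": 1e-4, "phase_correct": True},
    "qa": {"gfactor": False, "n_replicas": 20, "gfactor_noise_sd": 0.02},
    "relax": {"t2s_max": 2000.0},
}

_TOP_LEVEL = {"seed", "output_dir", "log_level"} | set(_SCHEMA)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "smsepi_out"
    log_level: str = "INFO"
    sections: dict = field(default_factory=dict)

    def __getitem__(self, section: str) -> dict:
        merged = dict(_SCHEMA[section])
        merged.update(self.sections.get(section, {}))
        return merged

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "output_dir": self.output_dir,
             "log_level": self.log_level}
        d.update({k: self[k] for k in _SCHEMA})
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(source) -> PipelineConfig:
    """Build a config from a YAML path, YAML text or a plain dict.

    Unknown top-level or section keys raise a ``ValueError`` naming them.
    """
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sections = {}
    for name, defaults in _SCHEMA.items():
        given = raw.get(name, {}) or {}
        bad = set(given) - set(defaults)
        if bad:
            raise ValueError(f"unknown keys in section '{name}': {sorted(bad)}")
        sections[name] = given
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "smsepi_out")),
        log_level=str(raw.get("log_level", "INFO")),
        sections=sections,
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: PipelineConfig, artifacts: dict[str, Path],
                   stage: str) -> Path:
    """Record config hash, seed and artifact checksums for one stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    manifest["stages"][stage] = {
        str(k): {"path": str(v), "sha256": sha256_file(v)}
        for k, v in artifacts.items()
        if Path(v).exists()
    }
    path.write_text(json.dumps(manifest, indent=2))
    return path
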