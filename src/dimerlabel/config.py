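"""YAML configuration round-trips and run provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import yaml

from . import __version__
from .scene import SceneSpec


def scene_spec_to_yaml(spec: SceneSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    for key in ("shape", "separation_bounds", "tilt_range", "membrane_pair"):
        if d[key] is not None:
            d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def scene_spec_from_yaml(path: str | Path) -> SceneSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SceneSpec)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown SceneSpec keys: {', '.join(sorted(unknown))}")
    for key in ("shape", "separation_bounds", "tilt_range", "membrane_pair"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return SceneSpec(**data)


def config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(output_path: str | Path, config, seed: int | None) -> Path:
    """Sidecar JSON recording config hash, seed, and versions next to an output."""
    sidecar = Path(str(output_path) + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "output": str(output_path),
                "config_hash": config_hash(config),
                "seed": seed,
                "dimerlabel_version": __version__,
                "python": sys.version.split()[0],
            },
            indent=2,
        )
    )
    return sidecar
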