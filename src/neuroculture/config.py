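"""Configuration round-tripping, seeded RNG hierarchy and writers.

Experiment specs are flat-ish dataclasses; they serialize to YAML and
load back with field-level validation (a missing or unknown field raises
an error naming it).  Every output file is stamped with a short hash of
the canonical config so results can be traced to the exact settings that
produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "config_save",
    "config_load",
    "config_hash",
    "seeded_rng",
    "child_seed",
    "write_csv_with_provenance",
]


def _plain(value):
    """Recursively convert to YAML/JSON-safe builtins."""
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return config_to_dict(value)
    return value


def config_to_dict(spec) -> dict:
    if not dataclasses.is_dataclass(spec):
        raise TypeError(f"expected a dataclass instance, got {type(spec)}")
    return {f.name: _plain(getattr(spec, f.name)) for f in dataclasses.fields(spec)}


def config_from_dict(cls, data: dict):
    """Rebuild a dataclass, naming any missing or unknown field."""
    if not isinstance(data, dict):
        raise ValueError(f"config for {cls.__name__} must be a mapping, got {type(data)}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown field(s) for {cls.__name__}: {sorted(unknown)}")
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(data)
    if missing:
        raise ValueError(f"missing required field(s) for {cls.__name__}: {sorted(missing)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_save(spec, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(spec), sort_keys=True))


def config_load(cls, path):
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(cls, data)


def config_hash(spec) -> str:
    """12-hex-digit digest of the canonical JSON form of a config."""
    payload = json.dumps(config_to_dict(spec), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def child_seed(seed: int, *keys: str) -> int:
    """Stable sub-seed (< 2**31) derived from a root seed and string keys."""
    h = hashlib.sha256(str(seed).encode())
    for k in keys:
        h.update(b"/" + str(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def seeded_rng(seed: int, *keys: str) -> np.random.Generator:
    """Generator for one named branch of the experiment's seed hierarchy."""
    return np.random.default_rng(child_seed(seed, *keys))


def write_csv_with_provenance(df, path, spec=None, extra: dict | None = None) -> None:
    """Write a DataFrame as CSV preceded by ``#``-comment provenance lines
    (config hash and any extra key/values)."""
    lines = []
    if spec is not None:
        lines.append(f"# config_hash: {config_hash(spec)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    body = df.to_csv(index=False)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)
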