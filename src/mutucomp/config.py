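"""Config files, parameter round-tripping and result serialization.

JSON is the canonical config format; YAML is accepted.  Numbers are written
with 17 significant digits so that params -> file -> params is the identity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .params import ChemostatParams, ExtendedLVParams

_OPERATIONS = ("simulate", "reduce", "fixedpoints", "basins", "scan",
               "branches", "survey")


class ConfigError(ValueError):
    """Raised on schema violations, with the offending field in the message."""


@dataclass
class RunConfig:
    model: str                       # "chemostat" | "elv"
    params: ChemostatParams | ExtendedLVParams
    operation: str
    options: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None
    tolerances: dict = field(default_factory=dict)


def params_from_dict(model: str, d: dict) -> ChemostatParams | ExtendedLVParams:
    cls = {"chemostat": ChemostatParams, "elv": ExtendedLVParams}.get(model)
    if cls is None:
        raise ConfigError(f"model must be 'chemostat' or 'elv', got {model!r}")
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(
            f"unknown parameter field(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}")
    missing = known - set(d)
    if missing:
        raise ConfigError(f"missing parameter field(s) {sorted(missing)}")
    return cls(**{k: float(v) for k, v in d.items()})


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON/YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed = {"model", "params", "operation", "options", "seed", "out",
               "tolerances"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")
    for key in ("model", "params", "operation"):
        if key not in raw:
            raise ConfigError(f"missing required key {key!r}")
    op = raw["operation"]
    if isinstance(op, dict):
        if len(op) != 1:
            raise ConfigError("operation block must contain exactly one entry")
        (op_name, op_opts), = op.items()
    else:
        op_name, op_opts = op, {}
    if op_name not in _OPERATIONS:
        raise ConfigError(f"operation must be one of {_OPERATIONS}, "
                          f"got {op_name!r}")
    params = params_from_dict(raw["model"], raw["params"])
    return RunConfig(model=raw["model"], params=params, operation=op_name,
                     options=dict(op_opts or {}), seed=int(raw.get("seed", 0)),
                     out_dir=raw.get("out"),
                     tolerances=dict(raw.get("tolerances", {})))


def _fmt(v) -> float:
    return float(f"{float(v):.17g}")


def config_dict(model: str, params, operation: str = "simulate",
                options: dict | None = None, seed: int = 0) -> dict:
    return {
        "model": model,
        "params": {k: _fmt(v) for k, v in params.to_dict().items()},
        "operation": {operation: options or {}},
        "seed": seed,
    }


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# outputs
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_trajectory_csv(traj, path: str | Path) -> None:
    import pandas as pd

    cols = traj.column_names()
    df = pd.DataFrame(np.column_stack([traj.times, traj.states]), columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


def write_outputs(files: dict[str, str | bytes], out_dir: str | Path,
                  config_echo: dict | None = None, seed: int = 0) -> dict:
    """Write result files plus a manifest with hashes and the config echo.

    ``files`` maps relative file names to already-rendered text content.
    Returns the manifest (also written as ``manifest.json``).  Byte-stable
    for deterministic operations under a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, content in files.items():
        target = out / name
        if isinstance(content, bytes):
            target.write_bytes(content)
        else:
            target.write_text(content)
        entries[name] = _sha256(target)
    import mutucomp

    manifest = {
        "files": entries,
        "seed": seed,
        "config": config_echo or {},
        "version": getattr(mutucomp, "__version__", "unknown"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
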