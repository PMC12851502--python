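"""Config files, table writers and run manifests.

Configs are flat key-value text files with dotted keys, e.g.::

    utilities.injured.query = -16
    observations.query = HI

Every run writes its fully resolved config (defaults included) next to its
outputs, and a JSON manifest (resolved config, seeds, solver metadata, file
checksums) from which the run can be replayed bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .model import CONFIG_SCHEMA, ConfigurationError, resolve_config

#: fixed float format for CSV output so reproduction checks are bit-stable
CSV_FLOAT_FORMAT = "%.12g"


def parse_config_text(text: str) -> dict[str, object]:
    """Parse the dotted key-value dialect; '#' starts a comment."""
    raw: dict[str, object] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigurationError(
                f"line {lineno}: expected 'key = value', got {stripped!r}"
            )
        key, value = (part.strip() for part in stripped.split("=", 1))
        if key in raw:
            raise ConfigurationError(f"line {lineno}: duplicate key {key!r}")
        raw[key] = value
    return raw


def load_config(path: "str | Path") -> dict[str, object]:
    """Read a config file and return the fully resolved mapping.

    Unknown keys are rejected by name; values are coerced to the schema
    types. An empty file resolves to the complete default configuration.
    """
    return resolve_config(parse_config_text(Path(path).read_text()))


def save_config(config: Mapping[str, object], path: "str | Path") -> None:
    """Write a fully resolved config, one dotted key per line."""
    lines = [f"{key} = {config[key]}" for key in CONFIG_SCHEMA if key in config]
    for key in config:
        if key not in CONFIG_SCHEMA:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(frame: pd.DataFrame, path: "str | Path") -> None:
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_json(payload, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def sha256_file(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to replay one experiment run bit-exactly."""

    experiment: str
    version: str
    resolved_config: dict
    params: dict
    base_seed: int
    solver: dict
    files: dict[str, str]  # filename -> sha256
    wall_time_s: float  # informational only

    def write(self, path: "str | Path") -> None:
        write_json(dataclasses.asdict(self), path)

    @classmethod
    def read(cls, path: "str | Path") -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def build_manifest(
    experiment: str,
    resolved_config: Mapping[str, object],
    params: Mapping[str, object],
    base_seed: int,
    solver_meta: Mapping[str, object],
    outdir: "str | Path",
    filenames: list[str],
    wall_time_s: float,
) -> RunManifest:
    outdir = Path(outdir)
    return RunManifest(
        experiment=experiment,
        version=__version__,
        resolved_config=dict(resolved_config),
        params=dict(params),
        base_seed=base_seed,
        solver=dict(solver_meta),
        files={name: sha256_file(outdir / name) for name in filenames},
        wall_time_s=wall_time_s,
    )
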