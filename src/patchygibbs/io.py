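"""File formats: extended-XYZ configurations, TSV sample streams, TOML run
configs and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SAMPLE_COLUMNS
from .model import Configuration, ModelParams

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_samples",
    "read_samples",
    "load_config",
    "write_manifest",
]

_SPECIES_TAG = {0: "P", 1: "R"}
_TAG_SPECIES = {"P": 0, "R": 1}


def write_xyz(
    path: str | Path,
    config: Configuration,
    params: ModelParams | None = None,
) -> None:
    """Extended-XYZ dialect: species tag, position, orientation quaternion.

    The comment line carries the box edge and (optionally) a parameter-set
    hash.  Values are printed at 17 significant digits so a round trip is
    bit-exact.
    """
    lines = [str(len(config))]
    comment = f"box_edge={config.box_edge!r}"
    if params is not None:
        comment += f" params_hash={params.content_hash()}"
    comment += ' Properties=species:S:1:pos:R:3:orientation:R:4'
    lines.append(comment)
    for i in range(len(config)):
        tag = _SPECIES_TAG[int(config.species[i])]
        vals = list(config.positions[i]) + list(config.orientations[i])
        lines.append(tag + " " + " ".join(f"{v:.17g}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> Configuration:
    """Read a configuration written by :func:`write_xyz`."""
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0])
    comment = text[1]
    box_edge = None
    for tok in comment.split():
        if tok.startswith("box_edge="):
            box_edge = float(tok.split("=", 1)[1])
    if box_edge is None:
        raise ValueError(f"{path}: comment line lacks box_edge=")
    pos = np.zeros((n, 3))
    quat = np.zeros((n, 4))
    spec = np.zeros(n, dtype=np.int64)
    for i in range(n):
        parts = text[2 + i].split()
        spec[i] = _TAG_SPECIES[parts[0]]
        pos[i] = [float(x) for x in parts[1:4]]
        quat[i] = [float(x) for x in parts[4:8]]
    return Configuration(pos, quat, spec, box_edge)


def write_samples(path: str | Path, samples: pd.DataFrame) -> None:
    """Sample stream as TSV with a fixed column order and header line."""
    cols = [c for c in SAMPLE_COLUMNS if c in samples.columns]
    extra = [c for c in samples.columns if c not in cols]
    samples[cols + extra].to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for box in ("a", "b"):
        if f"rho_P_{box}" not in df.columns:
            df[f"rho_P_{box}"] = df[f"n_P_{box}"] / df[f"volume_{box}"]
            df[f"rho_R_{box}"] = df[f"n_R_{box}"] / df[f"volume_{box}"]
    return df


_REQUIRED = {
    "model": ["chi", "lam", "eps_PP", "eps_PR", "eps_RR"],
    "system": ["n_total", "x_ratio", "rho0", "temperature"],
    "schedule": ["n_displacement", "n_exchange", "n_volume"],
    "run": ["n_equil_cycles", "n_collect_cycles", "sample_stride", "seed"],
}


def load_config(path: str | Path) -> dict:
    """Parse and validate a TOML run configuration.

    All physics keys are required; there are no silent defaults.  Optional
    schedule keys: max_translation, max_rotation, max_ln_volume_change.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for section, keys in _REQUIRED.items():
        if section not in cfg:
            raise KeyError(f"config missing [{section}] section")
        for key in keys:
            if key not in cfg[section]:
                raise KeyError(f"config missing {section}.{key}")
    return cfg


def write_manifest(path: str | Path, config: dict, extra: dict | None = None) -> None:
    """JSON run manifest: full config echo plus a content hash."""
    payload = {"config": config}
    if extra:
        payload.update(extra)
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["content_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
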