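"""Deterministic writers and config loading for the pipeline CLI."""

from __future__ import annotations

import hashlib
import json
import os
from typing import Any

import pandas as pd
import yaml

__all__ = ["write_tsv", "write_bed", "load_config", "config_hash", "write_manifest"]

FLOAT_FORMAT = "%.6g"  # fixed so reruns are byte-identical


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_bed(reads: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    write_tsv(reads[cols].rename(columns=dict(zip(cols, cols))), path)


def load_config(path: str) -> dict[str, Any]:
    """YAML config (JSON is valid YAML, so both are accepted)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(outdir: str, cfg: dict[str, Any], seed: int, command: str) -> None:
    from trdecomp import __version__

    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256_16": config_hash(cfg),
        "trdecomp_version": __version__,
    }
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
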