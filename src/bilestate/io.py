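"""Small-format helpers: GMT gene sets and cohort config files."""

from __future__ import annotations

import os
from typing import Mapping

import yaml

from .exceptions import FormatError


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into ``{set name: [genes]}`` (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need name, description and >=1 gene"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, list[str]], path: str | os.PathLike, description: str = "."
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_config(path: str | os.PathLike) -> dict:
    """Read a YAML cohort/pipeline config into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    if "cnv_segments" in cfg:
        cfg["cnv_segments"] = [tuple(seg) for seg in cfg["cnv_segments"]]
    return cfg
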