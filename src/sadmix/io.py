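"""Delimited-text I/O, run configuration and run manifests.

File formats (all plain delimited text, comma by default, tab accepted):

* phenotypes — wide: header ``animal,time,<trait1>,<trait2>,...[,covariates]``,
  one row per animal x parity, missing trait cells marked by the missing
  token ("NA" default); parities are 1-based integers;
* pedigree — ``animal,sire,dam`` with a configurable missing-parent token
  ("0" default);
* model config — the YAML serialization of :class:`~sadmix.spec.ModelSpec`
  (lossless round-trip);
* matrices / heritability / selection traces — labelled CSV tables.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PhenotypeTable
from .spec import ModelSpec, SpecError

__all__ = ["read_phenotypes", "write_phenotypes", "RunConfig", "write_manifest"]


def read_phenotypes(
    path,
    spec: ModelSpec,
    sep: str = ",",
    missing_token: str = "NA",
    extra_columns=None,
) -> PhenotypeTable:
    """Read a wide phenotype file and return the long-format table.

    Missing trait cells (the missing token or empty) are dropped and counted;
    duplicate (animal, time) rows and malformed rows raise with their line
    number.  Covariate columns listed in the spec's fixed effects (plus any
    ``extra_columns``) are carried along.
    """
    df = pd.read_csv(path, sep=sep, na_values=[missing_token], keep_default_na=False)
    required = {"animal", "time"}
    if not required.issubset(df.columns):
        raise SpecError(f"phenotype file must have columns {sorted(required)}")
    for t in spec.traits:
        if t not in df.columns:
            raise SpecError(f"phenotype file lacks trait column '{t}'")
    dup = df.duplicated(subset=["animal", "time"])
    if dup.any():
        line = int(df.index[dup][0]) + 2  # +1 header, +1 one-based
        raise SpecError(f"duplicate (animal, time) row at line {line}")
    try:
        df["time"] = df["time"].astype(float)
    except (TypeError, ValueError) as err:
        raise SpecError(f"non-numeric time value in {path}: {err}") from None
    wanted = {fe.column for fe in spec.fixed_effects if fe.column not in ("time",)}
    wanted |= {ri.column for ri in spec.extra_random_intercepts}
    if extra_columns:
        wanted |= set(extra_columns)
    missing_cols = wanted - set(df.columns)
    if missing_cols:
        raise SpecError(f"phenotype file lacks columns {sorted(missing_cols)}")
    n_missing = int(df[list(spec.traits)].isna().sum().sum())
    table = PhenotypeTable.from_wide(df, spec.traits, extra_columns=sorted(wanted))
    table.n_missing_cells = n_missing
    return table


def write_phenotypes(table: PhenotypeTable, path, spec: ModelSpec, sep: str = ",",
                     missing_token: str = "NA") -> None:
    wide = table.to_wide(spec.traits)
    wide["time"] = wide["time"].astype(float).map(lambda t: int(t) if t == int(t) else t)
    wide.to_csv(path, sep=sep, index=False, na_rep=missing_token)


@dataclass
class RunConfig:
    """Paths and options of a command-line run."""

    phenotypes: str | None = None
    pedigree: str | None = None
    model_config: str | None = None
    output_dir: str = "."
    seed: int = 0
    alpha_sig: float = 0.05
    multi_start: int = 3
    maxiter: int = 500
    sep: str = ","
    verbosity: int = 1


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, inputs: dict | None = None, extra: dict | None = None):
    """Record everything needed to reproduce a run: input hashes, options,
    seed and package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sadmix",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "options": {
            "alpha_sig": config.alpha_sig,
            "multi_start": config.multi_start,
            "maxiter": config.maxiter,
            "sep": config.sep,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _file_hash(p)}
            for name, p in (inputs or {}).items()
            if p is not None
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    tmp.replace(path)
    return path


def write_matrix(frame: pd.DataFrame, path, sep: str = ",") -> None:
    frame.to_csv(path, sep=sep)


def read_matrix(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)
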