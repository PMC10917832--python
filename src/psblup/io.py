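"""Readers and writers for the canonical tab-separated tables.

All tables are UTF-8 TSV with a header row:

* phenotypes: clone, env, trial, block, row, column, trait, value
* spectra:    clone, env, trial, block, row, column, flight_date, channel, value
* genotypes:  wide, clone + one column per marker, dosages 0-4 (blank = missing)
* pedigree:   clone, family, parent1, parent2, is_check
* kernels:    square matrix with clone ids as header and first column, plus a
  JSON sidecar (<name>.meta.json) carrying kind and provenance

Environment codes are a location letter followed by a 2-digit year ("W20");
design coordinates are 1-based.  The run configuration is a YAML file with
strict (unknown keys rejected) fields.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import RelationshipMatrix
from .simulate import PLOT_COLUMNS, SPECTRA_COLUMNS

__all__ = [
    "RunConfig",
    "load_config",
    "read_phenotypes",
    "write_phenotypes",
    "read_spectra",
    "write_spectra",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_kernel",
    "write_kernel",
    "load_dataset",
    "Dataset",
]

ENV_CODE = re.compile(r"^[A-Z][0-9]{2}$")


def _check_env_codes(values, file: str) -> None:
    bad = sorted({v for v in values if not ENV_CODE.match(str(v))})
    if bad:
        raise ValueError(f"{file}: invalid environment codes {bad}; expected "
                         "a location letter plus 2-digit year, e.g. 'W20'")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    _check_env_codes(df["env"].unique(), str(path))
    dup = df.duplicated(subset=["clone", "env", "block", "row", "column",
                                "trait"])
    if dup.any():
        i = int(np.where(dup)[0][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: duplicate plot row at line {i}")
    return df[PLOT_COLUMNS]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PLOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spectra(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    _check_env_codes(df["env"].unique(), str(path))
    return df[SPECTRA_COLUMNS]


def write_spectra(df: pd.DataFrame, path) -> None:
    df[SPECTRA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(float)
    bad = np.argwhere(np.isfinite(vals) & ((vals < 0) | (vals > 4)
                                           | (vals != np.round(vals))))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: invalid dosage {vals[r, c]!r} at line {r + 2}, "
            f"marker {df.columns[c]!r} (must be an integer 0-4 or blank)"
        )
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate clone or marker ids")
    return df


def write_genotypes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "clone"
    out.to_csv(path, sep="\t")


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"parent1": str, "parent2": str})
    need = ["clone", "family", "parent1", "parent2", "is_check"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["is_check"] = df["is_check"].astype(str).str.lower().isin(
        ("true", "1", "yes"))
    return df[need]


def write_pedigree(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_kernel(K: RelationshipMatrix, path) -> None:
    path = Path(path)
    K.to_frame().to_csv(path, sep="\t", index_label="clone")
    meta = {"kind": K.kind, **{k: v for k, v in K.meta.items()}}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, default=str, indent=1))


def read_kernel(path) -> RelationshipMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    kind = meta.pop("kind", "G")
    return RelationshipMatrix(df.to_numpy(float), list(df.index), kind, meta)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    phenotypes: str = ""
    genotypes: str = ""
    spectra: str = ""
    pedigree: str = ""
    out_dir: str = "results"
    seed: int = 0
    traits: list = field(default_factory=list)  # empty = all in the table
    sqrt_traits: list = field(default_factory=list)
    scenarios: list = field(default_factory=lambda: list(
        ("S1", "S2", "S3", "S3b", "S4", "S5", "S6", "S7")))
    n_folds: int = 5
    n_reps: int = 25
    cv_max: float = 150.0
    missing_max: int = 100
    max_missing: float = 0.20  # marker QC
    min_maf: float = 0.05
    outlier_z: float = 4.0  # spectral PCA outlier threshold (SD units)
    pheno_outlier_z: float = 4.0  # studentized-residual plot outliers
    k_donors: int = 5
    center_markers: bool = True
    include_column: str | bool = "auto"
    weight_grid: list = field(default_factory=lambda: [round(0.05 * i, 2)
                                                       for i in range(21)])
    genetic_models: list = field(default_factory=lambda: [["G"]])

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        if "seed" not in d:
            raise ValueError("configuration must set a seed")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.from_dict(raw)
    base = Path(path).parent
    for key in ("phenotypes", "genotypes", "spectra", "pedigree"):
        p = getattr(cfg, key)
        if p:
            full = (base / p) if not Path(p).is_absolute() else Path(p)
            if not full.exists():
                raise FileNotFoundError(f"configured {key} file not found: {full}")
            setattr(cfg, key, str(full))
    return cfg


@dataclass
class Dataset:
    """Validated in-memory bundle of the input tables."""

    phenotypes: pd.DataFrame | None
    genotypes: pd.DataFrame | None
    spectra: pd.DataFrame | None
    pedigree: pd.DataFrame | None

    @property
    def check_clones(self) -> list:
        if self.pedigree is None:
            return []
        return self.pedigree.loc[self.pedigree.is_check, "clone"].tolist()


def load_dataset(config: RunConfig) -> Dataset:
    """Read and validate every configured table."""
    return Dataset(
        phenotypes=read_phenotypes(config.phenotypes) if config.phenotypes else None,
        genotypes=read_genotypes(config.genotypes) if config.genotypes else None,
        spectra=read_spectra(config.spectra) if config.spectra else None,
        pedigree=read_pedigree(config.pedigree) if config.pedigree else None,
    )
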