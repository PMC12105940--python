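"""Validated CSV readers/writers and the seeded run manifest.

All interchange is headed CSV; floats are written with 12 significant digits
so that re-running a pipeline from its manifest reproduces outputs
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Input table violates its schema."""


#: column -> pandas dtype per table kind; key columns checked for duplicates
SCHEMAS: dict[str, dict] = {
    "abundance": {
        "columns": {"species": str, "site": str, "year": int, "count": int},
        "keys": ["species", "site", "year"],
        "non_negative": ["count"],
    },
    "sites": {
        "columns": {"site_id": str, "easting_m": float, "northing_m": float},
        "keys": ["site_id"],
    },
    "climate": {
        "columns": {
            "grid_cell": str,
            "year": int,
            "season": str,
            "variable": str,
            "value": float,
        },
        "keys": ["grid_cell", "year", "season", "variable"],
    },
    "habitat": {
        "columns": {"site_id": str, "biotope": str, "proportion": float},
        "keys": ["site_id", "biotope"],
        "non_negative": ["proportion"],
    },
    "attributes": {
        "columns": {"species": str},
        "keys": ["species"],
    },
    "synchrony": {
        "columns": {
            "variable": str,
            "species": str,
            "site_a": str,
            "site_b": str,
            "start_year": int,
            "mid_year": float,
            "r": float,
            "n_shared": int,
        },
        "keys": [],
    },
    "dropped": {
        "columns": {
            "species": str,
            "site_a": str,
            "site_b": str,
            "start_year": int,
            "reason": str,
        },
        "keys": [],
    },
    "pair_covariates": {
        "columns": {
            "site_a": str,
            "site_b": str,
            "distance_km": float,
            "mean_northing_km": float,
            "habitat_similarity": float,
        },
        "keys": ["site_a", "site_b"],
    },
    "model_results": {"columns": {"model": str, "term": str}, "keys": []},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises ValidationError naming the first missing column, duplicated key or
    negative value encountered.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema '{schema}'")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for c, dtype in spec["columns"].items():
        try:
            df[c] = df[c].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: column '{c}' is not {dtype.__name__}: {exc}")
    keys = spec.get("keys", [])
    if keys:
        dup = df.duplicated(subset=keys)
        if dup.any():
            first = df.loc[dup.idxmax(), keys].tolist()
            raise ValidationError(f"{path}: duplicate key {tuple(first)}")
    for c in spec.get("non_negative", []):
        if (df[c] < 0).any():
            bad = df.loc[df[c] < 0].iloc[0]
            raise ValidationError(f"{path}: negative {c} in row {bad.to_dict()}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with the package's reproducible float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it byte-identically."""

    config: dict
    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    dropped_by_reason: dict[str, int] = field(default_factory=dict)
    version: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
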