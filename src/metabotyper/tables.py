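"""Core table types: sample-by-feature abundance tables and biomass tables.

CSV dialects
------------
FeatureTable: one row per tissue-sample; first columns
``plant_id, genotype, tissue, regime, replicate`` then one column per
feature (``F0001`` ...). Missing values are empty cells. Blank samples use
the same feature columns without plant metadata.

BiomassTable: ``plant_id, genotype, regime, shoot_dw_g, root_dw_g``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

METADATA_COLUMNS = ("plant_id", "genotype", "tissue", "regime", "replicate")
BIOMASS_COLUMNS = ("plant_id", "genotype", "regime", "shoot_dw_g", "root_dw_g")

#: design-cell factors within which filters and quartiles are computed
CELL_FACTORS = ("genotype", "regime", "tissue")


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with factor metadata.

    ``values`` holds non-negative abundances (NaN = missing), indexed by
    sample id; ``meta`` carries the design factors for the same index;
    ``log`` is a provenance list of applied filter steps.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    log: list = field(default_factory=list)
    #: True once abundances have been log-transformed (negatives allowed)
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise SchemaError("values and meta must share the same sample index")
        if self.values.columns.duplicated().any():
            raise SchemaError("feature identifiers must be unique")
        missing_meta = [c for c in METADATA_COLUMNS if c not in self.meta.columns]
        if missing_meta:
            raise SchemaError(f"metadata missing columns: {missing_meta}")
        if self.meta[list(METADATA_COLUMNS)].isna().any().any():
            raise SchemaError("metadata factors must be complete for every sample")
        if not self.log_scale:
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) < 0:
                raise SchemaError("abundances must be non-negative")

    # -- accessors ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def cell_groups(self):
        """Iterate ``((genotype, regime, tissue), row_positions)`` cells."""
        key = list(CELL_FACTORS)
        grouped = self.meta.groupby(key, sort=True, observed=True)
        for cell, sub in grouped:
            yield cell, self.values.index.get_indexer(sub.index)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.meta.copy(), list(self.log), self.log_scale
        )

    def logged(self, **entry) -> "FeatureTable":
        self.log.append(entry)
        return self

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = pd.concat([self.meta[list(METADATA_COLUMNS)], self.values], axis=1)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing metadata columns {missing}")
        meta = df[list(METADATA_COLUMNS)]
        values = df.drop(columns=list(METADATA_COLUMNS)).astype(float)
        return cls(values, meta)


@dataclass
class BiomassTable:
    """Per-plant shoot/root dry weights with accession and regime labels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BIOMASS_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"biomass table missing columns: {missing}")
        w = self.data[["shoot_dw_g", "root_dw_g"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise SchemaError("biomass weights must be finite")
        if np.any(w <= 0):
            raise SchemaError("biomass weights must be strictly positive")

    @property
    def genotypes(self) -> list:
        return sorted(self.data["genotype"].unique())

    def subset_regime(self, regime: str) -> "BiomassTable":
        return BiomassTable(self.data[self.data["regime"] == regime].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.data[list(BIOMASS_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BiomassTable":
        return cls(pd.read_csv(path))


def read_blanks(path) -> pd.DataFrame:
    """Read a blank-sample CSV (feature columns only)."""
    return pd.read_csv(path, index_col="sample_id").astype(float)


def write_blanks(blanks: pd.DataFrame, path) -> None:
    blanks.to_csv(path, index_label="sample_id")


def validate_feature_csv(path) -> list[str]:
    """Return a list of problems (empty = pass) for a FeatureTable CSV."""
    problems: list[str] = []
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col="sample_id")
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        return [f"{path.name}: unreadable ({exc})"]
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            problems.append(f"{path.name}: missing column '{col}'")
    if problems:
        return problems
    meta = df[list(METADATA_COLUMNS)]
    na_rows = meta.index[meta.isna().any(axis=1)]
    for r in na_rows:
        problems.append(f"{path.name}: incomplete metadata in row '{r}'")
    feat = df.drop(columns=list(METADATA_COLUMNS))
    neg = feat.lt(0).any(axis=1)
    for r in feat.index[neg]:
        problems.append(f"{path.name}: negative abundance in row '{r}'")
    return problems


def validate_biomass_csv(path) -> list[str]:
    """Return a list of problems (empty = pass) for a biomass CSV."""
    problems: list[str] = []
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        return [f"{path.name}: unreadable ({exc})"]
    for col in BIOMASS_COLUMNS:
        if col not in df.columns:
            problems.append(f"{path.name}: missing column '{col}'")
    if problems:
        return problems
    bad = (df["shoot_dw_g"] <= 0) | (df["root_dw_g"] <= 0)
    for i in df.index[bad]:
        problems.append(f"{path.name}: non-positive weight in row {i} (plant {df.loc[i, 'plant_id']})")
    return problems
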