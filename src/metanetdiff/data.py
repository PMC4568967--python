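"""Core data containers: the feature intensity matrix and the sample design table.

An untargeted LC-MS experiment is summarised by a feature table — one row per
metabolomic feature, keyed by (m/z, retention time, chromatography column) —
and a design table describing each sample (diet, age, tissue, batch,
biological and technical replicate). Both are stored as plain pandas objects
so every downstream operation is an ordinary DataFrame computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DataError

#: columns every sample-design table must carry
DESIGN_COLUMNS = ("sample_id", "bio_id", "diet", "age", "tissue", "batch",
                  "bio_rep", "tech_rep")

#: columns identifying a feature, written first in every feature-table TSV
FEATURE_KEY_COLUMNS = ("feature_id", "mz", "rt", "column_id")


@dataclass
class FeatureMatrix:
    """Features x samples intensity matrix with per-feature LC-MS keys.

    Parameters
    ----------
    values
        DataFrame indexed by ``feature_id`` with one column per sample.
        Cells are ion intensities (``scale='raw'``), log2 intensities
        (``'log'``) or mean-centred log2 intensities (``'centered'``).
    features
        DataFrame indexed by ``feature_id`` with columns ``mz`` (Da),
        ``rt`` (seconds) and ``column_id`` (chromatography column).
    scale
        One of ``{'raw', 'log', 'centered'}``.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log", "centered"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise DataError("duplicate feature ids")
        if not self.values.index.equals(self.features.index):
            raise AlignmentError("values and features must share the same feature index")
        if "mz" in self.features and not (self.features["mz"] > 0).all():
            raise DataError("m/z values must be positive")

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing cells."""
        return self.values.isna().mean(axis=1)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "FeatureMatrix":
        """New matrix with the same feature keys (restricted to ``values.index``)."""
        return FeatureMatrix(values=values,
                             features=self.features.loc[values.index],
                             scale=self.scale if scale is None else scale)

    def subset_features(self, ids) -> "FeatureMatrix":
        ids = pd.Index(ids)
        return replace(self, values=self.values.loc[ids], features=self.features.loc[ids])

    def subset_samples(self, ids) -> "FeatureMatrix":
        return replace(self, values=self.values.loc[:, list(ids)],
                       features=self.features)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.features.copy(), self.scale)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write a TSV whose first columns are feature_id, mz, rt, column_id."""
        out = pd.concat([self.features, self.values], axis=1)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "raw") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        key_cols = [c for c in FEATURE_KEY_COLUMNS if c != "feature_id" and c in df]
        features = df[key_cols]
        values = df.drop(columns=key_cols)
        return cls(values=values, features=features, scale=scale)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check that a design table has the required columns and unique sample ids."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DataError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in design table")
    return design


def bio_design(design: pd.DataFrame) -> pd.DataFrame:
    """Collapse a technical-replicate design to one row per biological sample."""
    validate_design(design)
    keep = [c for c in design.columns if c != "tech_rep" and c != "sample_id"]
    out = design.drop_duplicates("bio_id")[["bio_id"] + [c for c in keep if c != "bio_id"]]
    out = out.rename(columns={"bio_id": "sample_id"}).reset_index(drop=True)
    out["bio_id"] = out["sample_id"]
    out["tech_rep"] = 1
    return out


def align_design(m: FeatureMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``design`` matching the matrix columns, in matrix column order."""
    d = design.set_index("sample_id")
    missing = [s for s in m.sample_ids if s not in d.index]
    if missing:
        raise AlignmentError(f"samples absent from design: {missing[:5]}...")
    out = d.loc[m.sample_ids]
    out.index.name = "sample_id"
    return out.reset_index()
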