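"""Sample x feature abundance container shared by every analysis stage.

The container couples three aligned tables: the abundance matrix (rows =
samples, columns = metabolite features, NaN = missing), per-sample metadata
(participant, sex, trial, timepoint, sample type, injection order) and
per-feature annotation (measurement platform stratum, optional biochemical
class). Study samples carry the biology; pooled-plasma QC injections carry
analytical precision only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIALS = ("moderate", "heavy", "severe")
TIMEPOINTS = ("pre", "post")
SEXES = ("male", "female")
SAMPLE_TYPES = ("study", "qc")
PLATFORMS = ("nmr-lipoprotein", "nmr-small-molecule", "lcms-lipid")

META_COLUMNS = [
    "participant_id",
    "sex",
    "trial",
    "timepoint",
    "sample_type",
    "injection_order",
]


class DatasetError(ValueError):
    """Raised when an abundance dataset violates its structural contract."""


@dataclass
class AbundanceDataset:
    """Abundance matrix plus sample metadata and feature annotation.

    Parameters
    ----------
    matrix
        DataFrame indexed by sample_id, columns = feature ids, values
        non-negative abundances; NaN marks a missing cell.
    sample_meta
        DataFrame indexed by sample_id with columns ``participant_id, sex,
        trial, timepoint, sample_type, injection_order``.  QC rows use empty
        strings for the biological factors.
    feature_meta
        DataFrame indexed by feature_id with at least a ``platform`` column
        and an optional ``feature_class`` column.
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"platform": "lcms-lipid"}, index=self.matrix.columns
            )
            self.feature_meta.index.name = "feature_id"
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        if len(self.matrix) != len(self.sample_meta):
            raise DatasetError(
                f"matrix has {len(self.matrix)} rows but sample_meta has "
                f"{len(self.sample_meta)}"
            )
        if not self.matrix.index.equals(self.sample_meta.index):
            raise DatasetError("matrix and sample_meta sample ids differ")
        if self.matrix.columns.duplicated().any():
            dupes = self.matrix.columns[self.matrix.columns.duplicated()]
            raise DatasetError(f"duplicate feature ids: {list(dupes[:5])}")
        if not self.matrix.columns.equals(self.feature_meta.index):
            raise DatasetError("matrix columns and feature_meta ids differ")
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta]
        if missing_cols:
            raise DatasetError(f"sample_meta lacks columns {missing_cols}")
        vals = self.matrix.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise DatasetError("negative abundance values present")
        bad_type = set(self.sample_meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise DatasetError(f"unknown sample_type values: {sorted(bad_type)}")
        study = self.sample_meta["sample_type"] == "study"
        for col, levels in (("trial", TRIALS), ("timepoint", TIMEPOINTS), ("sex", SEXES)):
            bad = set(self.sample_meta.loc[study, col]) - set(levels)
            if bad:
                raise DatasetError(f"unknown {col} values: {sorted(bad)}")

    # -- convenience views -------------------------------------------------

    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["sample_type"] == "qc"

    @property
    def study_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[~self.is_qc]

    @property
    def qc_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.is_qc]

    @property
    def study_meta(self) -> pd.DataFrame:
        return self.sample_meta.loc[~self.is_qc]

    @property
    def n_samples(self) -> int:
        return len(self.matrix)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def features_on_platform(self, platform: str) -> pd.Index:
        return self.feature_meta.index[self.feature_meta["platform"] == platform]

    def copy(self) -> "AbundanceDataset":
        return AbundanceDataset(
            self.matrix.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )

    def select_features(self, features) -> "AbundanceDataset":
        features = pd.Index(features)
        return AbundanceDataset(
            self.matrix.loc[:, features].copy(),
            self.sample_meta.copy(),
            self.feature_meta.loc[features].copy(),
        )

    # -- serialization -----------------------------------------------------

    def to_csv(self, matrix_path, metadata_path, feature_path=None) -> None:
        """Write the matrix and metadata as plain CSV (missing cells empty)."""
        out = self.matrix.copy()
        out.index.name = "sample_id"
        out.to_csv(matrix_path)
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path)
        if feature_path is not None:
            feats = self.feature_meta.copy()
            feats.index.name = "feature_id"
            feats.to_csv(feature_path)

    @classmethod
    def from_csv(
        cls, matrix_path, metadata_path, feature_path=None
    ) -> "AbundanceDataset":
        matrix = pd.read_csv(Path(matrix_path), index_col="sample_id")
        meta = pd.read_csv(
            Path(metadata_path), index_col="sample_id", keep_default_na=False
        )
        feats = None
        if feature_path is not None:
            feats = pd.read_csv(Path(feature_path), index_col="feature_id")
        return cls(matrix, meta, feats)
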