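"""Per-participant log2 fold changes and unit-variance autoscaling.

The multivariate and univariate stages both consume the paired pre/post
structure as log2(post/pre) per participant x trial, and autoscaled (mean 0,
unit variance per column) matrices.  Scaling parameters are always stored so
held-out data can be projected with the *training* scaling, never their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AbundanceDataset

log = logging.getLogger(__name__)


@dataclass
class FoldChangeTable:
    """log2(post/pre) per (participant, trial) with carried sex labels."""

    values: pd.DataFrame  # MultiIndex (participant_id, trial) x features
    sex: pd.Series  # indexed like values.index

    def for_trial(self, trial: str) -> pd.DataFrame:
        sub = self.values.xs(trial, level="trial")
        if sub.empty:
            raise KeyError(f"trial {trial!r} absent from fold-change table")
        return sub

    @property
    def trials(self) -> list:
        return list(self.values.index.get_level_values("trial").unique())

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "sex", self.sex.to_numpy())
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FoldChangeTable":
        df = pd.read_csv(path, index_col=["participant_id", "trial"])
        sex = df.pop("sex")
        return cls(values=df, sex=sex)

    def to_long(self) -> pd.DataFrame:
        """Long format for the mixed-model entry point on fold changes."""
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["participant_id", "trial", "metabolite_id", "value"]
        long["sex"] = self.sex.reindex(
            pd.MultiIndex.from_frame(long[["participant_id", "trial"]])
        ).to_numpy()
        return long


def compute_log2fc(dataset: AbundanceDataset) -> FoldChangeTable:
    """log2(post/pre) per participant x trial, from an imputed dataset.

    Participant x trial cells lacking exactly one pre and one post study
    sample are dropped with a logged warning.  Nonpositive abundances are a
    hard error (the ratio cannot be logged).
    """
    meta = dataset.study_meta
    mat = dataset.study_matrix
    if mat.isna().any().any():
        raise ValueError("dataset contains missing values; impute first")

    rows = []
    index = []
    sexes = []
    for (pid, trial), grp in meta.groupby(["participant_id", "trial"], sort=True):
        pre = grp.index[grp["timepoint"] == "pre"]
        post = grp.index[grp["timepoint"] == "post"]
        if len(pre) != 1 or len(post) != 1:
            log.warning(
                "dropping participant %s trial %s: %d pre / %d post samples",
                pid, trial, len(pre), len(post),
            )
            continue
        pre_v = mat.loc[pre[0]].to_numpy(dtype=float)
        post_v = mat.loc[post[0]].to_numpy(dtype=float)
        for name, vec, sid in (("pre", pre_v, pre[0]), ("post", post_v, post[0])):
            if (vec <= 0).any():
                feat = mat.columns[np.argmax(vec <= 0)]
                raise ValueError(
                    f"nonpositive abundance in sample {sid!r}, feature {feat!r}: "
                    "cannot take log2 ratio"
                )
        rows.append(np.log2(post_v / pre_v))
        index.append((pid, trial))
        sexes.append(grp["sex"].iloc[0])

    idx = pd.MultiIndex.from_tuples(index, names=["participant_id", "trial"])
    values = pd.DataFrame(np.vstack(rows) if rows else [], index=idx, columns=mat.columns)
    return FoldChangeTable(values=values, sex=pd.Series(sexes, index=idx, name="sex"))


@dataclass
class Autoscaler:
    """Column mean/SD scaling fitted on training data, reusable on new data.

    Uses the population SD convention (ddof=0).  Zero-variance columns are
    centered, left at zero, and flagged rather than raising.
    """

    means: np.ndarray = None  # type: ignore[assignment]
    sds: np.ndarray = None  # type: ignore[assignment]
    zero_variance: np.ndarray = None  # type: ignore[assignment]
    columns: pd.Index = None  # type: ignore[assignment]

    def fit(self, matrix) -> "Autoscaler":
        X = _as_array(matrix)
        if X.shape[0] < 2:
            raise ValueError("autoscaling needs at least 2 rows")
        if np.isnan(X).any():
            raise ValueError("autoscaling input contains missing values")
        self.means = X.mean(axis=0)
        self.sds = X.std(axis=0, ddof=0)
        self.zero_variance = self.sds == 0
        self.sds = np.where(self.zero_variance, 1.0, self.sds)
        self.columns = matrix.columns if isinstance(matrix, pd.DataFrame) else None
        return self

    def transform(self, matrix):
        X = _as_array(matrix)
        Z = (X - self.means) / self.sds
        if isinstance(matrix, pd.DataFrame):
            return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
        return Z

    def fit_transform(self, matrix):
        return self.fit(matrix).transform(matrix)


def autoscale(matrix):
    """Autoscale a matrix; returns (scaled, fitted Autoscaler)."""
    scaler = Autoscaler()
    scaled = scaler.fit_transform(matrix)
    if scaler.zero_variance.any():
        n = int(scaler.zero_variance.sum())
        log.warning("autoscale: %d zero-variance column(s) left centered at 0", n)
    return scaled, scaler


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)
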