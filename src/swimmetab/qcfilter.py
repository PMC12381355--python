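"""Feature-quality filtering and random-forest imputation.

Three filters mirror standard targeted-lipidomics practice: (i) features
whose relative standard deviation across pooled-plasma QC injections exceeds
30% are analytically imprecise and removed; (ii) LC-MS features whose raw
intensity falls below 5000 counts in more than half of the QC injections are
too close to the noise floor; (iii) features missing in more than 70% of
study samples carry too little information to impute.  All thresholds are
strict inequalities, so boundary cases are retained.  Remaining missing
cells are imputed with an iterative random-forest scheme (missForest-style):
features are swept in order of increasing missingness, each regressed on all
other features, iterating until the change in imputed values stops
decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dataset import AbundanceDataset

log = logging.getLogger(__name__)

RSD_MAX_DEFAULT = 30.0
INTENSITY_FLOOR_DEFAULT = 5000.0
QC_LOW_FRAC_DEFAULT = 0.5
MISSING_MAX_DEFAULT = 0.7


@dataclass
class FilterReport:
    """Bookkeeping of which features each rule removed and why."""

    n_input_features: int
    removed_rsd: List[str] = field(default_factory=list)
    removed_intensity: List[str] = field(default_factory=list)
    removed_missing: List[str] = field(default_factory=list)
    thresholds: Dict[str, float] = field(default_factory=dict)
    rsd: pd.Series = None  # type: ignore[assignment]
    all_removed_warning: bool = False

    @property
    def removed_union(self) -> set:
        return set(self.removed_rsd) | set(self.removed_intensity) | set(self.removed_missing)

    @property
    def n_retained(self) -> int:
        return self.n_input_features - len(self.removed_union)

    def to_frame(self) -> pd.DataFrame:
        """Long-form report: one row per (feature, removal reason)."""
        rows = []
        for reason, ids, thr_key in (
            ("rsd", self.removed_rsd, "rsd_max"),
            ("intensity", self.removed_intensity, "intensity_floor"),
            ("missing", self.removed_missing, "missing_max"),
        ):
            for fid in ids:
                stat = float(self.rsd.get(fid, np.nan)) if reason == "rsd" and self.rsd is not None else np.nan
                rows.append(
                    {
                        "feature_id": fid,
                        "reason": reason,
                        "statistic": stat,
                        "threshold": self.thresholds.get(thr_key, np.nan),
                    }
                )
        return pd.DataFrame(rows, columns=["feature_id", "reason", "statistic", "threshold"])


def compute_feature_rsd(dataset: AbundanceDataset) -> pd.Series:
    """Percent RSD of each feature across QC injections.

    RSD = 100 x sd(QC values, ddof=1) / mean(QC values).  Features with
    fewer than two non-missing QC values, or a zero QC mean, are returned as
    NaN (undefined).
    """
    qc = dataset.qc_matrix
    if qc.empty:
        raise ValueError("dataset contains no QC samples; RSD undefined")
    vals = qc.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=0)
    rsd = np.full(dataset.n_features, np.nan)
    ok = n_obs >= 2
    if ok.any():
        mean = np.nanmean(vals[:, ok], axis=0)
        sd = np.nanstd(vals[:, ok], axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rsd[ok] = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    return pd.Series(rsd, index=dataset.matrix.columns, name="rsd_pct")


def apply_qc_filters(
    dataset: AbundanceDataset,
    rsd_max: float = RSD_MAX_DEFAULT,
    intensity_floor: float = INTENSITY_FLOOR_DEFAULT,
    qc_low_frac: float = QC_LOW_FRAC_DEFAULT,
    missing_max: float = MISSING_MAX_DEFAULT,
) -> tuple[AbundanceDataset, FilterReport]:
    """Apply RSD, intensity-floor and missingness filters; return report.

    The precision filters (RSD, intensity floor) apply only to the
    ``lcms-lipid`` platform stratum — NMR-derived quantities are absolute
    concentrations, not ion counts.  Missingness is computed over study
    samples only (QC injections inform precision, not biology).
    """
    if dataset.n_features == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")

    lcms = set(dataset.features_on_platform("lcms-lipid"))
    report = FilterReport(
        n_input_features=dataset.n_features,
        thresholds={
            "rsd_max": rsd_max,
            "intensity_floor": intensity_floor,
            "qc_low_frac": qc_low_frac,
            "missing_max": missing_max,
        },
    )

    has_qc = bool(dataset.is_qc.any())
    if lcms and not has_qc:
        raise ValueError("LC-MS features present but no QC samples to filter on")

    if has_qc:
        rsd = compute_feature_rsd(dataset)
        report.rsd = rsd
        qc_vals = dataset.qc_matrix.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            low_frac = np.nanmean(qc_vals < intensity_floor, axis=0)
        low_frac = pd.Series(low_frac, index=dataset.matrix.columns)
        for fid in dataset.matrix.columns:
            if fid not in lcms:
                continue
            if np.isfinite(rsd[fid]) and rsd[fid] > rsd_max:
                report.removed_rsd.append(fid)
            if low_frac[fid] > qc_low_frac:
                report.removed_intensity.append(fid)
    else:
        report.rsd = pd.Series(np.nan, index=dataset.matrix.columns, name="rsd_pct")

    study = dataset.study_matrix.to_numpy(dtype=float)
    miss_frac = np.mean(np.isnan(study), axis=0)
    for fid, frac in zip(dataset.matrix.columns, miss_frac):
        if frac > missing_max:
            report.removed_missing.append(fid)

    keep = [f for f in dataset.matrix.columns if f not in report.removed_union]
    if not keep:
        report.all_removed_warning = True
        log.warning("all %d features removed by QC filters", dataset.n_features)
        filtered = dataset.select_features([])
    else:
        filtered = dataset.select_features(keep)
    log.info(
        "QC filters: %d -> %d features (rsd %d, intensity %d, missing %d)",
        report.n_input_features,
        report.n_retained,
        len(report.removed_rsd),
        len(report.removed_intensity),
        len(report.removed_missing),
    )
    return filtered, report


def impute_missforest(
    dataset: AbundanceDataset,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> AbundanceDataset:
    """Iterative random-forest imputation of missing study-sample cells.

    Works per platform stratum on natural-log-transformed abundances
    (multiplicative error model), back-transforming afterwards.  Features
    are initialized at their observed means and swept in increasing-
    missingness order; each sweep regresses every incomplete feature on all
    other features with a random forest and replaces its missing cells with
    the predictions.  Iteration stops when the mean squared change in the
    imputed values increases (the missForest stopping rule, returning the
    previous sweep's values) or after ``max_iter`` sweeps.  QC rows are
    excluded from both training and imputation.  Observed cells are never
    altered.
    """
    mat = dataset.matrix.to_numpy(dtype=float)
    study_rows = np.flatnonzero(~dataset.is_qc.to_numpy())
    block = mat[study_rows]
    if not np.isnan(block).any():
        return dataset
    if np.isnan(block).all(axis=0).any():
        bad = dataset.matrix.columns[np.isnan(block).all(axis=0)]
        raise ValueError(f"features 100% missing, cannot impute: {list(bad[:5])}")

    out = dataset.copy()
    result = block.copy()
    platforms = dataset.feature_meta["platform"].to_numpy()
    for platform in pd.unique(platforms):
        cols = np.flatnonzero(platforms == platform)
        sub = result[:, cols]
        if np.isnan(sub).any():
            result[:, cols] = _missforest_block(sub, n_trees, max_iter, seed)
    mat[study_rows] = result
    out.matrix.iloc[:, :] = mat
    return out


def _missforest_block(block: np.ndarray, n_trees: int, max_iter: int, seed: int) -> np.ndarray:
    """missForest on one stratum; operates in natural-log space."""
    miss = np.isnan(block)
    with np.errstate(divide="ignore"):
        logx = np.log(np.where(block <= 0, np.nan, block))
    # zero abundances (below detection) are treated as missing for imputation
    miss = miss | np.isnan(logx)
    if not miss.any():
        return block
    col_means = np.nanmean(np.where(miss, np.nan, logx), axis=0)
    filled = np.where(miss, col_means[None, :], logx)

    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()]

    prev_filled = filled.copy()
    prev_diff = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        new_filled = filled.copy()
        for j in order:
            obs = ~miss[:, j]
            predictors = np.delete(new_filled, j, axis=1)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            rf.fit(predictors[obs], new_filled[obs, j])
            new_filled[miss[:, j], j] = rf.predict(predictors[miss[:, j]])
        denom = np.sum(new_filled[miss] ** 2)
        diff = np.sum((new_filled[miss] - filled[miss]) ** 2) / denom if denom > 0 else 0.0
        if diff > prev_diff:
            filled = prev_filled  # change grew: keep the previous sweep
            break
        prev_filled = filled
        filled = new_filled
        prev_diff = diff
    out = np.where(miss, np.exp(filled), block)
    return out
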