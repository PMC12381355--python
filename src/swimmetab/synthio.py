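"""Synthetic swimming-cohort metabolomics data with known planted effects.

Emulates the study design the analysis assumes: ~16 highly trained swimmers
of both sexes, paired pre/post capillary-plasma samples across three swim
trials (moderate, heavy, severe exercise intensity domains), ~1000 metabolite
features in biochemical classes (free fatty acids, glycolytic/TCA small
molecules, lipoprotein subfractions, inert background), a participant random
intercept, trial-specific effect directions (FFAs rise after the moderate
trial, lactate/pyruvate/alanine-like small molecules after the severe trial),
trial-heteroscedastic residual noise, a sex-modulated FFA response in the
severe trial, feature-wise missingness, and repeated pooled-plasma QC
injections with controlled relative standard deviation.

Abundances are generated on the natural-log scale and exponentiated, so every
value is strictly positive and planted log2 fold-change effects are exact:
a planted effect ``d`` adds ``d * ln(2)`` to the post-sample log-abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .dataset import AbundanceDataset, META_COLUMNS, TRIALS

FEATURE_CLASSES = ("ffa", "glycolytic", "lipoprotein", "inert")

# Platform stratum per feature class: FFAs ride the LC-MS lipidomics panel,
# glycolytic intermediates the NMR small-molecule panel, subfractions the
# NMR lipoprotein panel; inert background fills out the lipidomics stratum.
CLASS_PLATFORM = {
    "ffa": "lcms-lipid",
    "glycolytic": "nmr-small-molecule",
    "lipoprotein": "nmr-lipoprotein",
    "inert": "lcms-lipid",
}


class ConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


def _default_features() -> Dict[str, int]:
    # ~1000 features split like the study's platforms: 112 lipoprotein
    # parameters, ~2 dozen small molecules, the rest LC-MS lipids.
    return {"ffa": 40, "glycolytic": 12, "lipoprotein": 112, "inert": 836}


def _default_effects() -> Dict[Tuple[str, str], float]:
    # log2 fold-change means per (feature class, trial).  FFAs rise most
    # after the moderate trial and barely move after severe (moderate-vs-
    # severe contrasts ~1 log2 unit); glycolytic small molecules
    # (lactate/pyruvate/alanine-like) rise most after severe; lipoprotein
    # subfractions shift subtly with intensity; inert features are null.
    return {
        ("ffa", "moderate"): 1.0,
        ("ffa", "heavy"): 0.7,
        ("ffa", "severe"): 0.0,
        ("glycolytic", "moderate"): 0.2,
        ("glycolytic", "heavy"): 0.8,
        ("glycolytic", "severe"): 1.5,
        ("lipoprotein", "moderate"): 0.0,
        ("lipoprotein", "heavy"): 0.05,
        ("lipoprotein", "severe"): 0.1,
        ("inert", "moderate"): 0.0,
        ("inert", "heavy"): 0.0,
        ("inert", "severe"): 0.0,
    }


def _default_residual_sds() -> Dict[str, float]:
    # Severe-trial responses are noisier within participant than the two
    # steady-state trials (heterogeneous level-1 variance).
    return {"moderate": 0.2, "heavy": 0.2, "severe": 0.4}


@dataclass
class CohortConfig:
    """Parameters controlling the synthetic cohort.

    All SDs are on the natural-log abundance scale; planted effects are in
    log2 fold-change units (post/pre).
    """

    n_participants: int = 16
    sex_ratio: float = 9 / 16  # fraction male, as in the study cohort
    n_features_per_class: Dict[str, int] = field(default_factory=_default_features)
    effect_matrix: Dict[Tuple[str, str], float] = field(default_factory=_default_effects)
    sex_modulation: float = -0.5  # added to male FFA log2FC in the severe trial
    sd_participant: float = 0.3
    sd_residual_by_trial: Dict[str, float] = field(default_factory=_default_residual_sds)
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.0
    missing_rate: float = 0.05
    n_qc: int = 10
    qc_rsd_target: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must lie in [0, 1]")
        for cls, n in self.n_features_per_class.items():
            if cls not in FEATURE_CLASSES:
                raise ConfigError(f"unknown feature class {cls!r}")
            if n < 1:
                raise ConfigError(f"n_features_per_class[{cls!r}] must be >= 1")
        if self.sd_participant < 0:
            raise ConfigError("sd_participant must be >= 0")
        for trial in TRIALS:
            sd = self.sd_residual_by_trial.get(trial)
            if sd is None:
                raise ConfigError(f"sd_residual_by_trial missing trial {trial!r}")
            if sd < 0:
                raise ConfigError(f"sd_residual_by_trial[{trial!r}] must be >= 0")
        if self.baseline_log_sd < 0:
            raise ConfigError("baseline_log_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 0.7:
            raise ConfigError("missing_rate must lie in [0, 0.7)")
        if self.n_qc < 0:
            raise ConfigError("n_qc must be >= 0")
        if self.qc_rsd_target < 0:
            raise ConfigError("qc_rsd_target must be >= 0")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """Generated dataset plus ground truth about what was planted."""

    dataset: AbundanceDataset
    truth: pd.DataFrame  # rows = features: feature_class + planted log2FC per trial

    def planted_effect(self, feature_id: str, trial: str) -> float:
        return float(self.truth.loc[feature_id, f"effect_{trial}"])


def generate_cohort(config: CohortConfig) -> SyntheticDataset:
    """Generate one synthetic cohort dataset.

    Post-sample log-abundance = feature baseline + participant intercept +
    planted effect x ln(2) + trial-specific residual noise; pre-samples omit
    the effect term.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # features
    classes = []
    feature_ids = []
    for cls in FEATURE_CLASSES:
        n = config.n_features_per_class.get(cls, 0)
        for k in range(n):
            feature_ids.append(f"{cls}_{k:04d}")
            classes.append(cls)
    feature_ids = pd.Index(feature_ids, name="feature_id")
    classes = np.asarray(classes)
    n_feat = len(feature_ids)

    feature_meta = pd.DataFrame(
        {
            "platform": [CLASS_PLATFORM[c] for c in classes],
            "feature_class": classes,
        },
        index=feature_ids,
    )

    # participants
    n_male = int(round(config.sex_ratio * config.n_participants))
    sexes = np.array(["male"] * n_male + ["female"] * (config.n_participants - n_male))
    participant_ids = np.array([f"P{i + 1:02d}" for i in range(config.n_participants)])

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_feat)
    intercepts = rng.normal(0.0, config.sd_participant, config.n_participants)

    effect = np.zeros((len(TRIALS), n_feat))
    for ti, trial in enumerate(TRIALS):
        for ci, cls in enumerate(classes):
            effect[ti, ci] = config.effect_matrix.get((cls, trial), 0.0)

    ln2 = np.log(2.0)
    rows = []
    meta_rows = []
    order = 0
    for pi, pid in enumerate(participant_ids):
        for ti, trial in enumerate(TRIALS):
            sd = config.sd_residual_by_trial[trial]
            eff = effect[ti].copy()
            if sexes[pi] == "male" and trial == "severe":
                eff = eff + np.where(classes == "ffa", config.sex_modulation, 0.0)
            for timepoint in ("pre", "post"):
                noise = rng.normal(0.0, sd, n_feat)
                log_val = baseline + intercepts[pi] + noise
                if timepoint == "post":
                    log_val = log_val + eff * ln2
                order += 1
                rows.append(np.exp(log_val))
                meta_rows.append(
                    {
                        "sample_id": f"{pid}_{trial}_{timepoint}",
                        "participant_id": pid,
                        "sex": sexes[pi],
                        "trial": trial,
                        "timepoint": timepoint,
                        "sample_type": "study",
                        "injection_order": order,
                    }
                )

    meta = pd.DataFrame(meta_rows).set_index("sample_id")[META_COLUMNS]
    matrix = pd.DataFrame(np.vstack(rows), index=meta.index, columns=feature_ids)
    dataset = AbundanceDataset(matrix, meta, feature_meta)

    if config.missing_rate > 0:
        dataset = inject_missingness(
            dataset, config.missing_rate, mechanism="mcar", seed=int(rng.integers(2**31))
        )
    if config.n_qc >= 2:
        dataset = make_qc_injections(
            dataset, config.n_qc, config.qc_rsd_target, seed=int(rng.integers(2**31))
        )

    truth = pd.DataFrame({"feature_class": classes}, index=feature_ids)
    for ti, trial in enumerate(TRIALS):
        truth[f"effect_{trial}"] = effect[ti]
    return SyntheticDataset(dataset=dataset, truth=truth)


def inject_missingness(
    dataset: AbundanceDataset,
    rate: float,
    mechanism: str = "mcar",
    seed: int = 0,
) -> AbundanceDataset:
    """Blank a fraction of study-sample cells; QC rows are never touched.

    ``mcar`` blanks exactly ``round(rate * n_cells)`` uniformly chosen study
    cells; ``low-intensity`` blanks the same count but preferentially among
    the lowest-abundance cells (intensity-dependent dropout, the mechanism
    that makes left-censored missingness in LC-MS data).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    if mechanism not in ("mcar", "low-intensity"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if rate == 0.0:
        return dataset
    out = dataset.copy()
    study_idx = np.flatnonzero(~out.is_qc.to_numpy())
    block = out.matrix.iloc[study_idx].to_numpy(dtype=float)
    n_cells = block.size
    n_blank = int(round(rate * n_cells))
    rng = np.random.default_rng(seed)
    observed = np.flatnonzero(~np.isnan(block.ravel()))
    n_blank = min(n_blank, observed.size)
    if mechanism == "mcar":
        chosen = rng.choice(observed, size=n_blank, replace=False)
    else:
        vals = block.ravel()[observed]
        # rank-based weights: lowest-intensity cells most likely to drop out
        ranks = np.empty(observed.size)
        ranks[np.argsort(vals)] = np.arange(observed.size)
        weights = np.exp(-3.0 * ranks / observed.size)
        weights /= weights.sum()
        chosen = rng.choice(observed, size=n_blank, replace=False, p=weights)
    flat = block.ravel()
    flat[chosen] = np.nan
    out.matrix.iloc[study_idx] = flat.reshape(block.shape)
    return out


def make_qc_injections(
    dataset: AbundanceDataset,
    n_qc: int,
    rsd_target: float,
    seed: int = 0,
) -> AbundanceDataset:
    """Append pooled-plasma QC injections with a controlled per-feature RSD.

    Each QC value is drawn Normal(pooled study mean, rsd_target/100 x mean),
    i.e. coefficient of variation ~= ``rsd_target`` percent, mimicking
    repeated injection of the same pooled sample through the sequence.
    """
    if n_qc < 2:
        raise ValueError("n_qc must be >= 2 (RSD is undefined below that)")
    if rsd_target < 0:
        raise ValueError("rsd_target must be >= 0")
    rng = np.random.default_rng(seed)
    pooled = np.nanmean(dataset.study_matrix.to_numpy(dtype=float), axis=0)
    pooled = np.where(np.isnan(pooled), 0.0, pooled)
    sd = (rsd_target / 100.0) * pooled
    qc_vals = rng.normal(pooled, sd, size=(n_qc, dataset.n_features))
    qc_vals = np.clip(qc_vals, 0.0, None)
    start_order = int(dataset.sample_meta["injection_order"].max()) if len(dataset.sample_meta) else 0
    qc_ids = [f"QC{k + 1:02d}" for k in range(n_qc)]
    qc_meta = pd.DataFrame(
        {
            "participant_id": "",
            "sex": "",
            "trial": "",
            "timepoint": "",
            "sample_type": "qc",
            "injection_order": np.arange(start_order + 1, start_order + 1 + n_qc),
        },
        index=pd.Index(qc_ids, name="sample_id"),
    )[META_COLUMNS]
    qc_matrix = pd.DataFrame(qc_vals, index=qc_meta.index, columns=dataset.matrix.columns)
    return AbundanceDataset(
        pd.concat([dataset.matrix, qc_matrix]),
        pd.concat([dataset.sample_meta, qc_meta]),
        dataset.feature_meta.copy(),
    )
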