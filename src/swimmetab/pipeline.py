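"""End-to-end orchestration: data -> QC -> fold changes -> OPLS-DA ->
effect sizes -> mixed models, with deterministic seeding and a manifest.

The analysis follows the study's workflow: per-trial pre-vs-post OPLS-DA on
autoscaled log abundances, then a trial-comparison OPLS-DA on the log2
fold-change table (default moderate vs severe) with permutation validation,
projection of the held-out trial (default heavy) onto that model, an
eruption table, and univariate mixed-model follow-up of the key features.

Every stage draws its randomness from a seed derived from the single run
seed and the stage name, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import effects, foldchange, lmm, opls, qcfilter
from .dataset import AbundanceDataset, TIMEPOINTS, TRIALS
from .synthio import CohortConfig, generate_cohort

log = logging.getLogger(__name__)


def derive_seed(base_seed: int, stage: str) -> int:
    """Stage seed = stable hash of (base seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    matrix_path: Optional[str] = None
    metadata_path: Optional[str] = None
    feature_path: Optional[str] = None
    synth: Optional[CohortConfig] = None
    comparison: Tuple[str, str] = ("moderate", "severe")
    projected_trial: str = "heavy"
    rsd_max: float = 30.0
    intensity_floor: float = 5000.0
    qc_low_frac: float = 0.5
    missing_max: float = 0.7
    vip_min: float = 3.0
    alpha: float = 0.05
    cv_folds: int = 8
    n_perm: int = 50
    n_ortho: int = 1  # -1 requests Q2-guided auto-selection
    run_prepost_models: bool = True
    lmm_scope: str = "key"  # "key" | "all" | "none"
    bootstrap_B: int = 0
    impute_trees: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.comparison[0] == self.comparison[1]:
            raise ValueError("comparison trials must be distinct")
        if self.projected_trial in self.comparison:
            raise ValueError("projected trial must not be in the comparison pair")
        for t in (*self.comparison, self.projected_trial):
            if t not in TRIALS:
                raise ValueError(f"unknown trial {t!r}")
        if self.synth is None and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("provide either input paths or a synthetic cohort config")


@dataclass
class RunResult:
    config: RunConfig
    dataset: AbundanceDataset
    filter_report: qcfilter.FilterReport
    fc_table: foldchange.FoldChangeTable
    prepost_models: Dict[str, opls.OplsModel]
    prepost_permutations: Dict[str, opls.PermutationResult]
    comparison_model: opls.OplsModel
    comparison_permutation: opls.PermutationResult
    projection_scores: pd.DataFrame
    eruption: effects.EruptionTable
    contrasts: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict:
        """Write the results bundle; returns the manifest with checksums."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.filter_report.to_frame().to_csv(out / "filter_report.csv", index=False)
        self.fc_table.to_csv(out / "fold_changes.csv")
        self.eruption.to_csv(out / "eruption_table.csv")
        self.projection_scores.to_csv(out / "projection_scores.csv", index=False)
        self.contrasts.to_csv(out / "lmm_contrasts.csv", index=False)
        stats = {
            "comparison": list(self.config.comparison),
            "r2x_cum": self.comparison_model.r2x_cum,
            "r2y_cum": self.comparison_model.r2y_cum,
            "q2_cum": self.comparison_model.q2_cum,
            "rmsee": self.comparison_model.rmsee,
            "p_r2y": self.comparison_permutation.p_r2y,
            "p_q2": self.comparison_permutation.p_q2,
            "n_key_features": int(self.eruption.table["key_feature"].sum()),
            "prepost": {
                trial: {
                    "r2x_cum": m.r2x_cum,
                    "r2y_cum": m.r2y_cum,
                    "q2_cum": m.q2_cum,
                    "rmsee": m.rmsee,
                    "p_r2y": self.prepost_permutations[trial].p_r2y,
                    "p_q2": self.prepost_permutations[trial].p_q2,
                }
                for trial, m in self.prepost_models.items()
            },
        }
        (out / "model_stats.json").write_text(json.dumps(stats, indent=1))
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        manifest = {}
        for f in sorted(out.iterdir()):
            # provenance carries wall-clock timing; checksums cover the
            # scientific outputs, which must be identical across reruns
            if f.name in ("manifest.json", "provenance.json") or f.is_dir():
                continue
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def load_abundance_csv(
    matrix_path, metadata_path, feature_path=None, column_map: Optional[dict] = None
) -> AbundanceDataset:
    """Load and validate an abundance matrix + metadata CSV pair.

    Factor labels are whitespace-stripped and lower-cased (with a logged
    warning when that changes anything); unknown levels and sample-id
    mismatches are rejected with locations.  ``column_map`` renames
    nonstandard metadata headers, e.g. ``{"subject": "participant_id"}``.
    """
    matrix = pd.read_csv(matrix_path)
    if matrix.columns[0] != "sample_id":
        matrix = matrix.rename(columns={matrix.columns[0]: "sample_id"})
    if matrix["sample_id"].duplicated().any():
        dup = matrix.loc[matrix["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in matrix: {dup!r}")
    matrix = matrix.set_index("sample_id")
    non_numeric = matrix.apply(
        lambda col: pd.to_numeric(col, errors="coerce").isna() & col.notna()
    )
    if non_numeric.any().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {matrix.index[r]!r}, "
            f"feature {matrix.columns[c]!r}"
        )
    matrix = matrix.apply(pd.to_numeric, errors="coerce")

    meta = pd.read_csv(metadata_path, keep_default_na=False)
    if column_map:
        meta = meta.rename(columns=column_map)
    if "sample_id" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    meta = meta.set_index("sample_id")

    missing_in_meta = matrix.index.difference(meta.index)
    if len(missing_in_meta):
        raise ValueError(
            f"matrix sample ids absent from metadata: {list(missing_in_meta[:5])}"
        )
    missing_in_matrix = meta.index.difference(matrix.index)
    if len(missing_in_matrix):
        raise ValueError(
            f"metadata sample ids absent from matrix: {list(missing_in_matrix[:5])}"
        )
    meta = meta.loc[matrix.index]

    for col in ("sex", "trial", "timepoint", "sample_type"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks column {col!r}")
        cleaned = meta[col].astype(str).str.strip().str.lower()
        changed = cleaned != meta[col].astype(str)
        if changed.any():
            rows = list(meta.index[changed][:3])
            log.warning("normalized %s labels (strip/lower) for rows %s", col, rows)
        meta[col] = cleaned
    if "injection_order" not in meta.columns:
        meta["injection_order"] = np.arange(1, len(meta) + 1)

    study = meta["sample_type"] == "study"
    for col, levels in (("trial", TRIALS), ("timepoint", TIMEPOINTS)):
        bad = ~meta.loc[study, col].isin(levels)
        if bad.any():
            rows = list(meta.index[study][bad][:5])
            raise ValueError(f"unknown {col} labels at rows {rows}")

    feats = None
    if feature_path is not None:
        feats = pd.read_csv(feature_path, index_col="feature_id")
    return AbundanceDataset(matrix, meta, feats)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis; deterministic given the config seed."""
    config.validate()
    t_start = time.time()
    stage = "input"
    try:
        if config.synth is not None:
            synth_cfg = config.synth
            if synth_cfg.seed == 0 and config.seed != 0:
                synth_cfg = synth_cfg.with_(seed=derive_seed(config.seed, "synthio"))
            dataset = generate_cohort(synth_cfg).dataset
        else:
            dataset = load_abundance_csv(
                config.matrix_path, config.metadata_path, config.feature_path
            )

        stage = "qcfilter"
        filtered, report = qcfilter.apply_qc_filters(
            dataset,
            rsd_max=config.rsd_max,
            intensity_floor=config.intensity_floor,
            qc_low_frac=config.qc_low_frac,
            missing_max=config.missing_max,
        )
        imputed = qcfilter.impute_missforest(
            filtered, n_trees=config.impute_trees, seed=derive_seed(config.seed, "impute")
        )

        stage = "foldchange"
        fc = foldchange.compute_log2fc(imputed)

        stage = "opls-prepost"
        prepost_models: Dict[str, opls.OplsModel] = {}
        prepost_perms: Dict[str, opls.PermutationResult] = {}
        if config.run_prepost_models:
            log_mat = np.log2(imputed.study_matrix)
            meta = imputed.study_meta
            for trial in TRIALS:
                rows = meta["trial"] == trial
                X = log_mat.loc[rows.to_numpy()]
                y = meta.loc[rows.to_numpy(), "timepoint"].to_numpy()
                n_o = _resolve_n_ortho(config, X, y, f"prepost-{trial}")
                m = opls.fit_opls_da(X, y, n_ortho=n_o)
                m.q2_cum, _ = opls.cross_validate(
                    X, y, k=config.cv_folds, n_ortho=n_o,
                    seed=derive_seed(config.seed, f"cv-prepost-{trial}"),
                )
                prepost_models[trial] = m
                prepost_perms[trial] = opls.permutation_test(
                    X, y, n_perm=config.n_perm, k=config.cv_folds, n_ortho=n_o,
                    seed=derive_seed(config.seed, f"perm-prepost-{trial}"),
                )

        stage = "opls-comparison"
        trial_a, trial_b = config.comparison
        fc_ab = fc.values[
            fc.values.index.get_level_values("trial").isin([trial_a, trial_b])
        ]
        y_ab = fc_ab.index.get_level_values("trial").to_numpy()
        n_o = _resolve_n_ortho(config, fc_ab, y_ab, "comparison")
        comp_model = opls.fit_opls_da(fc_ab, y_ab, n_ortho=n_o)
        comp_model.q2_cum, _ = opls.cross_validate(
            fc_ab, y_ab, k=config.cv_folds, n_ortho=n_o,
            seed=derive_seed(config.seed, "cv-comparison"),
        )
        comp_perm = opls.permutation_test(
            fc_ab, y_ab, n_perm=config.n_perm, k=config.cv_folds, n_ortho=n_o,
            seed=derive_seed(config.seed, "perm-comparison"),
        )

        stage = "projection"
        fc_proj = fc.for_trial(config.projected_trial)
        t_proj, _, margin = comp_model.project(fc_proj)
        t_a, _, _ = comp_model.project(fc.for_trial(trial_a))
        t_b, _, _ = comp_model.project(fc.for_trial(trial_b))
        projection = pd.concat(
            [
                pd.DataFrame(
                    {"trial": name, "participant_id": tab.index, "t": scores}
                )
                for name, tab, scores in (
                    (trial_a, fc.for_trial(trial_a), t_a),
                    (trial_b, fc.for_trial(trial_b), t_b),
                    (config.projected_trial, fc_proj, t_proj),
                )
            ],
            ignore_index=True,
        )

        stage = "effects"
        eruption = effects.eruption_table(
            fc, comp_model, config.comparison, vip_min=config.vip_min, alpha=config.alpha
        )

        stage = "lmm"
        if config.lmm_scope == "none":
            metabolites: Sequence[str] = []
        elif config.lmm_scope == "key":
            metabolites = list(eruption.key_features)
        else:
            metabolites = list(imputed.matrix.columns)
        if metabolites:
            long = lmm.long_from_dataset(imputed)
            contrasts = lmm.fit_all_metabolites(
                long,
                metabolites,
                bootstrap_B=config.bootstrap_B,
                seed=derive_seed(config.seed, "lmm-bootstrap"),
            )
        else:
            contrasts = pd.DataFrame(
                columns=[
                    "metabolite_id", "contrast", "estimate", "se", "p_raw",
                    "p_bh", "ci_low", "ci_high", "model_form", "converged",
                ]
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise PipelineError(stage, str(exc)) from exc

    provenance = {
        "seed": config.seed,
        "comparison": list(config.comparison),
        "projected_trial": config.projected_trial,
        "n_perm": config.n_perm,
        "cv_folds": config.cv_folds,
        "elapsed_s": round(time.time() - t_start, 2),
        "config": {
            k: v
            for k, v in asdict(config).items()
            if not isinstance(v, (dict,)) or k != "synth"
        },
    }
    return RunResult(
        config=config,
        dataset=imputed,
        filter_report=report,
        fc_table=fc,
        prepost_models=prepost_models,
        prepost_permutations=prepost_perms,
        comparison_model=comp_model,
        comparison_permutation=comp_perm,
        projection_scores=projection,
        eruption=eruption,
        contrasts=contrasts,
        provenance=provenance,
    )


def _resolve_n_ortho(config: RunConfig, X, y, stage: str) -> int:
    if config.n_ortho >= 0:
        return config.n_ortho
    return opls.select_n_ortho(
        X, y, k=config.cv_folds, seed=derive_seed(config.seed, f"northo-{stage}")
    )
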