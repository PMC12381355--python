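#!/usr/bin/env python
"""Fit the OPLS-DA models: pre/post per trial, then the moderate-vs-severe
fold-change model with permutation validation and heavy-trial projection.

Reports R2X/R2Y/Q2/RMSEE per model and the permutation p-values, and writes
predictive scores (including the projected heavy trial) for plotting.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from swimmetab.foldchange import FoldChangeTable
from swimmetab.opls import cross_validate, fit_opls_da, permutation_test
from swimmetab.pipeline import derive_seed, load_abundance_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
SEED = 20250924


def main() -> None:
    ds = load_abundance_csv(
        DATA / "abundance_imputed.csv",
        DATA / "sample_metadata_imputed.csv",
        DATA / "feature_metadata_imputed.csv",
    )
    log_mat = np.log2(ds.study_matrix)
    meta = ds.study_meta

    print("pre-vs-post OPLS-DA per trial (autoscaled log2 abundances):")
    for trial in ("moderate", "heavy", "severe"):
        rows = (meta["trial"] == trial).to_numpy()
        X, y = log_mat.loc[rows], meta.loc[rows, "timepoint"].to_numpy()
        m = fit_opls_da(X, y, n_ortho=1)
        q2, _ = cross_validate(X, y, k=8, n_ortho=1, seed=derive_seed(SEED, f"cv-{trial}"))
        perm = permutation_test(X, y, n_perm=50, k=8, n_ortho=1,
                                seed=derive_seed(SEED, f"perm-{trial}"))
        print(
            f"  {trial:>8}: R2X {m.r2x_cum:.2f}  R2Y {m.r2y_cum:.2f}  Q2 {q2:.2f}  "
            f"RMSEE {m.rmsee:.2f}  pR2Y {perm.p_r2y:.2f}  pQ2 {perm.p_q2:.2f}"
        )

    fc = FoldChangeTable.from_csv(ROOT / "fold_changes.csv")
    both = fc.values[fc.values.index.get_level_values("trial").isin(["moderate", "severe"])]
    y = both.index.get_level_values("trial").to_numpy()
    model = fit_opls_da(both, y, n_ortho=1)
    model.q2_cum, _ = cross_validate(both, y, k=8, n_ortho=1, seed=derive_seed(SEED, "cv-fc"))
    perm = permutation_test(both, y, n_perm=50, k=8, n_ortho=1,
                            seed=derive_seed(SEED, "perm-fc"))
    print(
        f"moderate-vs-severe fold-change model: R2X {model.r2x_cum:.2f}  "
        f"R2Y {model.r2y_cum:.2f}  Q2 {model.q2_cum:.2f}  RMSEE {model.rmsee:.2f}  "
        f"pR2Y {perm.p_r2y:.2f}  pQ2 {perm.p_q2:.2f}"
    )
    model.save(ROOT / "opls_comparison_model")

    scores = []
    for trial in ("moderate", "severe", "heavy"):
        tab = fc.for_trial(trial)
        t, _, _ = model.project(tab)
        scores.append(pd.DataFrame({"trial": trial, "participant_id": tab.index, "t": t}))
    scores = pd.concat(scores, ignore_index=True)
    scores.to_csv(ROOT / "projection_scores.csv", index=False)
    means = scores.groupby("trial")["t"].mean()
    print("mean predictive score by trial (heavy projected, no refit):")
    for trial in ("moderate", "heavy", "severe"):
        print(f"  {trial:>8}: {means[trial]:+.2f}")


if __name__ == "__main__":
    main()
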