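#!/usr/bin/env python
"""Univariate mixed-model follow-up of the key features.

Per metabolite: log2 abundance ~ time * trial + sex with a participant
random intercept and (where AIC prefers it) per-trial residual variances;
pairwise differences in the pre-to-post change between trials with BH
correction and cluster-bootstrap 95% CIs.
"""

from pathlib import Path

import pandas as pd

from swimmetab.lmm import fit_all_metabolites, long_from_dataset
from swimmetab.pipeline import load_abundance_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    ds = load_abundance_csv(
        DATA / "abundance_imputed.csv",
        DATA / "sample_metadata_imputed.csv",
        DATA / "feature_metadata_imputed.csv",
    )
    eruption = pd.read_csv(ROOT / "eruption_table.csv", index_col="feature_id")
    keys = list(eruption.index[eruption["key_feature"]])
    if not keys:
        # fall back to the highest-VIP features so the table is never empty
        keys = list(eruption.sort_values("vip", ascending=False).head(8).index)
        print("no key features; following up the 8 highest-VIP features instead")

    long = long_from_dataset(ds)
    out = fit_all_metabolites(long, keys, bootstrap_B=200, seed=11)
    out.to_csv(ROOT / "lmm_contrasts.csv", index=False)

    print(f"fitted {len(keys)} metabolites; moderate-severe contrasts:")
    ms = out[out["contrast"] == "moderate-severe"].sort_values("estimate")
    for _, row in pd.concat([ms.head(4), ms.tail(4)]).iterrows():
        print(
            f"  {row['metabolite_id']:<18} beta {row['estimate']:+.2f} "
            f"[{row['ci_low']:+.2f}, {row['ci_high']:+.2f}]  p_bh {row['p_bh']:.2e} "
            f"({row['model_form']})"
        )


if __name__ == "__main__":
    main()
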