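#!/usr/bin/env python
"""Eruption table for the moderate-vs-severe comparison.

Cliff's delta per feature against the fitted model's VIP, Welch p-values
with BH adjustment, key-feature flags (VIP > 3, adjusted p < 0.05), and the
delta-vs-VIP eruption plot.
"""

from pathlib import Path

from swimmetab.effects import eruption_table
from swimmetab.foldchange import FoldChangeTable
from swimmetab.opls import fit_opls_da

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fc = FoldChangeTable.from_csv(ROOT / "fold_changes.csv")
    both = fc.values[fc.values.index.get_level_values("trial").isin(["moderate", "severe"])]
    y = both.index.get_level_values("trial").to_numpy()
    model = fit_opls_da(both, y, n_ortho=1)

    tab = eruption_table(fc, model, ("moderate", "severe"))
    tab.to_csv(ROOT / "eruption_table.csv")
    tab.plot(ROOT / "eruption_plot.svg")

    keys = tab.table[tab.table["key_feature"]].sort_values("vip", ascending=False)
    print(f"{len(keys)} key features (VIP > 3, BH-adjusted p < 0.05):")
    for fid, row in keys.head(10).iterrows():
        print(
            f"  {fid:<18} delta {row['cliffs_delta']:+.2f}  VIP {row['vip']:.2f}  "
            f"p_adj {row['p_adjusted']:.2e}"
        )


if __name__ == "__main__":
    main()
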