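"""Nonparametric effect sizes and the eruption-plot table.

An eruption plot combines, per metabolite, a nonparametric effect size
(Cliff's delta between the two compared groups) on one axis with the
multivariate importance (VIP from the OPLS-DA model) on the other, colored
by -log10 p from a univariate test.  Metabolites with VIP > 3.0 and a
Benjamini-Hochberg adjusted p < 0.05 are flagged as key features: because a
feature with a chance-concentrated weight (high VIP) is the same feature
whose raw univariate p is small, only the FDR-adjusted conjunction is
calibrated under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .foldchange import FoldChangeTable
from .opls import OplsModel

VIP_MIN_DEFAULT = 3.0
ALPHA_DEFAULT = 0.05


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y), in [-1, 1].

    delta = (#{(i,j): x_i > y_j} - #{(i,j): x_i < y_j}) / (n_x * n_y); tied
    pairs contribute zero.  Computed in O((n+m) log(n+m)) by counting
    dominated pairs against the sorted second sample — equivalent to full
    pairwise enumeration (the enumeration oracle lives in the test suite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    ys = np.sort(y)
    # for each x_i: #{y_j < x_i} and #{y_j <= x_i}
    below = np.searchsorted(ys, x, side="left")
    below_eq = np.searchsorted(ys, x, side="right")
    greater = int(below.sum())  # pairs with x > y
    less = int((y.size - below_eq).sum())  # pairs with x < y
    return (greater - less) / (x.size * y.size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sorted ascending, adj_i = min_{j >= i} (p_j * m / j), capped at 1; the
    original order is restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class EruptionTable:
    """Per-feature delta / VIP / p summary behind the eruption plot."""

    table: pd.DataFrame  # columns: cliffs_delta, vip, p_value, p_adjusted,
    #                       neg_log10_p, key_feature

    @property
    def key_features(self) -> pd.Index:
        return self.table.index[self.table["key_feature"]]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path)

    def plot(self, path=None, ax=None):
        """Delta-vs-VIP scatter colored by -log10 p (the eruption plot)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        sc = ax.scatter(
            self.table["cliffs_delta"],
            self.table["vip"],
            c=self.table["neg_log10_p"],
            cmap="viridis",
            s=18,
        )
        ax.axhline(VIP_MIN_DEFAULT, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("Cliff's delta")
        ax.set_ylabel("VIP")
        ax.figure.colorbar(sc, ax=ax, label=r"$-\log_{10} p$")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def eruption_table(
    fc_table: FoldChangeTable,
    model: OplsModel,
    comparison: Tuple[str, str],
    test: Literal["welch", "wilcoxon"] = "welch",
    vip_min: float = VIP_MIN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> EruptionTable:
    """Assemble the eruption table for one two-trial comparison.

    Per feature: Cliff's delta of group-a values against group-b values, VIP
    from the fitted model, a two-sided per-feature p (Welch's t by default,
    rank-sum optionally), BH adjustment across features, and the key-feature
    flag (VIP > ``vip_min`` and BH-adjusted p < ``alpha``).
    """
    trial_a, trial_b = comparison
    a = fc_table.for_trial(trial_a)
    b = fc_table.for_trial(trial_b)
    features = a.columns
    if model.feature_names is not None and not features.equals(model.feature_names):
        a = a.loc[:, model.feature_names]
        b = b.loc[:, model.feature_names]
        features = a.columns

    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    deltas = np.array([cliffs_delta(av[:, j], bv[:, j]) for j in range(av.shape[1])])

    if test == "welch":
        res = stats.ttest_ind(av, bv, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif test == "wilcoxon":
        p = np.array(
            [stats.mannwhitneyu(av[:, j], bv[:, j]).pvalue for j in range(av.shape[1])]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    # identical groups give p = NaN under Welch; treat as no evidence
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    vip = model.vip
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "cliffs_delta": deltas,
            "vip": vip,
            "p_value": p,
            "p_adjusted": p_adj,
            "neg_log10_p": -np.log10(p),
            "key_feature": (vip > vip_min) & (p_adj < alpha),
        },
        index=features,
    )
    return EruptionTable(table=table)
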