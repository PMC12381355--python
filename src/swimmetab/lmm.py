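"""Per-metabolite linear mixed models with trial-heteroscedastic residuals.

Model (per metabolite, on log2-scale abundance):

    y_ijk = beta0 + time + trial + time x trial + sex + u_i + e_ijk
    u_i ~ N(0, sigma_p^2)            (participant random intercept)
    e_ijk ~ N(0, sigma^2_{trial(j)}) (optionally one variance per trial)

Fixed effects use treatment coding with reference levels (pre, moderate,
female).  Estimation is REML: for a candidate set of variance parameters the
fixed effects are profiled out by GLS over per-participant blocks, and the
restricted likelihood is maximized numerically over the log-variances.  The
heteroscedastic and homoscedastic forms are both fitted and the lower-AIC
form selected (heterogeneous level-1 variance is kept only where it improves
the fit).  Inference on pairwise trial contrasts — differences in the
pre-to-post change between trials — uses Wald z statistics with
Benjamini-Hochberg correction within the per-metabolite family of three
contrasts, plus nonparametric cluster-bootstrap percentile confidence
intervals resampling participants.

A second entry point fits the per-participant log2 fold-change table
directly (trial + sex fixed effects, participant random intercept); on
balanced data its trial contrasts equal the interaction contrasts of the
full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import AbundanceDataset, TRIALS
from .effects import bh_adjust

LOG2 = np.log(2.0)
_LOGVAR_BOUNDS = (-30.0, 15.0)

CONTRAST_PAIRS = (("moderate", "heavy"), ("moderate", "severe"), ("heavy", "severe"))


class LmmError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# long-table plumbing


def long_from_dataset(dataset: AbundanceDataset, log2_transform: bool = True) -> pd.DataFrame:
    """Melt an imputed dataset into per-observation long format.

    Values are log2-transformed abundances by default so that model
    contrasts read directly in log2 fold-change units.
    """
    mat = dataset.study_matrix
    if (mat.to_numpy(dtype=float) <= 0).any():
        raise ValueError("nonpositive abundances cannot be log-transformed")
    meta = dataset.study_meta
    long = mat.stack().rename("value").reset_index()
    long.columns = ["sample_id", "metabolite_id", "value"]
    for col in ("participant_id", "sex", "trial", "timepoint"):
        long[col] = meta.loc[long["sample_id"], col].to_numpy()
    if log2_transform:
        long["value"] = np.log2(long["value"])
    return long[["participant_id", "sex", "trial", "timepoint", "metabolite_id", "value"]]


def _design_full(df: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """Treatment-coded design: reference levels pre / moderate / female."""
    post = (df["timepoint"] == "post").astype(float).to_numpy()
    heavy = (df["trial"] == "heavy").astype(float).to_numpy()
    severe = (df["trial"] == "severe").astype(float).to_numpy()
    male = (df["sex"] == "male").astype(float).to_numpy()
    X = np.column_stack(
        [np.ones(len(df)), post, heavy, severe, post * heavy, post * severe, male]
    )
    names = [
        "intercept",
        "time[post]",
        "trial[heavy]",
        "trial[severe]",
        "time[post]:trial[heavy]",
        "time[post]:trial[severe]",
        "sex[male]",
    ]
    return X, names


def _design_fc(df: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    heavy = (df["trial"] == "heavy").astype(float).to_numpy()
    severe = (df["trial"] == "severe").astype(float).to_numpy()
    male = (df["sex"] == "male").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(df)), heavy, severe, male])
    return X, ["intercept", "trial[heavy]", "trial[severe]", "sex[male]"]


# ---------------------------------------------------------------------------
# REML core


def _reml_neg2ll(
    logvars: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_slices: List[np.ndarray],
    strata_codes: np.ndarray,
    n_strata: int,
) -> float:
    """-2 x restricted log-likelihood for a random-intercept model with
    per-stratum residual variances (first parameter is the intercept
    variance)."""
    var_p = np.exp(logvars[0])
    var_res = np.exp(logvars[1:])
    p = X.shape[1]
    logdet_v = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    for idx in group_slices:
        d = var_res[strata_codes[idx]]
        V = np.diag(d) + var_p
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v += 2.0 * np.sum(np.log(np.diag(L)))
        Xi = X[idx]
        yi = y[idx]
        sol = np.linalg.solve(V, np.column_stack([Xi, yi]))
        vx, vy = sol[:, :-1], sol[:, -1]
        xtvx += Xi.T @ vx
        xtvy += Xi.T @ vy
        ytvy += yi @ vy
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - xtvy @ beta  # r' V^-1 r for the GLS residual
    n = y.size
    return logdet_v + logdet_xtvx + rss + (n - p) * np.log(2 * np.pi)


def _make_balanced_objective(
    y: np.ndarray,
    X: np.ndarray,
    group_slices: List[np.ndarray],
    strata_codes: np.ndarray,
):
    """Batched REML criterion for equal-sized participant blocks.

    Same value as :func:`_reml_neg2ll`, but the per-participant solves run
    as one stacked (g, m, m) Cholesky instead of a Python loop.
    """
    G = np.vstack(group_slices)  # (g, m)
    g, m = G.shape
    n, p = X.shape
    XG = X[G]  # (g, m, p)
    yG = y[G]  # (g, m)
    sG = strata_codes[G]  # (g, m)
    eye = np.eye(m)
    rhs = np.concatenate([XG, yG[:, :, None]], axis=2)  # (g, m, p+1)

    def objective(logvars: np.ndarray) -> float:
        var_p = np.exp(logvars[0])
        var_res = np.exp(logvars[1:])
        # [g,i,j] = var_p + (i == j) * var_res[stratum of obs i in group g]
        V = var_p + var_res[sG][:, :, None] * eye
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
        sol = np.linalg.solve(V, rhs)  # (g, m, p+1)
        vx, vy = sol[:, :, :-1], sol[:, :, -1]
        xtvx = np.einsum("gmp,gmq->pq", XG, vx)
        xtvy = np.einsum("gmp,gm->p", XG, vy)
        ytvy = float(np.einsum("gm,gm->", yG, vy))
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - xtvy @ beta
        return logdet_v + logdet_xtvx + rss + (n - p) * np.log(2 * np.pi)

    return objective


def _fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    strata: np.ndarray,
    heteroscedastic: bool,
) -> dict:
    """Maximize the REML criterion; returns beta, cov(beta), variances."""
    group_ids, group_codes = np.unique(groups, return_inverse=True)
    group_slices = [np.flatnonzero(group_codes == g) for g in range(len(group_ids))]
    strata_ids, strata_codes = np.unique(strata, return_inverse=True)
    if heteroscedastic:
        n_strata = len(strata_ids)
    else:
        n_strata = 1
        strata_codes = np.zeros_like(strata_codes)

    # moment starts from an OLS fit
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    v0 = max(float(np.var(resid)), 1e-8)
    grp_means = np.array([resid[idx].mean() for idx in group_slices])
    vp0 = max(float(np.var(grp_means)), v0 * 1e-3)
    x0 = np.log(np.concatenate([[vp0], np.full(n_strata, v0)]))
    x0 = np.clip(x0, *_LOGVAR_BOUNDS)

    sizes = {len(idx) for idx in group_slices}
    if len(sizes) == 1:
        balanced = _make_balanced_objective(y, X, group_slices, strata_codes)
        obj = lambda lv: balanced(np.clip(lv, *_LOGVAR_BOUNDS))
    else:
        obj = lambda lv: _reml_neg2ll(
            np.clip(lv, *_LOGVAR_BOUNDS), y, X, group_slices, strata_codes, n_strata
        )
    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    lv = np.clip(res.x, *_LOGVAR_BOUNDS)
    var_p = float(np.exp(lv[0]))
    var_res = np.exp(lv[1:])

    # GLS fixed effects and covariance at the optimum
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for idx in group_slices:
        V = np.diag(var_res[strata_codes[idx]]) + var_p
        sol = np.linalg.solve(V, np.column_stack([X[idx], y[idx]]))
        xtvx += X[idx].T @ sol[:, :-1]
        xtvy += X[idx].T @ sol[:, -1]
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ xtvy

    singular_intercept = var_p < 1e-10 * max(var_res.max(), 1e-12)
    if singular_intercept:
        var_p = 0.0
    loglik = -0.5 * obj(lv)
    by_stratum: Dict[str, float]
    if heteroscedastic:
        by_stratum = {s: float(v) for s, v in zip(strata_ids, var_res)}
    else:
        by_stratum = {s: float(var_res[0]) for s in np.unique(strata)}
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "var_participant": var_p,
        "var_residual_by_stratum": by_stratum,
        "loglik": float(loglik),
        "n_varparams": 1 + n_strata,
        "converged": bool(res.success or res.fun < np.inf),
        "singular_intercept": bool(singular_intercept),
    }


# ---------------------------------------------------------------------------
# public fit objects


@dataclass
class LmmFit:
    """One metabolite's fitted mixed model."""

    metabolite: str
    entry: str  # "abundance" (full model) or "foldchange"
    coef_names: List[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    var_participant: float
    var_residual_by_trial: Dict[str, float]
    loglik: float
    aic: float
    converged: bool
    model_form: str  # "heteroscedastic" | "homoscedastic"
    singular_intercept: bool = False
    data: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.beta, "se": self.se}, index=self.coef_names)

    def _contrast_vector(self, trial_a: str, trial_b: str) -> np.ndarray:
        """Difference in the pre->post change (or in mean log2FC) between
        trial_a and trial_b, as a row on the coefficient vector."""
        c = np.zeros(len(self.coef_names))

        def eff(trial: str, cvec: np.ndarray, sign: float) -> None:
            if self.entry == "abundance":
                # change_t = time[post] + time[post]:trial[t]
                cvec[self.coef_names.index("time[post]")] += sign
                name = f"time[post]:trial[{trial}]"
                if name in self.coef_names:
                    cvec[self.coef_names.index(name)] += sign
            else:
                name = f"trial[{trial}]"
                if name in self.coef_names:
                    cvec[self.coef_names.index(name)] += sign

        eff(trial_a, c, +1.0)
        eff(trial_b, c, -1.0)
        return c

    def contrast_estimate(self, trial_a: str, trial_b: str) -> Tuple[float, float]:
        c = self._contrast_vector(trial_a, trial_b)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        return est, se


def _fit_entry(
    df: pd.DataFrame,
    metabolite: str,
    entry: str,
    heteroscedastic: bool,
    form: str = "auto",
) -> LmmFit:
    """Fit one metabolite.  ``form`` pins the residual-variance structure
    ("homoscedastic" | "heteroscedastic") instead of AIC selection —
    bootstrap replicates reuse the full-data form this way."""
    if entry == "abundance":
        X, names = _design_full(df)
    else:
        X, names = _design_fc(df)
    y = df["value"].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    strata = df["trial"].to_numpy()

    def build(form: str, core: dict) -> LmmFit:
        aic = -2.0 * core["loglik"] + 2.0 * (core["n_varparams"] + X.shape[1])
        return LmmFit(
            metabolite=metabolite,
            entry=entry,
            coef_names=names,
            beta=core["beta"],
            se=np.sqrt(np.diag(core["cov_beta"])),
            cov_beta=core["cov_beta"],
            var_participant=core["var_participant"],
            var_residual_by_trial=core["var_residual_by_stratum"],
            loglik=core["loglik"],
            aic=aic,
            converged=core["converged"],
            model_form=form,
            singular_intercept=core["singular_intercept"],
            data=df,
        )

    if form != "auto":
        het_flag = form == "heteroscedastic"
        return build(form, _fit_reml(y, X, groups, strata, heteroscedastic=het_flag))

    homo = build("homoscedastic", _fit_reml(y, X, groups, strata, heteroscedastic=False))
    if not heteroscedastic:
        return homo
    try:
        het = build("heteroscedastic", _fit_reml(y, X, groups, strata, heteroscedastic=True))
    except (np.linalg.LinAlgError, LmmError):
        return homo
    if not het.converged and homo.converged:
        return homo
    return het if het.aic < homo.aic else homo


def fit_metabolite_lmm(
    table: pd.DataFrame, metabolite: str, heteroscedastic: bool = True
) -> LmmFit:
    """Fit the full model to one metabolite of a long table.

    ``table`` is long format (columns participant_id, sex, trial, timepoint,
    metabolite_id, value) with log-scale values.  With
    ``heteroscedastic=True`` both residual-variance forms are fitted and the
    lower-AIC form returned.
    """
    df = table[table["metabolite_id"] == metabolite]
    if df.empty:
        raise LmmError(f"metabolite {metabolite!r} absent from table")
    if df["participant_id"].nunique() < 2:
        raise LmmError("need >= 2 participants")
    trials_with_both = sum(
        set(g["timepoint"]) >= {"pre", "post"} for _, g in df.groupby("trial")
    )
    if trials_with_both < 2:
        raise LmmError("need both timepoints in >= 2 trials")
    return _fit_entry(df, metabolite, "abundance", heteroscedastic)


def fit_foldchange_lmm(
    fc_long: pd.DataFrame, metabolite: str, heteroscedastic: bool = True
) -> LmmFit:
    """Fit the log2 fold-change entry point (trial + sex, random intercept).

    ``fc_long`` needs columns participant_id, sex, trial, metabolite_id,
    value (= log2FC).  On balanced data its trial contrasts equal the full
    model's interaction contrasts.
    """
    df = fc_long[fc_long["metabolite_id"] == metabolite]
    if df.empty:
        raise LmmError(f"metabolite {metabolite!r} absent from table")
    return _fit_entry(df, metabolite, "foldchange", heteroscedastic)


# ---------------------------------------------------------------------------
# contrasts & bootstrap


@dataclass
class ContrastResult:
    """Pairwise trial contrasts for one metabolite, BH-adjusted."""

    table: pd.DataFrame  # rows: contrast label; columns estimate, se,
    #                      p_raw, p_bh, ci_low, ci_high

    def __getitem__(self, label: str) -> pd.Series:
        return self.table.loc[label]


def pairwise_contrasts(fit: LmmFit) -> ContrastResult:
    """The three trial-pair differences in pre->post change.

    Wald z inference; BH applied within this per-metabolite family of three
    contrasts.  Confidence bounds here are Wald; ``bootstrap_ci`` supplies
    the nonparametric percentile version.
    """
    if not fit.converged:
        raise LmmError("cannot form contrasts on an unconverged fit")
    rows = []
    for a, b in CONTRAST_PAIRS:
        est, se = fit.contrast_estimate(a, b)
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        rows.append(
            {
                "contrast": f"{a}-{b}",
                "estimate": est,
                "se": se,
                "p_raw": max(min(p, 1.0), np.finfo(float).tiny),
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
            }
        )
    tab = pd.DataFrame(rows).set_index("contrast")
    tab["p_bh"] = bh_adjust(tab["p_raw"].to_numpy())
    return ContrastResult(table=tab[["estimate", "se", "p_raw", "p_bh", "ci_low", "ci_high"]])


def _bootstrap_contrast_cis(
    table: pd.DataFrame,
    metabolite: str,
    B: int,
    seed: int,
    entry: str = "abundance",
    heteroscedastic: bool = True,
) -> Dict[Tuple[str, str], Tuple[float, float]]:
    """One set of cluster-bootstrap refits; percentile CIs for all three
    trial contrasts.

    Participants are resampled with replacement (the cluster bootstrap —
    within-participant correlation is preserved), the model refitted per
    replicate with the full-data residual-variance form, and each contrast
    recomputed; bounds are the 2.5/97.5 percentiles over converged
    replicates.  Replicates that fail to converge are dropped; more than
    50% failures is an error.
    """
    fitter = fit_metabolite_lmm if entry == "abundance" else fit_foldchange_lmm
    full = fitter(table, metabolite, heteroscedastic=heteroscedastic)
    if not full.converged:
        raise LmmError("full-data fit did not converge")
    df = table[table["metabolite_id"] == metabolite]
    participants = df["participant_id"].unique()
    by_participant = {pid: df[df["participant_id"] == pid] for pid in participants}
    rng = np.random.default_rng(seed)

    estimates: Dict[Tuple[str, str], list] = {pair: [] for pair in CONTRAST_PAIRS}
    n_failed = 0
    for _ in range(B):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        parts = []
        for k, pid in enumerate(chosen):
            sub = by_participant[pid].copy()
            sub["participant_id"] = f"boot{k:03d}"  # duplicates become distinct clusters
            parts.append(sub)
        boot = pd.concat(parts, ignore_index=True)
        try:
            fit = _fit_entry(boot, metabolite, entry, heteroscedastic, form=full.model_form)
            if not fit.converged:
                raise LmmError("unconverged replicate")
            for pair in CONTRAST_PAIRS:
                est, _ = fit.contrast_estimate(*pair)
                estimates[pair].append(est)
        except (LmmError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > B / 2:
        raise LmmError(f"{n_failed}/{B} bootstrap replicates failed to converge")
    return {
        pair: tuple(np.percentile(vals, [2.5, 97.5])) for pair, vals in estimates.items()
    }


def bootstrap_ci(
    table: pd.DataFrame,
    metabolite: str,
    contrast: Tuple[str, str],
    B: int = 1000,
    seed: int = 0,
    entry: str = "abundance",
    heteroscedastic: bool = True,
) -> Tuple[float, float]:
    """Cluster-bootstrap percentile 95% CI for one trial contrast."""
    cis = _bootstrap_contrast_cis(
        table, metabolite, B, seed, entry=entry, heteroscedastic=heteroscedastic
    )
    trial_a, trial_b = contrast
    for (a, b), bounds in cis.items():
        if {a, b} == {trial_a, trial_b}:
            lo, hi = bounds
            if (a, b) != (trial_a, trial_b):
                lo, hi = -hi, -lo  # requested orientation flips the contrast
            return float(lo), float(hi)
    raise LmmError(f"unknown contrast {contrast!r}")


# ---------------------------------------------------------------------------
# batch driver


def fit_all_metabolites(
    table: pd.DataFrame,
    metabolites: Optional[Sequence[str]] = None,
    heteroscedastic: bool = True,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every requested metabolite; one row per (metabolite, contrast).

    With ``bootstrap_B > 0`` the Wald CI columns are replaced by cluster-
    bootstrap percentile bounds.
    """
    if metabolites is None:
        metabolites = table["metabolite_id"].unique()
    rows = []
    for i, met in enumerate(metabolites):
        fit = fit_metabolite_lmm(table, met, heteroscedastic=heteroscedastic)
        contrasts = pairwise_contrasts(fit)
        boot_cis = None
        if bootstrap_B > 0:
            boot_cis = _bootstrap_contrast_cis(
                table, met, B=bootstrap_B, seed=seed + i,
                heteroscedastic=heteroscedastic,
            )
        for label, row in contrasts.table.iterrows():
            ci_low, ci_high = row["ci_low"], row["ci_high"]
            if boot_cis is not None:
                ci_low, ci_high = boot_cis[tuple(label.split("-"))]
            rows.append(
                {
                    "metabolite_id": met,
                    "contrast": label,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "p_raw": row["p_raw"],
                    "p_bh": row["p_bh"],
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "model_form": fit.model_form,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
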