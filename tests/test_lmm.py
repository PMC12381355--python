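"""Mixed models: recovery, heteroscedastic selection, contrasts, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from swimmetab.lmm import (
    LmmError,
    _design_full,
    _fit_reml,
    bootstrap_ci,
    fit_all_metabolites,
    fit_foldchange_lmm,
    fit_metabolite_lmm,
    long_from_dataset,
    pairwise_contrasts,
)
from swimmetab.foldchange import compute_log2fc
from swimmetab.synthio import CohortConfig, generate_cohort

BETA = {
    "intercept": 10.0,
    "time[post]": 0.5,
    "trial[heavy]": 0.1,
    "trial[severe]": -0.2,
    "time[post]:trial[heavy]": 0.3,
    "time[post]:trial[severe]": 1.5,
    "sex[male]": 0.4,
}


def exact_table(n_participants=4, beta=BETA, intercepts=None, noise=None):
    """Balanced long table generated exactly from the model equation."""
    rows = []
    k = 0
    for pi in range(n_participants):
        sex = "male" if pi < n_participants // 2 else "female"
        u = intercepts[pi] if intercepts is not None else 0.0
        for trial in ("moderate", "heavy", "severe"):
            for tp in ("pre", "post"):
                v = beta["intercept"] + u
                v += beta["time[post]"] if tp == "post" else 0.0
                v += beta.get(f"trial[{trial}]", 0.0)
                if tp == "post":
                    v += beta.get(f"time[post]:trial[{trial}]", 0.0)
                v += beta["sex[male]"] if sex == "male" else 0.0
                if noise is not None:
                    v += noise[k]
                k += 1
                rows.append(
                    dict(
                        participant_id=f"P{pi:02d}",
                        sex=sex,
                        trial=trial,
                        timepoint=tp,
                        metabolite_id="m1",
                        value=v,
                    )
                )
    return pd.DataFrame(rows)


def heteroscedastic_table(seed, n_participants=16, sds=(0.2, 0.2, 0.6), effect=1.5):
    rng = np.random.default_rng(seed)
    n_obs = n_participants * 6
    noise = np.empty(n_obs)
    k = 0
    sd_map = dict(zip(("moderate", "heavy", "severe"), sds))
    for pi in range(n_participants):
        for trial in ("moderate", "heavy", "severe"):
            for tp in ("pre", "post"):
                noise[k] = rng.normal(0.0, sd_map[trial])
                k += 1
    beta = dict(BETA)
    beta["time[post]:trial[severe]"] = effect
    beta["time[post]:trial[heavy]"] = 0.0
    intercepts = rng.normal(0.0, 0.3, n_participants)
    return exact_table(n_participants, beta, intercepts=intercepts, noise=noise)


class TestFit:
    def test_noise_free_recovery_exact(self):
        fit = fit_metabolite_lmm(exact_table(), "m1")
        assert fit.converged
        for name, truth in BETA.items():
            assert fit.fixed_effects.loc[name, "estimate"] == pytest.approx(
                truth, abs=1e-6
            )

    def test_matches_statsmodels_mixedlm_homoscedastic(self):
        import statsmodels.api as sm_api

        df = heteroscedastic_table(seed=0, sds=(0.3, 0.3, 0.3))
        fit = fit_metabolite_lmm(df, "m1", heteroscedastic=False)
        X, names = _design_full(df)
        oracle = sm_api.MixedLM(
            df["value"].to_numpy(), X, groups=df["participant_id"].to_numpy()
        ).fit(reml=True)
        assert np.allclose(fit.beta, oracle.fe_params, atol=1e-4)
        assert fit.var_participant == pytest.approx(
            float(np.asarray(oracle.cov_re)[0, 0]), rel=1e-2
        )
        assert list(fit.var_residual_by_trial.values())[0] == pytest.approx(
            float(oracle.scale), rel=1e-2
        )

    def test_heteroscedastic_wins_aic_when_variances_differ(self):
        fit = fit_metabolite_lmm(heteroscedastic_table(seed=1), "m1")
        assert fit.model_form == "heteroscedastic"
        assert len(fit.var_residual_by_trial) == 3
        assert (
            fit.var_residual_by_trial["severe"] > fit.var_residual_by_trial["moderate"]
        )

    def test_homoscedastic_wins_when_variances_equal(self):
        wins = sum(
            fit_metabolite_lmm(
                heteroscedastic_table(seed=s, sds=(0.3, 0.3, 0.3)), "m1"
            ).model_form
            == "homoscedastic"
            for s in range(10)
        )
        # two extra variance params pay for themselves (delta -2logLik > 4,
        # ~ chi2_2) only ~14% of the time under equal variances
        assert wins >= 7

    def test_forced_equal_variances_reproduce_homoscedastic_loglik(self):
        df = heteroscedastic_table(seed=2, sds=(0.3, 0.3, 0.3))
        X, _ = _design_full(df)
        y = df["value"].to_numpy()
        groups = df["participant_id"].to_numpy()
        strata = df["trial"].to_numpy()
        homo = _fit_reml(y, X, groups, strata, heteroscedastic=False)
        from swimmetab.lmm import _reml_neg2ll

        group_ids, codes = np.unique(groups, return_inverse=True)
        slices = [np.flatnonzero(codes == g) for g in range(len(group_ids))]
        _, s_codes = np.unique(strata, return_inverse=True)
        v = list(homo["var_residual_by_stratum"].values())[0]
        lv = np.log([homo["var_participant"] or 1e-12, v, v, v])
        het_at_equal = -0.5 * _reml_neg2ll(lv, y, X, slices, s_codes, 3)
        assert het_at_equal == pytest.approx(homo["loglik"], abs=1e-6)

    def test_participant_relabeling_invariance(self):
        df = heteroscedastic_table(seed=3)
        fit1 = fit_metabolite_lmm(df, "m1")
        relabeled = df.copy()
        mapping = {
            pid: f"Z{99 - i}" for i, pid in enumerate(df["participant_id"].unique())
        }
        relabeled["participant_id"] = relabeled["participant_id"].map(mapping)
        fit2 = fit_metabolite_lmm(relabeled, "m1")
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-8)

    def test_absent_metabolite_rejected(self):
        with pytest.raises(LmmError, match="absent"):
            fit_metabolite_lmm(exact_table(), "nope")


class TestContrasts:
    def test_planted_change_difference_exact(self):
        beta = dict(BETA)
        beta["time[post]"] = 1.0  # moderate change = +1.0
        beta["time[post]:trial[heavy]"] = -1.0  # heavy change = 0
        beta["time[post]:trial[severe]"] = -1.0  # severe change = 0
        fit = fit_metabolite_lmm(exact_table(beta=beta), "m1")
        contrasts = pairwise_contrasts(fit)
        assert contrasts["moderate-severe"]["estimate"] == pytest.approx(1.0, abs=1e-6)
        assert contrasts["moderate-heavy"]["estimate"] == pytest.approx(1.0, abs=1e-6)
        assert contrasts["heavy-severe"]["estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_ffa_like_ordering_gives_all_positive_contrasts(self):
        # planted changes moderate > heavy > severe, like free fatty acids
        rng = np.random.default_rng(7)
        beta = dict(BETA)
        beta["time[post]"] = 1.0
        beta["time[post]:trial[heavy]"] = -0.6
        beta["time[post]:trial[severe]"] = -1.0
        df = exact_table(
            n_participants=16,
            beta=beta,
            intercepts=rng.normal(0, 0.3, 16),
            noise=rng.normal(0, 0.2, 96),
        )
        contrasts = pairwise_contrasts(fit_metabolite_lmm(df, "m1"))
        assert (contrasts.table["estimate"] > 0).all()

    def test_bh_within_family(self):
        df = heteroscedastic_table(seed=8)
        contrasts = pairwise_contrasts(fit_metabolite_lmm(df, "m1"))
        tab = contrasts.table
        assert (tab["p_bh"] >= tab["p_raw"] - 1e-15).all()
        assert (tab["ci_low"] <= tab["estimate"]).all()
        assert (tab["estimate"] <= tab["ci_high"]).all()

    def test_null_data_has_small_estimates(self):
        rng = np.random.default_rng(9)
        beta = {k: 0.0 for k in BETA}
        beta["intercept"] = 5.0
        df = exact_table(
            n_participants=16, beta=beta, noise=rng.normal(0, 0.1, 96)
        )
        contrasts = pairwise_contrasts(fit_metabolite_lmm(df, "m1"))
        assert np.abs(contrasts.table["estimate"]).max() < 0.2


class TestFoldChangeEntry:
    def test_equals_interaction_contrasts_on_balanced_data(self):
        cfg = CohortConfig(
            n_participants=12,
            n_features_per_class={"glycolytic": 1},
            effect_matrix={("glycolytic", "severe"): 1.2},
            sex_modulation=0.0,
            missing_rate=0.0,
            n_qc=0,
            seed=11,
        )
        ds = generate_cohort(cfg).dataset
        met = ds.matrix.columns[0]

        long = long_from_dataset(ds)
        full = fit_metabolite_lmm(long, met, heteroscedastic=False)

        fc_long = compute_log2fc(ds).to_long()
        fc_fit = fit_foldchange_lmm(fc_long, met, heteroscedastic=False)

        for pair in (("moderate", "heavy"), ("moderate", "severe")):
            est_full, _ = full.contrast_estimate(*pair)
            est_fc, _ = fc_fit.contrast_estimate(*pair)
            assert est_full == pytest.approx(est_fc, abs=1e-4)


class TestBootstrap:
    def test_zero_noise_ci_degenerate(self):
        df = exact_table(n_participants=6)
        lo, hi = bootstrap_ci(
            df, "m1", ("moderate", "severe"), B=30, seed=0, heteroscedastic=False
        )
        truth = -BETA["time[post]:trial[severe]"]
        assert hi - lo < 1e-6
        assert lo == pytest.approx(truth, abs=1e-6)

    def test_seeded_determinism(self):
        df = heteroscedastic_table(seed=12, n_participants=8)
        a = bootstrap_ci(df, "m1", ("moderate", "severe"), B=20, seed=5, heteroscedastic=False)
        b = bootstrap_ci(df, "m1", ("moderate", "severe"), B=20, seed=5, heteroscedastic=False)
        assert a == b

    def test_coverage_at_reduced_scale(self):
        # planted moderate-severe fold-change difference of 1.0 with noise;
        # nominal 95% percentile CI should cover the truth nearly always in
        # a small run
        hits = 0
        n_outer = 12
        for rep in range(n_outer):
            rng = np.random.default_rng(100 + rep)
            rows = []
            for pi in range(16):
                u = rng.normal(0, 0.2)
                sex = "male" if pi < 8 else "female"
                for trial, eff in (("moderate", 1.0), ("heavy", 0.5), ("severe", 0.0)):
                    rows.append(
                        dict(
                            participant_id=f"P{pi:02d}", sex=sex, trial=trial,
                            metabolite_id="m1", value=eff + u + rng.normal(0, 0.3),
                        )
                    )
            fc = pd.DataFrame(rows)
            lo, hi = bootstrap_ci(
                fc, "m1", ("moderate", "severe"), B=60, seed=rep,
                entry="foldchange", heteroscedastic=False,
            )
            if lo <= 1.0 <= hi:
                hits += 1
        assert hits >= int(0.8 * n_outer)


def test_batch_driver_shapes():
    cfg = CohortConfig(
        n_participants=8,
        n_features_per_class={"glycolytic": 2},
        missing_rate=0.0,
        n_qc=0,
        seed=13,
    )
    long = long_from_dataset(generate_cohort(cfg).dataset)
    out = fit_all_metabolites(long, heteroscedastic=False)
    assert len(out) == 2 * 3  # two metabolites x three contrasts
    assert set(out["contrast"]) == {"moderate-heavy", "moderate-severe", "heavy-severe"}
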