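"""OPLS-DA: oracle equivalence, cross-validation, permutations, VIP,
projection."""

import numpy as np
import pandas as pd
import pytest

from swimmetab.foldchange import autoscale, compute_log2fc
from swimmetab.opls import (
    OplsError,
    OplsModel,
    compute_vip,
    cross_validate,
    fit_opls_da,
    permutation_test,
    select_n_ortho,
)
from swimmetab.synthio import CohortConfig, generate_cohort


def pls1_oracle(X, y_coded):
    """Brute-force single-component NIPALS PLS1, written with explicit loops.

    Independent of the package implementation; X pre-scaled, y centered.
    """
    n, p = X.shape
    yc = y_coded - np.mean(y_coded)
    w = np.zeros(p)
    for j in range(p):
        for i in range(n):
            w[j] += X[i, j] * yc[i]
    norm = np.sqrt(sum(wj * wj for wj in w))
    w = w / norm
    i_max = int(np.argmax(np.abs(w)))
    if w[i_max] < 0:
        w = -w
    t = np.array([sum(X[i, j] * w[j] for j in range(p)) for i in range(n)])
    tt = sum(ti * ti for ti in t)
    c = sum(yc[i] * t[i] for i in range(n)) / tt
    p_load = np.array([sum(X[i, j] * t[i] for i in range(n)) / tt for j in range(p)])
    yhat = t * c
    return w, t, c, p_load, yhat


def two_class_matrix(seed, n=24, p=50, signal=0.0):
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * (n // 2))
    X = rng.normal(size=(n, p))
    if signal:
        X[y == "b", :5] += signal
    return X, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_n_ortho_zero_matches_pls1(self, seed):
        X, y = two_class_matrix(seed, signal=1.0)
        Xs, _ = autoscale(X)
        model = fit_opls_da(Xs, y, n_ortho=0, scale=False)
        w, t, c, p_load, yhat = pls1_oracle(Xs, (y == "b").astype(float))
        assert np.allclose(model.w, w, atol=1e-8)
        assert np.allclose(model.t, t, atol=1e-8)
        assert model.c == pytest.approx(c, abs=1e-8)
        assert np.allclose(model.p, p_load, atol=1e-8)
        assert np.allclose(model.t * model.c, yhat, atol=1e-8)


class TestFit:
    def test_indicator_column_dominates(self):
        # pre-scaled input: the class column carries the signal, the rest is
        # low-amplitude noise
        rng = np.random.default_rng(10)
        n = 24
        y = np.array(["a"] * 12 + ["b"] * 12)
        X = rng.normal(scale=0.05, size=(n, 12))
        X[:, 0] = np.where(y == "b", 1.0, -1.0)
        model = fit_opls_da(X, y, n_ortho=0, scale=False)
        assert model.r2y_cum > 0.99
        assert np.argmax(np.abs(model.w)) == 0

    def test_identical_classes_give_no_separation(self):
        rng = np.random.default_rng(11)
        half = rng.normal(size=(8, 10))
        X = np.vstack([half, half])  # class b duplicates class a exactly
        y = np.array(["a"] * 8 + ["b"] * 8)
        model = fit_opls_da(X, y, n_ortho=0)
        assert abs(model.r2y_cum) < 1e-8

    def test_three_classes_rejected(self):
        X = np.random.default_rng(0).normal(size=(9, 4))
        y = np.array(["a", "b", "c"] * 3)
        with pytest.raises(OplsError, match="two-class"):
            fit_opls_da(X, y)

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        y = np.array(["a"] * 4 + ["b"] * 2)
        with pytest.raises(OplsError, match=">= 3"):
            fit_opls_da(X, y)

    def test_repeat_fits_bit_identical(self):
        X, y = two_class_matrix(3, signal=0.7)
        m1 = fit_opls_da(X, y, n_ortho=1)
        m2 = fit_opls_da(X, y, n_ortho=1)
        assert np.array_equal(m1.w, m2.w)
        assert np.array_equal(m1.t, m2.t)
        assert np.array_equal(m1.w_ortho, m2.w_ortho)

    def test_orthogonal_scores_uncorrelated_with_predictive(self):
        X, y = two_class_matrix(4, signal=0.8)
        model = fit_opls_da(X, y, n_ortho=2)
        for t_o in model.t_ortho:
            assert abs(np.corrcoef(model.t, t_o)[0, 1]) < 1e-8

    def test_r2y_monotone_in_n_ortho(self):
        X, y = two_class_matrix(5, signal=0.5)
        r2y = [fit_opls_da(X, y, n_ortho=k).r2y_cum for k in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2y, r2y[1:]))

    def test_r2x_r2y_in_unit_interval(self):
        X, y = two_class_matrix(6, signal=0.5)
        for k in (0, 1, 2):
            m = fit_opls_da(X, y, n_ortho=k)
            assert 0.0 <= m.r2x_cum <= 1.0
            assert 0.0 <= m.r2y_cum <= 1.0
            assert np.linalg.norm(m.w) == pytest.approx(1.0)


class TestCrossValidation:
    def test_separable_data_has_high_q2(self):
        # several near-duplicate class-indicator columns survive the
        # within-fold autoscaling with little weight leakage
        rng = np.random.default_rng(12)
        y = np.array(["a", "b"] * 12)
        X = rng.normal(size=(24, 20))
        ind = np.where(y == "b", 1.0, -1.0)
        for j in range(8):
            X[:, j] = ind + rng.normal(0, 0.05, 24)
        q2, _ = cross_validate(X, y, k=8, n_ortho=0, seed=1)
        assert q2 > 0.9

    def test_permuted_labels_have_negative_expected_q2(self):
        rng = np.random.default_rng(13)
        q2s = []
        for rep in range(20):
            y = np.array(["a", "b"] * 12)
            X = rng.normal(size=(24, 15))
            ind = np.where(y == "b", 1.0, -1.0)
            for j in range(5):
                X[:, j] = ind + rng.normal(0, 0.1, 24)
            y_perm = rng.permutation(y)
            q2, _ = cross_validate(X, y_perm, k=8, n_ortho=0, seed=rep)
            q2s.append(q2)
        assert np.mean(q2s) < 0.0

    def test_seeded_determinism(self):
        X, y = two_class_matrix(14, signal=0.6)
        a = cross_validate(X, y, k=8, n_ortho=1, seed=7)
        b = cross_validate(X, y, k=8, n_ortho=1, seed=7)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])

    def test_folds_are_stratified(self):
        X, y = two_class_matrix(15)
        _, folds = cross_validate(X, y, k=4, n_ortho=0, seed=0)
        for fold in range(4):
            labels = y[folds == fold]
            assert set(labels) == {"a", "b"}

    def test_k_larger_than_n_rejected(self):
        X, y = two_class_matrix(16, n=8)
        with pytest.raises(OplsError):
            cross_validate(X, y, k=20)


class TestPermutationTest:
    def test_strong_signal_hits_the_floor(self):
        X, y = two_class_matrix(20, signal=3.0)
        res = permutation_test(X, y, n_perm=50, k=8, seed=2)
        assert res.p_r2y == pytest.approx(1 / 50)
        assert res.p_q2 == pytest.approx(1 / 50)
        assert res.n_perm == 50

    def test_null_data_gives_large_p_sometimes(self):
        rng = np.random.default_rng(21)
        large_p = 0
        for rep in range(20):
            X, y = two_class_matrix(100 + rep, signal=2.0)
            y_null = rng.permutation(y)  # break the signal-label link
            res = permutation_test(X, y_null, n_perm=20, k=4, seed=rep)
            if res.p_q2 > 0.5:
                large_p += 1
        assert large_p >= 1

    def test_p_respects_floor(self):
        X, y = two_class_matrix(22, signal=2.0)
        for n_perm in (1, 5, 20):
            res = permutation_test(X, y, n_perm=n_perm, k=4, seed=0)
            assert res.p_r2y >= 1 / n_perm
            assert res.p_q2 >= 1 / n_perm
            assert res.p_r2y <= 1.0 and res.p_q2 <= 1.0


class TestVip:
    def test_uniform_weights_give_unit_vip(self):
        p = 16
        model = _bare_model(w=np.full(p, 1.0 / np.sqrt(p)))
        assert np.allclose(compute_vip(model), 1.0)

    def test_mean_square_is_one_for_fitted_models(self):
        for seed in (0, 1, 2):
            X, y = two_class_matrix(seed, signal=0.8)
            model = fit_opls_da(X, y, n_ortho=1)
            assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_indicator_column_has_max_vip_above_3(self):
        # weight concentrates on the lone informative column, so with
        # p >= 10 features its VIP = sqrt(p) |w| exceeds 3
        rng = np.random.default_rng(30)
        y = np.array(["a"] * 12 + ["b"] * 12)
        X = rng.normal(scale=0.05, size=(24, 12))
        X[:, 0] = np.where(y == "b", 1.0, -1.0)
        model = fit_opls_da(X, y, n_ortho=0, scale=False)
        assert np.argmax(model.vip) == 0
        assert model.vip[0] > 3.0


def _bare_model(w):
    p = w.size
    return OplsModel(
        w=w, p=np.zeros(p), t=np.zeros(4), c=1.0,
        w_ortho=np.empty((0, p)), p_ortho=np.empty((0, p)), t_ortho=np.empty((0, 4)),
        scaler=None, y_mean=0.5, class_labels=["a", "b"],
        r2x_cum=0.0, r2y_cum=0.0, rmsee=0.0, n_ortho=0,
    )


class TestProjection:
    def test_self_projection_reproduces_training_scores(self):
        X, y = two_class_matrix(40, signal=1.0)
        model = fit_opls_da(X, y, n_ortho=2)
        t, t_o, _ = model.project(X)
        assert np.allclose(t, model.t, atol=1e-10)
        assert np.allclose(t_o, model.t_ortho, atol=1e-10)

    def test_class_centroids_on_opposite_sides(self):
        X, y = two_class_matrix(41, signal=1.5)
        model = fit_opls_da(X, y, n_ortho=1)
        centroids = np.vstack([X[y == "a"].mean(0), X[y == "b"].mean(0)])
        t, _, margin = model.project(centroids)
        assert t[0] * t[1] < 0
        assert margin[0] < 0 < margin[1]

    def test_feature_mismatch_reported(self):
        X, y = two_class_matrix(42)
        Xdf = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        model = fit_opls_da(Xdf, y, n_ortho=1)
        with pytest.raises(OplsError, match="f0"):
            model.project(Xdf.drop(columns=["f0"]))

    def test_intermediate_class_projects_between_training_means(self):
        cfg = CohortConfig(
            n_participants=16,
            n_features_per_class={"ffa": 15, "glycolytic": 10, "inert": 25},
            missing_rate=0.0,
            n_qc=0,
            seed=77,
        )
        fc = compute_log2fc(generate_cohort(cfg).dataset)
        both = fc.values[
            fc.values.index.get_level_values("trial").isin(["moderate", "severe"])
        ]
        y = both.index.get_level_values("trial").to_numpy()
        model = fit_opls_da(both, y, n_ortho=1)
        t_mod, _, _ = model.project(fc.for_trial("moderate"))
        t_sev, _, _ = model.project(fc.for_trial("severe"))
        t_heavy, _, _ = model.project(fc.for_trial("heavy"))
        lo, hi = sorted([t_mod.mean(), t_sev.mean()])
        assert lo < t_heavy.mean() < hi


def test_select_n_ortho_stops_when_q2_stalls():
    rng = np.random.default_rng(50)
    y = np.array(["a", "b"] * 12)
    X = rng.normal(size=(24, 20))
    ind = np.where(y == "b", 1.0, -1.0)
    for j in range(8):
        X[:, j] = ind + rng.normal(0, 0.05, 24)  # clean signal: no ortho needed
    assert select_n_ortho(X, y, k=4, seed=0) == 0


def test_model_save_round_trip(tmp_path):
    X, y = two_class_matrix(60, signal=1.0)
    model = fit_opls_da(X, y, n_ortho=1)
    model.save(tmp_path / "model")
    import json

    manifest = json.loads((tmp_path / "model" / "manifest.json").read_text())
    assert manifest["n_ortho"] == 1
    loadings = pd.read_csv(tmp_path / "model" / "loadings.csv", index_col=0)
    assert np.allclose(loadings["w"].to_numpy(), model.w)
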