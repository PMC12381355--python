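"""Orthogonal projections to latent structures discriminant analysis.

OPLS-DA separates, for a two-class response, the predictor variation that is
correlated with class membership (one predictive component for a single
response) from variation orthogonal to it (one or more orthogonal
components).  This module implements the NIPALS/orthogonal-signal-correction
algorithm from scratch: fitting, stratified k-fold cross-validation (Q2),
class-label permutation testing of R2Y and Q2, variable importance in
projection (VIP), and projection of new observations — including a third
class — onto a fitted two-class model without refitting.

Conventions
-----------
* The two class labels are sorted and coded {0, 1}, then mean-centered.
* Each weight vector is sign-fixed so its largest-magnitude element is
  positive (NIPALS leaves the sign undetermined; this makes repeat fits
  bit-identical).
* Scaling parameters (column means/SDs) fitted on training data are stored
  on the model and reused for every projection; held-out data are never
  scaled with their own statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .foldchange import Autoscaler, _as_array


class OplsError(ValueError):
    pass


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude element is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _encode_y(y: Sequence) -> Tuple[np.ndarray, List]:
    y = np.asarray(y)
    labels = sorted(pd.unique(y).tolist())
    if len(labels) != 2:
        raise OplsError(
            f"OPLS-DA here is strictly two-class (one-vs-one); got {len(labels)} "
            f"classes {labels}"
        )
    coded = (y == labels[1]).astype(float)
    counts = [int((coded == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 3:
        raise OplsError(f"each class needs >= 3 members, got sizes {counts}")
    return coded, labels


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (1 predictive + ``n_ortho`` orthogonal comps)."""

    w: np.ndarray  # predictive weights, unit norm
    p: np.ndarray  # predictive loadings
    t: np.ndarray  # predictive scores (training)
    c: float  # response loading
    w_ortho: np.ndarray  # (n_ortho, n_features)
    p_ortho: np.ndarray
    t_ortho: np.ndarray  # (n_ortho, n_samples)
    scaler: Optional[Autoscaler]
    y_mean: float
    class_labels: List
    r2x_cum: float
    r2y_cum: float
    rmsee: float
    n_ortho: int
    q2_cum: Optional[float] = None
    feature_names: Optional[pd.Index] = None
    vip: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_pred(self) -> int:
        return 1

    def _prepare(self, X_new) -> np.ndarray:
        X = _as_array(X_new)
        if isinstance(X_new, pd.DataFrame) and self.feature_names is not None:
            missing = self.feature_names.difference(X_new.columns)
            if len(missing):
                raise OplsError(f"projection input lacks features: {list(missing[:10])}")
            X = X_new.loc[:, self.feature_names].to_numpy(dtype=float)
        if X.shape[1] != self.w.size:
            raise OplsError(
                f"projection input has {X.shape[1]} features, model has {self.w.size}"
            )
        if self.scaler is not None:
            X = (X - self.scaler.means) / self.scaler.sds
        return X

    def project(self, X_new) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project new observations; no refit occurs.

        Returns (predictive scores, orthogonal scores with one row per
        orthogonal component, centered class margin).  The margin's sign
        predicts the class: negative -> ``class_labels[0]``, positive ->
        ``class_labels[1]``.
        """
        X = self._prepare(X_new)
        t_orthos = []
        for wo, po in zip(self.w_ortho, self.p_ortho):
            t_o = X @ wo
            X = X - np.outer(t_o, po)
            t_orthos.append(t_o)
        t = X @ self.w
        t_ortho = np.vstack(t_orthos) if t_orthos else np.empty((0, X.shape[0]))
        margin = t * self.c + self.y_mean - 0.5
        return t, t_ortho, margin

    def predict_labels(self, X_new) -> np.ndarray:
        _, _, margin = self.project(X_new)
        return np.where(margin > 0, self.class_labels[1], self.class_labels[0])

    # -- serialization -----------------------------------------------------

    def save(self, directory) -> None:
        """Serialize as a directory of CSV blocks plus a manifest."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        feats = (
            self.feature_names
            if self.feature_names is not None
            else pd.Index([f"f{i}" for i in range(self.w.size)])
        )
        pd.DataFrame(
            {
                "w": self.w,
                "p": self.p,
                "vip": self.vip,
                "mean": self.scaler.means if self.scaler else np.zeros_like(self.w),
                "sd": self.scaler.sds if self.scaler else np.ones_like(self.w),
                **{f"w_ortho_{i}": wo for i, wo in enumerate(self.w_ortho)},
                **{f"p_ortho_{i}": po for i, po in enumerate(self.p_ortho)},
            },
            index=feats,
        ).to_csv(d / "loadings.csv")
        scores = pd.DataFrame({"t": self.t})
        for i, to in enumerate(self.t_ortho):
            scores[f"t_ortho_{i}"] = to
        scores.to_csv(d / "scores.csv", index=False)
        manifest = {
            "class_labels": [str(c) for c in self.class_labels],
            "c": self.c,
            "y_mean": self.y_mean,
            "n_ortho": self.n_ortho,
            "r2x_cum": self.r2x_cum,
            "r2y_cum": self.r2y_cum,
            "q2_cum": self.q2_cum,
            "rmsee": self.rmsee,
            "blocks": ["loadings.csv", "scores.csv"],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def fit_opls_da(
    X,
    y: Sequence,
    n_ortho: int = 1,
    scale: bool = True,
) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    X
        Sample x feature matrix (DataFrame or array).  With ``scale=True``
        (default) columns are autoscaled internally and the scaling stored
        on the model; pass ``scale=False`` for pre-scaled input.
    y
        Class label per row; exactly two distinct labels, each with >= 3
        members.
    n_ortho
        Number of orthogonal (y-uncorrelated) components removed before the
        single predictive component.
    """
    feature_names = X.columns if isinstance(X, pd.DataFrame) else None
    Xa = _as_array(X)
    yc_raw, labels = _encode_y(y)
    n, p_feat = Xa.shape
    if n < n_ortho + 2:
        raise OplsError(f"need >= n_ortho + 2 = {n_ortho + 2} samples, got {n}")

    scaler = None
    if scale:
        scaler = Autoscaler().fit(X if feature_names is not None else Xa)
        Xs = (Xa - scaler.means) / scaler.sds
    else:
        Xs = Xa.copy()

    y_mean = float(yc_raw.mean())
    yc = yc_raw - y_mean
    ss_y = float(yc @ yc)
    ss_x = float(np.sum(Xs**2))
    if ss_y == 0:
        raise OplsError("constant class vector")

    # predictive weight direction from the undeflated matrix
    w = Xs.T @ yc
    norm_w = np.linalg.norm(w)
    if norm_w < 1e-12:
        # X carries no covariance with the class vector at all (e.g. the two
        # classes share identical rows); fall back to a flat direction so the
        # fit degenerates gracefully to R2Y ~ 0 instead of dividing by zero
        w = np.full(p_feat, 1.0 / np.sqrt(p_feat))
    else:
        w = w / norm_w
    w = _sign_fix(w)

    Xd = Xs.copy()
    w_os, p_os, t_os = [], [], []
    r2x_parts = []
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o = _sign_fix(w_o / norm)
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
        r2x_parts.append(float((t_o @ t_o) * (p_o @ p_o)))

    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    r2x_parts.append(float((t @ t) * (p_load @ p_load)))

    resid = yc - t * c
    ss_res = float(resid @ resid)
    n_components = 1 + len(w_os)
    dof = max(n - 1 - n_components, 1)

    model = OplsModel(
        w=w,
        p=p_load,
        t=t,
        c=c,
        w_ortho=np.vstack(w_os) if w_os else np.empty((0, p_feat)),
        p_ortho=np.vstack(p_os) if p_os else np.empty((0, p_feat)),
        t_ortho=np.vstack(t_os) if t_os else np.empty((0, n)),
        scaler=scaler,
        y_mean=y_mean,
        class_labels=labels,
        r2x_cum=float(sum(r2x_parts) / ss_x) if ss_x > 0 else 0.0,
        r2y_cum=float(1.0 - ss_res / ss_y),
        rmsee=float(np.sqrt(ss_res / dof)),
        n_ortho=len(w_os),
        feature_names=feature_names,
    )
    model.vip = compute_vip(model)
    return model


def compute_vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over predictive components.

    With a single predictive component, VIP_j = sqrt(p_feat) * |w_j| (the
    weight vector has unit norm), so sum(VIP^2) = p_feat and mean(VIP^2) = 1.
    """
    if model.w is None:
        raise OplsError("model not fitted")
    p_feat = model.w.size
    # single predictive component: the SSY weighting collapses
    return np.sqrt(p_feat) * np.abs(model.w) / np.linalg.norm(model.w)


def _stratified_folds(y_coded: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per sample; classes dealt round-robin after a seeded shuffle.

    With n mod k leftover samples, the extras land in the first folds.
    """
    n = y_coded.size
    if k > n:
        raise OplsError(f"k={k} exceeds n={n}")
    if k < 2:
        raise OplsError("k must be >= 2")
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y_coded == cls)
        idx = rng.permutation(idx)
        for j, sample in enumerate(idx):
            folds[sample] = (j + offset) % k
        offset += len(idx)  # stagger so small classes spread across folds
    return folds


def cross_validate(
    X,
    y: Sequence,
    k: int = 8,
    n_ortho: int = 1,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Stratified k-fold cross-validated Q2.

    Q2 = 1 - PRESS / SS_tot(y), PRESS summing squared held-out prediction
    errors over all folds.  Autoscaling is refit inside each training fold
    and applied to the held-out fold.
    """
    Xa = _as_array(X)
    yc_raw, labels = _encode_y(y)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(yc_raw, k, rng)

    press = 0.0
    y_arr = np.asarray(y)
    for fold in range(k):
        test = folds == fold
        train = ~test
        if not test.any():
            continue
        if len(np.unique(yc_raw[train])) < 2:
            raise OplsError(f"fold {fold}: training split lost a class")
        model = fit_opls_da(Xa[train], y_arr[train], n_ortho=n_ortho, scale=True)
        t_new, _, _ = model.project(Xa[test])
        yhat = t_new * model.c + model.y_mean
        press += float(np.sum((yc_raw[test] - yhat) ** 2))
    ss_tot = float(np.sum((yc_raw - yc_raw.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    return q2, folds


def select_n_ortho(
    X, y, k: int = 8, seed: int = 0, max_ortho: int = 5, min_gain: float = 0.01
) -> int:
    """Add orthogonal components while cross-validated Q2 improves by more
    than ``min_gain``; capped at ``max_ortho``."""
    best_q2, _ = cross_validate(X, y, k=k, n_ortho=0, seed=seed)
    best = 0
    for n_o in range(1, max_ortho + 1):
        q2, _ = cross_validate(X, y, k=k, n_ortho=n_o, seed=seed)
        if q2 > best_q2 + min_gain:
            best_q2, best = q2, n_o
        else:
            break
    return best


@dataclass
class PermutationResult:
    """Null distributions of R2Y and Q2 under class-label permutation."""

    observed_r2y: float
    observed_q2: float
    perm_r2y: np.ndarray
    perm_q2: np.ndarray
    p_r2y: float
    p_q2: float

    @property
    def n_perm(self) -> int:
        return self.perm_r2y.size


def permutation_test(
    X,
    y: Sequence,
    n_perm: int = 50,
    k: int = 8,
    n_ortho: int = 1,
    seed: int = 0,
) -> PermutationResult:
    """Class-label permutation test of R2Y and Q2.

    For each permutation the class vector is shuffled and the full
    fit + cross-validation pipeline re-run.  p = (1 + #{perm >= observed})
    / n_perm, so the smallest attainable p is 1/n_perm (0.02 at the default
    50 permutations).
    """
    if n_perm < 1:
        raise OplsError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y_arr = np.asarray(y)

    model = fit_opls_da(X, y_arr, n_ortho=n_ortho, scale=True)
    obs_q2, _ = cross_validate(X, y_arr, k=k, n_ortho=n_ortho, seed=int(rng.integers(2**31)))
    obs_r2y = model.r2y_cum

    perm_r2y = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y_arr)
        m = fit_opls_da(X, y_perm, n_ortho=n_ortho, scale=True)
        q2, _ = cross_validate(
            X, y_perm, k=k, n_ortho=n_ortho, seed=int(rng.integers(2**31))
        )
        perm_r2y[b] = m.r2y_cum
        perm_q2[b] = q2

    p_r2y = (1 + int(np.sum(perm_r2y >= obs_r2y))) / n_perm
    p_q2 = (1 + int(np.sum(perm_q2 >= obs_q2))) / n_perm
    return PermutationResult(
        observed_r2y=obs_r2y,
        observed_q2=obs_q2,
        perm_r2y=perm_r2y,
        perm_q2=perm_q2,
        p_r2y=min(p_r2y, 1.0),
        p_q2=min(p_q2, 1.0),
    )
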