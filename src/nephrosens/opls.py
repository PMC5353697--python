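"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

NIPALS-based OPLS-DA with cross-validated Q2, R2X/R2Y, and VIP (variable
importance in the projection) with jackknife confidence intervals.  The
orthogonal filter removes class-uncorrelated X variation before each
predictive component, so score plots separate between-class from
within-class structure; for a single response the fitted predictions
coincide with an ordinary PLS model of matched total component count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .matrix import IntensityMatrix
from .preprocess import _scale_matrix

_TOL = 1e-10
_MAX_ITER = 500


class FitError(RuntimeError):
    pass


def _as_array(X):
    if isinstance(X, IntensityMatrix):
        return X.values.to_numpy(dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _encode_labels(y, classes: np.ndarray) -> np.ndarray:
    """Class labels -> indicator matrix: single 0/1 column for two classes,
    one-hot for more."""
    y = np.asarray(y)
    if len(classes) == 2:
        return (y == classes[1]).astype(float)[:, None]
    return (y[:, None] == classes[None, :]).astype(float)


class OPLSDA(BaseEstimator, ClassifierMixin):
    """OPLS-DA classifier with NIPALS fitting.

    Parameters
    ----------
    n_pred : int
        Predictive components.  For more than two classes the convention is
        ``n_classes - 1``.
    n_orth : int
        Orthogonal (class-uncorrelated) components removed before the
        predictive fit.
    scaling : {'uv', 'pareto'}
        Column scaling after mean centering: unit variance or Pareto
        (square root of the standard deviation).

    Attributes
    ----------
    x_weights_, x_loadings_, x_scores_ : predictive W, P, T
    y_loadings_ : class-indicator loadings C
    orth_weights_, orth_loadings_, orth_scores_ : orthogonal W_o, P_o, T_o
    r2x_ : float -- fraction of scaled-X variance modelled (pred + orth)
    r2y_ : float -- fraction of centered class-indicator variance modelled
    """

    def __init__(self, n_pred: int = 1, n_orth: int = 1, scaling: str = "uv"):
        self.n_pred = n_pred
        self.n_orth = n_orth
        self.scaling = scaling

    # ------------------------------------------------------------------
    def fit(self, X, y):
        Xa = _as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise FitError("need at least 2 classes")
        for c in self.classes_:
            # technical minimum; the user-facing contract (>= 3 per class)
            # is enforced by fit_oplsda so that CV/jackknife refits stay legal
            if (y == c).sum() < 2:
                raise FitError(f"class {c!r} has fewer than 2 samples")
        if self.n_pred < 1:
            raise FitError("n_pred must be >= 1")

        Y = _encode_labels(y, self.classes_)
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_
        Xs, self.x_mean_, self.x_div_ = _scale_matrix(Xa, self.scaling)
        n, p = Xs.shape
        m = Yc.shape[1]
        ss_x = float((Xs**2).sum())
        ss_y = float((Yc**2).sum())

        # fixed basis of the class-predictive weight space (from undeflated X)
        W0 = Xs.T @ Yc
        U0, s0, _ = np.linalg.svd(W0, full_matrices=False)
        basis = U0[:, s0 > s0[0] * 1e-12] if s0[0] > 0 else U0[:, :0]
        if basis.shape[1] == 0:
            raise FitError("X carries no class-correlated variation")

        Xd = Xs.copy()
        W_o, P_o, T_o = [], [], []
        for _ in range(self.n_orth):
            w = basis[:, :1] if m == 1 else self._nipals_weight(Xd, Yc)
            t = Xd @ w
            tt = float(np.vdot(t, t))
            if tt < _TOL:
                raise FitError(
                    "rank deficiency during orthogonal extraction; at most "
                    f"{len(W_o)} orthogonal components are feasible"
                )
            p_load = (Xd.T @ t) / tt
            w_orth = p_load - basis @ (basis.T @ p_load)
            norm = float(np.linalg.norm(w_orth))
            if norm < 1e-12:
                warnings.warn(
                    "no further orthogonal variation; stopping at "
                    f"{len(W_o)} orthogonal components"
                )
                break
            w_orth /= norm
            t_orth = Xd @ w_orth
            p_orth = (Xd.T @ t_orth) / float(np.vdot(t_orth, t_orth))
            Xd = Xd - t_orth @ p_orth.T
            W_o.append(w_orth)
            P_o.append(p_orth)
            T_o.append(t_orth)

        self.orth_weights_ = np.hstack(W_o) if W_o else np.zeros((p, 0))
        self.orth_loadings_ = np.hstack(P_o) if P_o else np.zeros((p, 0))
        self.orth_scores_ = np.hstack(T_o) if T_o else np.zeros((n, 0))
        self._X_filtered_ = Xd.copy()

        # predictive PLS (NIPALS) on the orthogonally filtered matrix
        W, P, T, C = [], [], [], []
        Xp, Yd = Xd.copy(), Yc.copy()
        for a in range(self.n_pred):
            w, t, c = self._nipals_component(Xp, Yd)
            tt = float(np.vdot(t, t))
            if tt < _TOL:
                raise FitError(
                    f"rank deficiency: at most {a} predictive components are feasible"
                )
            p_load = (Xp.T @ t) / tt
            Xp = Xp - t @ p_load.T
            Yd = Yd - t @ c.T
            W.append(w)
            P.append(p_load)
            T.append(t)
            C.append(c)
        self.x_weights_ = np.hstack(W)
        self.x_loadings_ = np.hstack(P)
        self.x_scores_ = np.hstack(T)
        self.y_loadings_ = np.hstack(C)

        modelled_x = sum(
            float(np.vdot(t, t)) * float(np.vdot(pl, pl)) for t, pl in zip(T, P)
        ) + sum(float(np.vdot(t, t)) * float(np.vdot(pl, pl)) for t, pl in zip(T_o, P_o))
        self.r2x_ = modelled_x / ss_x
        self.r2y_ = 1.0 - float((Yd**2).sum()) / ss_y
        # per-component explained class-indicator sum of squares (orthogonal
        # components contribute ~0 by construction) -- used by VIP
        ssy_pred = [float(np.vdot(t, t)) * float(np.vdot(c, c)) for t, c in zip(T, C)]
        ssy_orth = []
        for t in T_o:
            c_o = (Yc.T @ t) / float(np.vdot(t, t))
            ssy_orth.append(float(np.vdot(t, t)) * float(np.vdot(c_o, c_o)))
        self._ssy_per_component_ = (np.array(ssy_pred), np.array(ssy_orth))
        self._train_X_ = Xa
        self._train_y_ = y
        return self

    # ------------------------------------------------------------------
    @staticmethod
    def _nipals_weight(Xd, Yc):
        w, _, _ = OPLSDA._nipals_component(Xd, Yc)
        return w

    @staticmethod
    def _nipals_component(Xd, Yd):
        """One NIPALS PLS component; deterministic Y-side start."""
        start = int(np.argmax((Yd**2).sum(axis=0)))
        u = Yd[:, start : start + 1]
        if float(np.vdot(u, u)) < _TOL:
            u = np.ones((Xd.shape[0], 1))
        w = np.zeros((Xd.shape[1], 1))
        for _ in range(_MAX_ITER):
            w_new = Xd.T @ u
            norm = float(np.linalg.norm(w_new))
            if norm < 1e-300:
                break
            w_new /= norm
            t = Xd @ w_new
            tt = float(np.vdot(t, t))
            if tt < _TOL:
                w = w_new
                break
            c = (Yd.T @ t) / tt
            cc = float(np.vdot(c, c))
            if cc < 1e-300:
                w = w_new
                break
            u_new = (Yd @ c) / cc
            if float(np.linalg.norm(w_new - w)) < _TOL:
                w = w_new
                u = u_new
                break
            w, u = w_new, u_new
        t = Xd @ w
        tt = float(np.vdot(t, t))
        c = (Yd.T @ t) / tt if tt > _TOL else np.zeros((Yd.shape[1], 1))
        return w, t, c

    # ------------------------------------------------------------------
    def _filter_orthogonal(self, Xs: np.ndarray) -> np.ndarray:
        for k in range(self.orth_weights_.shape[1]):
            t_o = Xs @ self.orth_weights_[:, k : k + 1]
            Xs = Xs - t_o @ self.orth_loadings_[:, k : k + 1].T
        return Xs

    def decision_function(self, X) -> np.ndarray:
        """Continuous class-indicator predictions (centered scale removed)."""
        Xa = _as_array(X)
        Xs = (Xa - self.x_mean_) / self.x_div_
        Xf = self._filter_orthogonal(Xs)
        W, P, C = self.x_weights_, self.x_loadings_, self.y_loadings_
        B = W @ np.linalg.solve(P.T @ W, C.T)
        return Xf @ B + self.y_mean_

    def transform(self, X) -> np.ndarray:
        """Predictive scores for new samples."""
        Xa = _as_array(X)
        Xs = (Xa - self.x_mean_) / self.x_div_
        Xf = self._filter_orthogonal(Xs)
        W, P = self.x_weights_, self.x_loadings_
        return Xf @ W @ np.linalg.inv(P.T @ W)

    def transform_orthogonal(self, X) -> np.ndarray:
        """Orthogonal-component scores for new samples."""
        Xa = _as_array(X)
        Xs = (Xa - self.x_mean_) / self.x_div_
        scores = []
        for k in range(self.orth_weights_.shape[1]):
            t_o = Xs @ self.orth_weights_[:, k : k + 1]
            scores.append(t_o)
            Xs = Xs - t_o @ self.orth_loadings_[:, k : k + 1].T
        return np.hstack(scores) if scores else np.zeros((Xa.shape[0], 0))

    def predict(self, X):
        Yhat = self.decision_function(X)
        if len(self.classes_) == 2:
            return self.classes_[(Yhat[:, 0] >= 0.5).astype(int)]
        return self.classes_[np.argmax(Yhat, axis=1)]

    @property
    def fitted_y_(self) -> np.ndarray:
        return self.x_scores_ @ self.y_loadings_.T + self.y_mean_


# ----------------------------------------------------------------------
@dataclass
class VipResult:
    vip: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_segments: int

    def as_frame(self, feature_ids=None) -> pd.DataFrame:
        idx = feature_ids if feature_ids is not None else np.arange(len(self.vip))
        return pd.DataFrame(
            {"vip": self.vip, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper},
            index=idx,
        )


def _vip_scores(model: OPLSDA, components: str = "all") -> np.ndarray:
    ssy_pred, ssy_orth = model._ssy_per_component_
    W = model.x_weights_
    num = (W**2) @ ssy_pred
    den = float(ssy_pred.sum())
    if components == "all" and model.orth_weights_.shape[1]:
        num = num + (model.orth_weights_**2) @ ssy_orth
        den += float(ssy_orth.sum())
    p = W.shape[0]
    return np.sqrt(p * num / den)


def vip(
    model: OPLSDA,
    n_segments: int = 7,
    seed: int = 0,
    level: float = 0.95,
    components: str = "all",
) -> VipResult:
    """VIP with jackknife confidence intervals from cross-validation segments.

    VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a) over all modelled
    components (``components='predictive'`` restricts the sum); the sum of
    squared VIPs equals the feature count.  Confidence bounds come from
    leave-one-segment-out refits and the jackknife standard error with a
    Student-t quantile.
    """
    point = _vip_scores(model, components)
    X, y = model._train_X_, model._train_y_
    rng = np.random.default_rng(seed)
    n = len(y)
    n_segments = min(n_segments, min(np.bincount(pd.factorize(y)[0])))
    # stratified segment assignment
    seg = np.empty(n, dtype=int)
    for c in model.classes_:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        seg[idx] = np.arange(len(idx)) % n_segments
    reps = []
    for g in range(n_segments):
        keep = seg != g
        yk = y[keep]
        if len(np.unique(yk)) < 2 or min((yk == c).sum() for c in model.classes_) < 2:
            warnings.warn(f"jackknife segment {g} degenerate; dropped")
            continue
        sub = OPLSDA(**model.get_params()).fit(X[keep], yk)
        reps.append(_vip_scores(sub, components))
    reps_arr = np.asarray(reps)
    g_eff = len(reps)
    if g_eff < 2:
        se = np.zeros_like(point)
        tq = 0.0
    else:
        se = np.sqrt((g_eff - 1) / g_eff * ((reps_arr - reps_arr.mean(0)) ** 2).sum(0))
        tq = float(stats.t.ppf(0.5 + level / 2, g_eff - 1))
    return VipResult(point, point - tq * se, point + tq * se, g_eff)


# ----------------------------------------------------------------------
def cross_validated_q2(
    X,
    y,
    n_pred: int = 1,
    n_orth: int = 1,
    folds: int = 7,
    seed: int = 0,
    scaling: str = "uv",
) -> float:
    """Q2 = 1 - PRESS/SSY by stratified K-fold cross-validation.

    PRESS accumulates squared held-out class-indicator residuals over the
    folds; SSY is the total centered sum of squares of the class indicator
    (the chemometrics convention).  Negative Q2 means the model predicts
    class membership worse than the mean.
    """
    Xa = _as_array(X)
    y = np.asarray(y)
    classes = np.unique(y)
    min_class = min(int((y == c).sum()) for c in classes)
    # training folds must retain >= 2 samples of every class
    folds_eff = folds
    while folds_eff > 2 and (
        folds_eff > min_class
        or min_class - int(np.ceil(min_class / folds_eff)) < 2
    ):
        folds_eff -= 1
    if folds_eff > min_class or min_class - int(np.ceil(min_class / folds_eff)) < 2:
        raise FitError("cannot cross-validate: smallest class too small")
    if folds_eff != folds:
        warnings.warn(f"folds reduced to {folds_eff} for the smallest class")
        folds = folds_eff
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Y_all = _encode_labels(y, classes)
    ssy = float(((Y_all - Y_all.mean(axis=0)) ** 2).sum())
    press = 0.0
    for train, test in skf.split(Xa, y):
        model = OPLSDA(n_pred=n_pred, n_orth=n_orth, scaling=scaling).fit(
            Xa[train], y[train]
        )
        Y_test = _encode_labels(y[test], model.classes_)
        Yhat = model.decision_function(Xa[test])
        press += float(((Y_test - Yhat) ** 2).sum())
    return 1.0 - press / ssy


def fit_oplsda(
    X,
    y,
    n_pred: int = 1,
    n_orth: int = 1,
    scaling: str = "uv",
    seed: int = 0,
    compute_q2: bool = True,
    folds: int = 7,
) -> OPLSDA:
    """Fit OPLS-DA and attach the cross-validated ``q2_`` attribute."""
    yarr = np.asarray(y)
    for c in np.unique(yarr):
        if (yarr == c).sum() < 3:
            raise FitError(f"class {c!r} has fewer than 3 samples")
    model = OPLSDA(n_pred=n_pred, n_orth=n_orth, scaling=scaling).fit(X, y)
    model.q2_ = (
        cross_validated_q2(X, y, n_pred, n_orth, folds=folds, seed=seed, scaling=scaling)
        if compute_q2
        else None
    )
    return model
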