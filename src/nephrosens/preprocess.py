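"""Normalization and data-quality diagnostics for intensity matrices.

Covers MSTUS (mass spectrometry total useful signal) normalization, relative
log abundance (RLA) values, PCA with row-wise cross-validated Q2, pooled-QC
retention-time variation, and merging of correlated co-eluting features
(adducts, isotopes, in-source fragments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import KFold

from .matrix import IntensityMatrix


class NormalizationError(ValueError):
    pass


def _scale_matrix(X: np.ndarray, scaling: str):
    """Center and scale columns; returns (scaled, mean, divisor)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        div = sd.copy()
    elif scaling == "pareto":
        div = np.sqrt(sd)
    elif scaling == "none":
        div = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    div = np.where(div == 0, 1.0, div)
    return (X - mean) / div, mean, div


class MSTUSNormalizer(BaseEstimator, TransformerMixin):
    """Per-sample normalization by the summed signal of ubiquitous features.

    The "useful" feature set is the set of features with strictly positive
    intensity in every real (non-QC) sample.  Each sample is divided by its
    sum over that set and rescaled by the median of those sums across real
    samples, so intensities stay on the original magnitude.

    Attributes
    ----------
    useful_features_ : pandas.Index
        Features entering the total-useful-signal sum.
    reference_sum_ : float
        Median useful-signal sum used for rescaling.
    """

    def fit(self, matrix: IntensityMatrix, y=None):
        real = matrix.values.loc[~matrix.is_qc().to_numpy()]
        positive_in_all = (real.to_numpy() > 0).all(axis=0)
        if not positive_in_all.any():
            prevalence = (real.to_numpy() > 0).mean(axis=0)
            top = matrix.feature_ids[np.argsort(prevalence)[::-1][:5]].tolist()
            raise NormalizationError(
                "no feature is detected in every sample; most prevalent "
                f"features: {top}"
            )
        self.useful_features_ = matrix.feature_ids[positive_in_all]
        sums = real[self.useful_features_].sum(axis=1)
        self.reference_sum_ = float(np.median(sums))
        return self

    def transform(self, matrix: IntensityMatrix) -> IntensityMatrix:
        sums = matrix.values[self.useful_features_].sum(axis=1).to_numpy()
        if (sums <= 0).any():
            raise NormalizationError("a sample has zero total useful signal")
        factors = self.reference_sum_ / sums
        values = matrix.values.mul(factors, axis=0)
        feature_meta = matrix.feature_meta.copy()
        feature_meta["mstus_useful"] = feature_meta.index.isin(self.useful_features_)
        return IntensityMatrix(values, matrix.sample_meta.copy(), feature_meta)


def mstus_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Fit-and-apply MSTUS normalization; useful set recorded in feature_meta."""
    return MSTUSNormalizer().fit(matrix).transform(matrix)


def _log_with_offset(values: np.ndarray) -> np.ndarray:
    """Natural log after replacing zeros with half the minimum positive value."""
    v = values.astype(float).copy()
    if (v < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    if (v == 0).any():
        pos_min = v[v > 0].min()
        v[v == 0] = pos_min / 2.0
    return np.log(v)


def rla_values(
    matrix: IntensityMatrix,
    grouping: pd.Series | None = None,
    mode: str = "within",
) -> pd.DataFrame:
    """Relative log abundance: log intensity minus the per-feature median.

    ``mode='within'`` centers each feature on its within-group median (the
    within-group per-feature median of the output is exactly zero);
    ``mode='across'`` uses the global per-feature median.  Zeros are replaced
    by half the minimum positive intensity before the natural log.
    """
    log_v = pd.DataFrame(
        _log_with_offset(matrix.values.to_numpy()),
        index=matrix.sample_ids,
        columns=matrix.feature_ids,
    )
    if mode == "across":
        return log_v - log_v.median(axis=0)
    if grouping is None:
        grouping = matrix.sample_meta["group"].copy()
        grouping[matrix.is_qc()] = "QC"
    out = log_v.copy()
    for g, idx in log_v.groupby(grouping.loc[log_v.index]).groups.items():
        if len(idx) == 1:
            warnings.warn(f"group {g!r} has a single sample; its RLA values are 0")
        out.loc[idx] = log_v.loc[idx] - log_v.loc[idx].median(axis=0)
    return out


def rla_summary(rla: pd.DataFrame) -> pd.DataFrame:
    """Per-sample boxplot statistics (median, quartiles, IQR) of RLA values."""
    q1 = rla.quantile(0.25, axis=1)
    q3 = rla.quantile(0.75, axis=1)
    return pd.DataFrame(
        {"median": rla.median(axis=1), "q1": q1, "q3": q3, "iqr": q3 - q1}
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # features x components
    r2x: np.ndarray            # per-component fraction of X variance
    q2: np.ndarray             # cumulative cross-validated predictive fraction
    scaling: str

    @property
    def r2x_cum(self) -> np.ndarray:
        return np.cumsum(self.r2x)


def pca(
    matrix: IntensityMatrix | pd.DataFrame,
    scaling: str = "uv",
    n_components: int = 2,
    cv_folds: int = 7,
    seed: int = 0,
) -> PcaResult:
    """PCA with per-component R2X and row-wise K-fold cross-validated Q2.

    Q2 at component ``a`` is 1 - PRESS_a / SS where PRESS_a reconstructs
    held-out rows by projection onto the leading ``a`` loadings fitted
    without them (a row-wise scheme; values are comparable to, but not
    bit-identical with, SIMCA's proprietary cross-validation).  Constant
    features are dropped with a warning under unit-variance scaling.
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    X = values.to_numpy(dtype=float)
    if scaling == "uv":
        const = X.std(axis=0, ddof=1) == 0
        if const.any():
            warnings.warn(f"dropping {const.sum()} constant feature(s) under uv scaling")
            X = X[:, ~const]
            values = values.loc[:, ~const]
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds min(samples - 1, features)")
    Xs, _, _ = _scale_matrix(X, scaling)
    # SVD gives the exact PCA solution
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    ss_tot = float((Xs**2).sum())
    r2x = (s[:n_components] ** 2) / ss_tot
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T

    cv_folds = min(cv_folds, n)
    press = np.zeros(n_components)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(Xs):
        Xtr_raw = X[train]
        Xtr, mean, div = _scale_matrix(Xtr_raw, scaling)
        div = np.where(div == 0, 1.0, div)
        Xte = (X[test] - mean) / div
        _, _, Vt_tr = np.linalg.svd(Xtr, full_matrices=False)
        for a in range(1, n_components + 1):
            P = Vt_tr[:a].T
            resid = Xte - (Xte @ P) @ P.T
            press[a - 1] += float((resid**2).sum())
    # PRESS is compared against the held-out sum of squares of the
    # centered/scaled data (training-fold centering), accumulated likewise
    ss_cv = 0.0
    for train, test in kf.split(Xs):
        Xtr, mean, div = _scale_matrix(X[train], scaling)
        div = np.where(div == 0, 1.0, div)
        ss_cv += float((((X[test] - mean) / div) ** 2).sum())
    q2 = 1.0 - press / ss_cv

    comp_names = [f"PC{a}" for a in range(1, n_components + 1)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=values.columns, columns=comp_names),
        r2x=r2x,
        q2=q2,
        scaling=scaling,
    )


def rt_variation(
    qc_rt: pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Retention-time range (max - min, minutes) per metabolite across QC injections.

    ``qc_rt`` holds one row per QC injection and one column per metabolite.
    Metabolites whose range exceeds ``threshold`` (default 0.01 min) are
    flagged; missing entries are excluded pairwise with a warning.
    """
    if qc_rt.shape[0] < 2:
        raise ValueError("need at least 2 QC injections")
    if qc_rt.isna().any().any():
        warnings.warn("missing retention times excluded pairwise")
    rng = qc_rt.max(axis=0, skipna=True) - qc_rt.min(axis=0, skipna=True)
    return pd.DataFrame({"rt_range": rng, "flagged": rng > threshold})


def collapse_correlated_features(
    matrix: IntensityMatrix,
    rt_tolerance: float = 0.05,
    r_threshold: float = 0.9,
) -> tuple[IntensityMatrix, dict[str, str]]:
    """Merge co-eluting, highly correlated features into one representative.

    Features whose retention times differ by at most ``rt_tolerance`` minutes
    and whose intensity profiles across samples have Pearson r >=
    ``r_threshold`` are taken to originate from the same metabolite (adducts,
    isotopes, fragments).  Connected groups collapse to the member with the
    highest mean intensity; returns the reduced matrix and a map
    feature -> representative.
    """
    if "rt" not in matrix.feature_meta.columns:
        raise ValueError("feature_meta must provide retention times ('rt')")
    rt = matrix.feature_meta["rt"].to_numpy(dtype=float)
    X = matrix.values.to_numpy(dtype=float)
    p = X.shape[1]
    order = np.argsort(rt)
    sd = X.std(axis=0)
    # union-find over RT-compatible, correlated pairs
    parent = np.arange(p)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    Xc = X - X.mean(axis=0)
    norm = np.sqrt((Xc**2).sum(axis=0))
    norm = np.where(norm == 0, 1.0, norm)
    Xn = Xc / norm
    for a in range(p):
        i = order[a]
        for b in range(a + 1, p):
            j = order[b]
            if rt[j] - rt[i] > rt_tolerance:
                break
            if sd[i] == 0 or sd[j] == 0:
                continue
            if float(Xn[:, i] @ Xn[:, j]) >= r_threshold:
                parent[find(i)] = find(j)

    mean_int = X.mean(axis=0)
    groups: dict[int, list[int]] = {}
    for i in range(p):
        groups.setdefault(find(i), []).append(i)
    fmap: dict[str, str] = {}
    keep: list[int] = []
    feats = matrix.feature_ids
    for members in groups.values():
        rep = members[int(np.argmax(mean_int[members]))]
        keep.append(rep)
        for m in members:
            fmap[str(feats[m])] = str(feats[rep])
    keep_idx = matrix.feature_ids[sorted(keep)]
    reduced = IntensityMatrix(
        matrix.values[keep_idx].copy(),
        matrix.sample_meta.copy(),
        matrix.feature_meta.loc[keep_idx].copy(),
    )
    return reduced, fmap
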