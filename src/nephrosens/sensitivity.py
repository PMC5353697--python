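"""Tissue-sensitivity comparisons: RF error-rate ensemble, matched Q2, MCFC.

Three independent quantifications of how strongly a cisplatin dose separates
treated from control samples in each tissue:

* a random-forest resampling protocol -- for each (ntree, mtry) cell of a
  2 x 4 grid, 125 stratified 2/3-1/3 splits are drawn, a forest is trained
  and the test-set error rate (ERT) recorded, 1000 records per comparison;
  higher ERT means the groups are harder to tell apart (less sensitive);
* Q2 of control-vs-dose OPLS-DA models with matched component counts;
* MCFC (metabolic cumulative fold change): per treated sample, the sum over
  common metabolites of the fold change vs the control reference, with fold
  changes below 1 replaced by their reciprocals.

The forest follows the classical contract -- bagged CART trees grown to
purity with Gini splits and a fresh random feature subset of size
round(mtry_fraction * p) at every split, majority vote over trees -- and is
compiled with numba so the 1000-model protocol runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .matrix import IntensityMatrix
from .opls import OPLSDA, cross_validated_q2

NTREE_LEVELS = (500, 1000)
MTRY_FRACTIONS = (1 / 5, 1 / 4, 1 / 3, 2 / 5)
REPS_PER_CELL = 125


@njit(cache=True)
def _forest_ert(Xtr, ytr, Xte, yte, n_trees, mtry, seed):  # pragma: no cover
    """Test-set error of one random forest (binary labels 0/1)."""
    np.random.seed(seed)
    n, p = Xtr.shape
    nte = Xte.shape[0]
    votes1 = np.zeros(nte, np.int64)
    tr_idx = np.empty(n, np.int64)
    te_idx = np.empty(nte, np.int64)
    stack = np.empty((2 * n + 4, 4), np.int64)
    feat_pool = np.empty(p, np.int64)
    vals = np.empty(n, np.float64)
    labs = np.empty(n, np.int64)
    for _tree in range(n_trees):
        for i in range(n):  # bootstrap resample of the training set
            tr_idx[i] = np.random.randint(0, n)
        for i in range(nte):
            te_idx[i] = i
        stack[0, 0] = 0
        stack[0, 1] = n
        stack[0, 2] = 0
        stack[0, 3] = nte
        sp = 1
        while sp > 0:
            sp -= 1
            tlo, thi, elo, ehi = stack[sp, 0], stack[sp, 1], stack[sp, 2], stack[sp, 3]
            ntot = thi - tlo
            c1 = 0
            for i in range(tlo, thi):
                c1 += ytr[tr_idx[i]]
            if elo == ehi:
                continue  # no test sample reaches this node
            if c1 == 0 or c1 == ntot:
                if c1 == ntot:
                    for i in range(elo, ehi):
                        votes1[te_idx[i]] += 1
                continue
            for j in range(p):
                feat_pool[j] = j
            best_imp = 1e18
            best_f = -1
            best_thr = 0.0
            k = 0
            # inspect mtry shuffled features; keep drawing past mtry only
            # while no valid split has been found (CART convention)
            while k < p and (k < mtry or best_f < 0):
                r = k + np.random.randint(0, p - k)
                tmp = feat_pool[k]
                feat_pool[k] = feat_pool[r]
                feat_pool[r] = tmp
                f = feat_pool[k]
                k += 1
                for i in range(ntot):
                    vals[i] = Xtr[tr_idx[tlo + i], f]
                    labs[i] = ytr[tr_idx[tlo + i]]
                # insertion sort by value (nodes are tiny)
                for i in range(1, ntot):
                    v = vals[i]
                    lb = labs[i]
                    j2 = i - 1
                    while j2 >= 0 and vals[j2] > v:
                        vals[j2 + 1] = vals[j2]
                        labs[j2 + 1] = labs[j2]
                        j2 -= 1
                    vals[j2 + 1] = v
                    labs[j2 + 1] = lb
                nl = 0
                c1l = 0
                for i in range(ntot - 1):
                    nl += 1
                    c1l += labs[i]
                    if vals[i + 1] <= vals[i]:
                        continue  # not a distinct-value boundary
                    nr = ntot - nl
                    c1r = c1 - c1l
                    # weighted Gini impurity of the two children
                    imp = (nl - (c1l * c1l + (nl - c1l) * (nl - c1l)) / nl) + (
                        nr - (c1r * c1r + (nr - c1r) * (nr - c1r)) / nr
                    )
                    if imp < best_imp:
                        best_imp = imp
                        best_f = f
                        best_thr = 0.5 * (vals[i] + vals[i + 1])
            if best_f < 0:
                # all features tied within the node: majority-vote leaf
                if 2 * c1 > ntot:
                    for i in range(elo, ehi):
                        votes1[te_idx[i]] += 1
                continue
            # partition training and test indices by the chosen split
            mid_t = tlo
            for j in range(tlo, thi):
                if Xtr[tr_idx[j], best_f] <= best_thr:
                    tmp = tr_idx[mid_t]
                    tr_idx[mid_t] = tr_idx[j]
                    tr_idx[j] = tmp
                    mid_t += 1
            mid_e = elo
            for j in range(elo, ehi):
                if Xte[te_idx[j], best_f] <= best_thr:
                    tmp = te_idx[mid_e]
                    te_idx[mid_e] = te_idx[j]
                    te_idx[j] = tmp
                    mid_e += 1
            stack[sp, 0] = tlo
            stack[sp, 1] = mid_t
            stack[sp, 2] = elo
            stack[sp, 3] = mid_e
            sp += 1
            stack[sp, 0] = mid_t
            stack[sp, 1] = thi
            stack[sp, 2] = mid_e
            stack[sp, 3] = ehi
            sp += 1
    errors = 0
    for i in range(nte):
        pred = 1 if 2 * votes1[i] > n_trees else 0  # tie -> first class
        if pred != yte[i]:
            errors += 1
    return errors / nte


def stratified_split(y: np.ndarray, rng: np.random.Generator):
    """2/3-1/3 stratified split; the training share is rounded up per class."""
    train_idx = []
    test_idx = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(np.ceil(2 * len(idx) / 3))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


@dataclass
class ErtEnsembleResult:
    comparison: str
    records: pd.DataFrame  # columns: ntree, mtry_fraction, repeat, ert

    @property
    def ert(self) -> np.ndarray:
        return self.records["ert"].to_numpy()

    def summary(self) -> dict:
        e = self.ert
        return {
            "comparison": self.comparison,
            "n_records": int(len(e)),
            "mean": float(e.mean()),
            "median": float(np.median(e)),
            "q25": float(np.quantile(e, 0.25)),
            "q75": float(np.quantile(e, 0.75)),
        }


def rf_ert_ensemble(
    X,
    y,
    ntree_levels=NTREE_LEVELS,
    mtry_fractions=MTRY_FRACTIONS,
    reps_per_cell: int = REPS_PER_CELL,
    seed: int = 0,
    comparison: str = "",
) -> ErtEnsembleResult:
    """Run the full (ntree x mtry x repeats) error-rate ensemble.

    With the default grid this yields 2 x 4 x 125 = 1000 records.  Each
    repeat draws its own stratified split, so the record distribution
    reflects split-to-split as well as hyperparameter variability.
    """
    if isinstance(X, IntensityMatrix):
        X = X.values
    Xa = np.ascontiguousarray(
        X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    )
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("the ERT protocol compares exactly two groups")
    if min(int((y == c).sum()) for c in classes) < 3:
        raise ValueError("both groups need >= 3 samples")
    ybin = (y == classes[1]).astype(np.int64)
    p = Xa.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for ntree in ntree_levels:
        for frac in mtry_fractions:
            mtry = max(1, int(round(frac * p)))
            for rep in range(reps_per_cell):
                tr, te = stratified_split(ybin, rng)
                # guard: ceiling split always keeps both classes in train;
                # a class of size < 2 could vanish from the test side
                tries = 0
                while len(np.unique(ybin[te])) < 2 and tries < 10:
                    tr, te = stratified_split(ybin, rng)
                    tries += 1
                ert = _forest_ert(
                    Xa[tr],
                    ybin[tr],
                    np.ascontiguousarray(Xa[te]),
                    ybin[te],
                    ntree,
                    mtry,
                    int(rng.integers(2**31)),
                )
                rows.append((ntree, frac, rep + 1, ert))
    records = pd.DataFrame(rows, columns=["ntree", "mtry_fraction", "repeat", "ert"])
    return ErtEnsembleResult(comparison=comparison, records=records)


def compare_ert(result_a: ErtEnsembleResult, result_b: ErtEnsembleResult) -> dict:
    """Two-sided Mann-Whitney U between two ERT distributions.

    The tissue with the higher ERT has the more similar (less separable)
    groups, i.e. is the less sensitive one.
    """
    a, b = result_a.ert, result_b.ert
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty ERT records")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "higher_ert": result_a.comparison
        if np.median(a) > np.median(b)
        else result_b.comparison,
    }


# ----------------------------------------------------------------------
def two_group_q2(
    X_control,
    X_dose,
    n_pred: int = 1,
    n_orth: int = 1,
    folds: int = 7,
    seed: int = 0,
    scaling: str = "uv",
) -> dict:
    """Q2 (with R2X/R2Y) of a control-vs-dose OPLS-DA at fixed components.

    Matched component counts across models make the Q2 values comparable
    between tissues and doses."""
    Xc = np.asarray(
        X_control.values.to_numpy() if isinstance(X_control, IntensityMatrix) else X_control,
        dtype=float,
    )
    Xd = np.asarray(
        X_dose.values.to_numpy() if isinstance(X_dose, IntensityMatrix) else X_dose,
        dtype=float,
    )
    X = np.vstack([Xc, Xd])
    y = np.array(["control"] * len(Xc) + ["dose"] * len(Xd))
    model = OPLSDA(n_pred=n_pred, n_orth=n_orth, scaling=scaling).fit(X, y)
    q2 = cross_validated_q2(
        X, y, n_pred=n_pred, n_orth=n_orth, folds=folds, seed=seed, scaling=scaling
    )
    return {"q2": q2, "r2x": model.r2x_, "r2y": model.r2y_, "n_pred": n_pred, "n_orth": n_orth}


# ----------------------------------------------------------------------
@dataclass
class McfcResult:
    """Per-sample metabolic cumulative fold change plus group/tissue summaries."""

    values: pd.DataFrame  # columns: sample_id, tissue, group, mcfc
    n_metabolites: int
    between_tissue_p: dict[str, float]  # dose -> Mann-Whitney p (if 2 tissues)

    def group_summary(self) -> pd.DataFrame:
        return (
            self.values.groupby(["tissue", "group"])["mcfc"]
            .agg(["mean", "std", "median", "count"])
            .reset_index()
        )


def mcfc(
    matrix: IntensityMatrix,
    common_metabolites,
    control_label: str = "C",
    dose_labels=None,
    reference: str = "median",
) -> McfcResult:
    """Metabolic cumulative fold change per treated sample.

    For sample i, MCFC_i = sum_j max(x_ij / c_j, c_j / x_ij) over the common
    metabolites j, where c_j is the control-group reference (median by
    default, mean by flag) of that sample's tissue.  MCFC >= m with equality
    iff every fold change is 1.  When the matrix holds two tissues, the
    per-dose distributions are compared by two-sided Mann-Whitney U.
    """
    common = list(common_metabolites)
    if not common:
        raise ValueError("common metabolite set is empty")
    if reference not in ("median", "mean"):
        raise ValueError("reference must be 'median' or 'mean'")
    real = matrix.real_samples()
    tissues = list(pd.unique(real.sample_meta["tissue"]))
    if dose_labels is None:
        dose_labels = [g for g in pd.unique(real.sample_meta["group"]) if g != control_label]
    rows = []
    import warnings as _warnings

    for tissue in tissues:
        sub = real.subset(tissue=tissue, features=common)
        ctrl = sub.values[sub.sample_meta["group"] == control_label]
        if ctrl.empty:
            raise ValueError(f"no control samples for tissue {tissue!r}")
        ref = ctrl.median(axis=0) if reference == "median" else ctrl.mean(axis=0)
        usable = ref > 0
        if not usable.all():
            _warnings.warn(
                f"{int((~usable).sum())} metabolite(s) with zero control "
                "reference excluded from MCFC"
            )
        ref_u = ref[usable].to_numpy()
        for dose in dose_labels:
            treated = sub.values.loc[sub.sample_meta["group"] == dose, usable.index[usable]]
            for sid, xi in treated.iterrows():
                x = xi.to_numpy()
                ok = x > 0
                if not ok.all():
                    _warnings.warn(f"zero intensities excluded from MCFC for {sid}")
                fc = x[ok] / ref_u[ok]
                val = float(np.maximum(fc, 1.0 / fc).sum())
                rows.append((sid, tissue, dose, val))
    values = pd.DataFrame(rows, columns=["sample_id", "tissue", "group", "mcfc"])
    between = {}
    if len(tissues) == 2:
        for dose in dose_labels:
            a = values.query("tissue == @tissues[0] and group == @dose")["mcfc"]
            b = values.query("tissue == @tissues[1] and group == @dose")["mcfc"]
            if len(a) and len(b):
                between[dose] = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
    return McfcResult(values=values, n_metabolites=len(common), between_tissue_p=between)
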