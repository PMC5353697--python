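"""Differential-feature screening and the cortex/medulla Venn partition.

A feature is differential for a dose group when, in the control-vs-dose
OPLS-DA, (1) its VIP exceeds 1.0, (2) the jackknife confidence interval on
VIP stays positive, and (3) the Benjamini-Hochberg adjusted two-sided
Wilcoxon-Mann-Whitney p-value is below alpha.  Features differential in at
least one dose comparison form the tissue's differential set ("all
comparisons" mode available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix
from .opls import OPLSDA, FitError, vip


def wilcoxon_bh(
    X: pd.DataFrame | np.ndarray,
    groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided rank-sum p per feature with Benjamini-Hochberg adjustment.

    ``groups`` must carry exactly two labels; features with all values tied
    across both groups get p = 1 with a warning.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("wilcoxon_bh expects exactly two group labels")
    a = Xv[groups == labels[0]]
    b = Xv[groups == labels[1]]
    if min(len(a), len(b)) < 3:
        raise ValueError("need >= 3 samples per group")
    raw = np.ones(Xv.shape[1])
    tied = 0
    for j in range(Xv.shape[1]):
        col = np.concatenate([a[:, j], b[:, j]])
        if np.all(col == col[0]):
            tied += 1
            continue
        raw[j] = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    if tied:
        warnings.warn(f"{tied} all-tied feature(s) assigned p = 1")
    adj = benjamini_hochberg(raw)
    idx = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xv.shape[1])
    return pd.DataFrame(
        {"raw_p": raw, "adj_p": adj, "significant": adj < alpha}, index=idx
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


# ----------------------------------------------------------------------
@dataclass
class ScreenResult:
    """Per-feature, per-comparison audit trail plus the pooled differential set."""

    records: pd.DataFrame  # columns: feature, comparison, tissue, vip,
    #          vip_ci_lower, raw_p, adj_p, passed
    differential_set: set[str]
    mode: str
    alpha: float
    skipped_comparisons: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_differential": len(self.differential_set),
            "mode": self.mode,
            "alpha": self.alpha,
            "comparisons": sorted(self.records["comparison"].unique().tolist()),
            "skipped": self.skipped_comparisons,
        }


def screen_differential(
    matrix: IntensityMatrix,
    tissue: str | None = None,
    n_pred: int = 1,
    n_orth: int = 1,
    scaling: str = "uv",
    alpha: float = 0.05,
    control_label: str = "C",
    mode: str = "any",
    n_segments: int = 7,
    seed: int = 0,
    key: str | None = None,
) -> ScreenResult:
    """Run the three-criterion screen for every control-vs-dose comparison.

    ``mode='any'`` (default) pools features passing in at least one
    comparison; ``mode='all'`` requires every comparison.  ``key`` names a
    feature_meta column (e.g. an annotation name) used as the identity in the
    differential set; defaults to the raw feature id.  Comparisons whose
    OPLS-DA fit fails are skipped and recorded.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    sub = matrix.subset(tissue=tissue) if tissue is not None else matrix.real_samples()
    groups = sub.sample_meta["group"]
    dose_labels = [g for g in pd.unique(groups) if g != control_label]
    if control_label not in groups.values or not dose_labels:
        raise ValueError("matrix must contain the control group and >= 1 treated group")

    rows = []
    skipped = []
    pass_sets: list[set[str]] = []
    rng = np.random.default_rng(seed)
    for dose in dose_labels:
        pair = sub.subset(groups=[control_label, dose])
        y = pair.sample_meta["group"].to_numpy()
        comp = f"{control_label}_vs_{dose}"
        try:
            model = OPLSDA(n_pred=n_pred, n_orth=n_orth, scaling=scaling).fit(
                pair.values, y
            )
            vres = vip(model, n_segments=n_segments, seed=int(rng.integers(2**31)))
        except FitError as exc:
            warnings.warn(f"comparison {comp} skipped: {exc}")
            skipped.append(comp)
            continue
        ptab = wilcoxon_bh(pair.values, y, alpha=alpha)
        passed = (vres.vip > 1.0) & (vres.ci_lower > 0.0) & (
            ptab["adj_p"].to_numpy() < alpha
        )
        feats = pair.feature_ids
        names = (
            pair.feature_meta[key].astype(str).to_numpy()
            if key is not None
            else feats.to_numpy()
        )
        pass_sets.append(set(names[passed]))
        rows.append(
            pd.DataFrame(
                {
                    "feature": feats,
                    "name": names,
                    "comparison": comp,
                    "tissue": tissue if tissue is not None else "all",
                    "vip": vres.vip,
                    "vip_ci_lower": vres.ci_lower,
                    "raw_p": ptab["raw_p"].to_numpy(),
                    "adj_p": ptab["adj_p"].to_numpy(),
                    "passed": passed,
                }
            )
        )
    if not rows:
        raise FitError("every comparison failed to fit")
    records = pd.concat(rows, ignore_index=True)
    if mode == "any":
        differential = set().union(*pass_sets)
    else:
        differential = set.intersection(*pass_sets)
    return ScreenResult(records, differential, mode, alpha, skipped)


# ----------------------------------------------------------------------
@dataclass
class VennPartition:
    common: set
    a_only: set
    b_only: set

    def sizes(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
        }


def venn(set_a, set_b, key=None) -> VennPartition:
    """Exact two-set partition (intersection and exclusive sides).

    ``key`` optionally maps raw ids to a comparable identity (for
    metabolomics: the annotation name, so the same metabolite matches across
    tissues)."""
    a = {key(x) for x in set_a} if key else set(set_a)
    b = {key(x) for x in set_b} if key else set(set_b)
    return VennPartition(common=a & b, a_only=a - b, b_only=b - a)
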