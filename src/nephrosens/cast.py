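"""CAST correlation clustering of dose-response fold-change profiles.

CAST (cluster affinity search technique) clusters items whose pairwise
Pearson correlations are high: clusters are grown by alternately adding the
outside element with the highest mean affinity to the cluster (if >= t) and
removing the member with the lowest (if < t), so at termination every member
has mean within-cluster affinity at least t.

The two-step screen runs CAST at t1 = 0.80 on all cortex- and medulla-tagged
fold-change profiles, keeps the two largest clusters (signed up/down by mean
log2 fold change), re-clusters each at t2 = 0.98, labels every sub-cluster
with a dose-response archetype, and collects the contributive set: medulla
profiles in sub-clusters that track dose monotonically or step up at the
medium dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .matrix import IntensityMatrix

ARCHETYPE_LABELS = ("dose_monotone", "step_M", "step_H", "uncorrelated")


@dataclass(frozen=True)
class FoldChangeProfile:
    """Group-level fold changes (FC_L, FC_M, FC_H) vs control for one metabolite."""

    metabolite: str
    tissue: str
    fc: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fc):
            raise ValueError("fold changes must be positive")

    @property
    def log_fc(self) -> np.ndarray:
        return np.log2(np.asarray(self.fc, dtype=float))

    @property
    def key(self) -> str:
        return f"{self.tissue}:{self.metabolite}"


def fold_change_profiles(
    matrix: IntensityMatrix,
    features,
    tissue: str,
    control_label: str = "C",
    dose_labels=("L", "M", "H"),
    reference: str = "mean",
) -> list[FoldChangeProfile]:
    """Group-level fold-change triples vs control for selected features."""
    sub = matrix.subset(tissue=tissue, features=list(features))
    stat = "median" if reference == "median" else "mean"
    agg = sub.values.groupby(sub.sample_meta["group"]).agg(stat)
    if control_label not in agg.index:
        raise ValueError(f"no control group {control_label!r} in tissue {tissue!r}")
    ctrl = agg.loc[control_label]
    profiles = []
    for feat in sub.feature_ids:
        fc = tuple(float(agg.loc[d, feat] / ctrl[feat]) for d in dose_labels)
        profiles.append(FoldChangeProfile(metabolite=str(feat), tissue=tissue, fc=fc))
    return profiles


def profiles_table(profiles: list[FoldChangeProfile]) -> pd.DataFrame:
    """Tidy fold-change table; cortex and medulla rows are kept distinct."""
    return pd.DataFrame(
        {
            "metabolite": [p.metabolite for p in profiles],
            "tissue": [p.tissue for p in profiles],
            "fc_L": [p.fc[0] for p in profiles],
            "fc_M": [p.fc[1] for p in profiles],
            "fc_H": [p.fc[2] for p in profiles],
        }
    )


def pearson_affinity(
    profiles: list[FoldChangeProfile],
) -> tuple[np.ndarray, list[int], list[int]]:
    """Pairwise Pearson r between log2 fold-change triples.

    Returns (affinity matrix over non-degenerate profiles, their indices,
    indices of degenerate profiles whose log-fc vector is constant -- those
    cannot be correlated and are routed to the unassigned pool).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    L = np.vstack([p.log_fc for p in profiles])
    sd = L.std(axis=1)
    good = np.flatnonzero(sd > 0)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        warnings.warn(f"{len(bad)} profile(s) with constant log-fc set aside")
    Lc = L[good] - L[good].mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Lc, axis=1)
    Ln = Lc / norm[:, None]
    aff = np.clip(Ln @ Ln.T, -1.0, 1.0)
    np.fill_diagonal(aff, 1.0)
    return aff, good.tolist(), bad.tolist()


# ----------------------------------------------------------------------
@dataclass
class CastResult:
    t: float
    clusters: list[list[int]]  # item indices, ordered by creation
    unassigned: list[int] = field(default_factory=list)

    def labels(self, n: int) -> np.ndarray:
        lab = np.full(n, -1, dtype=int)
        for k, members in enumerate(self.clusters):
            lab[members] = k
        return lab


class CASTClustering(BaseEstimator, ClusterMixin):
    """CAST over a precomputed affinity (Pearson correlation) matrix.

    Parameters
    ----------
    t : float in (0, 1]
        Affinity threshold: mean within-cluster affinity every member must
        reach.  Thresholds are quoted on the raw correlation scale.

    Deterministic tie-breaking: cluster seeds maximize total affinity over
    the still-unassigned items (ties -> lowest index); add/remove choices
    break ties by input order.  ``fit`` sets ``labels_`` and ``clusters_``.
    """

    def __init__(self, t: float = 0.8):
        self.t = t

    def fit(self, affinity: np.ndarray, y=None):
        res = cast_cluster(affinity, self.t)
        self.clusters_ = res.clusters
        self.labels_ = res.labels(len(affinity))
        return self

    def fit_predict(self, affinity: np.ndarray, y=None):
        return self.fit(affinity).labels_


def cast_cluster(affinity: np.ndarray, t: float, max_rounds: int = 10_000) -> CastResult:
    """Canonical CAST on a symmetric affinity matrix with unit diagonal.

    Repeatedly opens a cluster seeded by the unassigned element with the
    largest total affinity to the remaining pool, then alternates ADD (the
    pool element with maximal mean affinity to the cluster, if >= t) and
    REMOVE (the member with minimal mean affinity, self included, if < t)
    until stable, closes the cluster and continues.
    """
    S = np.asarray(affinity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if not (0 < t <= 1):
        raise ValueError("t must lie in (0, 1]")
    n = S.shape[0]
    pool = list(range(n))
    clusters: list[list[int]] = []
    while pool:
        totals = S[np.ix_(pool, pool)].sum(axis=1)
        seed = pool[int(np.argmax(totals))]  # argmax ties -> lowest index
        cluster = [seed]
        pool.remove(seed)
        for _ in range(max_rounds):
            changed = False
            # ADD phase
            while pool:
                means = S[np.ix_(pool, cluster)].mean(axis=1)
                best = int(np.argmax(means))
                if means[best] >= t:
                    cluster.append(pool.pop(best))
                    changed = True
                else:
                    break
            # REMOVE phase (mean affinity to the cluster, self included)
            while len(cluster) > 1:
                means = S[np.ix_(cluster, cluster)].mean(axis=1)
                worst = int(np.argmin(means))
                if means[worst] < t:
                    pool.append(cluster.pop(worst))
                    pool.sort()
                    changed = True
                else:
                    break
            if not changed:
                break
        else:
            warnings.warn("CAST add/remove cycle did not stabilize; closing as-is")
        clusters.append(sorted(cluster))
    return CastResult(t=t, clusters=clusters)


# ----------------------------------------------------------------------
def classify_subcluster(
    profiles: list[FoldChangeProfile], delta: float = 0.25
) -> str:
    """Archetype label from the sub-cluster's mean absolute log2 fold changes.

    On the mean |log2 fc| triple (a_L, a_M, a_H): ``dose_monotone`` when the
    magnitudes increase by at least ``delta`` at each dose step, ``step_M``
    when the jump happens at the medium dose and the high dose adds little,
    ``step_H`` when only the high dose responds, otherwise ``uncorrelated``.
    """
    if not profiles:
        raise ValueError("empty sub-cluster")
    a = np.abs(np.vstack([p.log_fc for p in profiles])).mean(axis=0)
    a_l, a_m, a_h = a
    if a_m - a_l >= delta and a_h - a_m >= delta:
        return "dose_monotone"
    if a_m - a_l >= delta and abs(a_h - a_m) < delta:
        return "step_M"
    if abs(a_m - a_l) < delta and a_h - a_m >= delta:
        return "step_H"
    return "uncorrelated"


@dataclass
class SubCluster:
    members: list[FoldChangeProfile]
    label: str
    parent_sign: str  # "up" or "down"


@dataclass
class TwoStepResult:
    t1: float
    t2: float
    step1: CastResult
    kept_up: list[FoldChangeProfile]
    kept_down: list[FoldChangeProfile]
    excluded: list[FoldChangeProfile]
    subclusters: list[SubCluster]
    contributive_set: set[str]  # medulla metabolite keys

    def summary(self) -> dict:
        return {
            "t1": self.t1,
            "t2": self.t2,
            "n_up": len(self.kept_up),
            "n_down": len(self.kept_down),
            "n_excluded": len(self.excluded),
            "subclusters": [
                {"label": s.label, "sign": s.parent_sign, "size": len(s.members)}
                for s in self.subclusters
            ],
            "n_contributive": len(self.contributive_set),
        }


def two_step_cast(
    profiles: list[FoldChangeProfile],
    t1: float = 0.80,
    t2: float = 0.98,
    delta: float = 0.25,
    medulla_tissue: str = "medulla",
) -> TwoStepResult:
    """Two-step CAST: rough trend clusters at t1, fine sub-clusters at t2.

    Step 1 clusters every profile at ``t1``; the two largest clusters are
    kept and signed up/down by their mean log2 fold change, everything else
    is excluded as poorly dose-correlated.  Step 2 re-clusters each kept
    cluster at ``t2`` and labels the sub-clusters with
    :func:`classify_subcluster`.  The contributive set collects the
    medulla-origin members of sub-clusters labelled ``dose_monotone`` or
    ``step_M`` -- metabolites tracking dose tightly or responding already at
    the medium dose.
    """
    aff, good, bad = pearson_affinity(profiles)
    step1 = cast_cluster(aff, t1)
    if len(step1.clusters) < 2:
        raise ValueError(
            "step-1 CAST produced a single cluster; the profiles carry only "
            "one trend and up/down clusters cannot be separated"
        )
    by_size = sorted(step1.clusters, key=len, reverse=True)
    kept_two = by_size[:2]
    kept_idx = {i for c in kept_two for i in c}
    sign = []
    for c in kept_two:
        mean_lfc = float(np.mean([profiles[good[i]].log_fc.mean() for i in c]))
        sign.append("up" if mean_lfc >= 0 else "down")
    if sign[0] == sign[1]:
        warnings.warn("the two largest step-1 clusters share the same trend sign")
    excluded = [profiles[good[i]] for c in by_size[2:] for i in c]
    excluded += [profiles[i] for i in bad]

    subclusters: list[SubCluster] = []
    contributive: set[str] = set()
    kept_lists: dict[str, list[FoldChangeProfile]] = {"up": [], "down": []}
    for c, s in zip(kept_two, sign):
        members_all = [profiles[good[i]] for i in c]
        kept_lists[s] = kept_lists.get(s, []) + members_all
        if len(c) == 1:
            sub_res = CastResult(t=t2, clusters=[[0]])
        else:
            sub_aff = aff[np.ix_(c, c)]
            sub_res = cast_cluster(sub_aff, t2)
        for sub in sub_res.clusters:
            members = [members_all[i] for i in sub]
            label = classify_subcluster(members, delta=delta)
            subclusters.append(SubCluster(members=members, label=label, parent_sign=s))
            if label in ("dose_monotone", "step_M"):
                contributive |= {
                    m.key for m in members if m.tissue == medulla_tissue
                }
    return TwoStepResult(
        t1=t1,
        t2=t2,
        step1=step1,
        kept_up=kept_lists.get("up", []),
        kept_down=kept_lists.get("down", []),
        excluded=excluded,
        subclusters=subclusters,
        contributive_set=contributive,
    )
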