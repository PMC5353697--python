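"""CAST clustering: affinities, stability contract, two-step archetype screen."""

import numpy as np
import pytest

from nephrosens.cast import (
    FoldChangeProfile,
    cast_cluster,
    classify_subcluster,
    pearson_affinity,
    two_step_cast,
)


def naive_cast(S, t):
    """Independent straight-line reimplementation of the add/remove scheme.

    Plain loops, no vectorization; used as the oracle for the production
    implementation on small instances."""
    n = len(S)
    pool = list(range(n))
    clusters = []
    while pool:
        best, best_tot = None, -np.inf
        for x in pool:
            tot = sum(S[x][y] for y in pool)
            if tot > best_tot:
                best, best_tot = x, tot
        cluster = [best]
        pool.remove(best)
        while True:
            moved = False
            while pool:
                cand, cand_mean = None, -np.inf
                for x in pool:
                    mean = sum(S[x][y] for y in cluster) / len(cluster)
                    if mean > cand_mean:
                        cand, cand_mean = x, mean
                if cand_mean >= t:
                    cluster.append(cand)
                    pool.remove(cand)
                    moved = True
                else:
                    break
            while len(cluster) > 1:
                worst, worst_mean = None, np.inf
                for x in cluster:
                    mean = sum(S[x][y] for y in cluster) / len(cluster)
                    if mean < worst_mean:
                        worst, worst_mean = x, mean
                if worst_mean < t:
                    cluster.remove(worst)
                    pool.append(worst)
                    pool.sort()
                    moved = True
                else:
                    break
            if not moved:
                break
        clusters.append(sorted(cluster))
    return clusters


def profile(fc, tissue="medulla", name="m"):
    return FoldChangeProfile(name, tissue, tuple(fc))


class TestAffinity:
    def test_self_and_affine_invariance(self):
        ps = [
            profile((2.0, 4.0, 8.0), name="a"),      # log2 (1,2,3)
            profile((4.0, 16.0, 64.0), name="b"),    # log2 (2,4,6)
            profile((8.0, 4.0, 2.0), name="c"),      # log2 (3,2,1)
        ]
        aff, good, bad = pearson_affinity(ps)
        assert aff[0, 0] == 1.0
        assert aff[0, 1] == pytest.approx(1.0)
        assert aff[0, 2] == pytest.approx(-1.0)
        assert bad == []

    def test_constant_profile_routed_to_unassigned(self):
        ps = [profile((2.0, 2.0, 2.0)), profile((1.0, 2.0, 4.0)), profile((2.0, 4.0, 8.0))]
        with pytest.warns(UserWarning, match="constant"):
            aff, good, bad = pearson_affinity(ps)
        assert bad == [0]
        assert good == [1, 2]


class TestCastCluster:
    def test_two_perfect_blocks(self):
        S = np.full((6, 6), -1.0)
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        np.fill_diagonal(S, 1.0)
        res = cast_cluster(S, 0.8)
        assert sorted(map(tuple, res.clusters)) == [(0, 1, 2), (3, 4, 5)]

    def test_threshold_one_gives_singletons(self):
        S = np.full((5, 5), 0.99)
        np.fill_diagonal(S, 1.0)
        res = cast_cluster(S, 1.0)
        assert all(len(c) == 1 for c in res.clusters)

    def test_asymmetric_matrix_rejected(self):
        S = np.eye(3)
        S[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            cast_cluster(S, 0.5)

    @pytest.mark.parametrize("t", [0.5, 0.8, 0.98])
    def test_matches_naive_oracle_on_random_instances(self, t):
        rng = np.random.default_rng(int(t * 100))
        for _ in range(60):
            n = int(rng.integers(3, 9))
            L = rng.normal(size=(n, 3))
            ps = [profile(tuple(2.0 ** L[i]), name=f"m{i}") for i in range(n)]
            S, good, bad = pearson_affinity(ps)
            got = cast_cluster(S, t).clusters
            assert got == naive_cast(S.tolist(), t)

    def test_stability_condition_at_termination(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            L = rng.normal(size=(n, 3))
            ps = [profile(tuple(2.0 ** L[i]), name=f"m{i}") for i in range(n)]
            S, _, _ = pearson_affinity(ps)
            for cluster in cast_cluster(S, 0.8).clusters:
                for x in cluster:
                    assert S[x, cluster].mean() >= 0.8 - 1e-12

    def test_partition_property(self, rng):
        L = rng.normal(size=(10, 3))
        ps = [profile(tuple(2.0 ** L[i]), name=f"m{i}") for i in range(10)]
        S, good, bad = pearson_affinity(ps)
        res = cast_cluster(S, 0.7)
        all_members = sorted(i for c in res.clusters for i in c)
        assert all_members == list(range(len(S)))

    def test_raising_threshold_refines(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(12, 3))
        ps = [profile(tuple(2.0 ** L[i]), name=f"m{i}") for i in range(12)]
        S, _, _ = pearson_affinity(ps)
        lo = cast_cluster(S, 0.6).clusters
        hi = cast_cluster(S, 0.95).clusters
        assert len(hi) >= len(lo)


class TestClassify:
    @pytest.mark.parametrize(
        "triple,label",
        [
            ((0.5, 1.5, 3.0), "dose_monotone"),
            ((0.1, 1.4, 1.5), "step_M"),
            ((0.1, 0.2, 2.0), "step_H"),
            ((0.2, 0.1, 0.3), "uncorrelated"),
        ],
    )
    def test_rule_application(self, triple, label):
        ps = [profile(tuple(2.0 ** np.array(triple)))]
        assert classify_subcluster(ps, delta=0.25) == label

    def test_down_profiles_classified_on_magnitude(self):
        ps = [profile((2.0 ** -0.5, 2.0 ** -1.5, 2.0 ** -3.0))]
        assert classify_subcluster(ps) == "dose_monotone"


class TestTwoStep:
    def _archetype_profiles(self, rng, per=6, tissues=("cortex", "medulla")):
        shapes = {
            "dose_monotone": (2.0, 4.0, 8.0),
            "step_M": (1.0, 4.0, 4.0),
            "step_H": (1.0, 1.0, 4.0),
        }
        truth = {}
        ps = []
        for name, fc in shapes.items():
            for sign in (1.0, -1.0):
                for tis in tissues:
                    for i in range(per):
                        jit = rng.uniform(0.97, 1.03, 3)
                        realized = tuple(np.asarray(fc) ** sign * jit)
                        key = f"{name}_{'up' if sign > 0 else 'dn'}_{tis}_{i}"
                        ps.append(FoldChangeProfile(key, tis, realized))
                        truth[f"{tis}:{key}"] = name
        return ps, truth

    def test_archetype_recovery_on_retained_profiles(self, rng):
        ps, truth = self._archetype_profiles(rng)
        res = two_step_cast(ps)
        checked = 0
        correct = 0
        for sub in res.subclusters:
            for m in sub.members:
                checked += 1
                correct += int(truth[m.key] == sub.label)
        assert checked > 0
        assert correct / checked >= 0.9

    def test_contributive_set_invariant(self, rng):
        ps, _ = self._archetype_profiles(rng)
        res = two_step_cast(ps)
        medulla_keys = {p.key for p in ps if p.tissue == "medulla"}
        assert res.contributive_set <= medulla_keys
        expected = {
            m.key
            for sub in res.subclusters
            if sub.label in ("dose_monotone", "step_M")
            for m in sub.members
            if m.tissue == "medulla"
        }
        assert res.contributive_set == expected

    def test_cortex_only_input_empty_contributive_set(self, rng):
        ps, _ = self._archetype_profiles(rng, tissues=("cortex",))
        res = two_step_cast(ps)
        assert res.contributive_set == set()

    def test_identical_profiles_single_cluster_is_an_error(self):
        # one trend only: up/down clusters cannot be separated
        with pytest.raises(ValueError, match="single cluster"):
            two_step_cast([profile((2.0, 4.0, 8.0), name=f"m{i}") for i in range(5)])

    def test_up_down_signing(self, rng):
        ups = [
            profile(tuple((2.0, 4.0, 8.0) * rng.uniform(0.98, 1.02, 3)), name=f"u{i}")
            for i in range(5)
        ]
        downs = [
            profile(tuple((0.5, 0.25, 0.125) * rng.uniform(0.98, 1.02, 3)), name=f"d{i}")
            for i in range(5)
        ]
        res = two_step_cast(ups + downs)
        up_names = {p.metabolite for p in res.kept_up}
        assert up_names == {f"u{i}" for i in range(5)}
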