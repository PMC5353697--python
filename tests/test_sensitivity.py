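"""RF error-rate ensemble, Q2 comparison and MCFC statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.ensemble import RandomForestClassifier

from nephrosens.sensitivity import (
    compare_ert,
    mcfc,
    rf_ert_ensemble,
    stratified_split,
    two_group_q2,
)

from conftest import make_matrix


class TestStratifiedSplit:
    def test_two_thirds_rounded_up_per_class(self, rng):
        y = np.array([0] * 13 + [1] * 11)
        tr, te = stratified_split(y, rng)
        assert (y[tr] == 0).sum() == 9  # ceil(2/3 * 13)
        assert (y[tr] == 1).sum() == 8  # ceil(2/3 * 11)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 24


class TestErtEnsemble:
    def test_small_grid_cardinality_and_determinism(self, rng):
        X = rng.normal(size=(20, 15))
        y = np.array(["a"] * 10 + ["b"] * 10)
        res1 = rf_ert_ensemble(
            X, y, ntree_levels=(50,), mtry_fractions=(0.2, 0.4), reps_per_cell=4, seed=3
        )
        res2 = rf_ert_ensemble(
            X, y, ntree_levels=(50,), mtry_fractions=(0.2, 0.4), reps_per_cell=4, seed=3
        )
        assert len(res1.records) == 1 * 2 * 4
        assert res1.records.equals(res2.records)
        assert ((res1.ert >= 0) & (res1.ert <= 1)).all()

    def test_disjoint_ranges_converge_to_zero_error(self, rng):
        # two groups with disjoint value ranges on 10 features
        X = rng.uniform(0, 1, size=(24, 10))
        X[12:] += 2.0
        y = np.array(["C"] * 12 + ["H"] * 12)
        res = rf_ert_ensemble(
            X, y, ntree_levels=(100,), mtry_fractions=(0.3,), reps_per_cell=20, seed=1
        )
        assert np.median(res.ert) == 0.0

    def test_permuted_labels_hover_at_chance(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.permutation(np.array(["a"] * 15 + ["b"] * 15))
        res = rf_ert_ensemble(
            X, y, ntree_levels=(100,), mtry_fractions=(0.25,), reps_per_cell=40, seed=2
        )
        # majority-class test error is 0.5 here (5 vs 5 held out)
        assert abs(res.ert.mean() - 0.5) < 0.1

    def test_agrees_with_sklearn_forest_statistically(self, rng):
        """Same protocol, sklearn backend as independent oracle."""
        X = rng.normal(size=(24, 12))
        X[12:, :3] += 1.2
        y01 = np.array([0] * 12 + [1] * 12)
        y = np.where(y01 == 1, "b", "a")
        res = rf_ert_ensemble(
            X, y, ntree_levels=(200,), mtry_fractions=(0.25,), reps_per_cell=40, seed=5
        )
        sk_rng = np.random.default_rng(5)
        sk_erts = []
        for _ in range(40):
            tr, te = stratified_split(y01, sk_rng)
            clf = RandomForestClassifier(
                n_estimators=200, max_features=3, random_state=int(sk_rng.integers(2**31))
            ).fit(X[tr], y01[tr])
            sk_erts.append(1.0 - clf.score(X[te], y01[te]))
        assert abs(res.ert.mean() - np.mean(sk_erts)) < 0.1

    def test_single_group_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="two groups"):
            rf_ert_ensemble(X, np.array(["a"] * 6))


class TestCompareErt:
    def _result(self, erts, name):
        from nephrosens.sensitivity import ErtEnsembleResult

        rec = pd.DataFrame(
            {"ntree": 500, "mtry_fraction": 0.25, "repeat": range(len(erts)), "ert": erts}
        )
        return ErtEnsembleResult(comparison=name, records=rec)

    def test_identical_distributions_not_significant(self, rng):
        e = rng.uniform(0, 1, 50)
        out = compare_ert(self._result(e, "a"), self._result(e, "b"))
        assert out["p_value"] > 0.5

    def test_complete_separation(self):
        out = compare_ert(
            self._result(np.zeros(100), "a"), self._result(np.full(100, 0.5), "b")
        )
        assert out["p_value"] < 1e-10
        assert out["higher_ert"] == "b"

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            compare_ert(self._result([], "a"), self._result([0.1], "b"))


class TestTwoGroupQ2:
    def test_null_effect_mostly_nonpositive(self):
        # at n = 30 the null Q2 distribution keeps some mass above zero
        # (chance alignment of labels with X structure), but its bulk and
        # mean are clearly negative
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            q = two_group_q2(
                rng.normal(size=(15, 100)), rng.normal(size=(15, 100)), seed=seed
            )
            vals.append(q["q2"])
        assert np.mean(vals) <= 0
        assert np.mean(np.asarray(vals) <= 0) >= 0.75

    def test_strong_effect_and_monotonicity(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(30, 100))
        q2s = []
        for shift in (0.0, 1.0, 2.0):
            Xc = base[:15].copy()
            Xd = base[15:].copy()
            Xd[:, :20] += shift  # effect on 20% of features
            q2s.append(two_group_q2(Xc, Xd, seed=1)["q2"])
        assert q2s[2] > 0.5
        assert q2s[0] < q2s[1] < q2s[2]


class TestMcfc:
    def _matrix(self, treated_rows, m=39, control_value=10.0):
        ctrl = np.full((5, m), control_value)
        rows = np.vstack([ctrl, treated_rows])
        groups = ["C"] * 5 + ["L"] * len(treated_rows)
        return make_matrix(rows, groups, tissue="medulla")

    def test_identity_fold_changes_hit_lower_bound(self):
        res = mcfc(self._matrix(np.full((3, 39), 10.0)), [f"F{j}" for j in range(39)])
        assert np.allclose(res.values["mcfc"], 39.0)

    def test_reciprocal_rule_hand_example(self):
        treated = np.array([[20.0, 5.0, 10.0]])  # fold changes 2, 0.5, 1
        res = mcfc(self._matrix(treated, m=3), ["F0", "F1", "F2"])
        assert res.values["mcfc"].iloc[0] == pytest.approx(5.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=20.0, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    def test_inversion_symmetry_and_lower_bound(self, fcs):
        fcs = np.asarray(fcs)
        m = len(fcs)
        treated = np.vstack([10.0 * fcs, 10.0 / fcs])
        res = mcfc(self._matrix(treated, m=m), [f"F{j}" for j in range(m)])
        a, b = res.values["mcfc"]
        assert a == pytest.approx(b, rel=1e-9)  # x -> 1/x symmetry
        assert a >= m - 1e-9
        if np.any(np.abs(np.log(fcs)) > 1e-9):
            assert a > m

    def test_strictly_increasing_in_single_fold_change(self):
        base = np.array([[20.0, 10.0, 10.0]])
        bigger = np.array([[40.0, 10.0, 10.0]])
        feats = ["F0", "F1", "F2"]
        lo = mcfc(self._matrix(base, m=3), feats).values["mcfc"].iloc[0]
        hi = mcfc(self._matrix(bigger, m=3), feats).values["mcfc"].iloc[0]
        assert hi > lo

    def test_between_tissue_comparison_direction(self):
        rng = np.random.default_rng(2)
        m = 10
        feats = [f"F{j}" for j in range(m)]
        blocks, meta_rows, ids = [], [], []
        for tissue, fc in (("cortex", 1.3), ("medulla", 3.0)):
            ctrl = rng.lognormal(2, 0.05, size=(6, m))
            trt = rng.lognormal(2, 0.05, size=(6, m)) * fc
            blocks.append(np.vstack([ctrl, trt]))
            for i, g in enumerate(["C"] * 6 + ["L"] * 6):
                ids.append(f"{tissue}_{i}")
                meta_rows.append((tissue, g, False))
        from nephrosens.matrix import IntensityMatrix

        values = pd.DataFrame(np.vstack(blocks), index=ids, columns=feats)
        meta = pd.DataFrame(
            meta_rows, index=ids, columns=["tissue", "group", "qc_flag"]
        )
        combined = IntensityMatrix(values, meta)
        res = mcfc(combined, feats)
        summ = res.group_summary().set_index("tissue")
        assert (
            summ.loc["medulla", "mean"] > summ.loc["cortex", "mean"]
        )
        assert res.between_tissue_p["L"] < 0.05

    def test_empty_metabolite_set_rejected(self):
        with pytest.raises(ValueError):
            mcfc(self._matrix(np.full((2, 3), 1.0), m=3), [])
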