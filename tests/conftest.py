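import numpy as np
import pandas as pd
import pytest

from nephrosens.matrix import IntensityMatrix
from nephrosens.simulate import (
    ArchetypeSpec,
    StudyDesign,
    default_archetypes,
    generate_dataset,
)


def make_matrix(values, groups, tissue="cortex", qc=None, rt=None):
    """Small helper to build an IntensityMatrix from raw arrays."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = [f"s{i}" for i in range(n)]
    feats = [f"F{j}" for j in range(p)]
    qc = [False] * n if qc is None else list(qc)
    meta = pd.DataFrame({"tissue": tissue, "group": groups, "qc_flag": qc}, index=ids)
    fm = pd.DataFrame(index=pd.Index(feats))
    if rt is not None:
        fm["rt"] = rt
    return IntensityMatrix(pd.DataFrame(values, index=ids, columns=feats), meta, fm)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-tissue synthetic study, moderate size, low noise."""
    design = StudyDesign(n_features=60, n_qc=5)
    archetypes = [(s, 4) for s in default_archetypes(2.0)]
    return generate_dataset(design, archetypes, baseline_cv=0.5, noise_cv=0.1, seed=42)


@pytest.fixture(scope="session")
def binary_data():
    """Two well-separated classes for OPLS/RF unit tests."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 40))
    X[15:, :6] += 2.0
    y = np.array(["a"] * 15 + ["b"] * 15)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
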