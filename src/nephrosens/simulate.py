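"""Synthetic cortex/medulla metabolomics datasets with known dose-response truth.

The generator emulates the structure of a four-group (control + three
cisplatin doses) rat kidney study: two tissue compartments, final group
sizes 13/11/13/16, pooled-QC injections, strictly positive log-normal
abundances with multiplicative measurement noise, and per-feature
dose-response archetypes (dose-monotone, step at the medium dose, step at
the high dose, dose-uncorrelated; each in up and down variants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

ARCHETYPE_NAMES = ("dose_monotone", "step_M", "step_H", "uncorrelated")
DOSE_GROUPS = ("C", "L", "M", "H")
#: nominal cisplatin doses in mg/kg for groups C, L, M, H
DOSES_MG_KG = {"C": 0.0, "L": 2.5, "M": 5.0, "H": 10.0}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: per-group animal counts, dose ordering, QC injections."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"C": 13, "L": 11, "M": 13, "H": 16}
    )
    dose_labels: tuple[str, ...] = DOSE_GROUPS
    n_qc: int = 8
    n_features: int = 100
    tissues: tuple[str, ...] = ("cortex", "medulla")

    def __post_init__(self) -> None:
        if len(set(self.dose_labels)) != len(self.dose_labels):
            raise ConfigurationError("dose labels must be unique")
        if set(self.group_sizes) != set(self.dose_labels):
            raise ConfigurationError("group_sizes keys must match dose_labels")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ConfigurationError("each group needs at least 2 samples")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be positive")
        if self.n_qc < 0:
            raise ConfigurationError("n_qc must be non-negative")

    @property
    def n_samples_per_tissue(self) -> int:
        return sum(self.group_sizes.values()) + self.n_qc


@dataclass(frozen=True)
class ArchetypeSpec:
    """A dose-response trend class with nominal fold changes (FC_L, FC_M, FC_H)."""

    name: str
    direction: str  # "up" or "down"
    fold_changes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ConfigurationError(f"unknown archetype {self.name!r}")
        if self.direction not in ("up", "down"):
            raise ConfigurationError("direction must be 'up' or 'down'")
        if any(fc <= 0 for fc in self.fold_changes):
            raise ConfigurationError("fold changes must be positive")
        fl, fm, fh = self.fold_changes
        if self.name == "dose_monotone":
            ok = 1 < fl < fm < fh if self.direction == "up" else 1 > fl > fm > fh
            if not ok:
                raise ConfigurationError(
                    "dose_monotone requires strictly dose-ordered fold changes"
                )


@dataclass(frozen=True)
class TruthRecord:
    """What was planted for one (tissue, feature): archetype + realized FCs."""

    archetype: ArchetypeSpec | None  # None = flat housekeeping feature
    tissue: str
    fc: tuple[float, float, float]  # realized (jittered) fold changes


@dataclass
class SyntheticDataset:
    matrix: IntensityMatrix
    truth: dict[tuple[str, str], TruthRecord]  # (tissue, feature_id) -> record
    seed: int

    def truth_json(self) -> dict:
        out = {}
        for (tissue, feat), rec in self.truth.items():
            out[f"{tissue}:{feat}"] = {
                "archetype": rec.archetype.name if rec.archetype else "flat",
                "direction": rec.archetype.direction if rec.archetype else None,
                "fc": list(rec.fc),
            }
        return out

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.matrix.to_csv(prefix.with_suffix(".csv"))
        with open(prefix.with_suffix(".truth.json"), "w") as fh:
            json.dump({"seed": self.seed, "truth": self.truth_json()}, fh, indent=1)


def default_archetypes(
    log2_effect: float = 2.0, directions: tuple[str, ...] = ("up", "down")
) -> list[ArchetypeSpec]:
    """The eight canonical archetypes at a given maximal |log2 FC|.

    ``dose_monotone`` is linear in log dose -- the three doses are equally
    spaced on the log scale (2.5, 5, 10 mg/kg), so its log2 fold changes
    rise in equal steps to ``log2_effect`` at the high dose; the step
    archetypes jump straight to ``log2_effect`` at their trigger dose.
    """
    e = float(log2_effect)
    specs = []
    for d in directions:
        s = 1.0 if d == "up" else -1.0
        specs += [
            ArchetypeSpec("dose_monotone", d, tuple(2.0 ** (s * e * f) for f in (1 / 3, 2 / 3, 1.0))),
            ArchetypeSpec("step_M", d, (1.0, 2.0 ** (s * e), 2.0 ** (s * e))),
            ArchetypeSpec("step_H", d, (1.0, 1.0, 2.0 ** (s * e))),
            ArchetypeSpec("uncorrelated", d, (1.0, 1.0, 1.0)),
        ]
    return specs


def _cv_to_sigma(cv: float) -> float:
    # log-normal: CV^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cv * cv)))


def _realized_fc(
    spec: ArchetypeSpec, rng: np.random.Generator, jitter: float, uncorr_log2_range: float
) -> np.ndarray:
    """Per-feature realized fold-change triple.

    Step-archetype components are jittered multiplicatively by +/-``jitter``
    (default 5%), which turns their "approximately 1" and "approximately
    equal" slots into realistic near-ties; ``dose_monotone`` has no
    approximate slots (its ordering is strict) and keeps its nominal triple
    exactly.  The ``uncorrelated`` archetype
    draws each component independently on a symmetric log2 range, rejecting
    draws whose log fold changes correlate strongly (|r| > 0.6) with the
    dose ordering -- otherwise the archetype would not honour its own name.
    """
    if spec.name == "uncorrelated":
        dose_trend = np.array([-1.0, 0.0, 1.0])
        lfc = np.zeros(3)
        for _ in range(1000):
            lfc = rng.uniform(-uncorr_log2_range, uncorr_log2_range, size=3)
            if np.std(lfc) == 0:
                continue
            if abs(float(np.corrcoef(lfc, dose_trend)[0, 1])) <= 0.6:
                break
        return 2.0 ** lfc
    fc = np.asarray(spec.fold_changes, dtype=float)
    if spec.name == "dose_monotone":
        return fc
    return fc * rng.uniform(1.0 - jitter, 1.0 + jitter, size=3)


def generate_dataset(
    design: StudyDesign | None = None,
    archetypes: list[tuple[ArchetypeSpec, int]] | None = None,
    baseline_cv: float = 0.5,
    noise_cv: float = 0.1,
    seed: int = 0,
    qc_cv: float = 0.05,
    fc_jitter: float = 0.05,
    uncorr_log2_range: float = 1.5,
) -> SyntheticDataset:
    """Generate a two-tissue intensity matrix with planted dose-response truth.

    Feature ``j`` in dose group ``g`` has expected abundance
    ``baseline_j * FC_j(g)`` with baselines drawn log-normally around 1e5
    (spread ``baseline_cv``) and multiplicative log-normal measurement noise
    of coefficient of variation ``noise_cv``.  Archetype assignments are drawn
    independently per tissue (shared feature identities, tissue-specific
    regulation), features beyond the requested archetype counts stay flat
    (FC = 1 at every dose), and ``n_qc`` pooled-QC rows per tissue are
    appended via :func:`make_qc_samples`.
    """
    design = design or StudyDesign()
    if archetypes is None:
        archetypes = [(spec, 5) for spec in default_archetypes()]
    total = sum(c for _, c in archetypes)
    if total > design.n_features:
        raise ConfigurationError(
            f"archetype counts sum to {total} > n_features={design.n_features}"
        )
    if not (0 < noise_cv < 1) or not (0 < baseline_cv < 1):
        # noise_cv may be made arbitrarily small but must stay positive
        if noise_cv <= 0 or baseline_cv <= 0 or noise_cv >= 1 or baseline_cv >= 1:
            raise ConfigurationError("CVs must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    feature_ids = [f"F{j:04d}" for j in range(design.n_features)]
    # log-normal baselines around 1e5, shared between tissues
    baselines = 1e5 * rng.lognormal(0.0, _cv_to_sigma(baseline_cv), design.n_features)
    sigma_noise = _cv_to_sigma(noise_cv)

    dose_groups = [g for g in design.dose_labels]
    treated = dose_groups[1:]

    tissue_mats: list[IntensityMatrix] = []
    truth: dict[tuple[str, str], TruthRecord] = {}
    for tissue in design.tissues:
        # independent archetype assignment per tissue
        perm = rng.permutation(design.n_features)
        fc_table = np.ones((design.n_features, len(treated)))
        pos = 0
        for spec, count in archetypes:
            for j in perm[pos : pos + count]:
                fc = _realized_fc(spec, rng, fc_jitter, uncorr_log2_range)
                fc_table[j] = fc
                truth[(tissue, feature_ids[j])] = TruthRecord(spec, tissue, tuple(fc))
            pos += count
        for j in perm[pos:]:
            truth[(tissue, feature_ids[j])] = TruthRecord(None, tissue, (1.0, 1.0, 1.0))

        rows, ids, groups = [], [], []
        for g in dose_groups:
            fc_g = (
                np.ones(design.n_features)
                if g == dose_groups[0]
                else fc_table[:, treated.index(g)]
            )
            n_g = design.group_sizes[g]
            noise = rng.lognormal(0.0, sigma_noise, size=(n_g, design.n_features))
            rows.append(baselines * fc_g * noise)
            ids += [f"{tissue[:3]}_{g}{i + 1:02d}" for i in range(n_g)]
            groups += [g] * n_g
        values = pd.DataFrame(np.vstack(rows), index=ids, columns=feature_ids)
        meta = pd.DataFrame(
            {"tissue": tissue, "group": groups, "qc_flag": False}, index=ids
        )
        feature_meta = pd.DataFrame(
            {
                "rt": np.round(np.sort(rng.uniform(0.5, 29.5, design.n_features)), 4),
                "mz": np.round(rng.uniform(50, 1000, design.n_features), 4),
            },
            index=feature_ids,
        )
        mat = IntensityMatrix(values, meta, feature_meta)
        mat = make_qc_samples(
            mat, design.n_qc, qc_cv, seed=int(rng.integers(2**31)), tissue=tissue
        )
        tissue_mats.append(mat)

    matrix = tissue_mats[0]
    for other in tissue_mats[1:]:
        matrix = matrix.concat(other)
    return SyntheticDataset(matrix=matrix, truth=truth, seed=seed)


def make_qc_samples(
    matrix: IntensityMatrix,
    n_qc: int,
    qc_cv: float = 0.05,
    seed: int = 0,
    tissue: str | None = None,
) -> IntensityMatrix:
    """Append pooled-QC rows: per-feature mean of all real samples x log-normal noise.

    Emulates pooling an equal aliquot of every study sample and re-injecting
    it periodically; ``qc_cv`` is the analytical coefficient of variation.
    """
    if n_qc < 0:
        raise ConfigurationError("n_qc must be non-negative")
    if matrix.n_samples < 1:
        raise ConfigurationError("matrix needs at least one real sample")
    if n_qc == 0:
        return matrix
    rng = np.random.default_rng(seed)
    real = matrix.values.loc[~matrix.is_qc().to_numpy()]
    pooled = real.to_numpy().mean(axis=0)
    sigma = _cv_to_sigma(qc_cv) if qc_cv > 0 else 0.0
    noise = (
        rng.lognormal(0.0, sigma, size=(n_qc, matrix.n_features))
        if sigma > 0
        else np.ones((n_qc, matrix.n_features))
    )
    tis = tissue or str(matrix.sample_meta["tissue"].iloc[0])
    ids = [f"{tis[:3]}_QC{i + 1:02d}" for i in range(n_qc)]
    qc_values = pd.DataFrame(pooled * noise, index=ids, columns=matrix.feature_ids)
    qc_meta = pd.DataFrame({"tissue": tis, "group": "QC", "qc_flag": True}, index=ids)
    return IntensityMatrix(
        pd.concat([matrix.values, qc_values]),
        pd.concat([matrix.sample_meta, qc_meta]),
        matrix.feature_meta.copy(),
    )


def ground_truth_foldchanges(dataset: SyntheticDataset):
    """Planted per-feature fold-change triples as tissue-tagged profiles.

    Returns one :class:`~nephrosens.cast.FoldChangeProfile` per (tissue,
    feature), flat features included as (1, 1, 1), for parameter-recovery
    tests against what the pipeline estimates.
    """
    from .cast import FoldChangeProfile

    profiles = []
    for (tissue, feat), rec in dataset.truth.items():
        profiles.append(FoldChangeProfile(metabolite=feat, tissue=tissue, fc=rec.fc))
    return profiles
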