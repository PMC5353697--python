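"""End-to-end pipeline orchestration and plot-data rendering.

The canonical outputs are tidy tables (heat-map matrices with dendrogram
structure, score tables, ERT records, fold-change profiles), not rendered
figures, so every figure analogue can be regenerated from the report bundle
alone and tests never assert on pixels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import cast as cast_mod
from . import preprocess, screening, sensitivity, simulate
from .matrix import IntensityMatrix

log = logging.getLogger("nephrosens")


# ----------------------------------------------------------------------
@dataclass
class HeatmapData:
    scaled: pd.DataFrame          # row-autoscaled values
    row_linkage: np.ndarray       # scipy linkage matrix
    row_order: list               # leaf order (permutation of row labels)
    col_order: list
    constant_rows: list           # rows left unscaled
    col_linkage: np.ndarray | None = None


def heatmap_data(
    matrix: pd.DataFrame,
    row_metric: str = "pearson_distance",
    linkage: str = "average",
    cluster_columns: bool = False,
) -> HeatmapData:
    """Row-autoscaled heat-map values with hierarchical row clustering.

    Rows are scaled to mean 0, variance 1 (constant rows are flagged and
    left unscaled); distances are 1 - Pearson r and linkage is average by
    default.  Leaf ordering is scipy's deterministic ordering, which breaks
    ties by input order.  Columns keep their input order (typically dose
    groups) unless ``cluster_columns`` is set, in which case they are
    clustered with Euclidean distance on the row-scaled values.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if row_metric != "pearson_distance":
        raise ValueError("only pearson_distance is supported")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) left unscaled")
    scale = np.where(constant, 1.0, sd)
    Xs = (X - X.mean(axis=1, keepdims=True)) / scale[:, None]
    # correlation distance 1 - r; constant rows get distance 1 to everything
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.where(constant, 1.0, np.linalg.norm(Xc, axis=1))
    Xn = Xc / norm[:, None]
    corr = Xn @ Xn.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    col_linkage = None
    col_order = list(matrix.columns)
    if cluster_columns and matrix.shape[1] >= 2:
        col_linkage = hierarchy.linkage(Xs.T, method=linkage, metric="euclidean")
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    return HeatmapData(
        scaled=pd.DataFrame(Xs, index=matrix.index, columns=matrix.columns),
        row_linkage=Z,
        row_order=[matrix.index[i] for i in order],
        col_order=col_order,
        constant_rows=list(matrix.index[constant]),
        col_linkage=col_linkage,
    )


# ----------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """Everything a full run needs; seeds are recorded in every artifact."""

    input_csv: str | None = None          # None -> simulate
    output_dir: str = "nephrosens_out"
    seed: int = 0
    # synthetic-data knobs (used when input_csv is None)
    n_features: int = 100
    archetype_count: int = 5              # features per archetype/direction
    log2_effect: float = 2.0
    baseline_cv: float = 0.5
    noise_cv: float = 0.1
    qc_cv: float = 0.05
    medulla_boost: float = 1.0            # >1: medulla |log2 FC| scaled up
    # analysis knobs
    control_label: str = "C"
    tissues: tuple[str, str] = ("cortex", "medulla")
    n_pred: int = 1
    n_orth: int = 1
    scaling: str = "uv"
    alpha: float = 0.05
    screen_mode: str = "any"
    ntree_levels: tuple[int, ...] = sensitivity.NTREE_LEVELS
    mtry_fractions: tuple[float, ...] = sensitivity.MTRY_FRACTIONS
    reps_per_cell: int = sensitivity.REPS_PER_CELL
    ert_doses: tuple[str, ...] = ("L", "M", "H")
    cast_t1: float = 0.80
    cast_t2: float = 0.98
    cast_delta: float = 0.25
    fc_reference: str = "mean"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "ntree_levels", "mtry_fractions", "ert_doses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (where outputs go is not
        part of the analysis identity)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _default_dataset(cfg: PipelineConfig) -> simulate.SyntheticDataset:
    """Synthetic study emulating the dose-response design.

    ``medulla_boost`` > 1 plants larger |log2 FC| in medulla than cortex so
    that the sensitivity comparisons have a known expected direction."""
    design = simulate.StudyDesign(n_features=cfg.n_features, tissues=cfg.tissues)
    if cfg.medulla_boost == 1.0:
        archetypes = [
            (s, cfg.archetype_count) for s in simulate.default_archetypes(cfg.log2_effect)
        ]
        return simulate.generate_dataset(
            design, archetypes, cfg.baseline_cv, cfg.noise_cv, cfg.seed, cfg.qc_cv
        )
    # per-tissue effect sizes: generate each tissue separately and merge
    parts = []
    truth = {}
    for i, tissue in enumerate(cfg.tissues):
        eff = cfg.log2_effect * (cfg.medulla_boost if tissue == "medulla" else 1.0)
        d = simulate.StudyDesign(n_features=cfg.n_features, tissues=(tissue,))
        arch = [(s, cfg.archetype_count) for s in simulate.default_archetypes(eff)]
        ds = simulate.generate_dataset(
            d, arch, cfg.baseline_cv, cfg.noise_cv, cfg.seed + i, cfg.qc_cv
        )
        parts.append(ds.matrix)
        truth.update(ds.truth)
    matrix = parts[0]
    for m in parts[1:]:
        matrix = matrix.concat(m)
    return simulate.SyntheticDataset(matrix=matrix, truth=truth, seed=cfg.seed)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, dataset=None) -> dict:
    """Execute normalize -> QC -> screen -> venn -> sensitivity -> CAST -> report.

    Writes the report bundle under ``config.output_dir`` (tidy CSVs plus a
    JSON summary stamped with the config hash and seed) and returns the
    in-memory bundle.  Reruns with the same config are identical."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config), "config_hash": config.config_hash()}
    rng = np.random.default_rng(config.seed)

    stage = "load"
    try:
        if dataset is not None:
            matrix = dataset.matrix if hasattr(dataset, "matrix") else dataset
        elif config.input_csv:
            matrix = IntensityMatrix.from_csv(config.input_csv)
        else:
            dataset = _default_dataset(config)
            matrix = dataset.matrix
            dataset.save(out / "synthetic")
        log.info("stage=load shape=%s seed=%d", matrix.values.shape, config.seed)

        stage = "normalize"
        norm = preprocess.mstus_normalize(matrix)
        norm.to_csv(out / "normalized.csv")

        stage = "qc"
        qc_report = {}
        for tissue in config.tissues:
            sub = norm.subset(tissue=tissue, include_qc=True)
            res = preprocess.pca(sub, scaling=config.scaling, n_components=2,
                                 seed=config.seed)
            rla = preprocess.rla_values(sub)
            qc_report[tissue] = {
                "pca_r2x": res.r2x.tolist(),
                "pca_q2": res.q2.tolist(),
                "rla_summary": preprocess.rla_summary(rla).to_dict(orient="index"),
            }
            res.scores.assign(
                group=sub.sample_meta["group"], qc=sub.is_qc()
            ).to_csv(out / f"pca_scores_{tissue}.csv")
        bundle["qc"] = qc_report

        stage = "screen"
        screens = {}
        for tissue in config.tissues:
            sc = screening.screen_differential(
                norm,
                tissue=tissue,
                n_pred=config.n_pred,
                n_orth=config.n_orth,
                scaling=config.scaling,
                alpha=config.alpha,
                control_label=config.control_label,
                mode=config.screen_mode,
                seed=int(rng.integers(2**31)),
            )
            screens[tissue] = sc
            sc.records.to_csv(out / f"screen_{tissue}.csv", index=False)
        bundle["screen"] = {t: s.summary() for t, s in screens.items()}

        stage = "venn"
        t_a, t_b = config.tissues
        part = screening.venn(screens[t_a].differential_set, screens[t_b].differential_set)
        bundle["venn"] = part.sizes()

        stage = "sensitivity"
        ert_results: dict[str, dict[str, sensitivity.ErtEnsembleResult]] = {}
        q2_table = []
        for tissue in config.tissues:
            ert_results[tissue] = {}
            sub = norm.subset(tissue=tissue)
            for dose in config.ert_doses:
                pair = sub.subset(groups=[config.control_label, dose])
                res = sensitivity.rf_ert_ensemble(
                    pair,
                    pair.sample_meta["group"].to_numpy(),
                    ntree_levels=config.ntree_levels,
                    mtry_fractions=config.mtry_fractions,
                    reps_per_cell=config.reps_per_cell,
                    seed=int(rng.integers(2**31)),
                    comparison=f"{tissue}:{config.control_label}_vs_{dose}",
                )
                ert_results[tissue][dose] = res
                ctrl = sub.subset(groups=[config.control_label])
                dosed = sub.subset(groups=[dose])
                q2_table.append(
                    {"tissue": tissue, "dose": dose}
                    | sensitivity.two_group_q2(
                        ctrl,
                        dosed,
                        n_pred=config.n_pred,
                        n_orth=config.n_orth,
                        seed=int(rng.integers(2**31)),
                        scaling=config.scaling,
                    )
                )
        all_records = pd.concat(
            [
                r.records.assign(comparison=r.comparison)
                for t in ert_results.values()
                for r in t.values()
            ],
            ignore_index=True,
        )
        all_records.to_csv(out / "ert_records.csv", index=False)
        bundle["ert"] = {
            t: {d: r.summary() for d, r in doses.items()}
            for t, doses in ert_results.items()
        }
        bundle["ert_comparison"] = {
            dose: sensitivity.compare_ert(ert_results[t_a][dose], ert_results[t_b][dose])
            for dose in config.ert_doses
        }
        bundle["q2"] = q2_table

        stage = "mcfc"
        common = sorted(part.common)
        if common:
            mres = sensitivity.mcfc(
                norm, common, control_label=config.control_label
            )
            mres.values.to_csv(out / "mcfc.csv", index=False)
            bundle["mcfc"] = {
                "n_metabolites": mres.n_metabolites,
                "group_summary": mres.group_summary().to_dict(orient="records"),
                "between_tissue_p": mres.between_tissue_p,
            }
        else:
            bundle["mcfc"] = {"n_metabolites": 0}

        stage = "cast"
        profiles = []
        for tissue in config.tissues:
            feats = sorted(screens[tissue].differential_set)
            if feats:
                profiles += cast_mod.fold_change_profiles(
                    norm,
                    feats,
                    tissue,
                    control_label=config.control_label,
                    reference=config.fc_reference,
                )
        if len(profiles) >= 2:
            cast_mod.profiles_table(profiles).to_csv(
                out / "fold_change_profiles.csv", index=False
            )
            try:
                two_step = cast_mod.two_step_cast(
                    profiles, t1=config.cast_t1, t2=config.cast_t2, delta=config.cast_delta
                )
                bundle["cast"] = two_step.summary()
                bundle["cast"]["contributive_set"] = sorted(two_step.contributive_set)
            except ValueError as exc:
                bundle["cast"] = {"error": str(exc)}
        else:
            bundle["cast"] = {"error": "fewer than 2 differential profiles"}

        stage = "heatmap"
        for tissue in config.tissues:
            feats = sorted(screens[tissue].differential_set)
            if len(feats) < 2:
                continue
            sub = norm.subset(tissue=tissue, features=feats)
            hm = heatmap_data(sub.values.T)  # rows = metabolites
            hm.scaled.to_csv(out / f"heatmap_{tissue}.csv")
            pd.DataFrame(
                hm.row_linkage, columns=["left", "right", "height", "count"]
            ).to_csv(out / f"heatmap_{tissue}_linkage.csv", index=False)
    except StageFailure:
        raise
    except Exception as exc:  # halt with stage name; partial outputs remain
        raise StageFailure(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    return bundle
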