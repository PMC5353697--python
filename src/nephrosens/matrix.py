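"""Sample x feature intensity matrix with sample and feature metadata.

The on-disk dialect is a wide CSV/TSV: one row per sample, metadata columns
(``sample_id``, ``tissue``, ``group``, ``qc_flag``) first, then one column per
feature.  Feature metadata (retention time, m/z, optional name) travels in a
sidecar table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["tissue", "group", "qc_flag"]


class MatrixError(ValueError):
    """Raised when an intensity matrix violates its structural contract."""


@dataclass
class IntensityMatrix:
    """Non-negative sample x feature abundances plus metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per feature id.
    sample_meta
        DataFrame indexed by sample id with columns ``tissue``, ``group``
        and boolean ``qc_flag``.
    feature_meta
        DataFrame indexed by feature id; recognised columns are
        ``rt`` (retention time, minutes), ``mz`` (Thomson) and ``name``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.values.columns)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise MatrixError("duplicate sample ids")
        if v.columns.has_duplicates:
            raise MatrixError("duplicate feature ids")
        if (v.to_numpy() < 0).any():
            raise MatrixError("negative intensities are not allowed")
        if not v.index.equals(self.sample_meta.index):
            raise MatrixError("sample_meta index must match values index")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise MatrixError(f"sample_meta lacks columns: {missing}")
        if not v.columns.equals(self.feature_meta.index):
            raise MatrixError("feature_meta index must match feature columns")
        qc = self.sample_meta["qc_flag"].astype(bool)
        if (~qc & self.sample_meta["group"].isna()).any():
            raise MatrixError("every non-QC sample needs a group label")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def is_qc(self) -> pd.Series:
        return self.sample_meta["qc_flag"].astype(bool)

    # ------------------------------------------------------------------
    def subset(
        self,
        tissue: str | None = None,
        groups: list[str] | None = None,
        features: list[str] | None = None,
        include_qc: bool = False,
    ) -> "IntensityMatrix":
        """Return a copy restricted to a tissue, dose groups and/or features."""
        mask = np.ones(self.n_samples, dtype=bool)
        if tissue is not None:
            mask &= (self.sample_meta["tissue"] == tissue).to_numpy()
        if groups is not None:
            gmask = self.sample_meta["group"].isin(groups).to_numpy()
            if include_qc:
                gmask |= self.is_qc().to_numpy()
            mask &= gmask
        elif not include_qc:
            mask &= ~self.is_qc().to_numpy()
        cols = self.values.columns if features is None else pd.Index(features)
        return IntensityMatrix(
            self.values.loc[mask, cols].copy(),
            self.sample_meta.loc[mask].copy(),
            self.feature_meta.loc[cols].copy(),
        )

    def real_samples(self) -> "IntensityMatrix":
        """Drop pooled-QC rows."""
        keep = ~self.is_qc().to_numpy()
        return IntensityMatrix(
            self.values.loc[keep].copy(),
            self.sample_meta.loc[keep].copy(),
            self.feature_meta.copy(),
        )

    def concat(self, other: "IntensityMatrix") -> "IntensityMatrix":
        if not self.values.columns.equals(other.values.columns):
            raise MatrixError("feature columns differ between matrices")
        return IntensityMatrix(
            pd.concat([self.values, other.values]),
            pd.concat([self.sample_meta, other.sample_meta]),
            self.feature_meta.copy(),
        )

    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        """Write the wide-table dialect; feature metadata in a sidecar."""
        path = Path(path)
        wide = pd.concat([self.sample_meta[META_COLUMNS], self.values], axis=1)
        wide.index.name = "sample_id"
        wide.to_csv(path, sep=sep)
        side = path.with_name(path.stem + ".features" + path.suffix)
        fm = self.feature_meta.copy()
        fm.index.name = "feature_id"
        fm.to_csv(side, sep=sep)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "IntensityMatrix":
        path = Path(path)
        wide = pd.read_csv(path, sep=sep, index_col="sample_id")
        meta = wide[META_COLUMNS].copy()
        meta["qc_flag"] = meta["qc_flag"].astype(bool)
        values = wide.drop(columns=META_COLUMNS)
        side = path.with_name(path.stem + ".features" + path.suffix)
        feature_meta = None
        if side.exists():
            feature_meta = pd.read_csv(side, sep=sep, index_col="feature_id")
            feature_meta.index = feature_meta.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, meta, feature_meta)
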