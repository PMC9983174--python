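"""In-memory container for a feature-by-sample expression matrix.

The matrix holds non-negative expression intensities exactly as provided
by the platform (unlogged).  All downstream statistics in this package are
rank-based within each sample, so no normalisation is applied or needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ExpressionMatrix:
    """Features x samples expression intensities with optional phenotype labels.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
        Must be complete (no missing entries) with unique identifiers.
    labels
        Mapping ``sample_id -> phenotype``.  Optional at read time; required
        for training operations.  Every labelled sample must exist in the
        matrix.
    """

    data: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if len(idx) == 0 or len(cols) == 0:
            raise ValidationError("empty expression matrix")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if not all(isinstance(c, str) for c in cols):
            self.data.columns = cols.astype(str)
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric cell in expression table")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("missing value in expression table")
        unknown = set(self.labels) - set(self.sample_ids)
        if unknown:
            raise ValidationError(
                f"labelled samples absent from matrix: {sorted(unknown)[:5]}"
            )

    # -- accessors -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_with_label(self, phenotype: str) -> list[str]:
        return [s for s in self.sample_ids if self.labels.get(s) == phenotype]

    def sample_vector(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise ValidationError(f"unknown sample id: {sample_id}")
        return self.data[sample_id]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)[:5]}")
        labels = {s: self.labels[s] for s in sample_ids if s in self.labels}
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and list(self.data.columns) == list(other.data.columns)
            and self.labels == other.labels
        )
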