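"""Correlation-based outlier sample removal.

Within each phenotype, the Pearson correlation between the expression
profiles of every two samples is computed; a sample is an outlier when the
mean of its correlations with the other samples of that phenotype falls
strictly outside ``center +/- sd_multiple * spread``, where center and
spread are the mean and standard deviation of those per-sample means.  The
rule is applied in a single pass (no iterative re-trimming), per phenotype.

Correlations are computed on the intensities as provided (no log
transform).  A zero-variance sample has no defined correlation with any
other sample and is removed and reported as degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .matrix import ExpressionMatrix


@dataclass
class OutlierReport:
    """Outcome of outlier screening for one phenotype."""

    phenotype: str
    per_sample_mean_corr: dict[str, float]
    center: float
    spread: float
    removed: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "per_sample_mean_corr": {
                k: (None if math.isnan(v) else v)
                for k, v in self.per_sample_mean_corr.items()
            },
            "center": self.center,
            "spread": self.spread,
            "removed": list(self.removed),
        }


def remove_outliers(
    matrix: ExpressionMatrix, phenotype: str, sd_multiple: float = 2.0
) -> tuple[ExpressionMatrix, OutlierReport]:
    """Drop outlier samples of one phenotype; other phenotypes pass through.

    Requires at least 3 samples of the phenotype.  The boundary case
    ``|mean - center| == sd_multiple * spread`` is retained ("outside" is
    a strict inequality).
    """
    sample_ids = matrix.samples_with_label(phenotype)
    if len(sample_ids) < 3:
        raise ValidationError(
            f"need >= 3 samples labelled {phenotype!r}, got {len(sample_ids)}"
        )
    vals = matrix.data[sample_ids].to_numpy(dtype=float)

    sd = vals.std(axis=0)
    degenerate = sd == 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals.T)
    # mean correlation with the *other* samples: exclude the diagonal and
    # any undefined (degenerate-partner) entries
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    n_defined = np.isfinite(off).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_corr = np.nansum(off, axis=1) / n_defined
    mean_corr[n_defined == 0] = np.nan
    mean_corr[degenerate] = np.nan

    finite = np.isfinite(mean_corr)
    if not finite.any():
        raise ValidationError(f"all samples of {phenotype!r} are degenerate")
    center = float(mean_corr[finite].mean())
    spread = float(mean_corr[finite].std(ddof=1)) if finite.sum() > 1 else 0.0

    removed_mask = degenerate | (
        finite & (np.abs(mean_corr - center) > sd_multiple * spread)
    )
    removed = [s for s, r in zip(sample_ids, removed_mask) if r]

    survivors = [s for s in matrix.sample_ids if s not in set(removed)]
    report = OutlierReport(
        phenotype=phenotype,
        per_sample_mean_corr=dict(zip(sample_ids, (float(x) for x in mean_corr))),
        center=center,
        spread=spread,
        removed=removed,
    )
    return matrix.subset_samples(survivors), report


def remove_outliers_all(
    matrix: ExpressionMatrix, sd_multiple: float = 2.0
) -> tuple[ExpressionMatrix, list[OutlierReport]]:
    """Apply outlier removal to every phenotype present in the labels."""
    reports: list[OutlierReport] = []
    current = matrix
    for phenotype in sorted(set(matrix.labels.values())):
        current, report = remove_outliers(current, phenotype, sd_multiple)
        reports.append(report)
    return current, reports
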