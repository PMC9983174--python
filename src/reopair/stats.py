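"""Per-feature two-group differential expression.

Classic two-sample Student's t-test (equal variances pooled) on the
intensities as provided, with Benjamini-Hochberg FDR control over all
tested features.  Welch's unequal-variance variant and a log2 transform
are available as flags.  Features with zero variance in both groups have
an undefined test statistic; they are reported with t = 0 and p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .screen import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class DiffExpResult:
    feature_id: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    q_value: float
    significant: bool


def diff_expression(
    matrix: ExpressionMatrix,
    label_a: str,
    label_b: str,
    fdr: float = 0.05,
    welch: bool = False,
    log2: bool = False,
) -> list[DiffExpResult]:
    """t-test every feature between two phenotypes; BH over all features.

    Results are sorted by q-value (ascending, original feature order on
    ties); ``significant`` marks q < fdr.
    """
    group_a = matrix.samples_with_label(label_a)
    group_b = matrix.samples_with_label(label_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(group_a)} "
            f"{label_a!r} and {len(group_b)} {label_b!r}"
        )
    xa = matrix.data[group_a].to_numpy(dtype=float)
    xb = matrix.data[group_b].to_numpy(dtype=float)
    if log2:
        if (xa < 0).any() or (xb < 0).any():
            raise ValidationError("negative intensity under log2 transform")
        xa = np.log2(xa + 1.0)
        xb = np.log2(xb + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = _sps.ttest_ind(xa, xb, axis=1, equal_var=not welch)
    undefined = ~np.isfinite(p)
    if undefined.any():
        logger.warning(
            "%d features had an undefined t-test (zero variance in both "
            "groups); reported with p = 1",
            int(undefined.sum()),
        )
        t = np.where(undefined, 0.0, t)
        p = np.where(undefined, 1.0, p)
    q = bh_adjust(p)

    results = [
        DiffExpResult(
            feature_id=fid,
            mean_a=float(xa[i].mean()),
            mean_b=float(xb[i].mean()),
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            significant=bool(q[i] < fdr),
        )
        for i, fid in enumerate(matrix.feature_ids)
    ]
    results.sort(key=lambda r: r.q_value)
    return results
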