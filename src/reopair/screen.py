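"""Screening of feature pairs by within-sample relative expression ordering.

For an ordered pair (a, b) the relative expression ordering (REO) within a
sample is the binary event E_a > E_b versus E_a <= E_b (exact ties count on
the <= side).  A pair is *stable* in the control phenotype when the fraction
P(E_a > E_b) over control samples is at least a stability threshold (e.g.
0.95).  A stable pair is *reversed* when the REO distribution differs
significantly between control and case samples (two-sided Fisher's exact
test, Benjamini-Hochberg FDR over the stable-pair family).  The effect size
is dP = P_control - P_case; candidate pairs must additionally satisfy
dP >= a configurable threshold (1.0 for complete reversal, 0.7 in the
cancer-versus-cancer setting).

All n(n-1) ordered pairs are enumerated; enumeration order is lexicographic
by (a, b) feature id, which also serves as the deterministic tie-break order
downstream.  Pair counting is blocked over features so screening a
2550-feature matrix never materialises all pair-by-sample booleans at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import EmptyResultError, ValidationError
from .matrix import ExpressionMatrix

_EPS = 1e-12  # guards >= comparisons of count ratios against fp rounding


class MiRPair(NamedTuple):
    """Ordered feature pair; (a, b) and (b, a) are distinct pairs."""

    a: str
    b: str


@dataclass
class PairScreenResult:
    """Per-pair REO fractions, 2x2 contingency counts and test results.

    n1/n2 are control samples with E_a > E_b / E_a <= E_b; m1/m2 the same
    for case samples.  delta_p = p_control - p_case, in [-1, 1].
    """

    pair: MiRPair
    n1: int
    n2: int
    m1: int
    m2: int
    p_control: float
    p_case: float
    delta_p: float
    p_value: float
    q_value: float


def _feature_indices(matrix: ExpressionMatrix, pair: MiRPair) -> tuple[int, int]:
    idx = matrix.data.index
    ia, ib = idx.get_indexer([pair.a, pair.b])
    if ia < 0:
        raise ValidationError(f"unknown feature: {pair.a}")
    if ib < 0:
        raise ValidationError(f"unknown feature: {pair.b}")
    return int(ia), int(ib)


def pair_fraction(
    matrix: ExpressionMatrix, pair: MiRPair, sample_subset: Sequence[str]
) -> float:
    """Fraction of the given samples with E_a strictly > E_b (ties are <=)."""
    if len(sample_subset) == 0:
        raise ValidationError("empty sample subset")
    if pair.a == pair.b:
        raise ValidationError("pair members must differ")
    ia, ib = _feature_indices(matrix, pair)
    cols = matrix.data.columns.get_indexer(list(sample_subset))
    if (cols < 0).any():
        missing = [s for s, c in zip(sample_subset, cols) if c < 0]
        raise ValidationError(f"unknown sample ids: {missing[:5]}")
    vals = matrix.values
    k = int((vals[ia, cols] > vals[ib, cols]).sum())
    return k / len(sample_subset)


def _pair_counts(values: np.ndarray, block: int = 64) -> np.ndarray:
    """counts[i, j] = number of samples (columns) with values[i] > values[j].

    Blocked over rows: peak extra memory is block * n_features * n_samples
    booleans, independent of the total pair count.
    """
    n_feat = values.shape[0]
    counts = np.empty((n_feat, n_feat), dtype=np.int64)
    for start in range(0, n_feat, block):
        stop = min(start + block, n_feat)
        gt = values[start:stop, None, :] > values[None, :, :]
        counts[start:stop] = gt.sum(axis=2)
    return counts


def _lex_order(feature_ids: list[str]) -> np.ndarray:
    """Row permutation putting feature ids in lexicographic order."""
    return np.argsort(np.asarray(feature_ids, dtype=object), kind="stable")


def find_stable_pairs(
    matrix: ExpressionMatrix,
    control_label: str,
    stability_threshold: float,
) -> list[tuple[MiRPair, float]]:
    """All ordered pairs with control REO fraction >= the threshold.

    Returned in lexicographic (a, b) enumeration order with their
    p_control values.
    """
    if not 0.5 < stability_threshold <= 1.0:
        raise ValidationError("stability threshold must be in (0.5, 1]")
    controls = matrix.samples_with_label(control_label)
    if len(controls) < 2:
        raise ValidationError(
            f"need >= 2 samples labelled {control_label!r}, got {len(controls)}"
        )
    sub = matrix.data[controls]
    order = _lex_order(matrix.feature_ids)
    feats = [matrix.feature_ids[i] for i in order]
    counts = _pair_counts(sub.to_numpy(dtype=float)[order])
    m = len(controls)
    frac = counts / m
    np.fill_diagonal(frac, -1.0)
    ii, jj = np.nonzero(frac >= stability_threshold - _EPS)
    return [
        (MiRPair(feats[i], feats[j]), float(frac[i, j])) for i, j in zip(ii, jj)
    ]


def fisher_reversal_p(n1: int, n2: int, m1: int, m2: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[n1, n2], [m1, m2]]."""
    for c in (n1, n2, m1, m2):
        if c < 0:
            raise ValidationError("negative contingency count")
    if n1 + n2 == 0 or m1 + m2 == 0:
        raise ValidationError("empty table margin")
    return float(_sps.fisher_exact([[n1, n2], [m1, m2]], alternative="two-sided")[1])


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone, capped at 1, returned in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def screen_candidates(
    matrix: ExpressionMatrix,
    control_label: str,
    case_label: str,
    stability_threshold: float = 0.95,
    fdr: float = 0.05,
    delta_p_threshold: float = 1.0,
) -> list[PairScreenResult]:
    """Full screen: stable pairs -> Fisher reversal tests -> BH -> dP filter.

    The BH family is exactly the stable-pair family (the set of tested
    hypotheses).  Kept pairs satisfy q < fdr and delta_p >= delta_p_threshold;
    results are sorted by (-delta_p, a, b).
    """
    controls = matrix.samples_with_label(control_label)
    cases = matrix.samples_with_label(case_label)
    if len(controls) < 2:
        raise ValidationError(f"need >= 2 control samples, got {len(controls)}")
    if len(cases) < 1:
        raise ValidationError(f"no samples labelled {case_label!r}")

    order = _lex_order(matrix.feature_ids)
    feats = [matrix.feature_ids[i] for i in order]
    vals = matrix.values[order]
    ctrl_cols = matrix.data.columns.get_indexer(controls)
    case_cols = matrix.data.columns.get_indexer(cases)

    n_ctrl, n_case = len(controls), len(cases)
    counts_ctrl = _pair_counts(vals[:, ctrl_cols])
    frac_ctrl = counts_ctrl / n_ctrl
    np.fill_diagonal(frac_ctrl, -1.0)
    stable_i, stable_j = np.nonzero(frac_ctrl >= stability_threshold - _EPS)
    if stable_i.size == 0:
        return []

    counts_case = _pair_counts(vals[:, case_cols])

    results: list[PairScreenResult] = []
    p_values = np.empty(stable_i.size, dtype=float)
    cache: dict[tuple[int, int], float] = {}
    for t, (i, j) in enumerate(zip(stable_i, stable_j)):
        n1 = int(counts_ctrl[i, j])
        m1 = int(counts_case[i, j])
        key = (n1, m1)
        if key not in cache:
            cache[key] = fisher_reversal_p(n1, n_ctrl - n1, m1, n_case - m1)
        p_values[t] = cache[key]
    q_values = bh_adjust(p_values)

    for t, (i, j) in enumerate(zip(stable_i, stable_j)):
        n1 = int(counts_ctrl[i, j])
        m1 = int(counts_case[i, j])
        p_control = n1 / n_ctrl
        p_case = m1 / n_case
        delta_p = p_control - p_case
        if q_values[t] < fdr and delta_p >= delta_p_threshold - _EPS:
            results.append(
                PairScreenResult(
                    pair=MiRPair(feats[i], feats[j]),
                    n1=n1, n2=n_ctrl - n1, m1=m1, m2=n_case - m1,
                    p_control=p_control, p_case=p_case, delta_p=delta_p,
                    p_value=float(p_values[t]), q_value=float(q_values[t]),
                )
            )
    results.sort(key=lambda r: (-r.delta_p, r.pair.a, r.pair.b))
    return results


def screen_to_frame(results: Sequence[PairScreenResult]) -> pd.DataFrame:
    """Tabular view of screen results (one row per pair)."""
    return pd.DataFrame(
        {
            "pair_a": [r.pair.a for r in results],
            "pair_b": [r.pair.b for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
            "m1": [r.m1 for r in results],
            "m2": [r.m2 for r in results],
            "p_control": [r.p_control for r in results],
            "p_case": [r.p_case for r in results],
            "delta_p": [r.delta_p for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
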