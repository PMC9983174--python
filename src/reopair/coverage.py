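"""Greedy maximum-sample-coverage combinations, activity scores and the
final top-k panel.

A candidate pair covers a training sample when the sample's REO matches the
*reference pattern* for its phenotype: E_a > E_b for a control sample, or
E_a <= E_b for a case sample.  For each candidate, a combination is grown
greedily from that seed, at each step adding the candidate that raises the
fraction of covered samples most (first-in-enumeration-order wins ties),
stopping when no addition strictly increases coverage.  A candidate's
activity score is the number of grown combinations that contain it.  The
final panel is the top-k candidates by activity score, where k is the
smallest panel size whose strict-majority vote attains the maximum
geometric mean of NPV and PPV on the training samples.

Everything here is deterministic: identical inputs yield identical
combinations, scores and k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import VotingModel, evaluate, predict_matrix
from .errors import ValidationError
from .matrix import ExpressionMatrix
from .screen import MiRPair


@dataclass
class CoverageCombination:
    """A greedily grown candidate set with its final sample coverage.

    ``members`` is ordered by addition (seed first); ``history`` records the
    coverage after each addition and is strictly increasing.
    """

    seed: MiRPair
    members: list[MiRPair]
    coverage: float
    history: list[float]


@dataclass
class ActivityRanking:
    """Candidates ranked by activity score (descending, stable ties)."""

    scores: dict[MiRPair, int]
    order: list[MiRPair]


def _cover_matrix(
    candidates: Sequence[MiRPair],
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    control_label: str,
    case_label: str,
) -> np.ndarray:
    """Boolean (n_candidates x n_samples): does pair p cover sample s."""
    samples = matrix.sample_ids
    unknown = [s for s in samples if labels.get(s) not in (control_label, case_label)]
    if unknown:
        raise ValidationError(
            f"samples without a control/case label: {unknown[:5]}"
        )
    idx = matrix.data.index
    row_a = idx.get_indexer([p.a for p in candidates])
    row_b = idx.get_indexer([p.b for p in candidates])
    if (row_a < 0).any() or (row_b < 0).any():
        bad = [
            p for p, ia, ib in zip(candidates, row_a, row_b) if ia < 0 or ib < 0
        ]
        raise ValidationError(f"candidate features not in matrix: {bad[:5]}")
    vals = matrix.values
    gt = vals[row_a, :] > vals[row_b, :]  # control pattern per pair x sample
    is_control = np.array([labels[s] == control_label for s in samples])
    return np.where(is_control[None, :], gt, ~gt)


def sample_covered(
    vector: Mapping[str, float],
    label: str,
    pair: MiRPair,
    control_label: str,
    case_label: str,
) -> bool:
    """Does one sample's REO match the reference pattern for its label."""
    try:
        va, vb = vector[pair.a], vector[pair.b]
    except KeyError as exc:
        raise ValidationError(f"sample missing feature {exc}") from exc
    if label == control_label:
        return bool(va > vb)
    if label == case_label:
        return bool(va <= vb)
    raise ValidationError(f"sample label {label!r} is neither control nor case")


def combination_coverage(
    members: Sequence[MiRPair],
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    control_label: str,
    case_label: str,
) -> float:
    """Fraction of all training samples covered by >= 1 member pair."""
    if len(members) == 0:
        raise ValidationError("empty member list")
    cover = _cover_matrix(members, matrix, labels, control_label, case_label)
    return float(cover.any(axis=0).mean())


def _greedy_grow(cover: np.ndarray, seed_idx: int) -> tuple[list[int], list[float]]:
    """Greedy growth on a precomputed cover matrix; returns member indices
    (seed first) and the coverage history."""
    n_cand, n_samp = cover.shape
    members = [seed_idx]
    covered = cover[seed_idx].copy()
    history = [covered.mean()]
    remaining = np.ones(n_cand, dtype=bool)
    remaining[seed_idx] = False
    while remaining.any():
        gains = (cover[:, ~covered]).sum(axis=1)
        gains[~remaining] = -1
        best = int(np.argmax(gains))  # first index wins ties
        if gains[best] <= 0:
            break
        members.append(best)
        covered |= cover[best]
        history.append(covered.mean())
        remaining[best] = False
        if covered.all():
            break
    return members, [float(h) for h in history]


def grow_combination(
    seed: MiRPair,
    candidates: Sequence[MiRPair],
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    control_label: str,
    case_label: str,
) -> CoverageCombination:
    """Grow the maximum-coverage combination seeded at one candidate."""
    candidates = [MiRPair(*c) for c in candidates]
    if seed not in candidates:
        raise ValidationError(f"seed {seed} is not a candidate")
    cover = _cover_matrix(candidates, matrix, labels, control_label, case_label)
    members_idx, history = _greedy_grow(cover, candidates.index(seed))
    return CoverageCombination(
        seed=seed,
        members=[candidates[i] for i in members_idx],
        coverage=history[-1],
        history=history,
    )


def activity_scores(
    candidates: Sequence[MiRPair],
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    control_label: str,
    case_label: str,
) -> ActivityRanking:
    """Grow one combination per candidate seed; score = membership count.

    Every candidate appears at least in its own combination, so scores lie
    in [1, n_candidates].  Ranking ties are broken by candidate enumeration
    order (stable sort).
    """
    candidates = [MiRPair(*c) for c in candidates]
    if len(candidates) == 0:
        raise ValidationError("no candidates")
    if len(set(candidates)) != len(candidates):
        raise ValidationError("duplicate candidates")
    cover = _cover_matrix(candidates, matrix, labels, control_label, case_label)
    counts = np.zeros(len(candidates), dtype=np.int64)
    for seed_idx in range(len(candidates)):
        members_idx, _ = _greedy_grow(cover, seed_idx)
        counts[members_idx] += 1
    order_idx = np.argsort(-counts, kind="stable")
    return ActivityRanking(
        scores={candidates[i]: int(counts[i]) for i in range(len(candidates))},
        order=[candidates[i] for i in order_idx],
    )


def select_top_k(
    ranking: ActivityRanking,
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    control_label: str,
    case_label: str,
) -> tuple[VotingModel, pd.DataFrame]:
    """Pick the smallest top-k panel attaining the best geometric mean.

    For every k = 1..n, a strict-majority voting model over the top-k
    candidates is evaluated on the training samples and sqrt(NPV * PPV)
    recorded (undefined PPV/NPV counts as 0).  Returns the model for the
    smallest k at the global maximum plus the full k-curve
    (k, ppv, npv, geometric_mean, acc).
    """
    if not ranking.order:
        raise ValidationError("empty ranking")
    labelled = ExpressionMatrix(matrix.data, dict(labels))

    rows = []
    for k in range(1, len(ranking.order) + 1):
        model = VotingModel.majority(
            ranking.order[:k], control_label, case_label
        )
        preds = predict_matrix(model, labelled)
        m = evaluate(preds, dict(labels), case_label)
        rows.append(
            {
                "k": k,
                "ppv": 0.0 if np.isnan(m.ppv) else m.ppv,
                "npv": 0.0 if np.isnan(m.npv) else m.npv,
                "geometric_mean": m.geometric_mean,
                "acc": m.acc,
            }
        )
    curve = pd.DataFrame(rows)
    best_k = int(curve.loc[curve["geometric_mean"].idxmax(), "k"])
    model = VotingModel.majority(
        ranking.order[:best_k],
        control_label,
        case_label,
        metadata={"selected_k": best_k, "selection": "first max of sqrt(npv*ppv)"},
    )
    return model, curve
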