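"""Single-sample majority-vote classification over a panel of miRNA pairs.

A :class:`VotingModel` is an ordered panel of feature pairs with a vote
threshold.  For each pair ``(a, b)`` the reference pattern under the
control phenotype is ``E_a > E_b``; a sample is called control iff the
number of pairs showing ``E_a > E_b`` strictly exceeds the threshold,
otherwise it is called case.  Ties in expression (``E_a == E_b``) count as
``E_a <= E_b``, i.e. toward the case pattern, everywhere in this package.

Because the vote depends only on within-sample orderings, predictions are
invariant under any strictly increasing per-sample transform of the
expression values (scaling, log, rank, batch shifts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .screen import MiRPair


@dataclass
class VotingModel:
    """Ordered pair panel + vote threshold + label semantics.

    ``vote_threshold`` is the count of control-pattern pairs that must be
    *strictly exceeded* to call a sample control.  The default used by the
    discovery pipeline is ``floor(n_pairs / 2)`` (strict majority); any
    value in ``[0, n_pairs)`` is allowed so that alternative published
    rules (e.g. "more than 3 of 5") can be expressed explicitly.
    """

    pairs: list[MiRPair]
    control_label: str
    case_label: str
    vote_threshold: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = [MiRPair(*p) for p in self.pairs]
        if not self.pairs:
            raise ValidationError("model has no pairs")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("model pairs must be distinct")
        if self.control_label == self.case_label:
            raise ValidationError("control and case labels must differ")
        if not 0 <= self.vote_threshold < len(self.pairs):
            raise ValidationError(
                f"vote_threshold {self.vote_threshold} outside "
                f"[0, {len(self.pairs)})"
            )

    @classmethod
    def majority(
        cls,
        pairs: list[MiRPair],
        control_label: str,
        case_label: str,
        metadata: dict | None = None,
    ) -> "VotingModel":
        """Build a strict-majority model: threshold = floor(n/2)."""
        return cls(
            pairs=list(pairs),
            control_label=control_label,
            case_label=case_label,
            vote_threshold=len(pairs) // 2,
            metadata=metadata or {},
        )

    @property
    def features(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.a)
            seen.setdefault(p.b)
        return list(seen)


def count_control_votes(model: VotingModel, vector: Mapping[str, float]) -> int:
    """Number of panel pairs showing the control pattern E_a > E_b."""
    votes = 0
    for pair in model.pairs:
        try:
            va, vb = vector[pair.a], vector[pair.b]
        except KeyError as exc:
            raise ValidationError(f"sample missing feature {exc}") from exc
        if va > vb:
            votes += 1
    return votes


def predict_sample(model: VotingModel, vector: Mapping[str, float]) -> str:
    """Classify one sample: control iff control votes > vote_threshold."""
    votes = count_control_votes(model, vector)
    return model.control_label if votes > model.vote_threshold else model.case_label


def predict_matrix(model: VotingModel, matrix: ExpressionMatrix) -> dict[str, str]:
    """Vectorised prediction for every sample in the matrix."""
    missing = set(model.features) - set(matrix.feature_ids)
    if missing:
        raise ValidationError(f"matrix missing model features: {sorted(missing)}")
    row = matrix.data.index.get_indexer([p.a for p in model.pairs])
    col = matrix.data.index.get_indexer([p.b for p in model.pairs])
    vals = matrix.values
    votes = (vals[row, :] > vals[col, :]).sum(axis=0)
    return {
        s: (model.control_label if v > model.vote_threshold else model.case_label)
        for s, v in zip(matrix.sample_ids, votes)
    }


def vote_counts(model: VotingModel, matrix: ExpressionMatrix) -> dict[str, int]:
    """Per-sample count of control-pattern pairs (for reporting)."""
    missing = set(model.features) - set(matrix.feature_ids)
    if missing:
        raise ValidationError(f"matrix missing model features: {sorted(missing)}")
    row = matrix.data.index.get_indexer([p.a for p in model.pairs])
    col = matrix.data.index.get_indexer([p.b for p in model.pairs])
    vals = matrix.values
    votes = (vals[row, :] > vals[col, :]).sum(axis=0)
    return dict(zip(matrix.sample_ids, (int(v) for v in votes)))


@dataclass
class PredictionMetrics:
    """Confusion counts and derived rates; the case phenotype is positive.

    Undefined ratios (zero denominator) are stored as NaN; the geometric
    mean of NPV and PPV treats an undefined component as 0, which is the
    conservative convention used for panel-size selection.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sen: float
    spe: float
    acc: float
    ppv: float
    npv: float
    geometric_mean: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sen": self.sen, "spe": self.spe, "acc": self.acc,
            "ppv": self.ppv, "npv": self.npv,
            "geometric_mean": self.geometric_mean,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> PredictionMetrics:
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    gm = math.sqrt(
        (0.0 if math.isnan(ppv) else ppv) * (0.0 if math.isnan(npv) else npv)
    )
    return PredictionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sen=_ratio(tp, tp + fn),
        spe=_ratio(tn, tn + fp),
        acc=_ratio(tp + tn, tp + tn + fp + fn),
        ppv=ppv, npv=npv, geometric_mean=gm,
    )


def evaluate(
    predictions: Mapping[str, str],
    truth: Mapping[str, str],
    case_label: str,
) -> PredictionMetrics:
    """SEN/SPE/ACC/PPV/NPV of predictions against true labels.

    Both mappings must cover the same sample ids; the case phenotype is
    the positive class.
    """
    if set(predictions) != set(truth):
        raise ValidationError("predictions and truth cover different samples")
    tp = fp = tn = fn = 0
    for s, pred in predictions.items():
        actual_pos = truth[s] == case_label
        predicted_pos = pred == case_label
        if predicted_pos and actual_pos:
            tp += 1
        elif predicted_pos and not actual_pos:
            fp += 1
        elif not predicted_pos and actual_pos:
            fn += 1
        else:
            tn += 1
    return metrics_from_confusion(tp, fp, tn, fn)
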