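"""Synthetic expression cohorts with planted REO structure.

The generator emulates the statistical situation the screening pipeline
assumes: a control phenotype carrying a set of planted ordered pairs whose
direction E_a > E_b holds in a target fraction of control samples, a case
phenotype in which a subset of those pairs is reversed by a target dP, and
nuisance structure that must not fool a rank-based method — per-sample
monotone distortions (scaling, log, additive batch shifts) that leave every
within-sample ordering intact, plus additive noise that occasionally flips
orderings.

Feature levels are log-normal: each feature has a baseline log2 level, each
observation adds independent Gaussian noise in log space, and intensities
are 2**x.  For a planted pair the log-level separation delta is chosen so
that P(E_a > E_b) hits the target hold fraction given the noise scale:
the log difference is N(delta, 2*sigma^2), so delta =
sqrt(2)*sigma*Phi^-1(hold).  Reversed pairs use the analogous separation in
the case group targeting p_case = hold - dP.  With zero noise the planted
fractions are exact (1 and 0).

Defaults mirror a modest serum-profiling study arm: 200 features, 50
control and 50 case samples, 20 planted stable pairs of which 10 reverse
completely (dP = 1), hold fraction 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .screen import MiRPair

_DISTORTIONS = ("none", "per_sample_scale", "log", "batch_shift")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort."""

    n_features: int = 200
    n_control: int = 50
    n_case: int = 50
    n_stable_pairs: int = 20
    stable_hold_fraction: float = 0.95
    n_reversed_pairs: int = 10
    target_delta_p: float = 1.0
    noise_sd: float = 0.3  # log2-space SD of observation noise
    distortion: str = "none"
    outlier_samples: int = 0
    seed: int = 0
    control_label: str = "control"
    case_label: str = "case"

    def validate(self) -> None:
        if self.n_reversed_pairs > self.n_stable_pairs:
            raise ValidationError("more reversed than stable pairs")
        if not 0.5 < self.stable_hold_fraction <= 1.0:
            raise ValidationError("stable_hold_fraction must be in (0.5, 1]")
        if not 0.0 < self.target_delta_p <= 1.0:
            raise ValidationError("target_delta_p must be in (0, 1]")
        if 2 * self.n_stable_pairs > self.n_features:
            raise ValidationError(
                "planted pairs need 2 features each; increase n_features"
            )
        if self.n_stable_pairs > 300:
            raise ValidationError(
                "at most 300 planted pairs (level tiers stay in float range)"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.distortion not in _DISTORTIONS:
            raise ValidationError(f"unknown distortion: {self.distortion!r}")
        if min(self.n_control, self.n_case) < 1:
            raise ValidationError("need at least one sample per phenotype")


@dataclass
class GroundTruth:
    """What was planted, and what was actually realised after noise."""

    stable_pairs: list[MiRPair] = field(default_factory=list)
    reversed_pairs: list[MiRPair] = field(default_factory=list)
    realized_p_control: dict[MiRPair, float] = field(default_factory=dict)
    realized_p_case: dict[MiRPair, float] = field(default_factory=dict)
    outlier_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stable_pairs": [list(p) for p in self.stable_pairs],
            "reversed_pairs": [list(p) for p in self.reversed_pairs],
            "realized_p_control": {
                f"{p.a}|{p.b}": v for p, v in self.realized_p_control.items()
            },
            "realized_p_case": {
                f"{p.a}|{p.b}": v for p, v in self.realized_p_case.items()
            },
            "outlier_ids": list(self.outlier_ids),
        }


def _separation(target_fraction: float, noise_sd: float) -> float:
    """Log2-level gap giving P(x_a > x_b) = target under N(0, sd) noise."""
    if noise_sd == 0.0:
        return 1.0 if target_fraction > 0.5 else -1.0
    z = norm.ppf(np.clip(target_fraction, 1e-9, 1 - 1e-9))
    return float(np.sqrt(2.0) * noise_sd * z)


def _apply_distortion(
    values: np.ndarray, distortion: str, rng: np.random.Generator
) -> np.ndarray:
    """Strictly increasing per-sample transform; REO-neutral by design."""
    if distortion == "none":
        return values
    if distortion == "per_sample_scale":
        scales = rng.uniform(0.25, 4.0, size=values.shape[1])
        return values * scales[None, :]
    if distortion == "log":
        return np.log1p(values)
    if distortion == "batch_shift":
        n_half = values.shape[1] // 2
        shift = np.zeros(values.shape[1])
        shift[n_half:] = rng.uniform(10.0, 100.0)
        return values + shift[None, :]
    raise ValidationError(f"unknown distortion: {distortion!r}")


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a labelled cohort plus ground truth, reproducibly from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat, n_ctrl, n_case = config.n_features, config.n_control, config.n_case

    width = len(str(n_feat))
    feats = [f"miR-{i:0{width}d}" for i in range(n_feat)]
    sample_ids = [f"ctrl_{i:03d}" for i in range(n_ctrl)] + [
        f"case_{i:03d}" for i in range(n_case)
    ]
    labels = {s: config.control_label for s in sample_ids[:n_ctrl]}
    labels.update({s: config.case_label for s in sample_ids[n_ctrl:]})

    # baseline log2 levels, shared between phenotypes for unplanted features
    mu = rng.normal(loc=8.0, scale=1.5, size=n_feat)
    mu_control = mu.copy()
    mu_case = mu.copy()

    delta_stable = _separation(config.stable_hold_fraction, config.noise_sd)
    p_case_target = config.stable_hold_fraction - config.target_delta_p
    delta_reversed = _separation(max(p_case_target, 0.0), config.noise_sd)

    # Planted pairs live on well-separated level tiers above the null
    # features (null mu <= ~14 at 4 SD).  The tier spacing (3 log2 units)
    # dwarfs both the within-pair separations and the noise scale, so a
    # reversal planted inside one pair cannot drag a planted feature across
    # any other feature's level: the reversed set is exactly the planted
    # one, and cross-pair orderings are essentially never disturbed.
    truth = GroundTruth()
    for k in range(config.n_stable_pairs):
        ia, ib = 2 * k, 2 * k + 1
        pair = MiRPair(feats[ia], feats[ib])
        base = 16.0 + 3.0 * k
        mu_control[ia] = base + delta_stable / 2
        mu_control[ib] = base - delta_stable / 2
        if k < config.n_reversed_pairs:
            mu_case[ia] = base + delta_reversed / 2
            mu_case[ib] = base - delta_reversed / 2
            truth.reversed_pairs.append(pair)
        else:
            mu_case[ia] = mu_control[ia]
            mu_case[ib] = mu_control[ib]
        truth.stable_pairs.append(pair)

    log_expr = np.empty((n_feat, n_ctrl + n_case))
    log_expr[:, :n_ctrl] = mu_control[:, None]
    log_expr[:, n_ctrl:] = mu_case[:, None]
    if config.noise_sd > 0:
        log_expr += rng.normal(scale=config.noise_sd, size=log_expr.shape)
    values = np.exp2(log_expr)

    # realised fractions are recorded before distortion; the distortion is
    # monotone per sample, so they are unchanged by it
    for pair in truth.stable_pairs:
        ia, ib = feats.index(pair.a), feats.index(pair.b)
        gt = values[ia] > values[ib]
        truth.realized_p_control[pair] = float(gt[:n_ctrl].mean())
        truth.realized_p_case[pair] = float(gt[n_ctrl:].mean())

    values = _apply_distortion(values, config.distortion, rng)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=feats, columns=sample_ids), labels
    )

    if config.outlier_samples > 0:
        matrix, injected = inject_outliers(
            matrix,
            config.control_label,
            config.outlier_samples,
            seed=config.seed + 1,
        )
        truth.outlier_ids = injected
    return matrix, truth


def inject_outliers(
    matrix: ExpressionMatrix,
    phenotype: str,
    count: int,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Append rank-reversed copies of the phenotype mean profile.

    Each injected sample takes the mean profile of the phenotype's samples
    and reassigns its values so feature ranks are exactly reversed (the
    highest-expressed feature receives the lowest value), with a small
    multiplicative jitter to avoid exact ties.  The result is strongly
    anti-correlated with every genuine sample, the situation the
    correlation-based QC rule is designed to catch.
    """
    if count == 0:
        return matrix, []
    members = matrix.samples_with_label(phenotype)
    if not members:
        raise ValidationError(f"no samples labelled {phenotype!r}")
    rng = np.random.default_rng(seed)
    mean_profile = matrix.data[members].to_numpy(dtype=float).mean(axis=1)
    ranks = rankdata(mean_profile, method="ordinal").astype(int)  # 1..n
    reversed_values = np.sort(mean_profile)[::-1][ranks - 1]

    data = matrix.data.copy()
    injected: list[str] = []
    labels = dict(matrix.labels)
    for i in range(count):
        sid = f"{phenotype}_outlier_{i:02d}"
        jitter = rng.uniform(0.99, 1.01, size=reversed_values.shape)
        data[sid] = reversed_values * jitter
        labels[sid] = phenotype
        injected.append(sid)
    return ExpressionMatrix(data, labels), injected
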