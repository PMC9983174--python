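import numpy as np
import pandas as pd
import pytest

from reopair import ExpressionMatrix, MiRPair


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 features x 4 samples with a strict ordering f1 > f2 > f3 everywhere."""
    data = pd.DataFrame(
        {
            "s1": [30.0, 20.0, 10.0],
            "s2": [31.0, 21.0, 11.0],
            "s3": [29.0, 19.0, 9.0],
            "s4": [33.0, 23.0, 13.0],
        },
        index=["f1", "f2", "f3"],
    )
    labels = {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    return ExpressionMatrix(data, labels)


def random_matrix(
    n_features: int,
    n_samples: int,
    seed: int,
    labels: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Tie-free random expression matrix (continuous uniforms)."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.uniform(1.0, 1000.0, size=(n_features, n_samples)),
        index=[f"f{i:03d}" for i in range(n_features)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data, labels or {})


def brute_force_stable_pairs(
    matrix: ExpressionMatrix, control_label: str, threshold: float
) -> set[MiRPair]:
    """Independent recount: iterate every ordered pair and every sample."""
    controls = matrix.samples_with_label(control_label)
    stable = set()
    for a in matrix.feature_ids:
        for b in matrix.feature_ids:
            if a == b:
                continue
            k = sum(
                1
                for s in controls
                if matrix.data.at[a, s] > matrix.data.at[b, s]
            )
            if k / len(controls) >= threshold - 1e-12:
                stable.add(MiRPair(a, b))
    return stable


def brute_force_coverage(
    members,
    matrix: ExpressionMatrix,
    labels: dict[str, str],
    control_label: str,
    case_label: str,
) -> float:
    """Independent recount of combination sample coverage."""
    covered = 0
    for s in matrix.sample_ids:
        vec = matrix.data[s]
        hit = False
        for p in members:
            if labels[s] == control_label:
                hit = vec[p.a] > vec[p.b]
            else:
                hit = vec[p.a] <= vec[p.b]
            if hit:
                break
        covered += bool(hit)
    return covered / matrix.n_samples
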