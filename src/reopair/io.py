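"""Reading and writing expression tables, label tables and model files.

Expression tables are plain TSV: a header row, a leading identifier column,
then one column per sample (or one per feature with
``orientation="samples_in_rows"``).  GEO series-matrix exports are accepted
transparently: lines starting with ``!`` are skipped.  Labels are two-column
TSV (sample id, phenotype), no header required.  Voting models round-trip
through a small versioned JSON schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .classify import VotingModel
from .errors import ValidationError
from .matrix import ExpressionMatrix
from .screen import MiRPair

MODEL_SCHEMA_VERSION = 1


def _check_header_unique(path: Path) -> None:
    # pandas silently renames duplicate header fields, so check them here
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")[1:]
            dups = {f for f in fields if fields.count(f) > 1}
            if dups:
                raise ValidationError(
                    f"duplicate column ids in {path}: {sorted(dups)[:5]}"
                )
            return
    raise ValidationError(f"empty expression table: {path}")


def read_expression_table(
    path: str | Path,
    orientation: str = "features_in_rows",
    labels: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into a validated matrix.

    Duplicate identifiers, non-numeric cells and missing values are errors;
    the method has no imputation rule and requires complete matrices.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    _check_header_unique(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            comment="!",
            na_values=["NA", "NaN", "nan", ""],
            keep_default_na=True,
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty expression table: {path}") from exc
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed expression table {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty expression table: {path}")
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric) > 0:
        raise ValidationError(
            f"non-numeric values in columns: {list(non_numeric[:5])}"
        )
    if df.isna().any().any():
        raise ValidationError(f"missing value in expression table: {path}")
    return ExpressionMatrix(df.astype(float), labels or {})


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV, features in rows."""
    matrix.data.to_csv(Path(path), sep="\t", index_label="feature_id")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample->phenotype table; duplicates are errors.

    A header row is optional; a first line whose two fields literally read
    ``sample_id``/``phenotype`` is skipped.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{line_no}: expected 2 tab-separated columns"
                )
            sample, phenotype = fields[0].strip(), fields[1].strip()
            if line_no == 1 and sample.lower() in ("sample_id", "sample"):
                continue
            if sample in labels:
                raise ValidationError(f"duplicate sample id in labels: {sample}")
            labels[sample] = phenotype
    if not labels:
        raise ValidationError(f"empty label table: {path}")
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for sample, phenotype in labels.items():
            fh.write(f"{sample}\t{phenotype}\n")


def save_model(model: VotingModel, path: str | Path) -> None:
    """Serialise a voting model to the versioned JSON schema."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "control_label": model.control_label,
        "case_label": model.case_label,
        "pairs": [{"a": p.a, "b": p.b} for p in model.pairs],
        "vote_threshold": model.vote_threshold,
        "metadata": model.metadata,
    }
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path: str | Path) -> VotingModel:
    """Load and validate a voting model saved by :func:`save_model`."""
    with open(Path(path), encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"not valid JSON: {path}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported model schema version: {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    required = {"control_label", "case_label", "pairs", "vote_threshold"}
    missing = required - set(payload)
    if missing:
        raise ValidationError(f"model file missing fields: {sorted(missing)}")
    try:
        pairs = [MiRPair(str(p["a"]), str(p["b"])) for p in payload["pairs"]]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed pair entry in {path}") from exc
    return VotingModel(
        pairs=pairs,
        control_label=str(payload["control_label"]),
        case_label=str(payload["case_label"]),
        vote_threshold=int(payload["vote_threshold"]),
        metadata=payload.get("metadata", {}),
    )
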