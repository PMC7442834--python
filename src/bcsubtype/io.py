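"""Readers and writers for every on-disk artifact.

Canonical dialect: UTF-8, tab-separated, one header row, first column is the
identifier, no quoting.  Lines starting with ``#`` are provenance comments
and are skipped on read.  Loading never mutates numeric values (no implicit
normalization or log transform); numeric round-trips are bit-exact because
floats are written with Python's shortest-repr formatting.

Fitted logistic-regression models are serialized to a versioned JSON schema
(see :data:`MODEL_SCHEMA_VERSION`); ``load_model(save_model(m))`` reproduces
every field exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    UNCLASSIFIABLE,
    CentroidTable,
    CohortAnnotations,
    ERStatus,
    ExpressionMatrix,
    ReferenceProfile,
    SubtypeCall,
)
from .errors import FormatError, SchemaVersionError, ValidationError

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# low-level table handling
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, *, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=index_col, comment="#", dtype=str)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0 and index_col is not None:
        raise FormatError(f"{path}: expected at least one data column after the identifier column")
    return df

def _to_numeric(df: pd.DataFrame, path: str | Path, *, row_kind: str, col_kind: str) -> pd.DataFrame:
    """Convert a str-typed table to float64, reporting the first bad cell."""
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raw = df.iat[r, c]
        what = "missing value" if (raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "") else f"non-numeric cell {raw!r}"
        raise FormatError(
            f"{path}: {what} at {row_kind} {df.index[r]!r}, {col_kind} {df.columns[c]!r}"
        )
    return numeric

def _check_no_duplicates(names: Iterable[str], kind: str, path: str | Path) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise FormatError(f"{path}: duplicate {kind} identifier {n!r}")
        seen.add(n)

def _write_tsv(df: pd.DataFrame, path: str | Path, *, index_label: str,
               provenance: Sequence[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# expression / centroid / reference tables
# ---------------------------------------------------------------------------

def load_expression(path: str | Path, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Load a log2-scale expression TSV into canonical genes x samples form.

    ``orientation="samples_by_genes"`` transposes the table on load.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    _check_no_duplicates((str(i) for i in df.index), "row", path)
    _check_no_duplicates((str(c) for c in df.columns), "column", path)
    numeric = _to_numeric(
        df, path,
        row_kind="gene" if orientation == "genes_by_samples" else "sample",
        col_kind="sample" if orientation == "genes_by_samples" else "gene",
    )
    if orientation == "samples_by_genes":
        numeric = numeric.T
    try:
        return ExpressionMatrix(numeric)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_expression(expr: ExpressionMatrix, path: str | Path,
                    provenance: Sequence[str] | None = None) -> None:
    _write_tsv(expr.values, path, index_label="gene", provenance=provenance)


def load_centroids(path: str | Path) -> CentroidTable:
    """Load a centroid table TSV (genes in rows, classes in columns).

    The class order of the file is preserved.
    """
    df = _read_tsv(path)
    _check_no_duplicates((str(i) for i in df.index), "gene", path)
    _check_no_duplicates((str(c) for c in df.columns), "class", path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: a centroid table needs >=2 classes, found {df.shape[1]}")
    numeric = _to_numeric(df, path, row_kind="gene", col_kind="class")
    try:
        return CentroidTable(numeric)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_centroids(centroids: CentroidTable, path: str | Path,
                   provenance: Sequence[str] | None = None) -> None:
    _write_tsv(centroids.values, path, index_label="gene", provenance=provenance)


def load_reference(path: str | Path) -> ReferenceProfile:
    """Load a two-column (gene, value) reference profile TSV."""
    df = _read_tsv(path)
    if df.shape[1] != 1:
        raise FormatError(f"{path}: a reference profile has exactly one value column, found {df.shape[1]}")
    _check_no_duplicates((str(i) for i in df.index), "gene", path)
    numeric = _to_numeric(df, path, row_kind="gene", col_kind="column")
    try:
        return ReferenceProfile(numeric.iloc[:, 0])
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_reference(ref: ReferenceProfile, path: str | Path,
                   provenance: Sequence[str] | None = None) -> None:
    df = ref.values.to_frame(name="value")
    _write_tsv(df, path, index_label="gene", provenance=provenance)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path,
                     class_vocabulary: Sequence[str] | None = None) -> list[CohortAnnotations]:
    """Load per-sample annotations (ER status, subtype label, tumor size).

    Only ``sample_id`` is required; missing optional columns become
    UNKNOWN/absent.  When ``class_vocabulary`` is given, every non-empty
    ``subtype_label`` must belong to it.
    """
    df = _read_tsv(path, index_col=None)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: annotation table must have a 'sample_id' column")
    _check_no_duplicates(df["sample_id"].astype(str), "sample", path)
    vocab = set(class_vocabulary) if class_vocabulary is not None else None
    out: list[CohortAnnotations] = []
    for _, row in df.iterrows():
        sample_id = str(row["sample_id"])
        er = ERStatus.UNKNOWN
        if "er_status" in df.columns and isinstance(row["er_status"], str) and row["er_status"].strip():
            token = row["er_status"].strip().upper()
            try:
                er = ERStatus(token)
            except ValueError as exc:
                raise FormatError(f"{path}: invalid er_status {row['er_status']!r} for {sample_id!r}") from exc
        label: str | None = None
        if "subtype_label" in df.columns and isinstance(row["subtype_label"], str) and row["subtype_label"].strip():
            label = row["subtype_label"].strip()
            if vocab is not None and label not in vocab:
                raise ValidationError(
                    f"{path}: subtype_label {label!r} for {sample_id!r} not in class vocabulary {sorted(vocab)}"
                )
        size: float | None = None
        if "tumor_size" in df.columns and isinstance(row["tumor_size"], str) and row["tumor_size"].strip():
            try:
                size = float(row["tumor_size"])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric tumor_size {row['tumor_size']!r} for {sample_id!r}") from exc
        out.append(CohortAnnotations(sample_id=sample_id, er_status=er, subtype_label=label, tumor_size=size))
    return out


def save_annotations(annotations: Sequence[CohortAnnotations], path: str | Path,
                     provenance: Sequence[str] | None = None) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "er_status": a.er_status.value,
            "subtype_label": a.subtype_label if a.subtype_label is not None else "",
            "tumor_size": repr(a.tumor_size) if a.tumor_size is not None else "",
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# subtype calls
# ---------------------------------------------------------------------------

def save_calls(calls: Sequence[SubtypeCall], path: str | Path,
               provenance: Sequence[str] | None = None) -> None:
    """Write calls as TSV: sample_id, call, then one score column per class."""
    classes: list[str] = []
    for c in calls:
        for k in c.correlations:
            if k not in classes:
                classes.append(k)
    rows = []
    for c in calls:
        row: dict[str, object] = {"sample_id": c.sample_id, "call": c.call}
        for k in classes:
            v = c.correlations.get(k)
            row[k] = repr(float(v)) if v is not None else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=["sample_id", "call", *classes])
    with open(Path(path), "w", encoding="utf-8") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_calls(path: str | Path) -> list[SubtypeCall]:
    df = _read_tsv(path, index_col=None)
    for col in ("sample_id", "call"):
        if col not in df.columns:
            raise FormatError(f"{path}: calls table must have a {col!r} column")
    _check_no_duplicates(df["sample_id"].astype(str), "sample", path)
    score_cols = [c for c in df.columns if c not in ("sample_id", "call")]
    out: list[SubtypeCall] = []
    for _, row in df.iterrows():
        scores: dict[str, float] = {}
        for col in score_cols:
            raw = row[col]
            if isinstance(raw, str) and raw.strip():
                try:
                    scores[col] = float(raw)
                except ValueError as exc:
                    raise FormatError(f"{path}: non-numeric score {raw!r} in column {col!r}") from exc
        out.append(SubtypeCall(sample_id=str(row["sample_id"]), call=str(row["call"]),
                               correlations=scores))
    return out


# ---------------------------------------------------------------------------
# gene signatures
# ---------------------------------------------------------------------------

def save_signature(signature, path: str | Path) -> None:
    """One gene per line, provenance in a leading '# provenance:' comment."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(f"# signature: {signature.name}\n")
        fh.write(f"# provenance: {json.dumps(signature.provenance, sort_keys=True)}\n")
        for gene in signature.genes:
            fh.write(f"{gene}\n")


def load_signature(path: str | Path):
    from .features import GeneSignature  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    name = path.stem
    provenance: dict = {}
    genes: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# signature:"):
            name = line.split(":", 1)[1].strip()
        elif line.startswith("# provenance:"):
            provenance = json.loads(line.split(":", 1)[1].strip())
        elif not line.startswith("#"):
            genes.append(line.upper())
    if not genes:
        raise FormatError(f"{path}: empty gene signature")
    return GeneSignature(name=name, genes=tuple(genes), provenance=provenance)


# ---------------------------------------------------------------------------
# mLR model serialization
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize an MLRModel to versioned JSON (bit-exact float round-trip)."""
    payload = {
        "schema": "bcsubtype-mlr",
        "schema_version": MODEL_SCHEMA_VERSION,
        "classes": list(model.classes),
        "feature_genes": list(model.feature_genes),
        "weights": [[float(v) for v in row] for row in model.weights],
        "intercepts": [float(v) for v in model.intercepts],
        "standardization": {
            "mean": [float(v) for v in model.standardization[0]],
            "sd": [float(v) for v in model.standardization[1]],
        },
        "hyperparams": {"l1": float(model.hyperparams[0]), "l2": float(model.hyperparams[1])},
        "fit_metadata": model.fit_metadata,
    }
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path):
    from .mlr import MLRModel  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: truncated or malformed model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != "bcsubtype-mlr":
        raise FormatError(f"{path}: not a bcsubtype mLR model file")
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r} unsupported (expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        return MLRModel(
            classes=tuple(payload["classes"]),
            feature_genes=tuple(payload["feature_genes"]),
            weights=np.asarray(payload["weights"], dtype=np.float64),
            intercepts=np.asarray(payload["intercepts"], dtype=np.float64),
            standardization=(
                np.asarray(payload["standardization"]["mean"], dtype=np.float64),
                np.asarray(payload["standardization"]["sd"], dtype=np.float64),
            ),
            hyperparams=(float(payload["hyperparams"]["l1"]), float(payload["hyperparams"]["l2"])),
            fit_metadata=payload.get("fit_metadata", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model payload: {exc}") from exc
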