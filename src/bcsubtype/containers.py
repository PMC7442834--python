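"""Core in-memory containers.

Expression matrices and centroid tables are thin, validated wrappers around
pandas DataFrames in a fixed canonical orientation (genes in rows).  Gene
symbols are stored upper-cased and matching between containers is always by
exact upper-cased symbol.  All numeric payloads are finite float64; missing
values are rejected rather than imputed, because Log2ratio centering and rank
correlation are undefined on missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sentinel call for samples that cannot be assigned a class (e.g. a profile
#: that is constant after centering, for which Spearman is undefined).
UNCLASSIFIABLE = "UNCLASSIFIABLE"


class ERStatus(str, Enum):
    """Estrogen-receptor status of a tumour sample."""

    POS = "POS"
    NEG = "NEG"
    UNKNOWN = "UNKNOWN"


def _find_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def _validated_frame(df: pd.DataFrame, *, row_kind: str, col_kind: str) -> pd.DataFrame:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty table: {df.shape[0]} {row_kind}(s) x {df.shape[1]} {col_kind}(s)")
    dup = _find_duplicate(str(i) for i in df.index)
    if dup is not None:
        raise ValidationError(f"duplicate {row_kind} identifier: {dup!r}")
    dup = _find_duplicate(str(c) for c in df.columns)
    if dup is not None:
        raise ValidationError(f"duplicate {col_kind} identifier: {dup!r}")
    try:
        values = df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric value in table: {exc}") from exc
    bad = ~np.isfinite(values.to_numpy())
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite value at {row_kind} {values.index[r]!r}, {col_kind} {values.columns[c]!r}"
        )
    values.index = [str(i) for i in values.index]
    values.columns = [str(c) for c in values.columns]
    return values


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples.

    Gene symbols (rows) are unique and upper-cased; sample identifiers
    (columns) are unique; every value is finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        values = _validated_frame(self.values, row_kind="gene", col_kind="sample")
        values.index = [g.upper() for g in values.index]
        dup = _find_duplicate(values.index)
        if dup is not None:
            raise ValidationError(f"duplicate gene identifier after upper-casing: {dup!r}")
        object.__setattr__(self, "values", values)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[list(samples)])


@dataclass(frozen=True)
class CentroidTable:
    """Class prototype profiles, genes x classes (log2ratio scale)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        values = _validated_frame(self.values, row_kind="gene", col_kind="class")
        values.index = [g.upper() for g in values.index]
        dup = _find_duplicate(values.index)
        if dup is not None:
            raise ValidationError(f"duplicate gene identifier after upper-casing: {dup!r}")
        if values.shape[1] < 2:
            raise ValidationError(f"centroid table needs >=2 classes, got {values.shape[1]}")
        object.__setattr__(self, "values", values)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def classes(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ReferenceProfile:
    """One log2-scale value per gene; the subtraction target for centering."""

    values: pd.Series

    def __post_init__(self) -> None:
        series = self.values
        if len(series) == 0:
            raise ValidationError("empty reference profile")
        try:
            series = series.astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric reference value: {exc}") from exc
        series.index = [str(g).upper() for g in series.index]
        dup = _find_duplicate(series.index)
        if dup is not None:
            raise ValidationError(f"duplicate gene in reference: {dup!r}")
        if not np.isfinite(series.to_numpy()).all():
            bad = series.index[~np.isfinite(series.to_numpy())][0]
            raise ValidationError(f"non-finite reference value for gene {bad!r}")
        object.__setattr__(self, "values", series)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class CohortAnnotations:
    """Per-sample clinical annotation used by reference building and ROR."""

    sample_id: str
    er_status: ERStatus = ERStatus.UNKNOWN
    subtype_label: str | None = None
    tumor_size: float | None = None

    def __post_init__(self) -> None:
        if self.tumor_size is not None and (
            not np.isfinite(self.tumor_size) or self.tumor_size < 0
        ):
            raise ValidationError(
                f"tumor_size for {self.sample_id!r} must be finite and >= 0, got {self.tumor_size}"
            )


@dataclass(frozen=True)
class SubtypeCall:
    """A per-sample class assignment with its per-class score vector.

    ``correlations`` holds the per-class similarity used for the call:
    rank/linear correlations for nearest-centroid classification
    (``score_type == "correlation"``) or softmax membership probabilities
    for the logistic-regression caller (``score_type == "membership"``).
    """

    sample_id: str
    call: str
    correlations: Mapping[str, float] = field(default_factory=dict)
    score_type: str = "correlation"
    reason: str | None = None

    @property
    def is_unclassifiable(self) -> bool:
        return self.call == UNCLASSIFIABLE


def calls_to_series(calls: "Sequence[SubtypeCall] | Mapping[str, str] | pd.Series") -> pd.Series:
    """Normalize calls/labels to a Series sample_id -> class name."""
    if isinstance(calls, pd.Series):
        return calls.astype(str)
    if isinstance(calls, Mapping):
        return pd.Series({str(k): str(v) for k, v in calls.items()})
    return pd.Series({c.sample_id: c.call for c in calls})


def annotations_by_sample(annotations: Sequence[CohortAnnotations]) -> dict[str, CohortAnnotations]:
    out: dict[str, CohortAnnotations] = {}
    for ann in annotations:
        if ann.sample_id in out:
            raise ValidationError(f"duplicate sample_id in annotations: {ann.sample_id!r}")
        out[ann.sample_id] = ann
    return out
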