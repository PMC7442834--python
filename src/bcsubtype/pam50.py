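"""Log2ratio centering and nearest-centroid subtype calling.

The classification contract is strictly single-sample: centering subtracts a
fixed reference profile and each sample's correlation with each class
centroid depends on that sample alone, so calls are invariant to cohort
composition.  Spearman rank correlation (average ranks for ties) is the
default similarity metric; a Pearson variant with class exclusion supports
nearest-shrunken-centroid-style callers that drop the Normal-like class.

Ties between classes are broken by canonical class order: alphabetical on
class names, fixed and documented.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    UNCLASSIFIABLE,
    CentroidTable,
    ExpressionMatrix,
    ReferenceProfile,
    SubtypeCall,
)
from .errors import UndefinedCorrelationError, ValidationError

#: Default minimum fraction of centroid genes that must survive the
#: matrix/reference/centroid intersection before classification proceeds.
DEFAULT_MIN_GENE_OVERLAP = 0.8


def center_against_reference(expr: ExpressionMatrix, ref: ReferenceProfile,
                             *, min_overlap: float = 0.0) -> ExpressionMatrix:
    """Subtract the reference from each sample (Log2ratio on log2 data).

    The output is restricted to the gene intersection of ``expr`` and
    ``ref`` (in ``expr`` order).  ``min_overlap`` is the minimum fraction of
    reference genes that must be present in ``expr``.
    """
    ref_genes = set(ref.genes)
    common = [g for g in expr.genes if g in ref_genes]
    if not common:
        raise ValidationError("empty gene intersection between expression matrix and reference")
    overlap = len(common) / len(ref.genes)
    if overlap < min_overlap:
        missing = [g for g in ref.genes if g not in set(expr.genes)]
        raise ValidationError(
            f"only {overlap:.1%} of reference genes present (< {min_overlap:.1%}); "
            f"missing e.g. {missing[:10]}"
        )
    sub = expr.values.loc[common]
    centered = sub.sub(ref.values.loc[common], axis=0)
    return ExpressionMatrix(centered)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises :class:`UndefinedCorrelationError` on a constant vector; callers
    in the classification path map that to an UNCLASSIFIABLE call.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise ValidationError("spearman_rho needs two equal-length 1-D vectors")
    if len(xa) < 3:
        raise ValidationError(f"spearman_rho needs length >= 3, got {len(xa)}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rx -= rx.mean()
    ry -= ry.mean()
    # sqrt of the product (not product of sqrts) keeps rho(x, x) exactly 1
    rho = float(rx @ ry) / np.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(np.clip(rho, -1.0, 1.0))


def _column_ranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=0)


def _correlation_matrix(profiles: np.ndarray, centroids: np.ndarray,
                        metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Correlations between every sample column and every centroid column.

    Returns (classes x samples correlation matrix, boolean mask of samples
    with zero variance, for which the correlation is undefined).
    """
    if metric == "spearman":
        profiles = _column_ranks(profiles)
        centroids = _column_ranks(centroids)
    elif metric != "pearson":
        raise ValidationError(f"unknown metric {metric!r}")
    p = profiles - profiles.mean(axis=0, keepdims=True)
    c = centroids - centroids.mean(axis=0, keepdims=True)
    p_sq = (p ** 2).sum(axis=0)
    c_sq = (c ** 2).sum(axis=0)
    degenerate = p_sq == 0
    if (c_sq == 0).any():
        raise ValidationError("constant centroid profile: correlation undefined")
    # per-sample vector products so a sample's correlations never depend on
    # which other samples share the batch (exact single-sample contract)
    corr = np.empty((c.shape[1], p.shape[1]))
    for j in range(p.shape[1]):
        if degenerate[j]:
            corr[:, j] = np.nan
            continue
        col = np.ascontiguousarray(p[:, j])
        corr[:, j] = (c.T @ col) / np.sqrt(c_sq * p_sq[j])
    return np.clip(corr, -1.0, 1.0), degenerate


def _argmax_call(corr_col: np.ndarray, classes: Sequence[str]) -> str:
    best = corr_col.max()
    candidates = [cls for cls, v in zip(classes, corr_col) if v == best]
    return min(candidates)  # alphabetical tie-break


def classify(centered: ExpressionMatrix, centroids: CentroidTable,
             metric: str = "spearman",
             excluded_classes: Sequence[str] | frozenset = frozenset(),
             *, min_gene_overlap: float = DEFAULT_MIN_GENE_OVERLAP) -> list[SubtypeCall]:
    """Assign each sample the class whose centroid it correlates with most.

    ``excluded_classes`` removes classes from the comparison (e.g. the
    Normal-like class for the Pearson nearest-shrunken-centroid variant);
    at least two classes must remain.
    """
    excluded = set(excluded_classes)
    unknown = excluded - set(centroids.classes)
    if unknown:
        raise ValidationError(f"excluded classes not in centroid table: {sorted(unknown)}")
    retained = [c for c in centroids.classes if c not in excluded]
    if len(retained) < 2:
        raise ValidationError(f"need >=2 non-excluded classes, kept {retained}")

    present = set(centered.genes)
    genes = [g for g in centroids.genes if g in present]
    coverage = len(genes) / len(centroids.genes)
    if coverage < min_gene_overlap:
        missing = [g for g in centroids.genes if g not in present]
        raise ValidationError(
            f"only {coverage:.1%} of centroid genes present (< {min_gene_overlap:.1%}); "
            f"missing e.g. {missing[:10]}"
        )
    if len(genes) < 3:
        raise ValidationError(f"need >=3 shared genes to correlate, got {len(genes)}")

    profile_values = centered.values.loc[genes].to_numpy()
    centroid_values = centroids.values.loc[genes, retained].to_numpy()
    corr, degenerate = _correlation_matrix(profile_values, centroid_values, metric)

    calls: list[SubtypeCall] = []
    for j, sample in enumerate(centered.samples):
        if degenerate[j]:
            calls.append(SubtypeCall(
                sample_id=sample, call=UNCLASSIFIABLE, correlations={},
                reason="constant centered profile: correlation undefined",
            ))
            continue
        col = corr[:, j]
        calls.append(SubtypeCall(
            sample_id=sample,
            call=_argmax_call(col, retained),
            correlations={cls: float(v) for cls, v in zip(retained, col)},
        ))
    return calls


def classify_single_sample(profile: ExpressionMatrix, ref: ReferenceProfile,
                           centroids: CentroidTable, metric: str = "spearman",
                           excluded_classes: Sequence[str] | frozenset = frozenset(),
                           *, min_gene_overlap: float = DEFAULT_MIN_GENE_OVERLAP) -> SubtypeCall:
    """Classify one sample against a fixed external reference.

    Exactly equivalent to running :func:`center_against_reference` followed
    by :func:`classify` on any batch containing the sample: nothing in the
    path depends on which other samples are present.
    """
    if len(profile.samples) != 1:
        raise ValidationError(f"expected exactly one sample, got {len(profile.samples)}")
    centered = center_against_reference(profile, ref)
    return classify(centered, centroids, metric, excluded_classes,
                    min_gene_overlap=min_gene_overlap)[0]


def classify_with_reference(expr: ExpressionMatrix, ref: ReferenceProfile,
                            centroids: CentroidTable, metric: str = "spearman",
                            excluded_classes: Sequence[str] | frozenset = frozenset(),
                            *, min_gene_overlap: float = DEFAULT_MIN_GENE_OVERLAP) -> list[SubtypeCall]:
    """Convenience: center against ``ref`` then classify."""
    centered = center_against_reference(expr, ref)
    return classify(centered, centroids, metric, excluded_classes,
                    min_gene_overlap=min_gene_overlap)
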