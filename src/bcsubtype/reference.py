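"""Reference-profile construction and the reference-stability experiment.

Two strategies are implemented:

* ER-stratified **median** reference: per-gene median across a random subset
  of samples with a fixed ER+/ER- proportion (the 60/40 convention).
* **AWCA** ("average of within-class averages"): starting from a preliminary
  classification, the per-gene mean is computed within each called class and
  those class means are then averaged with equal weight.  Double averaging
  makes the reference independent of how many samples each class contains.

The AWCA means are accumulated in exact rational arithmetic (float64 values
are dyadic rationals) with a single final rounding to float64, so the
duplication invariance of the double average holds bit-for-bit, not merely
to within summation round-off.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

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
    calls_to_series,
)
from .errors import ValidationError
from .metrics import concordance
from .pam50 import classify_with_reference

logger = logging.getLogger(__name__)

#: Below this subset size a warning (not an error) recommends a larger
#: subset; robust references want at least 50-100 samples.
RECOMMENDED_MIN_SUBSET = 50

DEFAULT_MIN_CLASS_SIZE = 10


@dataclass(frozen=True)
class SubsetSpec:
    """An ER-stratified random subset request."""

    size: int
    er_pos_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValidationError(f"subset size must be positive, got {self.size}")
        if not 0.0 < self.er_pos_fraction < 1.0:
            raise ValidationError(
                f"er_pos_fraction must be in (0, 1), got {self.er_pos_fraction}"
            )


def sample_er_stratified_subset(annotations: Sequence[CohortAnnotations],
                                spec: SubsetSpec) -> list[str]:
    """Sample ``spec.size`` ids with a fixed ER+/ER- proportion.

    The ER+ quota is round-half-up of ``size * er_pos_fraction``; the
    remainder goes to ER-.  Samples with UNKNOWN ER status are ineligible.
    """
    pos = sorted(a.sample_id for a in annotations if a.er_status == ERStatus.POS)
    neg = sorted(a.sample_id for a in annotations if a.er_status == ERStatus.NEG)
    n_pos = math.floor(spec.size * spec.er_pos_fraction + 0.5)
    n_neg = spec.size - n_pos
    if len(pos) < n_pos:
        raise ValidationError(
            f"ER+ stratum has {len(pos)} eligible samples, need {n_pos} "
            f"(short by {n_pos - len(pos)})"
        )
    if len(neg) < n_neg:
        raise ValidationError(
            f"ER- stratum has {len(neg)} eligible samples, need {n_neg} "
            f"(short by {n_neg - len(neg)})"
        )
    rng = np.random.default_rng(spec.seed)
    chosen_pos = list(rng.choice(pos, size=n_pos, replace=False))
    chosen_neg = list(rng.choice(neg, size=n_neg, replace=False))
    return [str(s) for s in chosen_pos + chosen_neg]


def build_median_reference(expr: ExpressionMatrix, subset: Sequence[str]) -> ReferenceProfile:
    """Per-gene median across the subset (even counts: mean of the middles)."""
    if len(subset) == 0:
        raise ValidationError("median reference needs a non-empty subset")
    sub = expr.subset_samples(list(subset))
    med = np.median(sub.values.to_numpy(), axis=1)
    return ReferenceProfile(pd.Series(med, index=expr.genes))


def _exact_mean(values: np.ndarray) -> Fraction:
    """Exact rational mean of float64 values (dyadic-denominator sums)."""
    num, den = 0, 1
    for v in values:
        p, q = float(v).as_integer_ratio()
        if q >= den:
            num = num * (q // den) + p
            den = q
        else:
            num += p * (den // q)
    return Fraction(num, den * len(values))


def build_awca_reference(expr: ExpressionMatrix,
                         calls: Sequence[SubtypeCall] | Mapping[str, str] | pd.Series,
                         excluded_classes: Sequence[str] | frozenset = frozenset(),
                         min_class_size: int = DEFAULT_MIN_CLASS_SIZE) -> ReferenceProfile:
    """Average of within-class averages over the retained classes.

    Classes in ``excluded_classes`` or with fewer than ``min_class_size``
    called samples are dropped from the outer average (the drop is logged).
    The result is exactly invariant to within-class sample duplication.
    """
    series = calls_to_series(calls)
    missing = [s for s in expr.samples if s not in series.index]
    if missing:
        raise ValidationError(f"calls do not cover samples: {missing[:10]}")
    labels = series.loc[expr.samples]
    labels = labels[labels != UNCLASSIFIABLE]

    sizes = labels.value_counts().to_dict()
    excluded = set(excluded_classes)
    retained = []
    for cls in sorted(sizes):
        if cls in excluded:
            logger.info("AWCA: class %s excluded by request (%d samples)", cls, sizes[cls])
        elif sizes[cls] < min_class_size:
            logger.info("AWCA: class %s auto-excluded, only %d < %d samples",
                        cls, sizes[cls], min_class_size)
        else:
            retained.append(cls)
    if len(retained) < 2:
        raise ValidationError(
            f"AWCA needs >=2 retained classes; class sizes {sizes}, "
            f"excluded {sorted(excluded)}, min_class_size {min_class_size}"
        )

    matrix = expr.values.to_numpy()
    col_index = {s: j for j, s in enumerate(expr.samples)}
    class_cols = {
        cls: [col_index[s] for s in labels.index[labels == cls]] for cls in retained
    }
    n_classes = len(retained)
    out = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        row = matrix[i]
        total = Fraction(0)
        for cls in retained:
            total += _exact_mean(row[class_cols[cls]])
        out[i] = float(total / n_classes)
    return ReferenceProfile(pd.Series(out, index=expr.genes))


@dataclass(frozen=True)
class AWCAPipelineResult:
    reference: ReferenceProfile
    calls: list[SubtypeCall]
    preliminary_calls: list[SubtypeCall] | None
    subset: list[str] | None


def awca_pipeline(expr: ExpressionMatrix,
                  annotations: Sequence[CohortAnnotations] | None,
                  centroids: CentroidTable,
                  spec: SubsetSpec | None = None,
                  excluded_classes: Sequence[str] | frozenset = frozenset(),
                  min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
                  *, metric: str = "spearman",
                  preliminary_labels: Mapping[str, str] | pd.Series | None = None
                  ) -> AWCAPipelineResult:
    """Full AWCA classification pipeline.

    Either runs the standard preliminary step (ER-stratified subset ->
    median reference -> classify the whole cohort) or accepts precomputed
    ``preliminary_labels`` (e.g. published subtype calls).  The AWCA
    reference is then built from the preliminary calls over the whole
    cohort and the cohort is re-classified once against it.
    """
    preliminary: list[SubtypeCall] | None = None
    subset: list[str] | None = None
    if preliminary_labels is not None:
        prelim_source: Sequence[SubtypeCall] | pd.Series = calls_to_series(preliminary_labels)
    else:
        if annotations is None or spec is None:
            raise ValidationError("awca_pipeline needs annotations and a SubsetSpec "
                                  "unless preliminary_labels are supplied")
        if spec.size < RECOMMENDED_MIN_SUBSET:
            warnings.warn(
                f"reference subset of {spec.size} samples is below the recommended "
                f"minimum of {RECOMMENDED_MIN_SUBSET}-100; expect less robust references",
                stacklevel=2,
            )
        subset = sample_er_stratified_subset(annotations, spec)
        median_ref = build_median_reference(expr, subset)
        preliminary = classify_with_reference(expr, median_ref, centroids, metric)
        prelim_source = preliminary
    reference = build_awca_reference(expr, prelim_source, excluded_classes, min_class_size)
    final = classify_with_reference(expr, reference, centroids, metric)
    return AWCAPipelineResult(reference=reference, calls=final,
                              preliminary_calls=preliminary, subset=subset)


# ---------------------------------------------------------------------------
# stability experiment
# ---------------------------------------------------------------------------

@dataclass
class StabilityCell:
    """Results for one (strategy, subset size) combination."""

    truth_concordances: list[float] = field(default_factory=list)
    pairwise_concordances: list[float] = field(default_factory=list)
    skipped: int = 0
    call_sets: list[pd.Series] = field(default_factory=list)

    @property
    def truth_mean(self) -> float:
        return float(np.mean(self.truth_concordances)) if self.truth_concordances else float("nan")

    @property
    def truth_sd(self) -> float:
        vals = self.truth_concordances
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def pairwise_mean(self) -> float:
        return float(np.mean(self.pairwise_concordances)) if self.pairwise_concordances else float("nan")

    @property
    def pairwise_sd(self) -> float:
        vals = self.pairwise_concordances
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


@dataclass
class StabilityReport:
    """Concordance-to-truth and pairwise concordance per strategy and size."""

    cells: dict[tuple[str, int], StabilityCell]
    replicates: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (strategy, size), cell in sorted(self.cells.items()):
            rows.append({
                "strategy": strategy,
                "subset_size": size,
                "replicates": len(cell.truth_concordances),
                "skipped": cell.skipped,
                "truth_concordance_mean": cell.truth_mean,
                "truth_concordance_sd": cell.truth_sd,
                "pairwise_concordance_mean": cell.pairwise_mean,
                "pairwise_concordance_sd": cell.pairwise_sd,
            })
        return pd.DataFrame(rows)


def stability_experiment(expr: ExpressionMatrix,
                         annotations: Sequence[CohortAnnotations],
                         centroids: CentroidTable,
                         sizes: Sequence[int],
                         replicates: int,
                         truth_labels: Mapping[str, str] | pd.Series,
                         seed: int = 0,
                         *, er_pos_fraction: float = 0.6,
                         excluded_classes: Sequence[str] | frozenset = frozenset(),
                         min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
                         metric: str = "spearman") -> StabilityReport:
    """Replicate median-based and AWCA-based classification across random
    ER-stratified subsets of varying size.

    For each size and replicate, a median reference is built from a fresh
    subset and used both directly (strategy ``median``) and as the seed of
    one AWCA round (strategy ``awca``).  Concordance with ``truth_labels``
    and all within-strategy pairwise concordances are recorded.  Replicates
    whose subset is infeasible for the ER strata are skipped with a logged
    warning and counted in the report.
    """
    if replicates < 2:
        warnings.warn("fewer than 2 replicates: pairwise concordances will be empty",
                      stacklevel=2)
    truth = calls_to_series(truth_labels)
    root = np.random.SeedSequence(seed)
    cells: dict[tuple[str, int], StabilityCell] = {}
    for size in sizes:
        med_cell = StabilityCell()
        awca_cell = StabilityCell()
        children = root.spawn(replicates)
        for rep in range(replicates):
            rep_seed = int(children[rep].generate_state(1)[0] % (2 ** 31))
            spec = SubsetSpec(size=size, er_pos_fraction=er_pos_fraction, seed=rep_seed)
            try:
                subset = sample_er_stratified_subset(annotations, spec)
            except ValidationError as exc:
                logger.warning("size %d replicate %d skipped: %s", size, rep, exc)
                med_cell.skipped += 1
                awca_cell.skipped += 1
                continue
            median_ref = build_median_reference(expr, subset)
            median_calls = classify_with_reference(expr, median_ref, centroids, metric)
            awca_ref = build_awca_reference(expr, median_calls, excluded_classes, min_class_size)
            awca_calls = classify_with_reference(expr, awca_ref, centroids, metric)
            for cell, calls in ((med_cell, median_calls), (awca_cell, awca_calls)):
                series = calls_to_series(calls)
                cell.truth_concordances.append(concordance(series, truth))
                cell.call_sets.append(series)
        for cell in (med_cell, awca_cell):
            sets = cell.call_sets
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    cell.pairwise_concordances.append(concordance(sets[i], sets[j]))
        cells[("median", size)] = med_cell
        cells[("awca", size)] = awca_cell
    return StabilityReport(cells=cells, replicates=replicates)
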