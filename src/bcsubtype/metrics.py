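"""Agreement and accuracy instruments for comparing classifications.

Call sets are always matched by sample id, never by position, because they
typically originate from different pipelines.  UNCLASSIFIABLE calls are
excluded pairwise, counted, and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .containers import UNCLASSIFIABLE, SubtypeCall, calls_to_series
from .errors import ValidationError

CallsLike = "Sequence[SubtypeCall] | Mapping[str, str] | pd.Series"


def _paired(a, b) -> tuple[pd.Series, pd.Series, int]:
    sa = calls_to_series(a)
    sb = calls_to_series(b)
    common = sa.index.intersection(sb.index)
    if len(common) == 0:
        raise ValidationError("no common sample ids between the two call sets")
    sa = sa.loc[common]
    sb = sb.loc[common]
    usable = (sa != UNCLASSIFIABLE) & (sb != UNCLASSIFIABLE)
    excluded = int((~usable).sum())
    if usable.sum() == 0:
        raise ValidationError("no classifiable sample pairs to compare")
    return sa[usable], sb[usable], excluded


@dataclass(frozen=True)
class ConcordanceResult:
    percent: float
    n_compared: int
    n_excluded: int


def concordance_detail(a, b) -> ConcordanceResult:
    sa, sb, excluded = _paired(a, b)
    pct = 100.0 * float((sa.to_numpy() == sb.to_numpy()).mean())
    return ConcordanceResult(percent=pct, n_compared=len(sa), n_excluded=excluded)


def concordance(a, b) -> float:
    """Percent of matched samples (by id) with identical calls."""
    return concordance_detail(a, b).percent


def cohens_kappa(a, b) -> float:
    """Chance-corrected agreement with marginal-product expected agreement.

    When both call sets are constant and equal (expected agreement 1), kappa
    is defined as 1 if observed agreement is 1; otherwise it is undefined.
    """
    sa, sb, _ = _paired(a, b)
    av, bv = sa.to_numpy(), sb.to_numpy()
    p_o = float((av == bv).mean())
    labels = sorted(set(av) | set(bv))
    table = pd.crosstab(pd.Series(av), pd.Series(bv)).reindex(
        index=labels, columns=labels, fill_value=0).to_numpy(dtype=float)
    n = table.sum()
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / (n * n)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValidationError("Cohen's kappa undefined: expected agreement is 1 "
                              "but observed agreement is not")
    return float(cohen_kappa_score(av, bv, labels=labels))


@dataclass(frozen=True)
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # rows = truth, columns = predicted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass(frozen=True)
class MacroReport:
    confusion: ConfusionMatrix
    recall: Mapping[str, float]          # per class, NaN when the class is absent from truth
    precision: Mapping[str, float]       # per class, NaN when never predicted
    macro_recall: float
    macro_precision: float
    recall_excluded: tuple[str, ...]     # classes with no truth samples
    precision_excluded: tuple[str, ...]  # classes never predicted


def confusion_and_macro(truth, pred, classes: Sequence[str]) -> MacroReport:
    """Confusion matrix plus per-class and macro-averaged recall/precision.

    Macro averages are unweighted means over classes with a nonzero
    denominator; excluded classes are reported explicitly.
    """
    st, sp, _ = _paired(truth, pred)
    unknown = (set(st) | set(sp)) - set(classes)
    if unknown:
        raise ValidationError(f"labels outside the declared classes: {sorted(unknown)}")
    counts = confusion_matrix(st.to_numpy(), sp.to_numpy(), labels=list(classes))
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    diag = np.diag(counts)
    recall = {
        cls: (diag[i] / row_sums[i] if row_sums[i] > 0 else float("nan"))
        for i, cls in enumerate(classes)
    }
    precision = {
        cls: (diag[i] / col_sums[i] if col_sums[i] > 0 else float("nan"))
        for i, cls in enumerate(classes)
    }
    recall_vals = [v for v in recall.values() if not np.isnan(v)]
    precision_vals = [v for v in precision.values() if not np.isnan(v)]
    return MacroReport(
        confusion=ConfusionMatrix(classes=tuple(classes), counts=counts),
        recall=recall,
        precision=precision,
        macro_recall=float(np.mean(recall_vals)),
        macro_precision=float(np.mean(precision_vals)),
        recall_excluded=tuple(c for c in classes if np.isnan(recall[c])),
        precision_excluded=tuple(c for c in classes if np.isnan(precision[c])),
    )


@dataclass(frozen=True)
class PairwiseConcordance:
    mean: float
    sd: float      # sample standard deviation; 0 by convention for a single pair
    values: tuple[float, ...]


def pairwise_concordance_distribution(call_sets: Sequence) -> PairwiseConcordance:
    """Concordance over all C(m, 2) pairs of call sets on shared samples."""
    if len(call_sets) < 2:
        raise ValidationError("need at least 2 call sets for pairwise concordance")
    values = [concordance(a, b) for a, b in combinations(call_sets, 2)]
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return PairwiseConcordance(mean=float(np.mean(values)), sd=sd, values=tuple(values))
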