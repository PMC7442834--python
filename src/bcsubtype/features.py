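"""Feature selection: univariate filters, pairwise-contrast DEG signatures,
and randomized multi-run backward elimination.

Three families are provided:

* **Filters** — Fisher scores, mutual information, chi-squared and
  label-correlation rankings over all genes.  Mutual information and
  chi-squared discretize each gene into per-gene quantile bins (default 4).
* **DEG contrasts** — per-gene two-sample t statistics on log2 values for
  every unordered class pair, optionally with empirical-Bayes variance
  moderation (per-gene variances shrunk toward a fitted scaled-inverse-
  chi-square prior), Benjamini-Hochberg adjustment within contrast, and the
  "union of the top N per contrast" signature construction.
* **Wrapper** — sequential backward elimination driven by cross-validated
  accuracy of a supplied trainer, run multiple times with randomized gene
  order; the final signature is the union of every run's kept set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, calls_to_series
from .errors import ValidationError

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12
DEFAULT_BINS = 4
DEFAULT_ALPHA = 0.05
DEFAULT_GAIN_THRESHOLD = 0.001


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureRanking:
    """All genes scored by one metric, ordered by descending score
    (ties broken by gene name)."""

    metric_name: str
    scores: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            bad = self.scores.index[~np.isfinite(self.scores.to_numpy())][0]
            raise ValidationError(f"non-finite score for gene {bad!r}")

    @property
    def order(self) -> list[str]:
        frame = self.scores.rename("score").to_frame()
        frame["gene"] = frame.index
        frame = frame.sort_values(["score", "gene"], ascending=[False, True])
        return list(frame.index)


@dataclass(frozen=True)
class GeneSignature:
    """An ordered, unique gene set with a construction record."""

    name: str
    genes: tuple[str, ...]
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError("a gene signature must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in signature")


@dataclass(frozen=True)
class ContrastResult:
    """Differential-expression result for one unordered class pair."""

    class_pair: tuple[str, str]
    table: pd.DataFrame  # per gene: statistic, p_value, adj_p_value
    significant_genes: tuple[str, ...]  # adj p < alpha, ascending adj p


# ---------------------------------------------------------------------------
# label handling
# ---------------------------------------------------------------------------

def _aligned_labels(expr: ExpressionMatrix, labels) -> pd.Series:
    series = calls_to_series(labels)
    missing = [s for s in expr.samples if s not in series.index]
    if missing:
        raise ValidationError(f"labels missing for samples: {missing[:10]}")
    return series.loc[expr.samples]


def _class_groups(expr: ExpressionMatrix, labels, *, min_size: int = 2) -> dict[str, np.ndarray]:
    series = _aligned_labels(expr, labels)
    groups: dict[str, np.ndarray] = {}
    for cls in sorted(series.unique()):
        idx = np.flatnonzero((series == cls).to_numpy())
        if len(idx) < min_size:
            raise ValidationError(f"class {cls!r} has {len(idx)} sample(s), need >= {min_size}")
        groups[cls] = idx
    if len(groups) < 2:
        raise ValidationError(f"need >=2 classes, got {sorted(groups)}")
    return groups


# ---------------------------------------------------------------------------
# univariate filters
# ---------------------------------------------------------------------------

def fisher_scores(expr: ExpressionMatrix, labels) -> FeatureRanking:
    """Per-gene Fisher score: between-class scatter of class means over the
    summed within-class (population) variances, floored at 1e-12."""
    groups = _class_groups(expr, labels)
    values = expr.values.to_numpy()
    overall = values.mean(axis=1)
    between = np.zeros(values.shape[0])
    within = np.zeros(values.shape[0])
    for idx in groups.values():
        sub = values[:, idx]
        mu = sub.mean(axis=1)
        between += len(idx) * (mu - overall) ** 2
        within += len(idx) * sub.var(axis=1)  # population variance
    scores = between / np.maximum(within, VARIANCE_FLOOR)
    return FeatureRanking("fisher", pd.Series(scores, index=expr.genes))


def _quantile_bins(values: np.ndarray, bins: int) -> np.ndarray | None:
    """Per-gene quantile binning; returns None for a single occupied bin."""
    edges = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(edges)
    if len(edges) == 0:
        return None
    binned = np.searchsorted(edges, values, side="left")
    if len(np.unique(binned)) < 2:
        return None
    return binned


def _contingency(binned: np.ndarray, label_codes: np.ndarray, n_labels: int) -> np.ndarray:
    n_bins = binned.max() + 1
    table = np.zeros((n_bins, n_labels))
    np.add.at(table, (binned, label_codes), 1)
    return table[table.sum(axis=1) > 0]


def mutual_information_scores(expr: ExpressionMatrix, labels,
                              bins: int = DEFAULT_BINS) -> FeatureRanking:
    """Plug-in mutual information (bits) between quantile-binned expression
    and the class label; a constant gene scores 0."""
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    _class_groups(expr, labels, min_size=1)
    series = _aligned_labels(expr, labels)
    codes, _ = pd.factorize(series, sort=True)
    n_labels = codes.max() + 1
    values = expr.values.to_numpy()
    scores = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        binned = _quantile_bins(values[i], bins)
        if binned is None:
            continue
        table = _contingency(binned, codes, n_labels)
        p = table / table.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / (px * py)), 0.0)
        scores[i] = max(terms.sum(), 0.0)
    return FeatureRanking("mutual_information", pd.Series(scores, index=expr.genes))


def chi_squared_scores(expr: ExpressionMatrix, labels,
                       bins: int = DEFAULT_BINS) -> FeatureRanking:
    """Pearson chi-square of the (quantile-bin x class) contingency table."""
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    _class_groups(expr, labels, min_size=1)
    series = _aligned_labels(expr, labels)
    codes, _ = pd.factorize(series, sort=True)
    n_labels = codes.max() + 1
    values = expr.values.to_numpy()
    scores = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        binned = _quantile_bins(values[i], bins)
        if binned is None:
            continue
        table = _contingency(binned, codes, n_labels)
        table = table[:, table.sum(axis=0) > 0]
        if min(table.shape) < 2:
            continue
        scores[i] = float(stats.chi2_contingency(table, correction=False)[0])
    return FeatureRanking("chi_squared", pd.Series(scores, index=expr.genes))


def spearman_label_scores(expr: ExpressionMatrix, labels) -> FeatureRanking:
    """Max over classes of |Spearman rho| between expression and the
    one-vs-rest class indicator; a constant gene scores 0."""
    groups = _class_groups(expr, labels, min_size=1)
    values = expr.values.to_numpy()
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    gene_norm = np.sqrt((ranks ** 2).sum(axis=1))
    scores = np.zeros(values.shape[0])
    for idx in groups.values():
        indicator = np.zeros(n)
        indicator[idx] = 1.0
        ind_ranks = stats.rankdata(indicator)
        ind_ranks = ind_ranks - ind_ranks.mean()
        ind_norm = np.sqrt((ind_ranks ** 2).sum())
        if ind_norm == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (ranks @ ind_ranks) / (gene_norm * ind_norm)
        rho = np.where(gene_norm > 0, rho, 0.0)
        scores = np.maximum(scores, np.abs(rho))
    return FeatureRanking("spearman_label", pd.Series(scores, index=expr.genes))


def top_k(ranking: FeatureRanking, k: int) -> GeneSignature:
    """The first ``k`` genes of the ranking (deterministic under ties)."""
    order = ranking.order
    if not 1 <= k <= len(order):
        raise ValidationError(f"k must be in [1, {len(order)}], got {k}")
    return GeneSignature(
        name=f"{ranking.metric_name}_top{k}",
        genes=tuple(order[:k]),
        provenance={"method": "filter_top_k", "metric": ranking.metric_name, "k": k},
    )


# ---------------------------------------------------------------------------
# pairwise-contrast differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled-inverse-chi-square prior (d0, s0^2) for empirical-Bayes
    variance moderation by matching moments of log sample variances.

    Returns ``d0 = inf`` when the observed spread of log variances is no
    larger than expected under a common variance.
    """
    s2 = np.maximum(np.asarray(s2, dtype=np.float64), VARIANCE_FLOOR)
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    e_var = float(((e - e_mean) ** 2).sum() / max(n - 1, 1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def pairwise_deg(expr: ExpressionMatrix, labels,
                 alpha: float = DEFAULT_ALPHA,
                 moderation: str = "empirical_bayes") -> list[ContrastResult]:
    """Two-sample (optionally moderated) t-tests on log2 values for every
    unordered class pair, with BH adjustment within each contrast.

    ``significant_genes`` holds genes with adjusted p below ``alpha``,
    sorted by ascending adjusted p (ties by raw p, then gene name).
    """
    if moderation not in ("none", "empirical_bayes"):
        raise ValidationError(f"unknown moderation {moderation!r}")
    groups = _class_groups(expr, labels)
    values = expr.values.to_numpy()
    genes = np.asarray(expr.genes)
    results: list[ContrastResult] = []
    for cls_a, cls_b in combinations(sorted(groups), 2):
        ia, ib = groups[cls_a], groups[cls_b]
        n1, n2 = len(ia), len(ib)
        if n1 < 2 or n2 < 2:
            raise ValidationError(f"contrast ({cls_a}, {cls_b}): each class needs >=2 samples")
        xa, xb = values[:, ia], values[:, ib]
        diff = xa.mean(axis=1) - xb.mean(axis=1)
        df_resid = n1 + n2 - 2
        pooled = (xa.var(axis=1, ddof=1) * (n1 - 1) + xb.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
        if moderation == "empirical_bayes":
            d0, s0_sq = fit_variance_prior(pooled, df_resid)
            if np.isinf(d0):
                post_var = np.full_like(pooled, s0_sq)
                df_total = np.inf
            else:
                post_var = (d0 * s0_sq + df_resid * pooled) / (d0 + df_resid)
                df_total = d0 + df_resid
        else:
            post_var = np.maximum(pooled, VARIANCE_FLOOR)
            df_total = df_resid
        se = np.sqrt(np.maximum(post_var, VARIANCE_FLOOR) * (1.0 / n1 + 1.0 / n2))
        t_stat = diff / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_stat))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        table = pd.DataFrame(
            {"statistic": t_stat, "p_value": p, "adj_p_value": adj}, index=genes
        )
        sig = table[table["adj_p_value"] < alpha].copy()
        sig["gene"] = sig.index
        sig = sig.sort_values(["adj_p_value", "p_value", "gene"])
        results.append(ContrastResult(
            class_pair=(cls_a, cls_b), table=table,
            significant_genes=tuple(sig.index),
        ))
    return results


def limma_n_signature(contrasts: Sequence[ContrastResult], n: int) -> GeneSignature:
    """Union over contrasts of the top ``n`` significant genes per contrast
    (or all of them if fewer), preserving first-appearance order."""
    if n < 1:
        raise ValidationError(f"N must be >= 1, got {n}")
    genes: list[str] = []
    contributions: dict[str, int] = {}
    for contrast in contrasts:
        taken = contrast.significant_genes[:n]
        contributions["|".join(contrast.class_pair)] = len(taken)
        for g in taken:
            if g not in genes:
                genes.append(g)
    if not genes:
        raise ValidationError("every contrast's significant gene list is empty")
    return GeneSignature(
        name=f"limma{n}",
        genes=tuple(genes),
        provenance={"method": "limma_n", "N": n, "per_contrast_taken": contributions},
    )


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

Trainer = Callable[[ExpressionMatrix, Mapping[str, str]], float]


def backward_elimination(expr: ExpressionMatrix, labels,
                         start: GeneSignature, trainer: Trainer,
                         gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
                         runs: int = 10, seed: int = 0) -> GeneSignature:
    """Randomized-order sequential backward elimination, union of kept sets.

    Each run shuffles the gene order (seeded), sweeps the genes repeatedly,
    and removes a gene whenever the trainer's cross-validated accuracy
    without it exceeds the current accuracy by more than ``gain_threshold``,
    until a full pass removes nothing.  The returned signature is the union
    of every run's kept set; failed runs are reported in the provenance and
    all runs failing is an error.
    """
    if runs < 1:
        raise ValidationError(f"runs must be >= 1, got {runs}")
    label_series = _aligned_labels(expr, labels)
    start_genes = [g for g in start.genes]
    missing = [g for g in start_genes if g not in set(expr.genes)]
    if missing:
        raise ValidationError(f"start signature genes not in matrix: {missing[:10]}")

    root = np.random.SeedSequence(seed)
    kept_sets: list[list[str]] = []
    failed: list[str] = []
    for run, child in enumerate(root.spawn(runs)):
        rng = np.random.default_rng(child)
        order = list(rng.permutation(start_genes))
        kept = list(start_genes)
        try:
            current = trainer(expr.subset_genes(kept), label_series)
            removed_in_pass = True
            while removed_in_pass:
                removed_in_pass = False
                for gene in order:
                    if gene not in kept or len(kept) <= 1:
                        continue
                    candidate = [g for g in kept if g != gene]
                    acc = trainer(expr.subset_genes(candidate), label_series)
                    if acc > current + gain_threshold:
                        kept = candidate
                        current = acc
                        removed_in_pass = True
        except Exception as exc:  # trainer failure aborts the run, not the whole job
            logger.warning("backward elimination run %d failed: %s", run, exc)
            failed.append(f"run {run}: {exc}")
            continue
        kept_sets.append(kept)
    if not kept_sets:
        raise ValidationError(f"all backward-elimination runs failed: {failed}")

    union: list[str] = [g for g in start_genes if any(g in ks for ks in kept_sets)]
    return GeneSignature(
        name=f"{start.name}_BWE",
        genes=tuple(union),
        provenance={
            "method": "backward_elimination",
            "start": start.name,
            "gain_threshold": gain_threshold,
            "runs": runs,
            "seed": seed,
            "kept_per_run": [list(ks) for ks in kept_sets],
            "failed_runs": failed,
        },
    )
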