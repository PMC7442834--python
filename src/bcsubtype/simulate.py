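"""Synthetic cohorts with the statistical structure the methods assume.

A simulated cohort has class-specific centroid profiles (log2ratio-scale
deviations around a shared per-gene baseline), independent Gaussian noise
on the log2 scale, class-dependent ER-status proportions, a fraction of
ambiguous samples drawn from a two-class centroid mixture, and optional
planted differentially expressed genes for named class pairs.  Everything
is reproducible from a single seed.

The default configuration is the package's reference study condition: 1,000
genes (100 class-informative), five classes sized (120, 100, 60, 50, 20)
with luminal-skewed ER+ probabilities, noise SD 1.0 on the log2 scale, and
10% ambiguous samples mixed half-and-half between two class centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CentroidTable,
    CohortAnnotations,
    ERStatus,
    ExpressionMatrix,
)
from .errors import ValidationError

DEFAULT_CLASS_COUNTS: Mapping[str, int] = {
    "LUMA": 120, "LUMB": 100, "BASAL": 60, "HER2": 50, "NORMAL": 20,
}
DEFAULT_ER_POS_PROB: Mapping[str, float] = {
    "LUMA": 0.95, "LUMB": 0.9, "BASAL": 0.1, "HER2": 0.4, "NORMAL": 0.7,
}


@dataclass(frozen=True)
class PlantedDE:
    """A gene block that separates exactly one class pair in mean."""

    class_pair: tuple[str, str]
    n_genes: int
    shift: float


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_informative: int = 100
    centroid_separation: float = 2.0   # log2 mean shift of class-marker genes
    noise_sd: float = 1.0              # per-gene Gaussian noise, log2 scale
    ambiguous_fraction: float = 0.1
    ambiguous_weight: float = 0.5      # mixture weight of the labeled class
    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    er_pos_prob: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ER_POS_PROB))
    baseline_mean: float = 7.0         # log2 abundance of the shared baseline
    baseline_sd: float = 1.5
    tumor_size_lognorm: tuple[float, float] = (0.7, 0.45)  # (mean, sd) of log size
    planted_de: tuple[PlantedDE, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_informative < 0:
            raise ValidationError("gene counts must be positive")
        if self.n_informative > self.n_genes:
            raise ValidationError("n_informative exceeds n_genes")
        if not 0.0 <= self.ambiguous_fraction < 1.0:
            raise ValidationError("ambiguous_fraction must be in [0, 1)")
        if not 0.0 < self.ambiguous_weight < 1.0:
            raise ValidationError("ambiguous_weight must be in (0, 1)")
        if len(self.class_counts) < 2:
            raise ValidationError("need at least 2 classes")
        for cls, count in self.class_counts.items():
            if count <= 0:
                raise ValidationError(f"class {cls!r} has non-positive count {count}")
        planted_total = sum(p.n_genes for p in self.planted_de)
        if self.n_informative + planted_total > self.n_genes:
            raise ValidationError(
                f"{self.n_informative} informative + {planted_total} planted DE genes "
                f"exceed {self.n_genes} total genes"
            )
        for p in self.planted_de:
            for cls in p.class_pair:
                if cls not in self.class_counts:
                    raise ValidationError(f"planted DE pair names unknown class {cls!r}")

    @property
    def classes(self) -> list[str]:
        return list(self.class_counts)

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())


@dataclass(frozen=True)
class SimulatedCohort:
    expression: ExpressionMatrix
    true_labels: Mapping[str, str]
    annotations: tuple[CohortAnnotations, ...]
    planted_de_genes: Mapping[tuple[str, str], tuple[str, ...]]
    planted_centroids: CentroidTable
    ambiguous_pairs: Mapping[str, tuple[str, str]]  # sample -> (primary, partner)
    config: SimulationConfig


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _centroid_deviations(config: SimulationConfig
                         ) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[str, ...]]]:
    """Class-centroid deviations (log2ratio scale) and planted-DE bookkeeping.

    Informative genes are assigned round-robin to classes with a positive
    shift of ``centroid_separation``; planted DE genes shift the two named
    classes by +/- half the planted shift so the full shift separates
    exactly that pair while disjoint pairs remain null.
    """
    genes = _gene_names(config.n_genes)
    classes = config.classes
    dev = pd.DataFrame(0.0, index=genes, columns=classes)
    for i in range(config.n_informative):
        dev.iloc[i, i % len(classes)] = config.centroid_separation
    planted: dict[tuple[str, str], tuple[str, ...]] = {}
    cursor = config.n_informative
    for block in config.planted_de:
        block_genes = genes[cursor:cursor + block.n_genes]
        cursor += block.n_genes
        cls_a, cls_b = block.class_pair
        dev.loc[block_genes, cls_a] += block.shift / 2.0
        dev.loc[block_genes, cls_b] -= block.shift / 2.0
        planted[(cls_a, cls_b)] = tuple(block_genes)
    return dev, planted


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw a cohort: sample s of class k is centroid_k + N(0, noise_sd),
    with the configured fraction of two-centroid mixture samples."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    classes = config.classes
    dev, planted = _centroid_deviations(config)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    labels: list[str] = []
    for cls in classes:
        labels.extend([cls] * config.class_counts[cls])
    samples = _sample_names(len(labels))
    label_map = dict(zip(samples, labels))

    n_ambiguous = int(np.floor(config.ambiguous_fraction * len(samples)))
    ambiguous_idx = rng.choice(len(samples), size=n_ambiguous, replace=False) if n_ambiguous else []
    ambiguous_pairs: dict[str, tuple[str, str]] = {}
    mean_matrix = np.empty((config.n_genes, len(samples)))
    dev_values = dev.to_numpy()
    class_index = {c: i for i, c in enumerate(classes)}
    ambiguous_set = set(int(i) for i in np.asarray(ambiguous_idx))
    lam = config.ambiguous_weight
    for j, sample in enumerate(samples):
        primary = class_index[labels[j]]
        profile = dev_values[:, primary]
        if j in ambiguous_set and len(classes) > 1:
            others = [c for c in classes if c != labels[j]]
            partner = others[int(rng.integers(len(others)))]
            profile = lam * profile + (1.0 - lam) * dev_values[:, class_index[partner]]
            ambiguous_pairs[sample] = (labels[j], partner)
        mean_matrix[:, j] = baseline + profile

    noise = rng.normal(0.0, config.noise_sd, size=mean_matrix.shape) if config.noise_sd > 0 \
        else np.zeros_like(mean_matrix)
    expr = ExpressionMatrix(pd.DataFrame(mean_matrix + noise, index=genes, columns=samples))

    mu, sigma = config.tumor_size_lognorm
    annotations = []
    for sample in samples:
        cls = label_map[sample]
        er = ERStatus.POS if rng.random() < config.er_pos_prob.get(cls, 0.5) else ERStatus.NEG
        size = float(rng.lognormal(mu, sigma)) if sigma > 0 else float(np.exp(mu))
        annotations.append(CohortAnnotations(
            sample_id=sample, er_status=er, subtype_label=cls, tumor_size=size,
        ))

    centroids = CentroidTable(dev)
    return SimulatedCohort(
        expression=expr,
        true_labels=label_map,
        annotations=tuple(annotations),
        planted_de_genes=planted,
        planted_centroids=centroids,
        ambiguous_pairs=ambiguous_pairs,
        config=config,
    )


def plant_pairwise_de(config: SimulationConfig,
                      pairs: Sequence[tuple[str, str]],
                      genes_per_pair: int,
                      shift: float) -> SimulationConfig:
    """Augment a config with DE gene blocks for the named class pairs.

    Each pair gets a disjoint block of ``genes_per_pair`` spare genes whose
    means differ by ``shift`` between the two classes.  Assigning the same
    pair twice is an error.
    """
    seen = set(tuple(sorted(p.class_pair)) for p in config.planted_de)
    blocks = list(config.planted_de)
    for pair in pairs:
        key = tuple(sorted(pair))
        if key in seen:
            raise ValidationError(f"pair {pair} already has planted DE genes")
        seen.add(key)
        blocks.append(PlantedDE(class_pair=(pair[0], pair[1]),
                                n_genes=genes_per_pair, shift=shift))
    return replace(config, planted_de=tuple(blocks))  # re-validates spare genes


def build_balanced_training_split(labels: Mapping[str, str] | pd.Series,
                                  quotas: Mapping[str, int],
                                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded per-class without-replacement sampling; test = complement."""
    series = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    rng = np.random.default_rng(seed)
    train: list[str] = []
    for cls, quota in quotas.items():
        members = sorted(series.index[series == cls])
        if quota > len(members):
            raise ValidationError(
                f"class {cls!r} has {len(members)} samples, quota {quota} "
                f"(short by {quota - len(members)})"
            )
        train.extend(str(s) for s in rng.choice(members, size=quota, replace=False))
    train_set = set(train)
    test = [str(s) for s in series.index if s not in train_set]
    if not test:
        warnings.warn("balanced split consumed every sample: empty test set", stacklevel=2)
    return train, test


def simulate_sparse_softmax(n_samples: int = 500, n_genes: int = 40,
                            n_classes: int = 3, n_support: int = 8,
                            coef_scale: float = 2.5, seed: int = 0
                            ) -> tuple[ExpressionMatrix, dict[str, str], set[str]]:
    """Cohort drawn from a known sparse softmax model, for recovery studies.

    Features are standard normal; ``n_support`` genes carry coefficients of
    magnitude ``coef_scale`` (alternating sign across classes); labels are
    sampled from the implied class probabilities.  Returns the expression
    matrix, the labels, and the true support gene set.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = _sample_names(n_samples)
    x = rng.normal(size=(n_samples, n_genes))
    weights = np.zeros((n_classes, n_genes))
    support = genes[:n_support]
    for i in range(n_support):
        cls = i % n_classes
        weights[cls, i] = coef_scale * (1.0 if i % 2 == 0 else -1.0)
    logits = x @ weights.T
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    class_names = [f"C{i + 1}" for i in range(n_classes)]
    draws = [class_names[rng.choice(n_classes, p=p)] for p in probs]
    expr = ExpressionMatrix(pd.DataFrame(x.T, index=genes, columns=samples))
    return expr, dict(zip(samples, draws)), set(support)
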