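"""Elastic-net regularized multiclass (softmax) logistic regression.

The penalized objective is

    (1/n) * multinomial negative log-likelihood
      + l1 * sum|W|  +  (l2 / 2) * sum W**2

over the class-by-gene weight matrix W; intercepts are unpenalized.
Features are z-scored with training statistics (standard deviations floored
at 1e-8) so the penalties act on comparable scales, and the stored
statistics are re-applied at prediction time.

Optimization is proximal gradient descent (ISTA with backtracking line
search) on the smooth part plus soft-thresholding for the L1 term, which
yields exact zero weights — the basis of the sparsity accounting.  The
penalized objective decreases monotonically across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix, SubtypeCall, calls_to_series
from .errors import ValidationError

SD_FLOOR = 1e-8
#: |w| above this counts as a non-zero weight.
ZERO_WEIGHT_THRESHOLD = 1e-8


@dataclass(frozen=True)
class OptimizerConfig:
    max_iter: int = 1000
    tol: float = 1e-6          # relative change of the penalized objective
    init_step: float = 1.0     # initial backtracking step size


@dataclass(frozen=True)
class MLRModel:
    classes: tuple[str, ...]
    feature_genes: tuple[str, ...]
    weights: np.ndarray          # K x G
    intercepts: np.ndarray       # K
    standardization: tuple[np.ndarray, np.ndarray]  # per-gene mean, sd
    hyperparams: tuple[float, float]                # (l1, l2)
    fit_metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        k, g = len(self.classes), len(self.feature_genes)
        if self.weights.shape != (k, g):
            raise ValidationError(f"weights shape {self.weights.shape} != ({k}, {g})")
        if self.intercepts.shape != (k,):
            raise ValidationError(f"intercepts shape {self.intercepts.shape} != ({k},)")
        mean, sd = self.standardization
        if mean.shape != (g,) or sd.shape != (g,):
            raise ValidationError("standardization statistics must be per-gene vectors")
        if (sd <= 0).any():
            raise ValidationError("standardization deviations must be positive")

    def nonzero_weight_count(self) -> int:
        return int((np.abs(self.weights) > ZERO_WEIGHT_THRESHOLD).sum())


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=1, keepdims=True)


def _smooth_objective(weights: np.ndarray, intercepts: np.ndarray,
                      x: np.ndarray, y_onehot: np.ndarray, l2: float) -> float:
    """(1/n) NLL + ridge; the differentiable part of the objective."""
    logits = x @ weights.T + intercepts
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1)) + logits.max(axis=1)
    nll = float((log_z - (logits * y_onehot).sum(axis=1)).mean())
    return nll + 0.5 * l2 * float((weights ** 2).sum())


def _smooth_gradient(weights: np.ndarray, intercepts: np.ndarray,
                     x: np.ndarray, y_onehot: np.ndarray,
                     l2: float) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    probs = _softmax(x @ weights.T + intercepts)
    resid = probs - y_onehot
    grad_w = resid.T @ x / n + l2 * weights
    grad_b = resid.mean(axis=0)
    return grad_w, grad_b


def penalized_objective(weights: np.ndarray, intercepts: np.ndarray,
                        x: np.ndarray, y_onehot: np.ndarray,
                        l1: float, l2: float) -> float:
    return _smooth_objective(weights, intercepts, x, y_onehot, l2) + l1 * float(np.abs(weights).sum())


def _soft_threshold(values: np.ndarray, amount: float) -> np.ndarray:
    return np.sign(values) * np.maximum(np.abs(values) - amount, 0.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = np.maximum(x.std(axis=0), SD_FLOOR)
    return (x - mean) / sd, mean, sd


def fit_mlr(expr: ExpressionMatrix, labels,
            l1: float = 0.0, l2: float = 0.0,
            optimizer: OptimizerConfig | None = None,
            seed: int = 0) -> MLRModel:
    """Fit the elastic-net softmax model by ISTA with backtracking.

    Deterministic given the data (the seed is recorded in the metadata for
    provenance; the zero initialization makes the fit seed-free).
    """
    if l1 < 0 or l2 < 0:
        raise ValidationError("l1 and l2 must be non-negative")
    config = optimizer or OptimizerConfig()
    series = calls_to_series(labels)
    missing = [s for s in expr.samples if s not in series.index]
    if missing:
        raise ValidationError(f"labels missing for samples: {missing[:10]}")
    y = series.loc[expr.samples]
    classes = tuple(sorted(y.unique()))
    if len(classes) < 2:
        raise ValidationError(f"need >=2 classes, got {classes}")

    x_raw = expr.values.to_numpy().T  # samples x genes
    x, mean, sd = _standardize_fit(x_raw)
    class_index = {c: i for i, c in enumerate(classes)}
    y_onehot = np.zeros((x.shape[0], len(classes)))
    y_onehot[np.arange(x.shape[0]), [class_index[c] for c in y]] = 1.0

    k, g = len(classes), x.shape[1]
    weights = np.zeros((k, g))
    intercepts = np.zeros(k)
    step = config.init_step
    objective = penalized_objective(weights, intercepts, x, y_onehot, l1, l2)
    trace = [objective]
    converged = False
    for _ in range(config.max_iter):
        grad_w, grad_b = _smooth_gradient(weights, intercepts, x, y_onehot, l2)
        f_current = _smooth_objective(weights, intercepts, x, y_onehot, l2)
        while True:
            new_w = _soft_threshold(weights - step * grad_w, step * l1)
            new_b = intercepts - step * grad_b
            dw = new_w - weights
            db = new_b - intercepts
            quad = (f_current + float((grad_w * dw).sum()) + float(grad_b @ db)
                    + (float((dw ** 2).sum()) + float(db @ db)) / (2.0 * step))
            f_new = _smooth_objective(new_w, new_b, x, y_onehot, l2)
            if f_new <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        weights, intercepts = new_w, new_b
        new_objective = f_new + l1 * float(np.abs(weights).sum())
        if not np.isfinite(new_objective):
            raise ValidationError("non-finite objective during optimization")
        trace.append(new_objective)
        if abs(objective - new_objective) <= config.tol * max(1.0, abs(new_objective)):
            objective = new_objective
            converged = True
            break
        objective = new_objective
        step *= 2.0  # allow the step to grow back after conservative phases
    if not converged:
        warnings.warn(
            f"mLR fit did not converge in {config.max_iter} iterations "
            f"(final objective {objective:.6g})", stacklevel=2,
        )
    return MLRModel(
        classes=classes,
        feature_genes=tuple(expr.genes),
        weights=weights,
        intercepts=intercepts,
        standardization=(mean, sd),
        hyperparams=(float(l1), float(l2)),
        fit_metadata={
            "seed": seed,
            "iterations": len(trace) - 1,
            "converged": converged,
            "final_objective": objective,
            "objective_trace": [float(v) for v in trace],
        },
    )


def predict_proba(model: MLRModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Softmax membership probabilities, samples x classes."""
    missing = [g for g in model.feature_genes if g not in set(expr.genes)]
    if missing:
        raise ValidationError(f"expression matrix lacks model feature genes: {missing[:10]}")
    x = expr.values.loc[list(model.feature_genes)].to_numpy().T
    mean, sd = model.standardization
    z = (x - mean) / sd
    # per-sample products keep predictions exactly independent of batch size
    probs = np.empty((z.shape[0], len(model.classes)))
    for j in range(z.shape[0]):
        logits = model.weights @ np.ascontiguousarray(z[j]) + model.intercepts
        probs[j] = _softmax(logits[None, :])[0]
    return pd.DataFrame(probs, index=expr.samples, columns=list(model.classes))


def predict_mlr(model: MLRModel, expr: ExpressionMatrix) -> list[SubtypeCall]:
    """Per-sample membership probabilities and arg-max call
    (alphabetical tie-break, matching the nearest-centroid convention)."""
    probs = predict_proba(model, expr)
    calls: list[SubtypeCall] = []
    for sample, row in probs.iterrows():
        best = row.max()
        call = min(cls for cls, v in row.items() if v == best)
        calls.append(SubtypeCall(
            sample_id=str(sample), call=call,
            correlations={cls: float(v) for cls, v in row.items()},
            score_type="membership",
        ))
    return calls


# ---------------------------------------------------------------------------
# cross-validation and model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    fold_assignments: Mapping[str, int]
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    sd_accuracy: float
    folds: int


def cross_validate(expr: ExpressionMatrix, labels, folds: int = 10,
                   l1: float = 0.0, l2: float = 0.0, seed: int = 0,
                   optimizer: OptimizerConfig | None = None) -> CVResult:
    """Seeded stratified k-fold accuracy; standardization refit per fold."""
    series = calls_to_series(labels).loc[expr.samples]
    min_count = series.value_counts().min()
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} samples; reducing folds from "
            f"{folds} to {min_count}", stacklevel=2,
        )
        folds = int(min_count)
    if folds < 2:
        raise ValidationError("cannot cross-validate with fewer than 2 folds")
    samples = np.asarray(expr.samples)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    accuracies: list[float] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(samples, series.to_numpy())):
        train_ids = list(samples[train_idx])
        test_ids = list(samples[test_idx])
        for s in test_ids:
            assignments[s] = fold
        model = fit_mlr(expr.subset_samples(train_ids), series.loc[train_ids],
                        l1=l1, l2=l2, optimizer=optimizer, seed=seed)
        calls = predict_mlr(model, expr.subset_samples(test_ids))
        truth = series.loc[test_ids]
        correct = sum(1 for c in calls if c.call == truth.loc[c.sample_id])
        accuracies.append(correct / len(test_ids))
    return CVResult(
        fold_assignments=assignments,
        fold_accuracies=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        sd_accuracy=float(np.std(accuracies, ddof=1)) if len(accuracies) > 1 else 0.0,
        folds=folds,
    )


def grid_search(expr: ExpressionMatrix, labels,
                l1_grid: Sequence[float] = (0.01, 0.1, 1.0),
                l2_grid: Sequence[float] = (0.01, 0.1, 1.0),
                folds: int = 10, seed: int = 0,
                optimizer: OptimizerConfig | None = None) -> tuple[MLRModel, pd.DataFrame]:
    """Evaluate every (l1, l2) cell by cross-validation, pick the best mean
    accuracy (ties to the smaller l1, then smaller l2), refit on all data."""
    if len(l1_grid) == 0 or len(l2_grid) == 0:
        raise ValidationError("hyperparameter grids must be non-empty")
    rows = []
    best: tuple[float, float, float] | None = None  # (-accuracy, l1, l2) minimized
    for l1 in l1_grid:
        for l2 in l2_grid:
            result = cross_validate(expr, labels, folds=folds, l1=l1, l2=l2,
                                    seed=seed, optimizer=optimizer)
            rows.append({"l1": l1, "l2": l2,
                         "mean_accuracy": result.mean_accuracy,
                         "sd_accuracy": result.sd_accuracy})
            key = (-result.mean_accuracy, float(l1), float(l2))
            if best is None or key < best:
                best = key
    report = pd.DataFrame(rows)
    _, l1_win, l2_win = best
    model = fit_mlr(expr, labels, l1=l1_win, l2=l2_win, optimizer=optimizer, seed=seed)
    return model, report


def cv_accuracy_trainer(l1: float = 0.1, l2: float = 0.1, folds: int = 5,
                        seed: int = 0, optimizer: OptimizerConfig | None = None):
    """Trainer contract for backward elimination: expression + labels ->
    cross-validated accuracy of the elastic-net softmax model."""
    def trainer(expr: ExpressionMatrix, labels) -> float:
        return cross_validate(expr, labels, folds=folds, l1=l1, l2=l2,
                              seed=seed, optimizer=optimizer).mean_accuracy
    return trainer
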