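"""Risk-of-recurrence (ROR) scoring downstream of subtype classification.

The ROR-C style score is a weighted sum of the per-class centroid
correlations plus a tumour-size term, optionally affinely rescaled, and
binned into low / intermediate / high risk groups.  Coefficients and
thresholds are configuration-supplied, never hard-coded: the published
Cox-model coefficients belong to the original assay authors and must be
transcribed by the user (see ``configs/ror_placeholder.yaml``).  The
Normal-like class is conventionally excluded from ROR weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .containers import CohortAnnotations, SubtypeCall, annotations_by_sample
from .errors import ValidationError


@dataclass(frozen=True)
class RORModel:
    """Weights, thresholds and optional rescaling for a ROR-style score."""

    class_weights: Mapping[str, float]
    tumor_size_weight: float = 0.0
    thresholds: tuple[float, float] = (40.0, 60.0)
    score_rescaling: tuple[float, float] | None = None  # (a, b): a * raw + b

    def __post_init__(self) -> None:
        low, high = self.thresholds
        if not low < high:
            raise ValidationError(f"thresholds must be strictly increasing, got {self.thresholds}")
        for cls, w in self.class_weights.items():
            if not np.isfinite(w):
                raise ValidationError(f"non-finite weight for class {cls!r}")


@dataclass(frozen=True)
class RORResult:
    sample_id: str
    score: float       # after optional affine rescaling
    risk_group: str    # "low" | "intermediate" | "high"


def _bin_score(score: float, thresholds: tuple[float, float]) -> str:
    # boundary values fall into the lower group
    low, high = thresholds
    if score <= low:
        return "low"
    if score <= high:
        return "intermediate"
    return "high"


def compute_ror(call: SubtypeCall, tumor_size: float | None, model: RORModel) -> RORResult:
    """Score one sample: sum(w_k * rho_k) + w_T * T, then rescale and bin."""
    missing = [cls for cls in model.class_weights if cls not in call.correlations]
    if missing:
        raise ValidationError(
            f"sample {call.sample_id!r}: no correlation for weighted class(es) {missing}"
        )
    raw = sum(w * call.correlations[cls] for cls, w in model.class_weights.items())
    if model.tumor_size_weight != 0.0:
        if tumor_size is None:
            raise ValidationError(
                f"sample {call.sample_id!r}: tumor size required (nonzero tumor_size_weight)"
            )
        raw += model.tumor_size_weight * tumor_size
    if model.score_rescaling is not None:
        a, b = model.score_rescaling
        raw = a * raw + b
    return RORResult(sample_id=call.sample_id, score=float(raw),
                     risk_group=_bin_score(float(raw), model.thresholds))


@dataclass(frozen=True)
class RORBatchResult:
    results: tuple[RORResult, ...]
    failures: tuple[tuple[str, str], ...]  # (sample_id, reason)


def ror_batch(calls: Sequence[SubtypeCall],
              annotations: Sequence[CohortAnnotations],
              model: RORModel) -> RORBatchResult:
    """Vectorized scoring; per-sample errors are collected, not dropped.

    Output order matches input order.
    """
    by_sample = annotations_by_sample(annotations)
    results: list[RORResult] = []
    failures: list[tuple[str, str]] = []
    for call in calls:
        ann = by_sample.get(call.sample_id)
        tumor_size = ann.tumor_size if ann is not None else None
        try:
            results.append(compute_ror(call, tumor_size, model))
        except ValidationError as exc:
            failures.append((call.sample_id, str(exc)))
    return RORBatchResult(results=tuple(results), failures=tuple(failures))


def ror_model_from_dict(config: Mapping) -> RORModel:
    """Build a RORModel from a parsed config mapping."""
    try:
        thresholds = tuple(float(v) for v in config["thresholds"])
        rescale = config.get("score_rescaling")
        return RORModel(
            class_weights={str(k): float(v) for k, v in config["class_weights"].items()},
            tumor_size_weight=float(config.get("tumor_size_weight", 0.0)),
            thresholds=(thresholds[0], thresholds[1]),
            score_rescaling=(float(rescale[0]), float(rescale[1])) if rescale is not None else None,
        )
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise ValidationError(f"malformed ROR model config: {exc}") from exc


def load_ror_model(path: str | Path) -> RORModel:
    """Load a ROR model from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return ror_model_from_dict(config.get("ror_model", config))
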