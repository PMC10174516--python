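"""Binary wrapper feature selection driven by any of the three optimizers.

Continuous optimizer positions binarize at the fixed 0.5 threshold (strict
inequality); a candidate mask is scored by the weighted sum of the holdout
misclassification rate of a named classifier and the relative subset size:
``fit = lambda * error + (1 - lambda) * |mask| / D``.  All-zero masks are
never fitted; they receive the penalty ``1 + lambda``, which exceeds any
feasible fitness.

Note on ranges: the headline configuration searches positions in ``[-1, 1]``
while the threshold stays at 0.5, so only the top quarter of the range selects
a feature; pass ``domain_range=(0, 1)`` on :class:`FitnessSpec` to override.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .aqo_core import AQOParams, run_aqo, run_hybrid
from .classifiers import ClassifierSpec, make_classifier
from .data_model import Dataset, SplitPair, train_test_split
from .exceptions import (
    EvaluationError,
    ParameterError,
    SchemaError,
    SelectionDegenerateError,
)
from .hgso_core import HGSOParams, OptimizationTrace, SearchSpace, run_hgso
from .evaluation import confusion, macro_metrics, MetricRecord

__all__ = [
    "FeatureMask",
    "FitnessSpec",
    "SelectionResult",
    "binarize",
    "subset_fitness",
    "make_objective",
    "select_features",
    "apply_mask",
]

BINARIZE_THRESHOLD = 0.5


@dataclass
class FeatureMask:
    """Boolean selection vector over the feature columns."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ParameterError("mask bits must be a 1-D vector")

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


@dataclass(frozen=True)
class FitnessSpec:
    """How a candidate mask is scored."""

    lambda_weight: float = 0.99
    classifier_name: str = "knn"
    classifier_seed: int = 0
    split_fraction: float = 0.8
    split_seed: int = 0
    domain_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ParameterError("lambda_weight must be in [0, 1]")


@dataclass
class SelectionResult:
    """Outcome of one wrapper-selection run."""

    best_mask: FeatureMask
    best_fitness: float
    trace: OptimizationTrace
    reduced_test_metrics: MetricRecord
    seed: int
    n_evaluations: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "mask": self.best_mask.to_string(),
                "n_selected": self.best_mask.count,
                "fitness": self.best_fitness,
                "seed": self.seed,
                "n_evaluations": self.n_evaluations,
                "test_accuracy": self.reduced_test_metrics.accuracy,
                "test_f_measure": self.reduced_test_metrics.f_measure,
            }
        )


def binarize(position: np.ndarray) -> FeatureMask:
    """Bit j is 1 iff position_j > 0.5 (strict, as printed)."""
    return FeatureMask(np.asarray(position, dtype=float) > BINARIZE_THRESHOLD)


def apply_mask(dataset: Dataset, mask: FeatureMask) -> Dataset:
    """Column-project a dataset onto the selected features, names preserved."""
    if mask.bits.size != dataset.n_features:
        raise SchemaError(
            f"mask length {mask.bits.size} != feature count {dataset.n_features}"
        )
    names = [n for n, b in zip(dataset.feature_names, mask.bits) if b]
    return Dataset(
        dataset.features[:, mask.bits], dataset.labels, names, dataset.class_names
    )


def subset_fitness(mask: FeatureMask, data: SplitPair, spec: FitnessSpec) -> float:
    """Weighted holdout-error + subset-size score of one mask.

    Empty masks return the penalty ``1 + lambda`` without fitting anything.
    """
    d = data.train.n_features
    lam = spec.lambda_weight
    if mask.count == 0:
        return 1.0 + lam
    try:
        handle = make_classifier(
            ClassifierSpec(spec.classifier_name, seed=spec.classifier_seed)
        )
        handle.fit(apply_mask(data.train, mask))
        predictions = handle.predict(apply_mask(data.test, mask).features)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending mask
        raise EvaluationError(
            f"classifier failed for mask {mask.to_string()}: {exc}"
        ) from exc
    error = float(
        np.mean(predictions.labels.astype(str) != data.test.labels.astype(str))
    )
    return lam * error + (1.0 - lam) * mask.count / d


def make_objective(data: SplitPair, spec: FitnessSpec):
    """Continuous objective = subset_fitness o binarize, memoized by mask bits.

    Returns ``(objective, cache)``; the cache maps mask strings to fitness, so
    positions that binarize identically cost one classifier fit in total.
    """
    cache: dict[str, float] = {}

    def objective(position: np.ndarray) -> float:
        mask = binarize(position)
        key = mask.to_string()
        if key not in cache:
            cache[key] = subset_fitness(mask, data, spec)
        return cache[key]

    return objective, cache


def select_features(
    dataset: Dataset,
    optimizer: str = "hgso",
    spec: FitnessSpec | None = None,
    params: HGSOParams | AQOParams | None = None,
    aqo_params: AQOParams | None = None,
) -> SelectionResult:
    """Run the end-to-end wrapper loop and score the winning mask on the holdout.

    ``optimizer`` is ``"hgso"``, ``"aqo"`` or ``"hybrid"`` (Aquila hand-off to
    the gas engine; supply ``aqo_params`` to tune the first stage).
    """
    spec = spec or FitnessSpec()
    split = train_test_split(
        dataset, fraction=spec.split_fraction, seed=spec.split_seed, stratified=True
    )
    if len(set(split.train.labels.astype(str))) < 2 or len(
        set(split.test.labels.astype(str))
    ) < 2:
        raise ParameterError("both split halves must contain >= 2 classes")
    objective, cache = make_objective(split, spec)
    space = SearchSpace(
        dataset.n_features, spec.domain_range[0], spec.domain_range[1]
    )
    if optimizer == "hgso":
        params = params or HGSOParams()
        best_pos, best_fit, trace = run_hgso(objective, space, params)
        seed = params.seed
    elif optimizer == "aqo":
        params = params or AQOParams()
        best_pos, best_fit, trace = run_aqo(objective, space, params)
        seed = params.seed
    elif optimizer == "hybrid":
        params = params or HGSOParams()
        aqo = aqo_params or AQOParams(seed=params.seed, max_iter=params.max_iter)
        best_pos, best_fit, trace = run_hybrid(objective, space, aqo, params)
        seed = params.seed
    else:
        raise ParameterError(f"unknown optimizer {optimizer!r}")

    best_mask = binarize(best_pos)
    if best_mask.count == 0:
        raise SelectionDegenerateError(
            "optimizer's best position binarizes to the all-zero mask", trace=trace
        )
    handle = make_classifier(
        ClassifierSpec(spec.classifier_name, seed=spec.classifier_seed)
    )
    handle.fit(apply_mask(split.train, best_mask))
    predictions = handle.predict(apply_mask(split.test, best_mask).features)
    cm = confusion(
        split.test.labels, predictions.labels, split.test.class_names
    )
    return SelectionResult(
        best_mask=best_mask,
        best_fitness=float(best_fit),
        trace=trace,
        reduced_test_metrics=macro_metrics(cm),
        seed=seed,
        n_evaluations=len(cache),
    )
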