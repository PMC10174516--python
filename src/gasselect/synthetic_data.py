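"""Synthetic neurosurgical-style tabular data with planted informative features.

Generates a 4-class outcome table whose informative columns are drawn from
class-conditional Gaussians (class centroids separated by a configurable
standardized effect size) and whose remaining columns are pure class-independent
noise.  A :class:`GroundTruth` sidecar records which columns carry signal so
that wrapper feature selection can be scored by recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_model import Dataset, min_max_scale, write_csv
from .exceptions import ParameterError

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "generate_dataset",
    "summarize_dataset",
    "write_generated",
    "DEFAULT_CLASS_NAMES",
]

DEFAULT_CLASS_NAMES = ("mortality", "morbidity", "the_same", "improved")

# feature-name prefixes cycle over the clinical schema's domain groups
_DOMAIN_GROUPS = ("history", "clinical", "lab", "radiology")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror the reference schema: 4 outcome classes with counts
    800/700/850/650 (3000 rows) and 37 features in total.
    """

    class_counts: tuple[int, ...] = (800, 700, 850, 650)
    n_informative: int = 12
    n_noise: int = 25
    effect_size: float = 2.0
    noise_scale: float = 1.0
    seed: int = 0
    domain_range: tuple[float, float] = (-1.0, 1.0)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    n_binary: int = 0  # noise columns discretized to 0/1 by latent thresholding

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(self.class_names):
            raise ParameterError("class_counts and class_names length mismatch")
        if any(c < 1 for c in self.class_counts):
            raise ParameterError("all class counts must be >= 1")
        if self.n_informative < 1 or self.n_noise < 0:
            raise ParameterError("need n_informative >= 1 and n_noise >= 0")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.noise_scale <= 0:
            raise ParameterError("noise_scale must be > 0")
        if not 0 <= self.n_binary <= self.n_noise:
            raise ParameterError("n_binary must be within the noise columns")


@dataclass
class GroundTruth:
    """Which generated columns carry class signal, and where the classes sit."""

    informative_mask: np.ndarray  # boolean over generated feature columns
    class_centroids: np.ndarray  # (n_classes, n_informative)

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_mask": [int(b) for b in self.informative_mask],
                "class_centroids": self.class_centroids.tolist(),
            }
        )


def _class_codes(n_classes: int, n_informative: int) -> np.ndarray:
    """A +-0.5 binary-code pattern so every class pair differs on some feature."""
    n_bits = max(1, math.ceil(math.log2(n_classes)))
    codes = np.empty((n_classes, n_informative))
    for c in range(n_classes):
        for j in range(n_informative):
            codes[c, j] = ((c >> (j % n_bits)) & 1) - 0.5
    return codes


def generate_dataset(spec: GeneratorSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset; bit-identical for identical specs (seed included)."""
    rng = np.random.default_rng(spec.seed)
    counts = np.asarray(spec.class_counts, dtype=int)
    n = int(counts.sum())
    if n == 0:
        raise ParameterError("zero total samples")
    n_classes = len(counts)
    d = spec.n_informative + spec.n_noise

    class_idx = np.repeat(np.arange(n_classes), counts)
    centroids = spec.effect_size * _class_codes(n_classes, spec.n_informative)
    informative = centroids[class_idx] + rng.standard_normal((n, spec.n_informative))
    noise = rng.normal(0.0, spec.noise_scale, size=(n, spec.n_noise))
    if spec.n_binary:
        # threshold the last n_binary latent noise columns at their median
        for j in range(spec.n_noise - spec.n_binary, spec.n_noise):
            noise[:, j] = (noise[:, j] > np.median(noise[:, j])).astype(float)

    # interleave informative columns among the noise at random positions
    col_perm = rng.permutation(d)
    informative_positions = np.sort(col_perm[: spec.n_informative])
    mask = np.zeros(d, dtype=bool)
    mask[informative_positions] = True
    features = np.empty((n, d))
    features[:, mask] = informative
    features[:, ~mask] = noise
    features = np.column_stack(
        [min_max_scale(features[:, j], spec.domain_range) for j in range(d)]
    )

    row_perm = rng.permutation(n)
    features = features[row_perm]
    labels = np.asarray([spec.class_names[c] for c in class_idx], dtype=object)[row_perm]
    names = [f"{_DOMAIN_GROUPS[j % len(_DOMAIN_GROUPS)]}_f{j:02d}" for j in range(d)]
    dataset = Dataset(features, labels, names, list(spec.class_names))
    return dataset, GroundTruth(mask, centroids)


def summarize_dataset(dataset: Dataset) -> dict:
    """Per-class counts, per-feature mean/SD, and max/min class balance ratio."""
    if dataset.n_samples == 0:
        raise ParameterError("empty dataset")
    labels = dataset.labels.astype(str)
    counts = {cls: int(np.sum(labels == str(cls))) for cls in dataset.class_names}
    present = [c for c in counts.values() if c > 0]
    return {
        "n_samples": dataset.n_samples,
        "n_features": dataset.n_features,
        "class_counts": counts,
        "balance_ratio": max(present) / min(present),
        "feature_means": dataset.features.mean(axis=0).tolist(),
        "feature_sds": dataset.features.std(axis=0).tolist(),
    }


def write_generated(
    spec: GeneratorSpec, out_csv: str | Path, *, label_column: str = "outcome"
) -> tuple[Path, Path]:
    """Generate and write the dataset CSV plus a ground-truth JSON sidecar."""
    dataset, truth = generate_dataset(spec)
    out_csv = Path(out_csv)
    write_csv(dataset, out_csv, label_column=label_column)
    sidecar = out_csv.with_suffix(".truth.json")
    payload = json.loads(truth.to_json())
    payload["spec"] = asdict(spec)
    sidecar.write_text(json.dumps(payload, indent=2))
    return out_csv, sidecar
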