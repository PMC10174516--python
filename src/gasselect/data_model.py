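"""Tabular dataset container, CSV I/O, declarative encoding and train/test splitting.

The core object is :class:`Dataset`: a fully numeric feature matrix with one
categorical outcome label per row.  Raw mixed-type tables are turned into a
``Dataset`` by :func:`encode_features` under a per-column rule file
(numeric passthrough, ordinal map, or one-hot), followed by per-column
min-max normalization into a configurable domain range (default ``[-1, 1]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EncodingError,
    ParseError,
    SchemaError,
    StratificationError,
    ParameterError,
)

__all__ = [
    "Dataset",
    "SplitPair",
    "EncodingRule",
    "load_csv",
    "write_csv",
    "encode_features",
    "min_max_scale",
    "train_test_split",
]


@dataclass
class Dataset:
    """A numeric feature table with categorical outcome labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Encoded, fully numeric feature values.
    labels : ndarray of shape (n_samples,)
        One class identifier per row.
    feature_names : sequence of str
        Column names, in feature-matrix order.
    class_names : sequence of str
        The full set of legal classes; every label must be a member.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_names = list(self.feature_names)
        self.class_names = list(self.class_names)
        if self.features.ndim != 2:
            raise SchemaError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise SchemaError(
                f"row mismatch: {self.features.shape[0]} feature rows vs "
                f"{self.labels.shape[0]} labels"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"column mismatch: {self.features.shape[1]} columns vs "
                f"{len(self.feature_names)} names"
            )
        if np.isnan(self.features).any():
            raise SchemaError("features contain missing values after encoding")
        unknown = set(map(str, self.labels)) - set(map(str, self.class_names))
        if unknown:
            raise SchemaError(f"labels not in class_names: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row-subset preserving the parent class universe."""
        return Dataset(
            self.features[idx],
            self.labels[idx],
            self.feature_names,
            self.class_names,
        )


@dataclass
class SplitPair:
    """An 80/20-style partition of a parent dataset."""

    train: Dataset
    test: Dataset
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ParameterError(f"fraction must be in (0,1), got {self.fraction}")


def load_csv(path: str | Path, label_column: str) -> Dataset:
    """Read an RFC-4180 CSV with a header row into a :class:`Dataset`.

    Every column except ``label_column`` is required to be numeric; an empty
    cell or a non-numeric cell raises :class:`ParseError` naming the row
    (0-based, excluding the header) and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} not in header {list(df.columns)}")
    labels = df[label_column].to_numpy(dtype=object)
    for i, v in enumerate(labels):
        if v == "":
            raise ParseError(f"empty cell at row {i}, column {label_column!r}")
    feats = df.drop(columns=[label_column])
    columns = []
    for name in feats.columns:
        raw = feats[name]
        empty = raw.to_numpy() == ""
        if empty.any():
            i = int(np.flatnonzero(empty)[0])
            raise ParseError(f"empty cell at row {i}, column {name!r}")
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna().to_numpy()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[i]!r} at row {i}, column {name!r}"
            )
        # python float() is correctly rounded; pd.to_numeric's fast path is not
        columns.append(np.array([float(v) for v in raw], dtype=float))
    features = np.column_stack(columns) if columns else np.empty((len(labels), 0))
    class_names = sorted(set(map(str, labels)))
    return Dataset(features, labels, list(feats.columns), class_names)


def write_csv(dataset: Dataset, path: str | Path, label_column: str = "outcome") -> None:
    """Write a dataset back to CSV; numeric values round-trip to full precision."""
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df[label_column] = dataset.labels
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


@dataclass(frozen=True)
class EncodingRule:
    """Declarative per-column encoding rule.

    kind is one of ``"numeric"`` (passthrough), ``"ordinal"`` (category ->
    number via ``mapping``) or ``"onehot"`` (one 0/1 column per category).
    """

    kind: str
    mapping: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "ordinal", "onehot"):
            raise EncodingError(f"unknown encoding kind {self.kind!r}")
        if self.kind == "ordinal" and not self.mapping:
            raise EncodingError("ordinal rule requires a mapping")


def _as_rule(rule) -> EncodingRule:
    if isinstance(rule, EncodingRule):
        return rule
    if isinstance(rule, str):
        return EncodingRule(rule)
    if isinstance(rule, Mapping):
        return EncodingRule(rule.get("kind", "numeric"), rule.get("mapping"))
    raise EncodingError(f"cannot interpret encoding rule {rule!r}")


def min_max_scale(
    column: np.ndarray, domain_range: tuple[float, float] = (-1.0, 1.0)
) -> np.ndarray:
    """Affinely map a column onto ``domain_range``; constant columns map to the midpoint."""
    lo, hi = float(domain_range[0]), float(domain_range[1])
    if not lo < hi:
        raise ParameterError(f"invalid domain range {domain_range}")
    cmin, cmax = float(np.min(column)), float(np.max(column))
    if cmax == cmin:
        return np.full_like(np.asarray(column, dtype=float), (lo + hi) / 2.0)
    return lo + (np.asarray(column, dtype=float) - cmin) * (hi - lo) / (cmax - cmin)


def encode_features(
    raw_table: pd.DataFrame,
    rules: Mapping[str, EncodingRule | Mapping | str],
    label_column: str,
    *,
    domain_range: tuple[float, float] = (-1.0, 1.0),
    normalize: bool = True,
    strict: bool = True,
    impute: str | None = None,
) -> Dataset:
    """Encode a mixed-type table into a fully numeric :class:`Dataset`.

    Every non-label column must have a rule in ``rules``.  After encoding,
    each column is min-max normalized into ``domain_range`` unless
    ``normalize=False``.  Missing values are rejected unless ``impute`` is
    ``"median"`` or ``"mode"`` (simple strategies only).  An unseen category
    under ``strict=True`` raises :class:`EncodingError`.
    """
    if label_column not in raw_table.columns:
        raise SchemaError(f"label column {label_column!r} missing")
    labels = raw_table[label_column].astype(str).to_numpy(dtype=object)
    names: list[str] = []
    columns: list[np.ndarray] = []
    for name in raw_table.columns:
        if name == label_column:
            continue
        if name not in rules:
            raise EncodingError(f"no encoding rule for column {name!r}")
        rule = _as_rule(rules[name])
        raw = raw_table[name]
        if rule.kind == "numeric":
            num = pd.to_numeric(raw, errors="coerce")
            columns.append(_fill(num.to_numpy(dtype=float), name, impute, kind="numeric"))
            names.append(str(name))
        elif rule.kind == "ordinal":
            mapped = raw.astype(str).map({str(k): float(v) for k, v in rule.mapping.items()})
            vals = mapped.to_numpy(dtype=float)
            if np.isnan(vals).any():
                unseen = sorted(set(raw.astype(str)[mapped.isna()]))
                if strict:
                    raise EncodingError(f"unseen categories {unseen} in column {name!r}")
            columns.append(_fill(vals, name, impute, kind="ordinal"))
            names.append(str(name))
        else:  # onehot
            cats = sorted(set(raw.astype(str)))
            for cat in cats:
                columns.append((raw.astype(str) == cat).to_numpy(dtype=float))
                names.append(f"{name}={cat}")
    features = np.column_stack(columns) if columns else np.empty((len(labels), 0))
    if normalize:
        features = np.column_stack(
            [min_max_scale(features[:, j], domain_range) for j in range(features.shape[1])]
        ) if features.shape[1] else features
    class_names = sorted(set(map(str, labels)))
    return Dataset(features, labels, names, class_names)


def _fill(values: np.ndarray, name, impute: str | None, kind: str) -> np.ndarray:
    bad = np.isnan(values)
    if not bad.any():
        return values
    if impute is None:
        i = int(np.flatnonzero(bad)[0])
        raise EncodingError(f"missing/unparseable value at row {i}, column {name!r}")
    good = values[~bad]
    if good.size == 0:
        raise EncodingError(f"column {name!r} has no usable values")
    if impute == "median":
        fill = float(np.median(good))
    elif impute == "mode":
        vals, counts = np.unique(good, return_counts=True)
        fill = float(vals[np.argmax(counts)])
    else:
        raise EncodingError(f"unknown impute strategy {impute!r}")
    out = values.copy()
    out[bad] = fill
    return out


def _largest_remainder(counts: np.ndarray, total: int, fraction: float) -> np.ndarray:
    """Allocate ``total`` across classes proportionally to ``fraction * counts``."""
    target = fraction * counts
    base = np.floor(target).astype(int)
    short = total - int(base.sum())
    if short < 0:  # fraction*counts summed above total due to rounding of total
        order = np.argsort(target - base, kind="stable")
        for c in order[: -short]:
            base[c] -= 1
        return base
    # hand the remainder to the largest fractional parts, class order breaking ties
    order = np.argsort(-(target - base), kind="stable")
    for c in order[:short]:
        base[c] += 1
    return base


def train_test_split(
    dataset: Dataset,
    fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPair:
    """Deterministic train/test split; train size is ``round(fraction * n)``.

    Stratified mode (the default, matching the 4-class balanced design)
    preserves per-class proportions within one sample.  The underlying
    permutation depends only on ``seed``, and the prefix/suffix selection rule
    flips at ``fraction = 0.5``, so splitting at ``f`` and ``1 - f`` with the
    same seed yields complementary partitions (train/test roles swapped).
    """
    n = dataset.n_samples
    if not (0.0 < fraction < 1.0):
        raise ParameterError(f"fraction must be in (0,1), got {fraction}")
    k_train = int(round(fraction * n))
    if k_train in (0, n):
        raise ParameterError("fraction leaves one side of the split empty")
    rng = np.random.default_rng(seed)
    if stratified:
        class_members: list[np.ndarray] = []
        counts = []
        for cls in dataset.class_names:
            members = np.flatnonzero(dataset.labels.astype(str) == str(cls))
            if members.size == 1:
                raise StratificationError(
                    f"class {cls!r} has a single sample; cannot stratify"
                )
            class_members.append(rng.permutation(members))
            counts.append(members.size)
        counts = np.array(counts, dtype=int)
        if fraction >= 0.5:
            test_alloc = _largest_remainder(counts, n - k_train, 1.0 - fraction)
            train_alloc = counts - test_alloc
            take_prefix = True
        else:
            train_alloc = _largest_remainder(counts, k_train, fraction)
            take_prefix = False
        train_parts, test_parts = [], []
        for members, k_c in zip(class_members, train_alloc):
            if take_prefix:
                train_parts.append(members[:k_c])
                test_parts.append(members[k_c:])
            else:
                split_at = members.size - k_c
                train_parts.append(members[split_at:])
                test_parts.append(members[:split_at])
        train_idx = np.concatenate(train_parts)
        test_idx = np.concatenate(test_parts)
    else:
        perm = rng.permutation(n)
        if fraction >= 0.5:
            train_idx, test_idx = perm[:k_train], perm[k_train:]
        else:
            train_idx, test_idx = perm[n - k_train:], perm[: n - k_train]
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    return SplitPair(
        dataset.subset(train_idx), dataset.subset(test_idx), fraction, seed
    )
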