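"""Discretization and information-theoretic statistics.

All quantities are plug-in (maximum-likelihood) estimates on empirical
frequencies of integer-coded columns, in bits (log base 2).  The relevance
score used throughout the selector is the symmetric uncertainty

    R(X, Y) = 2 * IG(X; Y) / (H(X) + H(Y)),   R in [0, 1],

where IG(X;Y) = H(X) + H(Y) - H(X,Y) is the mutual information.  R = 1 iff
the two variables determine each other; R = 0 under empirical independence.

Entropy sums are accumulated over canonically sorted count tables so that
``info_gain(x, y) == info_gain(y, x)`` holds bit-for-bit, not just to
rounding: the multiset of joint counts is identical under argument swap, so
sorting fixes the floating-point summation order.

Continuous columns are discretized before any entropy is computed; class
labels are categorical already and are never binned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("fsbrr")

__all__ = [
    "BinningSpec",
    "DiscreteVector",
    "DiscretizedTable",
    "discretize",
    "discretize_table",
    "entropy",
    "conditional_entropy",
    "joint_entropy",
    "info_gain",
    "normalized_relevance",
]

_METHODS = ("equal_width", "equal_frequency", "none")


@dataclass(frozen=True)
class BinningSpec:
    """How continuous feature columns are mapped to integer category codes.

    ``method="none"`` asserts the input is already integer-coded and passes
    it through.  ``equal_width`` splits [min, max] into ``n_bins`` half-open
    intervals with the last interval closed; ``equal_frequency`` uses
    empirical quantile boundaries.
    """

    method: str = "equal_width"
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown binning method {self.method!r}")
        if self.method != "none" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True, eq=False)
class DiscreteVector:
    """A column of dense non-negative integer category codes.

    ``cardinality`` is the number of distinct observed categories and every
    code is < cardinality (codes are densified at construction, preserving
    the sorted order of the original values, which leaves every entropy
    unchanged).
    """

    codes: np.ndarray
    cardinality: int

    @classmethod
    def from_codes(cls, values) -> "DiscreteVector":
        arr = np.asarray(values)
        if arr.size == 0:
            raise ValueError("empty vector")
        uniques, dense = np.unique(arr, return_inverse=True)
        return cls(codes=dense.astype(np.int64), cardinality=len(uniques))

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class DiscretizedTable:
    """A feature table after binning: the domain of all entropy computations."""

    feature_ids: list[str]
    features: list[DiscreteVector]
    class_codes: DiscreteVector

    @property
    def n_features(self) -> int:
        return len(self.features)


def discretize(column, spec: BinningSpec) -> DiscreteVector:
    """Bin one real-valued column to integer codes according to ``spec``.

    Deterministic.  Constant columns map to the single code 0.  Raises on
    non-finite values, and on non-integer input when ``method="none"``.
    """
    arr = np.asarray(column, dtype=float)
    if arr.size == 0:
        raise ValueError("empty column")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in column")
    if spec.method == "none":
        if not np.all(arr == np.floor(arr)):
            raise ValueError("method 'none' requires integer-coded input")
        return DiscreteVector.from_codes(arr.astype(np.int64))
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        return DiscreteVector(codes=np.zeros(arr.size, dtype=np.int64), cardinality=1)
    if spec.method == "equal_width":
        edges = np.linspace(lo, hi, spec.n_bins + 1)
        codes = np.searchsorted(edges, arr, side="right") - 1
        np.clip(codes, 0, spec.n_bins - 1, out=codes)  # closes the last bin
    else:  # equal_frequency
        codes = pd.qcut(arr, spec.n_bins, labels=False, duplicates="drop")
        codes = np.asarray(codes, dtype=np.int64)
    return DiscreteVector.from_codes(codes)


def discretize_table(table, spec: BinningSpec) -> DiscretizedTable:
    """Discretize every feature column of a FeatureTable; factor the labels.

    Class labels are categorical and are never binned — they are mapped to
    dense codes directly.
    """
    features = [discretize(table.values[:, k], spec) for k in range(table.n_features)]
    class_codes = DiscreteVector.from_codes(
        pd.factorize(np.asarray(table.class_labels), sort=True)[0]
    )
    return DiscretizedTable(
        feature_ids=list(table.feature_ids),
        features=features,
        class_codes=class_codes,
    )


def _entropy_from_counts(counts: np.ndarray) -> float:
    """H in bits from a flat array of non-negative counts (0 log 0 = 0).

    Counts are sorted ascending before accumulation to pin the summation
    order independently of how the table was laid out.
    """
    c = counts[counts > 0]
    if c.size == 0:
        raise ValueError("empty vector")
    p = np.sort(c) / c.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_counts(x: DiscreteVector, y: DiscreteVector) -> np.ndarray:
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    joint = x.codes.astype(np.int64) * y.cardinality + y.codes
    return np.bincount(joint, minlength=x.cardinality * y.cardinality).reshape(
        x.cardinality, y.cardinality
    )


def entropy(x: DiscreteVector) -> float:
    """Shannon entropy H(X) in bits over empirical frequencies."""
    return _entropy_from_counts(np.bincount(x.codes, minlength=x.cardinality))


def joint_entropy(x: DiscreteVector, y: DiscreteVector) -> float:
    """H(X,Y) in bits; satisfies max(H(X),H(Y)) <= H(X,Y) <= H(X)+H(Y)."""
    return _entropy_from_counts(_joint_counts(x, y).ravel())


def conditional_entropy(x: DiscreteVector, y: DiscreteVector) -> float:
    """H(X|Y) = -sum_j p(y_j) sum_i p(x_i|y_j) log2 p(x_i|y_j), in bits."""
    counts = _joint_counts(x, y)
    n = counts.sum()
    total = 0.0
    for j in range(counts.shape[1]):
        col = counts[:, j]
        ny = col.sum()
        if ny == 0:
            continue
        p_cond = np.sort(col[col > 0]) / ny
        total += (ny / n) * float(-(p_cond * np.log2(p_cond)).sum())
    return total


def info_gain(x: DiscreteVector, y: DiscreteVector) -> float:
    """Mutual information IG(X;Y) = H(X) + H(Y) - H(X,Y), in bits.

    Non-negative and symmetric in its arguments; equals H(X) - H(X|Y) up to
    floating-point rounding.
    """
    ig = entropy(x) + entropy(y) - joint_entropy(x, y)
    return max(ig, 0.0)


def normalized_relevance(x: DiscreteVector, y: DiscreteVector) -> float:
    """Symmetric uncertainty R = 2*IG(X;Y)/(H(X)+H(Y)), clipped to [0, 1].

    When both variables are constant (H(X)+H(Y) = 0) the statistic is
    defined as 0: constants carry no usable relevance.
    """
    hx, hy = entropy(x), entropy(y)
    denom = hx + hy
    if denom == 0.0:
        return 0.0
    r = 2.0 * info_gain(x, y) / denom
    return min(max(r, 0.0), 1.0)
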