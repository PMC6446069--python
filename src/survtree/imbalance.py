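"""Class balancing for the one-vs-rest nodes: SMOTE, oversampling, cost weights.

One-vs-rest binarization of six very unequal classes leaves each node badly
imbalanced (down to 6 positives vs 341 negatives), so the training portion of
each fold can be balanced by synthetic minority oversampling (SMOTE), random
oversampling with replacement, or per-sample cost weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_warned_k: set[tuple[int, int]] = set()  # (requested k, minority size) already warned


@dataclass
class BalanceSpec:
    """How to balance a node's training data.

    target_ratio is the desired minority/majority count after balancing; the
    2x2 cost matrix (rows = true class, cols = predicted) is used only by the
    cost-sensitive path, with None meaning the class-frequency-equalizing
    default.
    """

    method: str = "smote"  # {smote, oversample, cost_sensitive, none}
    smote_k: int = 5
    target_ratio: float = 1.0
    cost_matrix: list[list[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("smote", "oversample", "cost_sensitive", "none"):
            raise ValueError(f"unknown balance method {self.method!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")
        if self.cost_matrix is not None:
            m = np.asarray(self.cost_matrix, dtype=float)
            if m.shape != (2, 2) or m[0, 0] != 0 or m[1, 1] != 0 or (m < 0).any():
                raise ValueError("cost_matrix must be 2x2, non-negative, zero diagonal")


def smote(
    minority: np.ndarray,
    k: int,
    n_synthetic: int,
    seed: int,
) -> np.ndarray:
    """Synthetic minority oversampling: interpolate toward k-nearest neighbors.

    Each synthetic point is x + u * (nn - x) with x a uniformly chosen minority
    sample, nn one of its k nearest minority neighbors (Euclidean) and
    u ~ Uniform(0, 1).
    """
    minority = np.atleast_2d(np.asarray(minority, dtype=float))
    n_min = minority.shape[0]
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if k >= n_min:
        raise ValueError(
            f"smote_k={k} must be below the minority count {n_min}; lower k "
            f"(e.g. k <= {n_min - 1})"
        )
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    rng = np.random.default_rng(seed)
    dist = cdist(minority, minority)
    np.fill_diagonal(dist, np.inf)
    # deterministic neighbor lists: distance then index
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]
    base = rng.integers(0, n_min, size=n_synthetic)
    picked = neighbors[base, rng.integers(0, k, size=n_synthetic)]
    u = rng.uniform(0.0, 1.0, size=(n_synthetic, 1))
    return minority[base] + u * (minority[picked] - minority[base])


def random_oversample(minority_indices: np.ndarray, n_extra: int, seed: int) -> np.ndarray:
    """Indices sampled with replacement from the minority class."""
    minority_indices = np.asarray(minority_indices)
    if minority_indices.size == 0:
        raise ValueError("empty minority class")
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    rng = np.random.default_rng(seed)
    return minority_indices[rng.integers(0, minority_indices.size, size=n_extra)]


def cost_weights(labels: np.ndarray, cost_matrix: np.ndarray | None = None) -> np.ndarray:
    """Per-sample weights from a misclassification-cost matrix.

    A sample of true class c weighs cost_matrix[c, 1-c] (the cost of
    misclassifying c).  The default matrix charges 1 for majority errors and
    majority/minority for minority errors, which equalizes the total weight of
    the two classes (minority/majority weight ratio = count ratio).
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if cost_matrix is None:
        cost_matrix = np.array(
            [[0.0, max(1.0, counts[1] / counts[0])], [max(1.0, counts[0] / counts[1]), 0.0]]
        )
    cost_matrix = np.asarray(cost_matrix, dtype=float)
    return np.where(labels == 0, cost_matrix[0, 1], cost_matrix[1, 0])


@dataclass
class BalancedTraining:
    """Balanced training arrays plus provenance of each row."""

    X: np.ndarray
    y: np.ndarray
    sample_weight: np.ndarray | None
    is_synthetic: np.ndarray = field(default=None)  # True for rows not in the input


def balance_training(
    X: np.ndarray,
    y: np.ndarray,
    spec: BalanceSpec,
    seed: int,
) -> BalancedTraining:
    """Apply the configured balancing to one training set (binary labels 0/1).

    Majority rows are never altered; smote_k is reduced (with a warning) when
    the minority class is too small for the requested neighbor count, as happens
    for the 6-sample deceased-hormone class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    minority_label = int(np.argmin(counts))
    n_min, n_maj = counts[minority_label], counts[1 - minority_label]
    none_result = BalancedTraining(X, y, None, np.zeros(y.size, dtype=bool))

    if spec.method == "none" or n_min == 0 or n_min == n_maj:
        return none_result
    if spec.method == "cost_sensitive":
        m = np.asarray(spec.cost_matrix, dtype=float) if spec.cost_matrix is not None else None
        return BalancedTraining(X, y, cost_weights(y, m), np.zeros(y.size, dtype=bool))

    n_target = int(round(spec.target_ratio * n_maj))
    n_extra = max(0, n_target - n_min)
    if n_extra == 0:
        return none_result
    minority_mask = y == minority_label

    if spec.method == "smote":
        if n_min < 2:
            logger.warning("minority class has <2 samples; falling back to oversampling")
            extra = X[minority_mask][
                random_oversample(np.arange(n_min), n_extra, seed)
            ]
        else:
            k = spec.smote_k
            if k >= n_min:
                k = n_min - 1
                if (spec.smote_k, n_min) not in _warned_k:
                    _warned_k.add((spec.smote_k, n_min))
                    logger.warning("reducing smote_k to %d for minority of %d samples", k, n_min)
            extra = smote(X[minority_mask], k, n_extra, seed)
    else:  # oversample
        idx = random_oversample(np.flatnonzero(minority_mask), n_extra, seed)
        extra = X[idx]

    Xb = np.vstack([X, extra])
    yb = np.concatenate([y, np.full(n_extra, minority_label, dtype=int)])
    synthetic = np.concatenate([np.zeros(y.size, dtype=bool), np.ones(n_extra, dtype=bool)])
    return BalancedTraining(Xb, yb, None, synthetic)
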