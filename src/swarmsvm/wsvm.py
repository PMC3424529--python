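"""Weighted RBF-kernel support vector machine.

The classifier is a soft-margin SVM whose RBF kernel rescales each gene's
contribution to the squared distance by a non-negative weight:

    K'(x_i, x_j) = exp(-gamma * sum_k alpha_k (x_ik - x_jk)^2),
    alpha_k >= 0,  sum_k alpha_k = 1.

Setting a weight to zero removes that gene from the decision geometry
entirely; uniform weights alpha_k = 1/d recover the standard RBF kernel at
width gamma/d, which makes the unweighted SVM the degenerate case of this
machine.  The kernel is a valid (PSD) RBF in the rescaled coordinates
sqrt(alpha_k) * x_k for any non-negative weights.

The quadratic program itself is delegated to scikit-learn's SVC through its
precomputed-kernel interface; the decision function is

    f(x) = sign( sum_i L_i y_i K'(x_i, x) + b ),

with a decision value of exactly zero mapped to +1 (fixed convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "KernelParams",
    "WeightVector",
    "TrainedModel",
    "weighted_rbf_kernel",
    "weighted_rbf_gram",
    "train_wsvm",
    "predict",
]

#: tolerance on the sum-to-one constraint of a weight vector
_WEIGHT_SUM_TOL = 1e-9


@dataclass
class KernelParams:
    """RBF width ``gamma`` and soft-margin penalty ``C`` (both > 0)."""

    C: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.C = float(self.C)
        self.gamma = float(self.gamma)
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass
class WeightVector:
    """Per-gene non-negative weights summing to one."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1:
            raise ValueError("alpha must be a 1-d vector")
        if np.any(self.alpha < 0):
            raise ValueError("weights must be non-negative")
        total = self.alpha.sum()
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(f"weights must sum to 1 (got {total!r})")

    @classmethod
    def uniform(cls, n_genes: int) -> "WeightVector":
        return cls(np.full(n_genes, 1.0 / n_genes))

    @property
    def n_genes(self) -> int:
        return self.alpha.size

    def surviving_indices(self) -> np.ndarray:
        """Indices of genes with strictly positive weight."""
        return np.flatnonzero(self.alpha > 0)


def _alpha_of(weights) -> np.ndarray:
    if isinstance(weights, WeightVector):
        return weights.alpha
    return np.asarray(weights, dtype=float)


def weighted_rbf_kernel(xi, xj, weights, gamma: float) -> float:
    """Scalar weighted RBF kernel between two gene vectors; value in (0, 1]."""
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    alpha = _alpha_of(weights)
    if not (xi.shape == xj.shape == alpha.shape):
        raise ValueError(
            f"dimension mismatch: xi {xi.shape}, xj {xj.shape}, weights {alpha.shape}"
        )
    d2 = float((alpha * (xi - xj) ** 2).sum())
    return float(np.exp(-gamma * d2))


def weighted_rbf_gram(X, Y, weights, gamma: float) -> np.ndarray:
    """Weighted RBF kernel matrix between the rows of X and Y.

    Pass ``Y=None`` for the training Gram matrix; in that case the result is
    made exactly symmetric with a unit diagonal.
    """
    X = np.asarray(X, dtype=float)
    alpha = _alpha_of(weights)
    if X.shape[1] != alpha.size:
        raise ValueError(f"X has {X.shape[1]} genes but weights have {alpha.size}")
    root = np.sqrt(alpha)
    Z = X * root
    zsq = (Z * Z).sum(axis=1)
    if Y is None:
        D = zsq[:, None] + zsq[None, :] - 2.0 * (Z @ Z.T)
        np.maximum(D, 0.0, out=D)
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
    else:
        Y = np.asarray(Y, dtype=float)
        if Y.shape[1] != alpha.size:
            raise ValueError(f"Y has {Y.shape[1]} genes but weights have {alpha.size}")
        W = Y * root
        wsq = (W * W).sum(axis=1)
        D = zsq[:, None] + wsq[None, :] - 2.0 * (Z @ W.T)
        np.maximum(D, 0.0, out=D)
    return np.exp(-gamma * D)


@dataclass
class TrainedModel:
    """A fitted weighted SVM.

    ``dual_coefficients[i]`` is the product L_i * y_i for the i-th support
    sample; magnitudes are bounded by C.  ``support_vectors`` holds the
    corresponding rows of the training matrix so the model is self-contained
    for prediction and serialization.
    """

    support_sample_indices: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    params: KernelParams
    weights: WeightVector
    training_gene_ids: list
    support_vectors: np.ndarray
    support_decision_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def decision_function(self, samples) -> np.ndarray:
        X = np.atleast_2d(np.asarray(samples, dtype=float))
        if X.shape[1] != len(self.training_gene_ids):
            raise ValueError(
                f"samples have {X.shape[1]} genes; model was trained on "
                f"{len(self.training_gene_ids)}"
            )
        K = weighted_rbf_gram(X, self.support_vectors, self.weights, self.params.gamma)
        return K @ self.dual_coefficients + self.bias

    def predict(self, samples) -> np.ndarray:
        """Predicted labels in {+1, -1}; decision value 0 maps to +1."""
        return np.where(self.decision_function(samples) >= 0.0, 1, -1)

    def save(self, path) -> None:
        """Serialize to a self-describing JSON file (exact round trip)."""
        payload = {
            "format": "swarmsvm-model",
            "version": 1,
            "C": self.params.C,
            "gamma": self.params.gamma,
            "bias": self.bias,
            "alpha": self.weights.alpha.tolist(),
            "training_gene_ids": list(self.training_gene_ids),
            "support_sample_indices": self.support_sample_indices.tolist(),
            "dual_coefficients": self.dual_coefficients.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "support_decision_values": self.support_decision_values.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "swarmsvm-model":
            raise ValueError(f"{path} is not a swarmsvm model file")
        return cls(
            support_sample_indices=np.asarray(
                payload["support_sample_indices"], dtype=int
            ),
            dual_coefficients=np.asarray(payload["dual_coefficients"], dtype=float),
            bias=float(payload["bias"]),
            params=KernelParams(C=payload["C"], gamma=payload["gamma"]),
            weights=WeightVector(np.asarray(payload["alpha"], dtype=float)),
            training_gene_ids=list(payload["training_gene_ids"]),
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            support_decision_values=np.asarray(
                payload["support_decision_values"], dtype=float
            ),
        )


def train_wsvm(train, weights, params: KernelParams) -> TrainedModel:
    """Fit the weighted SVM on an :class:`~swarmsvm.datasets.ExpressionDataset`.

    Solves the standard soft-margin dual with the weighted RBF Gram matrix.
    Requires both classes in the training labels.
    """
    weights = weights if isinstance(weights, WeightVector) else WeightVector(weights)
    if weights.n_genes != train.n_genes:
        raise ValueError(
            f"weight vector has {weights.n_genes} entries for {train.n_genes} genes"
        )
    if np.unique(train.labels).size < 2:
        raise ValueError("training requires samples from both classes")

    K = weighted_rbf_gram(train.matrix, None, weights, params.gamma)
    svc = SVC(C=params.C, kernel="precomputed")
    try:
        svc.fit(K, train.labels)
    except Exception as exc:  # pragma: no cover - solver failures are rare
        raise RuntimeError(
            f"SVM solver failed on the weighted Gram matrix "
            f"(C={params.C}, gamma={params.gamma}): {exc}"
        ) from exc

    support = svc.support_.astype(int)
    decision = svc.decision_function(K)
    return TrainedModel(
        support_sample_indices=support.copy(),
        dual_coefficients=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        params=params,
        weights=weights,
        training_gene_ids=list(train.gene_ids),
        support_vectors=train.matrix[support].copy(),
        support_decision_values=decision[support].copy(),
    )


def predict(model: TrainedModel, samples) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values for a matrix of samples."""
    decision = model.decision_function(samples)
    return np.where(decision >= 0.0, 1, -1), decision
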