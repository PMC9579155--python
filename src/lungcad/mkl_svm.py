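"""Multi-kernel soft-margin SVM.

The kernel is the convex combination

    K_mix(x, y) = gamma * (x.y + 1)^d + (1 - gamma) * exp(-||x-y||^2 / (2 g^2))

of a polynomial kernel (order d, default 3) and an RBF kernel (width g).
Both summands are positive semidefinite, so any convex mixture is a valid
kernel.  Training solves the standard soft-margin dual on the precomputed
mixed Gram matrix; the fitted model records its dual coefficients, bias and
the worst Karush-Kuhn-Tucker (KKT) violation as a convergence certificate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "KernelParams",
    "MklSvmModel",
    "kernel_poly",
    "kernel_rbf",
    "kernel_mix",
    "gram_mix",
    "svm_train",
    "svm_predict",
    "dual_objective",
]


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the mixed-kernel SVM.

    C: soft-margin regularization (> 0); g: RBF width (> 0); gamma: mixture
    weight of the polynomial kernel in [0, 1]; d: polynomial order (>= 1,
    fixed at 3 in the tuned pipeline).
    """

    C: float = 1.0
    g: float = 1.0
    gamma: float = 0.5
    d: int = 3

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.g <= 0:
            raise ValueError("g must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.d < 1 or int(self.d) != self.d:
            raise ValueError("d must be a positive integer")


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x, y = np.atleast_2d(np.asarray(x, float)), np.atleast_2d(np.asarray(y, float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("vectors must have equal length")
    return x, y


def kernel_poly(x, y, d: int = 3) -> np.ndarray | float:
    """Polynomial kernel (x.y + 1)^d; accepts vectors or sample matrices."""
    if d < 1:
        raise ValueError("d must be >= 1")
    x2, y2 = _pair(x, y)
    k = (x2 @ y2.T + 1.0) ** d
    return float(k[0, 0]) if k.size == 1 else k


def kernel_rbf(x, y, g: float = 1.0) -> np.ndarray | float:
    """Gaussian RBF kernel exp(-||x-y||^2 / (2 g^2))."""
    if g <= 0:
        raise ValueError("g must be positive")
    x2, y2 = _pair(x, y)
    k = np.exp(-cdist(x2, y2, "sqeuclidean") / (2.0 * g * g))
    return float(k[0, 0]) if k.size == 1 else k


def kernel_mix(x, y, params: KernelParams) -> np.ndarray | float:
    """Convex mixture gamma*poly + (1-gamma)*rbf."""
    return params.gamma * kernel_poly(x, y, params.d) + \
        (1.0 - params.gamma) * kernel_rbf(x, y, params.g)


def gram_mix(x, y, params: KernelParams) -> np.ndarray:
    """Mixed-kernel Gram matrix between two sample sets (always 2-D)."""
    x2, y2 = _pair(x, y)
    return params.gamma * (x2 @ y2.T + 1.0) ** params.d + \
        (1.0 - params.gamma) * np.exp(-cdist(x2, y2, "sqeuclidean") / (2 * params.g**2))


@dataclass
class MklSvmModel:
    """A trained mixed-kernel SVM (dual form)."""

    support_vectors: np.ndarray     # n_sv x p
    dual_coef: np.ndarray           # alpha_i * y_i over support vectors
    bias: float
    params: KernelParams
    kkt_residual: float
    support_indices: np.ndarray | None = None  # indices into the training set

    def to_json(self) -> str:
        return json.dumps({
            "params": {"C": self.params.C, "g": self.params.g,
                       "gamma": self.params.gamma, "d": self.params.d},
            "bias": self.bias,
            "kkt_residual": self.kkt_residual,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "MklSvmModel":
        obj = json.loads(text)
        return cls(
            support_vectors=np.asarray(obj["support_vectors"], float),
            dual_coef=np.asarray(obj["dual_coef"], float),
            bias=float(obj["bias"]),
            params=KernelParams(**obj["params"]),
            kkt_residual=float(obj["kkt_residual"]),
        )


def _kkt_residual(k: np.ndarray, y: np.ndarray, alpha_signed: np.ndarray,
                  bias: float, c: float) -> float:
    """Worst violation of the soft-margin KKT conditions over training points."""
    f = k @ alpha_signed + bias
    margins = y * f
    alpha = np.abs(alpha_signed)
    at_zero = alpha <= 1e-9 * c
    at_c = alpha >= (1.0 - 1e-9) * c
    interior = ~(at_zero | at_c)
    viol = np.zeros_like(margins)
    viol[at_zero] = np.maximum(0.0, 1.0 - margins[at_zero])
    viol[interior] = np.abs(1.0 - margins[interior])
    viol[at_c] = np.maximum(0.0, margins[at_c] - 1.0)
    return float(viol.max()) if viol.size else 0.0


def svm_train(x, y, params: KernelParams, tol: float = 1e-8,
              max_iter: int = -1) -> MklSvmModel:
    """Train the soft-margin SVM on the precomputed mixed Gram matrix.

    Labels must be in {-1, +1} with both classes present.  The bias comes
    from the solver's averaging over unbounded support vectors; the returned
    ``kkt_residual`` is recomputed directly from the dual solution, so a
    run truncated by ``max_iter`` is visible in the model it produces.
    """
    from .fusion import FeatureBlock  # local import avoids a cycle
    if isinstance(x, FeatureBlock):
        x = x.matrix
    x = np.asarray(x, float)
    y = np.asarray(y)
    if x.ndim != 2 or not np.all(np.isfinite(x)):
        raise ValueError("features must be a finite 2-D array")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must be in {-1, +1} with both classes present")

    k = gram_mix(x, x, params)
    clf = SVC(C=params.C, kernel="precomputed", tol=tol, cache_size=200,
              max_iter=max_iter)
    clf.fit(k, y)
    sv_idx = clf.support_
    alpha_signed_full = np.zeros(x.shape[0])
    alpha_signed_full[sv_idx] = clf.dual_coef_.ravel()
    residual = _kkt_residual(k, y.astype(float), alpha_signed_full,
                             float(clf.intercept_[0]), params.C)
    return MklSvmModel(
        support_vectors=x[sv_idx],
        dual_coef=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        params=params,
        kkt_residual=residual,
        support_indices=np.asarray(sv_idx, dtype=int),
    )


def svm_predict(model: MklSvmModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and decision values for new samples.

    decision(x) = sum_i alpha_i y_i K_mix(sv_i, x) + b; labels are the sign
    of the decision value (ties to +1).  Decision values feed the ROC curve.
    """
    from .fusion import FeatureBlock
    if isinstance(x, FeatureBlock):
        x = x.matrix
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("feature-dimension mismatch with the trained model")
    dec = gram_mix(x, model.support_vectors, model.params) @ model.dual_coef + model.bias
    labels = np.where(dec >= 0, 1, -1)
    return labels, dec


def dual_objective(k: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Soft-margin dual objective sum(alpha) - 1/2 (alpha*y)' K (alpha*y)."""
    az = alpha * y
    return float(alpha.sum() - 0.5 * az @ k @ az)
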