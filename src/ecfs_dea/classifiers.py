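"""Uniform contract over the four base classifiers (LDA, kNN, SVM, RF).

The importance engine and the ensemble only ever see :func:`fit` and
``FittedClassifier.predict``; the scikit-learn estimators behind them are an
implementation detail. Defaults: kNN k=5 (Euclidean distance on raw expression
values, no scaling), SVM with RBF kernel and cost 1, RF with 100 trees per
forest, LDA parameter-free (the svd solver tolerates near-singular within-class
scatter, which keeps degenerate resamples alive). LDA/kNN/SVM are deterministic
regardless of the seed; RF is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

VALID_KINDS = ("lda", "knn", "svm", "rf")
_SVM_KERNELS = ("linear", "poly", "rbf", "sigmoid")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "lda": {},
    "knn": {"k": 5},
    "svm": {"kernel": "rbf", "cost": 1.0},
    "rf": {"trees": 100},
}


@dataclass(frozen=True)
class BaseClassifierSpec:
    """Kind + hyperparameters of a base classifier."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        object.__setattr__(self, "kind", kind)
        if kind not in VALID_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {VALID_KINDS}")
        merged = {**_DEFAULTS[kind], **self.params}
        unknown = set(merged) - set(_DEFAULTS[kind])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {kind}: {sorted(unknown)}")
        if kind == "knn" and (int(merged["k"]) < 1):
            raise ValueError("kNN needs k >= 1")
        if kind == "rf" and (int(merged["trees"]) < 1):
            raise ValueError("RF needs trees >= 1")
        if kind == "svm":
            if merged["cost"] <= 0:
                raise ValueError("SVM needs cost > 0")
            if merged["kernel"] not in _SVM_KERNELS:
                raise ValueError(f"SVM kernel must be one of {_SVM_KERNELS}")
        object.__setattr__(self, "params", merged)


@dataclass
class FittedClassifier:
    """A fitted base classifier restricted to a fixed variable count."""

    spec: BaseClassifierSpec
    estimator: Any
    n_variables: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_variables:
            raise ValueError(
                f"expected 2-D input with {self.n_variables} variables, got shape {X.shape}"
            )
        return np.asarray(self.estimator.predict(X), dtype=np.int64)


def _build(spec: BaseClassifierSpec, seed: int):
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=int(spec.params["k"]))
    if spec.kind == "svm":
        return SVC(kernel=spec.params["kernel"], C=float(spec.params["cost"]))
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(spec.params["trees"]), random_state=int(seed) % (2**32)
        )
    raise AssertionError(spec.kind)


def fit(spec: BaseClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedClassifier:
    """Fit one base classifier on (X, y) with y in {0, 1}.

    Deterministic given (spec, X, y, seed); the seed only matters for RF.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if p < 1:
        raise ValueError("at least one variable is required")
    if n < 2 or len(np.unique(y)) != 2:
        raise ValueError("training data must contain >= 2 samples from both classes")
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    est = _build(spec, seed)
    est.fit(X, y)
    return FittedClassifier(spec, est, p)


def classification_error(model: FittedClassifier, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of misclassified samples."""
    y = np.asarray(y, dtype=np.int64)
    return float(np.mean(model.predict(X) != y))
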