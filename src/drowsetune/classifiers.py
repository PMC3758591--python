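"""Base drowsiness classifiers: backprop ANN, SVM with sigmoid map, kNN.

Each classifier maps a 4*n-value relative-energy pattern to the probability
that the pattern is drowsy:

* the neural network emits a single logistic output trained against 1
  (drowsy) / 0 (non-drowsy) targets with mean-squared-error backprop;
* the support vector machine's decision value f(x) is squashed through the
  fixed sigmoid P = 1 / (1 + exp(-f(x)));
* the k-nearest-neighbour probability is the fraction of drowsy patterns
  among the k Euclidean-nearest reference patterns.

All three serialize to JSON so a trained detector round-trips through the
command line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "AnnClassifier",
    "SvmClassifier",
    "KnnClassifier",
    "train_ann",
    "ann_prob",
    "train_svm",
    "svm_prob",
    "knn_prob",
    "SVM_KERNELS",
]

#: kernel names accepted for the SVM, mapped to sklearn's spellings
SVM_KERNELS: dict[str, str] = {
    "linear": "linear",
    "polynomial": "poly",
    "rbf": "rbf",
    "sigmoid": "sigmoid",
}


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            "training data must contain both classes labelled 0 (non-drowsy) "
            f"and 1 (drowsy); got classes {classes.tolist()}"
        )
    return y


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AnnClassifier:
    """Fully connected feed-forward network with logistic units throughout.

    Architecture: input 4n -> ``hidden_layers`` hidden layers of 2*4n units
    each -> one logistic output.  Trained by full-batch gradient descent on
    the mean-squared error against 0/1 targets, with a fixed learning rate
    and classical momentum; training stops at ``epochs`` or when the loss
    improvement drops below ``tol``.
    """

    def __init__(
        self,
        hidden_layers: int = 3,
        epochs: int = 800,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        tol: float = 1e-9,
        seed: int = 0,
    ):
        if hidden_layers < 1:
            raise ValueError("hidden_layers must be at least 1")
        self.hidden_layers = hidden_layers
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.tol = tol
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.loss_curve_: list[float] = []

    @property
    def layer_sizes_(self) -> list[int]:
        if self.weights_ is None:
            raise ValueError("classifier is not fitted")
        return [self.weights_[0].shape[0]] + [w.shape[1] for w in self.weights_]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AnnClassifier":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y).astype(float)
        rng = np.random.default_rng(self.seed)
        d = X.shape[1]
        sizes = [d] + [2 * d] * self.hidden_layers + [1]
        # Xavier-style uniform init keeps logistic units away from saturation
        self.weights_ = []
        self.biases_ = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights_.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))
        vel_w = [np.zeros_like(w) for w in self.weights_]
        vel_b = [np.zeros_like(b) for b in self.biases_]
        target = y[:, None]
        m = X.shape[0]
        self.loss_curve_ = []
        prev_loss = np.inf
        for _ in range(self.epochs):
            # forward pass
            acts = [X]
            for w, b in zip(self.weights_, self.biases_):
                acts.append(_logistic(acts[-1] @ w + b))
            out = acts[-1]
            loss = float(np.mean((out - target) ** 2))
            self.loss_curve_.append(loss)
            if prev_loss - loss < self.tol and prev_loss >= loss:
                break
            prev_loss = loss
            # backward pass: dL/dout * logistic'
            delta = (2.0 / m) * (out - target) * out * (1 - out)
            for li in range(len(self.weights_) - 1, -1, -1):
                grad_w = acts[li].T @ delta
                grad_b = delta.sum(axis=0)
                if li > 0:
                    a = acts[li]
                    delta = (delta @ self.weights_[li].T) * a * (1 - a)
                vel_w[li] = self.momentum * vel_w[li] - self.learning_rate * grad_w
                vel_b[li] = self.momentum * vel_b[li] - self.learning_rate * grad_b
                self.weights_[li] += vel_w[li]
                self.biases_[li] += vel_b[li]
        return self

    @property
    def final_loss_(self) -> float:
        if not self.loss_curve_:
            raise ValueError("classifier is not fitted")
        return self.loss_curve_[-1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights_[0].shape[0]:
            raise ValueError(
                f"pattern has {X.shape[1]} values but the network expects "
                f"{self.weights_[0].shape[0]}"
            )
        a = X
        for w, b in zip(self.weights_, self.biases_):
            a = _logistic(a @ w + b)
        return a.ravel()

    def to_dict(self) -> dict:
        if self.weights_ is None:
            raise ValueError("classifier is not fitted")
        return {
            "kind": "ann",
            "hidden_layers": self.hidden_layers,
            "weights": [w.tolist() for w in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnClassifier":
        obj = cls(hidden_layers=d["hidden_layers"])
        obj.weights_ = [np.array(w) for w in d["weights"]]
        obj.biases_ = [np.array(b) for b in d["biases"]]
        return obj


class SvmClassifier:
    """Soft-margin SVM whose decision value feeds the fixed sigmoid.

    The probability is 1 / (1 + exp(-f(x))) with f the signed distance to
    the separating hyperplane, oriented so f(x) > 0 on the drowsy side.
    No Platt scaling is fitted: the slope and offset are fixed at 1 and 0.
    """

    def __init__(self, kernel: str = "polynomial", degree: int = 3, C: float = 1.0):
        if kernel not in SVM_KERNELS:
            raise ValueError(
                f"kernel must be one of {sorted(SVM_KERNELS)}, got {kernel!r}"
            )
        self.kernel = kernel
        self.degree = degree
        self.C = C
        self._svc: SVC | None = None
        # kept after fit for serialization / standalone evaluation
        self.support_vectors_: np.ndarray | None = None
        self.dual_coef_: np.ndarray | None = None
        self.intercept_: float | None = None
        self.gamma_: float | None = None
        self.coef0_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SvmClassifier":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        var = X.var()
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]
        svc = SVC(kernel=SVM_KERNELS[self.kernel], degree=self.degree, C=self.C,
                  gamma=gamma, coef0=1.0 if self.kernel == "polynomial" else 0.0)
        svc.fit(X, y)
        self._svc = svc
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_.copy()
        self.intercept_ = float(svc.intercept_[0])
        self.gamma_ = gamma
        self.coef0_ = float(svc.coef0)
        return self

    def _kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        sv = self.support_vectors_
        if self.kernel == "linear":
            return X @ sv.T
        if self.kernel == "polynomial":
            return (self.gamma_ * (X @ sv.T) + self.coef0_) ** self.degree
        if self.kernel == "rbf":
            return np.exp(-self.gamma_ * cdist(X, sv, "sqeuclidean"))
        return np.tanh(self.gamma_ * (X @ sv.T) + self.coef0_)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x); positive values fall on the drowsy side."""
        if self.support_vectors_ is None:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = self._kernel_matrix(X)
        return K @ self.dual_coef_.ravel() + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _logistic(self.decision_function(X))

    def to_dict(self) -> dict:
        if self.support_vectors_ is None:
            raise ValueError("classifier is not fitted")
        return {
            "kind": "svm",
            "kernel": self.kernel,
            "degree": self.degree,
            "C": self.C,
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "gamma": self.gamma_,
            "coef0": self.coef0_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmClassifier":
        obj = cls(kernel=d["kernel"], degree=d["degree"], C=d["C"])
        obj.support_vectors_ = np.array(d["support_vectors"])
        obj.dual_coef_ = np.array(d["dual_coef"])
        obj.intercept_ = d["intercept"]
        obj.gamma_ = d["gamma"]
        obj.coef0_ = d["coef0"]
        return obj


@dataclass
class KnnClassifier:
    """k-nearest-neighbour drowsy-probability estimator.

    The probability of a query pattern is the fraction of drowsy patterns
    among its k Euclidean-nearest reference patterns.  Distance ties at the
    k-th neighbour are broken by stable reference order.
    """

    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be an odd positive integer")
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).astype(int).ravel()
        if X.shape[0] == 0:
            raise ValueError("reference set must be non-empty")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds reference size {X.shape[0]}")
        self.X_ = X
        self.y_ = y
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.X_ is None:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = cdist(X, self.X_)
        # stable argsort keeps input order among equidistant neighbours
        nearest = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return self.y_[nearest].mean(axis=1)

    def to_dict(self) -> dict:
        if self.X_ is None:
            raise ValueError("classifier is not fitted")
        return {
            "kind": "knn",
            "k": self.k,
            "reference": self.X_.tolist(),
            "labels": self.y_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnnClassifier":
        obj = cls(k=d["k"])
        obj.fit(np.array(d["reference"]), np.array(d["labels"]))
        return obj


def classifier_from_dict(d: dict):
    kinds = {"ann": AnnClassifier, "svm": SvmClassifier, "knn": KnnClassifier}
    try:
        cls = kinds[d["kind"]]
    except KeyError:
        raise ValueError(f"unknown classifier kind {d.get('kind')!r}") from None
    return cls.from_dict(d)


def save_classifier(clf, path) -> None:
    with open(path, "w") as fh:
        json.dump(clf.to_dict(), fh)


def load_classifier(path):
    with open(path) as fh:
        return classifier_from_dict(json.load(fh))


# -- thin functional aliases matching the pipeline vocabulary ---------------

def train_ann(X, y, hidden_layers: int = 3, epochs: int = 800,
              learning_rate: float = 0.5, seed: int = 0) -> AnnClassifier:
    """Train the backprop network; deterministic for a fixed seed."""
    return AnnClassifier(hidden_layers=hidden_layers, epochs=epochs,
                         learning_rate=learning_rate, seed=seed).fit(X, y)


def ann_prob(model: AnnClassifier, pattern) -> np.ndarray:
    return model.predict_proba(pattern)


def train_svm(X, y, kernel: str = "polynomial", degree: int = 3) -> SvmClassifier:
    return SvmClassifier(kernel=kernel, degree=degree).fit(X, y)


def svm_prob(model: SvmClassifier, pattern) -> np.ndarray:
    return model.predict_proba(pattern)


def knn_prob(model: KnnClassifier, pattern) -> np.ndarray:
    return model.predict_proba(pattern)
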