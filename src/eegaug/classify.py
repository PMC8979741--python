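"""Binary valence/arousal classifiers: linear-kernel SVM and the
512-256-128 DNN.

The DNN is the fixed architecture input -> 512 -> 256 -> 128 -> dropout ->
1, ReLU hidden activations, sigmoid output thresholded at 0.5, trained with
binary cross-entropy and Adam.  The SVM is a thin wrapper around
scikit-learn's SVC with a linear kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._mlp import MLP, Adam

__all__ = [
    "SVMSpec",
    "DNNSpec",
    "DNNClassifier",
    "train_svm",
    "train_dnn",
    "evaluate_accuracy",
]


@dataclass(frozen=True)
class SVMSpec:
    kernel: str = "linear"
    C: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass(frozen=True)
class DNNSpec:
    hidden: tuple[int, ...] = (512, 256, 128)
    dropout: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("epochs", "batch_size"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training labels contain a single class ({classes.tolist()}); "
            "need both 0 and 1"
        )
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return y


def train_svm(X: np.ndarray, y: np.ndarray, spec: SVMSpec = SVMSpec()):
    """Fit a linear-kernel SVM; deterministic given data and spec."""
    from sklearn.svm import SVC

    spec.validate()
    y = _check_labels(y)
    clf = SVC(kernel=spec.kernel, C=spec.C, random_state=spec.seed)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


class DivergenceError(RuntimeError):
    """DNN training produced a non-finite loss."""


class DNNClassifier:
    """Feed-forward binary classifier with the fixed 512/256/128 topology.

    ``predict_proba`` returns the sigmoid output; ``predict`` thresholds it
    at 0.5.  Dropout (after the last hidden layer) is active only during
    training, so inference is deterministic.
    """

    def __init__(self, spec: DNNSpec = DNNSpec()):
        spec.validate()
        self.spec = spec
        self.net_: MLP | None = None
        self.loss_history_: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        if self.net_ is None:
            raise RuntimeError("model is not fitted")
        return self.net_.n_parameters

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DNNClassifier":
        spec = self.spec
        X = np.asarray(X, dtype=float)
        y = _check_labels(y)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n, d) with one label per row")
        n, d = X.shape
        rng = np.random.default_rng(spec.seed)
        net = MLP((d, *spec.hidden, 1), rng, dropout=spec.dropout)
        opt = Adam(net.parameters(), lr=spec.learning_rate)
        B = spec.batch_size
        losses = []
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, B):
                idx = order[start : start + B]
                xb, yb = X[idx], y[idx][:, None]
                logits, cache = net.forward(xb, train=True, rng=rng)
                p = 1.0 / (1.0 + np.exp(-logits))
                eps = 1e-12
                loss = float(
                    -(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)).mean()
                )
                if not np.isfinite(loss):
                    raise DivergenceError("non-finite training loss")
                epoch_loss += loss * idx.size
                dlogits = (p - yb) / idx.size
                dWs, dbs, _ = net.backward(cache, dlogits)
                opt.step(dWs + dbs)
            losses.append(epoch_loss / n)
        self.net_ = net
        self.loss_history_ = np.asarray(losses)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("model is not fitted")
        logits, _ = self.net_.forward(np.asarray(X, dtype=float))
        return (1.0 / (1.0 + np.exp(-logits))).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)


def train_dnn(X: np.ndarray, y: np.ndarray, spec: DNNSpec = DNNSpec()) -> DNNClassifier:
    """Fit the DNN classifier; reproducible under a fixed seed."""
    return DNNClassifier(spec).fit(X, y)


def evaluate_accuracy(classifier, X: np.ndarray, y: np.ndarray) -> float:
    """Percentage of correct predictions: ``100 * correct / total``."""
    y = np.asarray(y).astype(int).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation set")
    pred = np.asarray(classifier.predict(np.asarray(X, dtype=float))).ravel()
    return float(100.0 * np.mean(pred == y))
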