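"""Seven-class activity classifier: a sequential feed-forward network.

The model maps a binary ECFP4 fingerprint to a probability distribution over
the seven pChEMBL activity classes. Architecture follows the standard
sequential recipe for this task: dense hidden layers with ReLU activations,
a softmax output layer, categorical cross-entropy loss, and stochastic
minibatch gradient descent with the Adam (adaptive moment estimation)
update rule. Training is fully seeded: weight initialization and epoch
shuffling both derive from ``NNModelSpec.seed``, so a single-threaded run
is bit-reproducible.

The implementation is pure NumPy, which keeps the training loop transparent
and deterministic; at fingerprint-sized inputs and the dataset sizes used
here it trains in seconds to minutes on one CPU core.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

N_CLASSES = 7


@dataclass(frozen=True)
class NNModelSpec:
    """Hyperparameters of the sequential activity classifier.

    Defaults mirror the published training protocol: 1000 epochs for a full
    fit (loss and accuracy typically stabilize after ~200), 100 epochs when
    averaging over repeated runs, batch size 32, Adam at learning rate 1e-3.
    Hidden topology [512, 128] is a configurable choice.
    """

    input_width: int = 2048
    hidden_layers: tuple[int, ...] = (512, 128)
    output_classes: int = N_CLASSES
    learning_rate: float = 1e-3
    epochs: int = 1000
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_classes != N_CLASSES:
            raise ValueError("the classifier is defined for exactly 7 classes")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.input_width < 1 or any(w < 1 for w in self.hidden_layers):
            raise ValueError("all layer widths must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        # tolerate lists from JSON round-trips
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))


@dataclass
class EvalResult:
    """Evaluation of a model on a labeled set.

    ``loss`` is the mean per-sample categorical cross-entropy of the
    predicted distributions against one-hot labels; ``accuracy`` is top-1
    agreement (argmax ties broken toward the lower class index);
    ``confusion`` is the 7×7 count table with true classes as rows.
    """

    loss: float
    accuracy: float
    confusion: np.ndarray

    def __post_init__(self) -> None:
        total = self.confusion.sum()
        if total:
            assert abs(self.accuracy - np.trace(self.confusion) / total) < 1e-9


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def categorical_cross_entropy(
    proba: np.ndarray, classes: np.ndarray, eps: float = 1e-12
) -> float:
    """Mean per-sample cross-entropy of predicted distributions vs labels 1–7."""
    idx = np.asarray(classes, dtype=np.int64) - 1
    p = np.clip(proba[np.arange(len(idx)), idx], eps, 1.0)
    return float(-np.mean(np.log(p)))


class ActivityClassifier:
    """Sequential ReLU/softmax network trained with Adam.

    Build with :meth:`build`; prediction is available immediately on the
    seeded initial weights, before any training.
    """

    def __init__(self, spec: NNModelSpec, weights: list[np.ndarray],
                 biases: list[np.ndarray]):
        self.spec = spec
        self.weights = weights
        self.biases = biases
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # -- construction --------------------------------------------------

    @classmethod
    def build(cls, spec: NNModelSpec) -> "ActivityClassifier":
        """Initialize parameters from the seeded He-uniform scheme."""
        rng = np.random.default_rng(spec.seed)
        widths = [spec.input_width, *spec.hidden_layers, spec.output_classes]
        weights, biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / fan_in)
            weights.append(
                rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float64)
            )
            biases.append(np.zeros(fan_out))
        return cls(spec, weights, biases)

    # -- forward / backward --------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        activations = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = _relu(h @ W + b)
            activations.append(h)
        proba = _softmax(h @ self.weights[-1] + self.biases[-1])
        return proba, activations

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-compound probability distribution over the 7 classes."""
        X = self._check_input(X)
        if X.shape[0] == 0:
            return np.zeros((0, self.spec.output_classes))
        proba, _ = self._forward(X)
        return proba

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Top-1 class labels in 1..7 (argmax, ties toward the lower class)."""
        return np.argmax(self.predict_proba(X), axis=1) + 1

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.spec.input_width:
            raise ValueError(
                f"expected input of width {self.spec.input_width}, "
                f"got shape {X.shape}"
            )
        return X

    # -- training ------------------------------------------------------

    def train(
        self,
        X: np.ndarray,
        classes: Sequence[int] | np.ndarray,
        epochs: int | None = None,
    ) -> "ActivityClassifier":
        """Fit on fingerprints ``X`` and activity classes 1–7.

        Minimizes categorical cross-entropy by minibatch Adam; one history
        entry (full-training-set loss and accuracy) is appended per epoch.
        Returns self.
        """
        X = self._check_input(X)
        y = np.asarray(classes, dtype=np.int64)
        if len(y) == 0:
            raise ValueError("training set is empty")
        if y.min() < 1 or y.max() > N_CLASSES:
            raise ValueError("classes must lie in 1..7")
        if len(y) != X.shape[0]:
            raise ValueError("X and classes length mismatch")
        n_epochs = self.spec.epochs if epochs is None else epochs
        if n_epochs < 1:
            raise ValueError("epochs must be >= 1")

        onehot = np.zeros((len(y), self.spec.output_classes))
        onehot[np.arange(len(y)), y - 1] = 1.0

        rng = np.random.default_rng(self.spec.seed + 1)
        lr = self.spec.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        n = X.shape[0]
        bs = min(self.spec.batch_size, n)

        for _ in range(n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                batch = order[start : start + bs]
                Xb, Yb = X[batch], onehot[batch]
                proba, acts = self._forward(Xb)
                grads = self._gradients(proba, Yb, acts)
                t += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            proba, _ = self._forward(X)
            self.history["loss"].append(categorical_cross_entropy(proba, y))
            self.history["accuracy"].append(
                float(np.mean(np.argmax(proba, axis=1) + 1 == y))
            )
        return self

    def _gradients(
        self, proba: np.ndarray, onehot: np.ndarray, acts: list[np.ndarray]
    ) -> list[np.ndarray]:
        # softmax + cross-entropy: output delta is (p - y)/batch
        nb = proba.shape[0]
        delta = (proba - onehot) / nb
        w_grads: list[np.ndarray] = []
        b_grads: list[np.ndarray] = []
        for layer in range(len(self.weights) - 1, -1, -1):
            w_grads.append(acts[layer].T @ delta)
            b_grads.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        return w_grads[::-1] + b_grads[::-1]

    # -- evaluation ----------------------------------------------------

    def evaluate(
        self, X: np.ndarray, classes: Sequence[int] | np.ndarray
    ) -> EvalResult:
        """Loss, accuracy and confusion table on a labeled validation set."""
        y = np.asarray(classes, dtype=np.int64)
        if len(y) == 0:
            raise ValueError("validation set is empty")
        proba = self.predict_proba(X)
        return evaluate_predictions(proba, y)

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Serialize spec (JSON), weights (npz) and history (CSV) to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "spec.json").write_text(json.dumps(asdict(self.spec), indent=2))
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez_compressed(directory / "weights.npz", **arrays)
        with open(directory / "history.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss", "accuracy"])
            for i, (l, a) in enumerate(
                zip(self.history["loss"], self.history["accuracy"]), start=1
            ):
                writer.writerow([i, l, a])
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ActivityClassifier":
        directory = Path(directory)
        raw = json.loads((directory / "spec.json").read_text())
        raw["hidden_layers"] = tuple(raw["hidden_layers"])
        spec = NNModelSpec(**raw)
        data = np.load(directory / "weights.npz")
        n_layers = len(spec.hidden_layers) + 1
        model = cls(
            spec,
            [data[f"W{i}"] for i in range(n_layers)],
            [data[f"b{i}"] for i in range(n_layers)],
        )
        hist_path = directory / "history.csv"
        if hist_path.exists():
            with open(hist_path) as fh:
                for row in csv.DictReader(fh):
                    model.history["loss"].append(float(row["loss"]))
                    model.history["accuracy"].append(float(row["accuracy"]))
        return model


def evaluate_predictions(proba: np.ndarray, classes: np.ndarray) -> EvalResult:
    """Score a matrix of predicted class distributions against labels 1–7."""
    y = np.asarray(classes, dtype=np.int64)
    if proba.shape[0] != len(y):
        raise ValueError("predictions and labels length mismatch")
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = np.argmax(proba, axis=1) + 1
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for truth, guess in zip(y, pred):
        confusion[truth - 1, guess - 1] += 1
    return EvalResult(
        loss=categorical_cross_entropy(proba, y),
        accuracy=float(np.mean(pred == y)),
        confusion=confusion,
    )
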