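"""Shared train / score / classify interface over the three classifiers.

The evaluation protocol treats classifiers as factories: zero-argument
callables returning an unfitted object with ``fit(sequences, labels)``,
``scores(sequences)`` (a ranking score, higher = more amyloidogenic) and
``classify(sequences)``. Models serialize to a JSON file with a ``kind``
tag so a single loader can dispatch.
"""

from __future__ import annotations

import json
from collections.abc import Sequence

import numpy as np

from . import adtree, baselines


class ADTreeClassifier:
    """Alternating decision tree with the standard hyperparameters."""

    def __init__(self, iterations: int = 50, smoothing: float = 1.0):
        self.iterations = iterations
        self.smoothing = smoothing
        self.model: adtree.ADTreeModel | None = None
        self.name = f"ADTree {iterations}"

    def fit(self, sequences: Sequence[str], labels: Sequence[bool]) -> "ADTreeClassifier":
        self.model = adtree.train_adtree(
            (sequences, labels), iterations=self.iterations, smoothing=self.smoothing
        )
        return self

    def scores(self, sequences: Sequence[str]) -> np.ndarray:
        return self.model.predict_proba(sequences)

    def classify(self, sequences: Sequence[str]) -> np.ndarray:
        return self.model.predict(sequences)


class NaiveBayesClassifier:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self.model: baselines.NaiveBayesModel | None = None
        self.name = "Naive Bayes"

    def fit(self, sequences, labels) -> "NaiveBayesClassifier":
        self.model = baselines.train_naive_bayes((sequences, labels), alpha=self.alpha)
        return self

    def scores(self, sequences) -> np.ndarray:
        return self.model.predict_proba(sequences)

    def classify(self, sequences) -> np.ndarray:
        return self.model.predict(sequences)


class MLPClassifier:
    def __init__(
        self,
        hidden: int = 60,
        lr: float = 0.1,
        momentum: float = 0.2,
        epochs: int = 500,
        seed: int = 0,
    ):
        self.params = dict(
            hidden=hidden, lr=lr, momentum=momentum, epochs=epochs, seed=seed
        )
        self.model: baselines.MLPModel | None = None
        self.name = "MLP"

    def fit(self, sequences, labels) -> "MLPClassifier":
        self.model = baselines.train_mlp((sequences, labels), **self.params)
        return self

    def scores(self, sequences) -> np.ndarray:
        return self.model.predict_proba(sequences)

    def classify(self, sequences) -> np.ndarray:
        return self.model.predict(sequences)


def save_model(clf, path) -> None:
    """Serialize a fitted classifier's model to a JSON file."""
    if clf.model is None:
        raise ValueError("classifier is not fitted")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(clf.model.to_dict(), fh, indent=1)


def load_model(path):
    """Load any saved model; returns a fitted classifier wrapper."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind == "adtree":
        clf = ADTreeClassifier(
            iterations=int(payload["iterations"]), smoothing=float(payload["smoothing"])
        )
        clf.model = adtree.ADTreeModel.from_dict(payload)
    elif kind == "naive_bayes":
        clf = NaiveBayesClassifier(alpha=float(payload["alpha"]))
        clf.model = baselines.NaiveBayesModel.from_dict(payload)
    elif kind == "mlp":
        clf = MLPClassifier(**payload["config"])
        clf.model = baselines.MLPModel.from_dict(payload)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return clf


def factory_from_spec(spec: str, seed: int = 0):
    """Build a classifier factory from a short name like 'adtree50'.

    Recognized: adtree<N>, adtree (=50), nb, mlp[:epochs].
    """
    spec = spec.strip().lower()
    if spec.startswith("adtree"):
        iters = int(spec[6:]) if len(spec) > 6 else 50
        return lambda: ADTreeClassifier(iterations=iters)
    if spec in {"nb", "naivebayes", "naive_bayes"}:
        return lambda: NaiveBayesClassifier()
    if spec.startswith("mlp"):
        epochs = int(spec.split(":", 1)[1]) if ":" in spec else 500
        return lambda: MLPClassifier(epochs=epochs, seed=seed)
    raise ValueError(f"unknown classifier spec {spec!r}")
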