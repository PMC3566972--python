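"""Categorical Naive Bayes and a one-hidden-layer perceptron.

Both classifiers consume 6-residue sequences. Naive Bayes treats the six
positions as independent categorical attributes with Laplace smoothing.
The perceptron consumes a 120-dimensional one-hot encoding (6 positions x
20 residues), has one hidden layer of logistic units and a single
logistic output trained by per-instance stochastic gradient descent with
momentum on squared error — the classical configuration for this task
(60 hidden units, learning rate 0.1, momentum 0.2, 500 epochs, seeded
uniform init in [-0.5, 0.5]).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .alphabet import AA_INDEX, AMINO_ACIDS
from .hexdata import HexDataset, validate_hexapeptide

N_POSITIONS = 6
N_RESIDUES = len(AMINO_ACIDS)
N_FEATURES = N_POSITIONS * N_RESIDUES


# ---------------------------------------------------------------------------
# encoding


def encode(peptide: str) -> np.ndarray:
    """One-hot encode a hexapeptide: 6 blocks of 20, exactly one set each."""
    validate_hexapeptide(peptide, allow_cysteine=True)
    vec = np.zeros(N_FEATURES)
    for p, ch in enumerate(peptide):
        vec[N_RESIDUES * p + AA_INDEX[ch]] = 1.0
    return vec


def decode(vector: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    vector = np.asarray(vector).reshape(N_POSITIONS, N_RESIDUES)
    if not np.all(vector.sum(axis=1) == 1.0):
        raise ValueError("not a valid one-hot hexapeptide encoding")
    return "".join(AMINO_ACIDS[int(j)] for j in vector.argmax(axis=1))


def encode_many(peptides: Sequence[str]) -> np.ndarray:
    return np.array([encode(p) for p in peptides])


def _split_input(
    train: HexDataset | tuple[Sequence[str], Sequence[bool]],
) -> tuple[list[str], np.ndarray]:
    if isinstance(train, HexDataset):
        return train.sequences, train.labels
    sequences, labels = train
    return list(sequences), np.asarray(labels, dtype=bool)


# ---------------------------------------------------------------------------
# Naive Bayes


@dataclass
class NaiveBayesModel:
    """Per-position categorical Naive Bayes with Laplace pseudo-count.

    ``log_cond[c, p, r]`` is log P(residue r at position p | class c),
    class index 0 = negative, 1 = positive (amyloidogenic).
    """

    log_prior: np.ndarray  # (2,)
    log_cond: np.ndarray  # (2, 6, 20)
    alpha: float

    def score(self, peptide: str) -> float:
        """Posterior probability of the amyloidogenic class."""
        validate_hexapeptide(peptide)
        logp = self.log_prior.copy()
        for p, ch in enumerate(peptide):
            logp = logp + self.log_cond[:, p, AA_INDEX[ch]]
        m = logp.max()
        probs = np.exp(logp - m)
        return float(probs[1] / probs.sum())

    def predict_proba(self, peptides: Sequence[str]) -> np.ndarray:
        return np.array([self.score(p) for p in peptides])

    def predict(self, peptides: Sequence[str]) -> np.ndarray:
        return self.predict_proba(peptides) > 0.5

    def to_dict(self) -> dict:
        return {
            "kind": "naive_bayes",
            "alpha": self.alpha,
            "log_prior": self.log_prior.tolist(),
            "log_cond": self.log_cond.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NaiveBayesModel":
        return cls(
            np.array(payload["log_prior"]),
            np.array(payload["log_cond"]),
            float(payload["alpha"]),
        )


def train_naive_bayes(
    train: HexDataset | tuple[Sequence[str], Sequence[bool]], alpha: float = 1.0
) -> NaiveBayesModel:
    """Estimate priors and per-position conditionals by smoothed counts.

    P(r | p, c) = (count(r, p, c) + alpha) / (n_c + 20*alpha).
    """
    sequences, labels = _split_input(train)
    n = len(sequences)
    if n == 0:
        raise ValueError("empty training set")
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both classes")
    counts = np.zeros((2, N_POSITIONS, N_RESIDUES))
    for seq, lab in zip(sequences, labels):
        validate_hexapeptide(seq)
        c = int(lab)
        for p, ch in enumerate(seq):
            counts[c, p, AA_INDEX[ch]] += 1
    class_n = np.array([float((~labels).sum()), float(labels.sum())])
    cond = (counts + alpha) / (class_n[:, None, None] + N_RESIDUES * alpha)
    return NaiveBayesModel(
        log_prior=np.log(class_n / n), log_cond=np.log(cond), alpha=alpha
    )


def nb_score(model: NaiveBayesModel, peptide: str) -> float:
    return model.score(peptide)


# ---------------------------------------------------------------------------
# multilayer perceptron


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


@dataclass
class MLPModel:
    """One-hidden-layer logistic perceptron over one-hot hexapeptides."""

    w1: np.ndarray  # (120, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    config: dict

    def forward(self, x: np.ndarray) -> float:
        h = _sigmoid(x @ self.w1 + self.b1)
        return float(_sigmoid(h @ self.w2 + self.b2))

    def score(self, peptide: str) -> float:
        return self.forward(encode(peptide))

    def predict_proba(self, peptides: Sequence[str]) -> np.ndarray:
        X = encode_many(peptides)
        H = _sigmoid(X @ self.w1 + self.b1)
        return _sigmoid(H @ self.w2 + self.b2)

    def predict(self, peptides: Sequence[str]) -> np.ndarray:
        return self.predict_proba(peptides) > 0.5

    def to_dict(self) -> dict:
        return {
            "kind": "mlp",
            "config": self.config,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPModel":
        return cls(
            np.array(payload["w1"]),
            np.array(payload["b1"]),
            np.array(payload["w2"]),
            float(payload["b2"]),
            dict(payload["config"]),
        )


def mlp_gradients(
    model: MLPModel, x: np.ndarray, target: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic gradients of the per-instance squared error L = (o-t)^2/2."""
    h = _sigmoid(x @ model.w1 + model.b1)
    o = float(_sigmoid(h @ model.w2 + model.b2))
    delta_o = (o - target) * o * (1.0 - o)
    g_w2 = delta_o * h
    g_b2 = delta_o
    delta_h = delta_o * model.w2 * h * (1.0 - h)
    g_w1 = np.outer(x, delta_h)
    g_b1 = delta_h
    return g_w1, g_b1, g_w2, g_b2


def mlp_loss(model: MLPModel, x: np.ndarray, target: float) -> float:
    return 0.5 * (model.forward(x) - target) ** 2


def train_mlp(
    train: HexDataset | tuple[Sequence[str], Sequence[bool]],
    hidden: int = 60,
    lr: float = 0.1,
    momentum: float = 0.2,
    epochs: int = 500,
    seed: int = 0,
) -> MLPModel:
    """Per-instance SGD with momentum on squared error, fixed epoch count.

    The instance order is reshuffled once per epoch with the training
    seed's generator; two runs with identical inputs and seed produce
    identical weight trajectories.
    """
    sequences, labels = _split_input(train)
    if len(sequences) == 0:
        raise ValueError("empty training set")
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both classes")
    X = encode_many(sequences)
    t = labels.astype(float)
    rng = np.random.default_rng(seed)
    model = MLPModel(
        w1=rng.uniform(-0.5, 0.5, (N_FEATURES, hidden)),
        b1=rng.uniform(-0.5, 0.5, hidden),
        w2=rng.uniform(-0.5, 0.5, hidden),
        b2=float(rng.uniform(-0.5, 0.5)),
        config={
            "hidden": hidden,
            "lr": lr,
            "momentum": momentum,
            "epochs": epochs,
            "seed": seed,
        },
    )
    v_w1 = np.zeros_like(model.w1)
    v_b1 = np.zeros_like(model.b1)
    v_w2 = np.zeros_like(model.w2)
    v_b2 = 0.0
    for _ in range(epochs):
        for i in rng.permutation(len(sequences)):
            g_w1, g_b1, g_w2, g_b2 = mlp_gradients(model, X[i], t[i])
            v_w1 = momentum * v_w1 - lr * g_w1
            v_b1 = momentum * v_b1 - lr * g_b1
            v_w2 = momentum * v_w2 - lr * g_w2
            v_b2 = momentum * v_b2 - lr * g_b2
            model.w1 += v_w1
            model.b1 += v_b1
            model.w2 += v_w2
            model.b2 += v_b2
    return model


def mlp_score(model: MLPModel, peptide: str) -> float:
    return model.score(peptide)
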