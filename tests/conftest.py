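"""Shared fixtures and helpers for the test suite.

All random inputs are generated programmatically with explicit seeds; no
data files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from hexamyloid.alphabet import AMINO_ACIDS
from hexamyloid.hexdata import HexDataset, LabeledHexapeptide

#: Sanitized residue alphabet (no cysteine) used for random peptides.
SANITIZED = [a for a in AMINO_ACIDS if a != "C"]


def random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    letters = rng.choice(SANITIZED, size=(n, 6))
    return ["".join(row) for row in letters]


def random_dataset(rng: np.random.Generator, n: int, p_pos: float = 0.5) -> HexDataset:
    peptides = random_peptides(rng, n)
    labels = rng.random(n) < p_pos
    # guarantee both classes
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return HexDataset(
        LabeledHexapeptide(p, bool(l), "random") for p, l in zip(peptides, labels)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_signal_data():
    """Tiny separable dataset: positives carry I at position 4."""
    pos = ["NNQINY", "AAAIAA", "QQQIQQ", "LLLILL"]
    neg = ["NNQQNY", "AAAAAA", "QQQQQQ", "LLLLLL"]
    return pos + neg, [True] * 4 + [False] * 4
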