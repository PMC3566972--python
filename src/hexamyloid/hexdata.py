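"""Hexapeptide ingestion, labeling and dataset statistics.

Protein sequences are sanitized (uppercase, cysteine -> serine), cut into
chunks of at most 80 residues, and scanned with a 6-residue window shifted
one position at a time. Windows touching a non-standard symbol (X, B, Z,
U, O, J, '*', gap) are dropped: the model space is the 20-letter alphabet
and imputation would fabricate sequence.

Labels derive from a steric-zipper threading energy: a hexapeptide is
amyloidogenic iff its minimal chain energy is not greater than a threshold
(default -23 kcal/mol). This module also computes the dataset-level
statistics used to compare two energy sources: classification overlap
after thresholding both energy columns, and the distribution of absolute
energy differences.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 6
CHUNK_MAX_LEN = 80
ENERGY_THRESHOLD = -23.0  # kcal/mol


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class LabeledHexapeptide:
    """A 6-residue sequence with a binary amyloidogenicity label.

    ``label`` is True for amyloidogenic; ``source`` is a free-text
    provenance tag (e.g. "trainset", "testset", "experimental").
    """

    sequence: str
    label: bool
    source: str = "unknown"

    def __post_init__(self) -> None:
        validate_hexapeptide(self.sequence)
        if not self.source:
            raise ValueError("source tag must be non-empty")


@dataclass(frozen=True)
class EnergyRecord:
    """A hexapeptide with its minimal threading energy in kcal/mol.

    ``reference_energy`` optionally carries the same peptide's energy from
    an independent source, enabling agreement statistics.
    """

    sequence: str
    energy: float
    reference_energy: float | None = None


def validate_hexapeptide(seq: str, allow_cysteine: bool = False) -> str:
    """Check that ``seq`` is a valid 6-residue sequence; return it.

    Sanitized datasets contain no cysteine (replaced by serine before
    threading); pass ``allow_cysteine=True`` for raw, pre-sanitization
    sequences.
    """
    if len(seq) != WINDOW_WIDTH:
        raise ValueError(f"hexapeptide must have 6 residues, got {seq!r}")
    for ch in seq:
        if ch not in AA_INDEX:
            raise ValueError(f"non-standard residue {ch!r} in {seq!r}")
    if not allow_cysteine and "C" in seq:
        raise ValueError(f"unsanitized cysteine in {seq!r}; sanitize first")
    return seq


# ---------------------------------------------------------------------------
# sequence operations


def sanitize_sequence(raw: str) -> str:
    """Uppercase a raw sequence and replace every cysteine by serine.

    The C->S substitution avoids disulfide bridges when the peptide is
    threaded onto the zipper scaffold. Symbols outside the 20-letter
    alphabet are kept here and flagged later by :func:`extract_windows`.
    """
    if not raw:
        raise ValueError("empty sequence")
    return raw.upper().replace("C", "S")


def chunk_sequence(seq: str, max_len: int = CHUNK_MAX_LEN) -> list[str]:
    """Cut ``seq`` into consecutive non-overlapping pieces of <= max_len.

    The concatenation of the chunks equals the input. Chunking mirrors the
    preprocessing used before redundancy reduction of long proteins; pass
    the whole sequence through :func:`extract_windows` directly to skip it.
    """
    if not seq:
        raise ValueError("empty sequence")
    if max_len < 1:
        raise ValueError("max_len must be positive")
    return [seq[i : i + max_len] for i in range(0, len(seq), max_len)]


def extract_windows(seq: str, width: int = WINDOW_WIDTH, step: int = 1) -> list[str]:
    """Slide a ``width``-residue window over ``seq`` with the given step.

    Windows containing any symbol outside the 20-letter alphabet are
    dropped (and logged): ambiguity codes cannot be threaded or encoded.
    A sequence shorter than ``width`` yields an empty list.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    windows: list[str] = []
    dropped = 0
    for start in range(0, len(seq) - width + 1, step):
        win = seq[start : start + width]
        if all(ch in AA_INDEX for ch in win):
            windows.append(win)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d windows containing non-standard symbols", dropped)
    return windows


def hexapeptides_from_sequence(
    raw: str,
    *,
    chunk: bool = True,
    max_len: int = CHUNK_MAX_LEN,
    width: int = WINDOW_WIDTH,
    step: int = 1,
) -> list[str]:
    """Sanitize, optionally chunk at ``max_len``, and window a sequence.

    With ``chunk=True`` windows never span an 80-residue chunk boundary
    (the default preprocessing); with ``chunk=False`` the full sequence is
    windowed in one pass.
    """
    clean = sanitize_sequence(raw)
    pieces = chunk_sequence(clean, max_len) if chunk else [clean]
    out: list[str] = []
    for piece in pieces:
        out.extend(extract_windows(piece, width=width, step=step))
    return out


# ---------------------------------------------------------------------------
# dataset container


class HexDataset:
    """Ordered collection of labeled hexapeptides; duplicates allowed.

    Duplicate sequences arising from different proteins are retained — the
    training distribution should reflect how often a segment occurs.
    """

    def __init__(self, items: Iterable[LabeledHexapeptide]):
        self.items: list[LabeledHexapeptide] = list(items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[LabeledHexapeptide]:
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    @property
    def sequences(self) -> list[str]:
        return [it.sequence for it in self.items]

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self.items], dtype=bool)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    def subset(self, indices: Iterable[int]) -> "HexDataset":
        return HexDataset(self.items[i] for i in indices)

    def label_map(self) -> dict[str, bool]:
        """Sequence -> label map; first occurrence wins on duplicates."""
        out: dict[str, bool] = {}
        for it in self.items:
            out.setdefault(it.sequence, it.label)
        return out

    def dedupe(self) -> tuple["HexDataset", list[str]]:
        """Keep the first occurrence of each sequence.

        Sequences whose duplicates disagree in label are reported (and the
        first occurrence kept), so a merge of computed and experimental
        sets can be audited rather than silently resolved.
        """
        seen: dict[str, LabeledHexapeptide] = {}
        conflicts: list[str] = []
        for it in self.items:
            prev = seen.get(it.sequence)
            if prev is None:
                seen[it.sequence] = it
            elif prev.label != it.label and it.sequence not in conflicts:
                conflicts.append(it.sequence)
        if conflicts:
            logger.warning("%d sequences with conflicting labels", len(conflicts))
        return HexDataset(seen.values()), conflicts

    # -- tabular IO (UTF-8, tab-separated, header line) --

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "label": self.labels.astype(int),
                "source": [it.source for it in self.items],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HexDataset":
        if "source" not in df.columns:
            df = df.assign(source="unknown")
        return cls(
            LabeledHexapeptide(str(r.sequence), bool(int(r.label)), str(r.source))
            for r in df.itertuples()
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "HexDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# energy-threshold labeling


def label_by_energy(
    records: Iterable[EnergyRecord],
    threshold: float = ENERGY_THRESHOLD,
    source: str = "energy",
) -> HexDataset:
    """Label records amyloidogenic iff energy <= threshold (kcal/mol).

    The boundary is inclusive: an energy *not greater than* the threshold
    is positive. Records with non-finite energy are rejected and logged.
    """
    records = list(records)
    if not records:
        raise ValueError("no energy records to label")
    items: list[LabeledHexapeptide] = []
    rejected = 0
    for rec in records:
        if not math.isfinite(rec.energy):
            rejected += 1
            continue
        items.append(
            LabeledHexapeptide(rec.sequence, rec.energy <= threshold, source)
        )
    if rejected:
        logger.warning("rejected %d records with non-finite energy", rejected)
    return HexDataset(items)


# ---------------------------------------------------------------------------
# dataset statistics


class PositionFrequencyMatrix:
    """Residue frequencies at each of the 6 positions (rows sum to 1).

    ``freq`` is a (6, 20) array indexed by (position-1, residue index in
    the canonical alphabet order). Construction validates normalization.
    """

    def __init__(self, freq: np.ndarray):
        freq = np.asarray(freq, dtype=float)
        if freq.shape != (WINDOW_WIDTH, len(AMINO_ACIDS)):
            raise ValueError(f"PFM must be (6, 20), got {freq.shape}")
        if np.any(freq < 0):
            raise ValueError("PFM frequencies must be non-negative")
        sums = freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PFM rows must sum to 1, got {sums}")
        self.freq = freq

    def __getitem__(self, key: tuple[int, str]) -> float:
        """Frequency of ``residue`` at 1-based ``position``: pfm[4, 'I']."""
        position, residue = key
        return float(self.freq[position - 1, AA_INDEX[residue]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq,
            index=pd.RangeIndex(1, WINDOW_WIDTH + 1, name="position"),
            columns=list(AMINO_ACIDS),
        )

    @classmethod
    def uniform(cls) -> "PositionFrequencyMatrix":
        return cls(np.full((WINDOW_WIDTH, len(AMINO_ACIDS)), 1 / len(AMINO_ACIDS)))

    @classmethod
    def from_background(
        cls, background: Mapping[str, float] | None = None
    ) -> "PositionFrequencyMatrix":
        """Position-independent PFM from a residue composition.

        Defaults to an overall protein composition with cysteine folded
        into serine (sanitized sequence space).
        """
        from .alphabet import BACKGROUND_FREQS

        background = dict(background or BACKGROUND_FREQS)
        row = np.array([background.get(a, 0.0) for a in AMINO_ACIDS], float)
        row = row / row.sum()
        return cls(np.tile(row, (WINDOW_WIDTH, 1)))

    def with_signal(
        self, position: int, residue: str, weight: float
    ) -> "PositionFrequencyMatrix":
        """Concentrate ``weight`` of one position's mass on one residue.

        The remaining residues at that position are rescaled to share
        ``1 - weight`` proportionally — a plantable class-discriminating
        motif for synthetic benchmarks.
        """
        if not 0.0 <= weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")
        freq = self.freq.copy()
        row = freq[position - 1].copy()
        j = AA_INDEX[residue]
        rest = row.sum() - row[j]
        row[j] = 0.0
        row = row * ((1.0 - weight) / rest) if rest > 0 else row
        row[j] = weight
        freq[position - 1] = row
        return PositionFrequencyMatrix(freq)


def position_frequencies(dataset: HexDataset) -> PositionFrequencyMatrix:
    """Empirical per-position residue frequencies of a dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    counts = np.zeros((WINDOW_WIDTH, len(AMINO_ACIDS)), dtype=float)
    for it in dataset:
        for p, ch in enumerate(it.sequence):
            counts[p, AA_INDEX[ch]] += 1
    return PositionFrequencyMatrix(counts / len(dataset))


@dataclass(frozen=True)
class OverlapReport:
    """Agreement between two binary classifications of shared peptides."""

    n_shared: int
    fraction_identical: float
    fraction_identical_a_positive: float
    fraction_identical_a_negative: float
    a_positives: int
    b_positives: int


def classification_overlap(
    a: Mapping[str, bool], b: Mapping[str, bool]
) -> OverlapReport:
    """Fraction of peptides labeled identically by two classifications.

    Only the intersection of the two key sets is compared; breakdowns are
    reported among a's positives and a's negatives. The total fraction is
    symmetric in its arguments.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared peptides between the two classifications")
    la = np.array([a[s] for s in shared], dtype=bool)
    lb = np.array([b[s] for s in shared], dtype=bool)
    same = la == lb

    def _frac(mask: np.ndarray) -> float:
        return float(same[mask].mean()) if mask.any() else float("nan")

    return OverlapReport(
        n_shared=len(shared),
        fraction_identical=float(same.mean()),
        fraction_identical_a_positive=_frac(la),
        fraction_identical_a_negative=_frac(~la),
        a_positives=int(la.sum()),
        b_positives=int(lb.sum()),
    )


@dataclass(frozen=True)
class EnergyAgreement:
    """Distribution summary of |energy - reference_energy| in kcal/mol."""

    mean_abs_diff: float
    percentile_abs_diff: float
    q: float
    n: int


def energy_agreement(
    records: Iterable[EnergyRecord], q: float = 90.0
) -> EnergyAgreement:
    """Mean and q-th percentile of absolute between-source energy gaps.

    Percentile uses the nearest-rank convention on the sorted absolute
    differences. Records without a reference energy are ignored.
    """
    diffs = np.array(
        [
            abs(r.energy - r.reference_energy)
            for r in records
            if r.reference_energy is not None
        ]
    )
    if diffs.size == 0:
        raise ValueError("no records carry a reference energy")
    srt = np.sort(diffs)
    rank = max(1, math.ceil(q / 100.0 * srt.size))
    return EnergyAgreement(
        mean_abs_diff=float(diffs.mean()),
        percentile_abs_diff=float(srt[rank - 1]),
        q=q,
        n=int(diffs.size),
    )
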