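"""Amino-acid alphabet constants shared across the package.

The model space is the 20 standard residues in one-letter code. After
sanitization (cysteine -> serine, to rule out disulfide bridges in the
zipper geometry) sequences entering the classifiers never contain 'C',
but 'C' remains a legal symbol at ingestion time.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Symbols that may appear in real protein records but are outside the
#: 20-letter model space: ambiguity codes, rare residues, stops, gaps.
NONSTANDARD_SYMBOLS: frozenset[str] = frozenset("XBZUOJ*-.")

#: One-letter -> three-letter residue codes (PDB naming).
AA_THREE: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Kyte-Doolittle hydropathy scale, used only by the non-physical
#: surrogate energy adapter shipped for testing the zipper pipeline.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Overall residue composition of well-annotated protein sequence space
# (Swiss-Prot-like frequencies, percent). Cysteine's mass is folded into
# serine because sanitized hexapeptide datasets contain no 'C'.
_RAW_COMPOSITION: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 0.0,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56 + 1.38, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}
_total = sum(_RAW_COMPOSITION.values())

#: Background residue frequencies (sum to 1, C = 0 after sanitization).
BACKGROUND_FREQS: dict[str, float] = {
    a: _RAW_COMPOSITION[a] / _total for a in AMINO_ACIDS
}
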