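"""Cut protein sequences into classifiable hexapeptide windows.

Builds a tiny in-memory FASTA-style input, sanitizes it (uppercase,
cysteine -> serine), chunks long sequences at 80 residues, and slides a
6-residue window one position at a time, dropping windows that touch a
non-standard symbol.
"""

from hexamyloid import hexapeptides_from_sequence, sanitize_sequence

sequences = {
    "sup35_fragment": "nnqqnyqqyqpqgg",
    "with_cysteines": "ACACACGGGGGG",
    "with_ambiguity": "NNXQQNYAAAAA",
    "long_protein": "MKV" * 40,  # 120 residues -> two 80/40 chunks
}

for name, raw in sequences.items():
    clean = sanitize_sequence(raw)
    windows = hexapeptides_from_sequence(raw)
    print(f"{name}: {len(raw)} residues -> {len(windows)} windows")
    print(f"  sanitized: {clean[:40]}{'...' if len(clean) > 40 else ''}")
    print(f"  first windows: {windows[:3]}")

# The 120-residue protein gives 75 + 35 = 110 windows, not 115: windows
# never span the 80-residue chunk boundary. The ambiguous sequence keeps
# only the 4 windows that avoid the 'X'.
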