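"""Readers and writers for the package's text formats.

FASTA goes through Biopython. Hexapeptide and energy tables are UTF-8
tab-separated files with a header line:

    sequence  energy  [reference_energy]     (energy tables, kcal/mol)
    sequence  label  [source]                (labeled tables, label 0/1)

A reference energy column may be absent or hold empty cells. The readers
accept tables re-exported from spreadsheet sheets named like trainset(+),
trainset(-), testset(+), testset(-): a ``source`` column carrying those
tags is preserved verbatim. A minimal ARFF importer covers WEKA-style
nominal attribute files.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import pandas as pd
from Bio import SeqIO

from .hexdata import EnergyRecord, HexDataset, LabeledHexapeptide


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA; returns (header, sequence) pairs.

    Wrapped lines are joined; the full '>'-line description is kept as
    provenance.
    """
    records = [(rec.description, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_energy_table(path) -> list[EnergyRecord]:
    """Read a TSV of sequence / energy / optional reference_energy."""
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns or "energy" not in df.columns:
        raise ValueError("energy table needs 'sequence' and 'energy' columns")
    has_ref = "reference_energy" in df.columns
    out: list[EnergyRecord] = []
    for row in df.itertuples():
        ref = None
        if has_ref:
            val = row.reference_energy
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                ref = float(val)
        out.append(EnergyRecord(str(row.sequence), float(row.energy), ref))
    return out


def write_energy_table(path, records: Iterable[EnergyRecord]) -> None:
    records = list(records)
    df = pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "energy": [r.energy for r in records],
            "reference_energy": [r.reference_energy for r in records],
        }
    )
    if df["reference_energy"].isna().all():
        df = df.drop(columns=["reference_energy"])
    df.to_csv(path, sep="\t", index=False)


def read_arff_hexapeptides(path) -> HexDataset:
    """Minimal ARFF importer for nominal per-position attribute files.

    Expects six single-character nominal attributes followed by a binary
    class attribute; data rows are comma-separated. Everything beyond this
    (sparse format, quoting, numeric attributes) is out of scope.
    """
    attrs: list[str] = []
    rows: list[LabeledHexapeptide] = []
    positive_value: str | None = None
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("@attribute"):
                name = line.split()[1]
                attrs.append(name)
                if "{" in line:
                    values = [
                        v.strip() for v in line[line.index("{") + 1 : line.rindex("}")].split(",")
                    ]
                    positive_value = values[-1]
            elif low.startswith("@data"):
                in_data = True
                if len(attrs) != 7:
                    raise ValueError("expected 6 position attributes plus a class")
            elif in_data:
                fields = [f.strip() for f in line.split(",")]
                if len(fields) != 7:
                    raise ValueError(f"malformed ARFF data row: {line!r}")
                seq = "".join(fields[:6]).upper()
                rows.append(
                    LabeledHexapeptide(seq, fields[6] == positive_value, "arff")
                )
    if not rows:
        raise ValueError(f"no data rows in {path}")
    return HexDataset(rows)
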