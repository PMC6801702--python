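"""File input/output: FASTA substrates, peptide tables, tidy TSV results."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA into {id: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# MaxQuant peptides.txt column names accepted as aliases for our canonical names
PEPTIDE_COLUMN_ALIASES = {
    "Sequence": "sequence",
    "Proteins": "substrate_id",
    "Leading razor protein": "substrate_id",
    "Start position": "start",
    "End position": "end",
    "Experiment": "sample_id",
    "Raw file": "sample_id",
    "sequence": "sequence",
    "substrate_id": "substrate_id",
    "start": "start",
    "end": "end",
    "sample_id": "sample_id",
    "cathepsin": "cathepsin",
    "time_h": "time_h",
    "ph": "ph",
}


def read_peptide_table(path) -> pd.DataFrame:
    """Parse a tab-separated peptide table (MaxQuant ``peptides.txt``-compatible).

    Required columns (canonical or MaxQuant alias): Sequence, Proteins,
    Start position, End position.  Optional: Experiment/Raw file (sample),
    cathepsin, time_h, ph.  Missing optional columns are filled with
    neutral defaults so a minimal table still maps.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = {}
    for col in raw.columns:
        canon = PEPTIDE_COLUMN_ALIASES.get(col)
        if canon is not None and canon not in cols:
            cols[canon] = raw[col]
    df = pd.DataFrame(cols)
    required = {"sequence", "substrate_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table lacks required columns: {sorted(missing)}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    for col, default in [("sample_id", "sample1"), ("cathepsin", "unknown"),
                         ("time_h", "24"), ("ph", "6.0")]:
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)
    df["time_h"] = df["time_h"].astype(float)
    df["ph"] = df["ph"].astype(float)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a tidy TSV deterministically (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
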