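"""Immunoglobulin variable-region cleavage profiling in CDR3-relative coordinates.

Heavy-chain variable regions differ in length, but the cysteine that opens
CDR3 is conserved, so cleavage positions become comparable across
sequences and IGHV families when expressed relative to that cysteine
(position 0).  Constant regions, which have no CDR3, are displayed from a
fixed offset of 30 so variable- and constant-region maps can share an
axis.  Family mean profiles average predicted cleavage probabilities at
each relative position over all family members covering it, and eluted or
digest peptides can be overlaid on those coordinates to ask whether their
termini coincide with predicted cleavage sites and whether known epitopes
survive processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest import locate_peptide

CONSTANT_REGION_START = 30


@dataclass(frozen=True)
class IghvRecord:
    """A variable-region sequence with IGHV family label and CDR3-anchor cysteine.

    ``cdr3_cys`` is the 1-based index of the conserved cysteine that marks
    the beginning of CDR3; family labels are taken as given (e.g. from
    IMGT), never inferred.
    """

    id: str
    sequence: str
    family: str
    cdr3_cys: int

    def __post_init__(self):
        if not self.family:
            raise ValueError("family label must be non-empty")
        if not 1 <= self.cdr3_cys <= len(self.sequence):
            raise ValueError("cdr3_cys outside sequence")
        if self.sequence[self.cdr3_cys - 1] != "C":
            raise ValueError(
                f"annotation error: residue at cdr3_cys={self.cdr3_cys} is "
                f"{self.sequence[self.cdr3_cys - 1]!r}, not 'C'")


def to_cdr3_relative(record: IghvRecord, p1prime_positions) -> np.ndarray:
    """Map absolute P1' positions to CDR3-relative coordinates (cysteine = 0)."""
    pos = np.asarray(p1prime_positions, dtype=int)
    if np.any((pos < 1) | (pos > len(record.sequence))):
        raise ValueError("position outside sequence")
    return pos - record.cdr3_cys


def from_cdr3_relative(record: IghvRecord, relative_positions) -> np.ndarray:
    """Inverse of :func:`to_cdr3_relative`."""
    return np.asarray(relative_positions, dtype=int) + record.cdr3_cys


def align_constant_region(constant_positions) -> np.ndarray:
    """Display coordinates for constant-region residues (residue 1 -> 30)."""
    pos = np.asarray(constant_positions, dtype=int)
    return pos + CONSTANT_REGION_START - 1


def family_mean_profile(records: list[IghvRecord], model) -> pd.DataFrame:
    """Mean predicted cleavage probability per CDR3-relative position, per family.

    Each record is profiled with the dipeptide-ensemble model, its P1'
    positions re-indexed relative to the CDR3 cysteine, and probabilities
    averaged per (family, relative position) over the records covering
    that position.  Positions covered by no record are absent, never
    zero-filled.
    """
    rows = []
    for rec in records:
        profile = model.predict_profile(rec.sequence, substrate_id=rec.id)
        rel = to_cdr3_relative(rec, profile["p1prime"].to_numpy())
        rows.append(pd.DataFrame({
            "family": rec.family, "relative_position": rel,
            "probability": profile["probability"].to_numpy(),
        }))
    if not rows:
        return pd.DataFrame(columns=["family", "relative_position",
                                     "mean_probability", "n"])
    allp = pd.concat(rows, ignore_index=True)
    out = (allp.groupby(["family", "relative_position"], as_index=False)
               .agg(mean_probability=("probability", "mean"),
                    n=("probability", "size")))
    return out.sort_values(["family", "relative_position"]).reset_index(drop=True)


def overlay_peptides(peptides: list[str], record: IghvRecord,
                     profile: pd.DataFrame, threshold: float = 0.5,
                     il_equivalent: bool = False,
                     max_mismatches: int = 0) -> pd.DataFrame:
    """Align peptides to a variable region and flag terminus compatibility.

    Each peptide is located in the record's sequence (exact by default;
    optionally I/L-equivalent or with up to ``max_mismatches``
    substitutions for somatic variants), reported with its CDR3-relative
    span, and flagged when a terminus coincides with a predicted cleavage
    site of probability >= ``threshold``.  Termini at the chain ends are
    not cleavage products, so their flags are left missing.
    """
    prob = dict(zip(profile["p1prime"], profile["probability"]))
    L = len(record.sequence)
    rows = []
    for pep in peptides:
        spans = locate_peptide(record.sequence, pep, il_equivalent)
        if not spans and max_mismatches > 0:
            spans = _fuzzy_locate(record.sequence, pep, max_mismatches)
        if not spans:
            rows.append({"peptide": pep, "mapped": False,
                         "relative_start": pd.NA, "relative_end": pd.NA,
                         "amino_compatible": pd.NA, "carboxy_compatible": pd.NA})
            continue
        for start, end in spans:
            amino = prob.get(start, 0.0) >= threshold if start > 1 else pd.NA
            carboxy = prob.get(end + 1, 0.0) >= threshold if end < L else pd.NA
            rows.append({
                "peptide": pep, "mapped": True,
                "relative_start": start - record.cdr3_cys,
                "relative_end": end - record.cdr3_cys,
                "amino_compatible": amino, "carboxy_compatible": carboxy,
            })
    return pd.DataFrame(rows)


def _fuzzy_locate(sequence: str, peptide: str,
                  max_mismatches: int) -> list[tuple[int, int]]:
    n, m = len(sequence), len(peptide)
    spans = []
    for start in range(n - m + 1):
        mismatches = sum(a != b for a, b in zip(sequence[start:start + m], peptide))
        if mismatches <= max_mismatches:
            spans.append((start + 1, start + m))
    return spans


def epitope_integrity(span: tuple[int, int], profile: pd.DataFrame,
                      threshold: float = 0.5) -> dict:
    """Is a defined epitope destroyed by predicted cleavage?

    An epitope spanning [start, end] is called destroyed when at least one
    predicted site with probability >= ``threshold`` lies strictly interior
    to it (P1' in [start+1, end]); cuts at the span boundaries release the
    epitope intact.  Spans shorter than 2 residues are trivially intact.
    """
    start, end = span
    if end - start < 1:
        return {"status": "intact", "internal_sites": []}
    interior = profile[(profile["p1prime"] >= start + 1) &
                       (profile["p1prime"] <= end) &
                       (profile["probability"] >= threshold)]
    sites = sorted(interior["p1prime"].tolist())
    return {"status": "destroyed" if sites else "intact",
            "internal_sites": sites}


def read_ighv_records(fasta: dict[str, str], annotations: pd.DataFrame) -> list[IghvRecord]:
    """Join FASTA sequences with an annotation table (id, family, cdr3_cys)."""
    records = []
    for row in annotations.itertuples():
        seq = fasta.get(row.id)
        if seq is None:
            raise KeyError(f"annotation references unknown sequence {row.id!r}")
        records.append(IghvRecord(id=row.id, sequence=seq, family=row.family,
                                  cdr3_cys=int(row.cdr3_cys)))
    return records


def suggest_cdr3_cys(sequence: str, j_motif: str = "WG") -> int | None:
    """Heuristic CDR3-anchor guess: last Cys before a J-region motif.

    Non-authoritative helper only — annotate from IMGT where possible.
    """
    j = sequence.find(j_motif)
    search_space = sequence[:j] if j != -1 else sequence
    idx = search_space.rfind("C")
    return idx + 1 if idx != -1 else None
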