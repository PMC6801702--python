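"""Amino-acid physicochemical property table.

The bundled table collects ten widely used published indices for the 20
canonical residues.  It is the default basis for the principal-component
encoding of cleavage-site octamers; any user table with the same layout
(one row per residue, one numeric column per property) can be substituted.

Indices
-------
hydropathy_kd        Kyte & Doolittle hydropathy
hydrophilicity_hw    Hopp & Woods hydrophilicity
residue_mass         monoisotopic-free average residue mass (Da)
volume               Zamyatnin residue volume (A^3)
polarity_grantham    Grantham polarity
isoelectric_point    pI of the free amino acid
net_charge_ph7       formal side-chain charge near neutral pH
bulkiness            Zimmerman bulkiness
helix_propensity     Chou & Fasman P(alpha)
sheet_propensity     Chou & Fasman P(beta)
"""

from __future__ import annotations

import hashlib

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_PROPERTIES: dict[str, dict[str, float]] = {
    "hydropathy_kd": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    "hydrophilicity_hw": {
        "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
        "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
        "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
        "Y": -2.3, "V": -1.5,
    },
    "residue_mass": {
        "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
        "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
        "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
        "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
    },
    "volume": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
        "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
        "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
        "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    },
    "polarity_grantham": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
        "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
        "Y": 6.2, "V": 5.9,
    },
    "isoelectric_point": {
        "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
        "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
        "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
        "Y": 5.66, "V": 5.96,
    },
    "net_charge_ph7": {
        "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0,
        "E": -1.0, "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
        "Y": 0.0, "V": 0.0,
    },
    "bulkiness": {
        "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
        "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
        "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
        "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
    },
    "helix_propensity": {
        "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
        "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
        "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
        "Y": 0.69, "V": 1.06,
    },
    "sheet_propensity": {
        "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
        "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
        "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
        "Y": 1.47, "V": 1.70,
    },
}


def default_property_table() -> pd.DataFrame:
    """Return the bundled property table, indexed by residue letter."""
    df = pd.DataFrame(_DEFAULT_PROPERTIES)
    return df.loc[list(AMINO_ACIDS)]


def load_property_table(path) -> pd.DataFrame:
    """Read a tab-separated property table (residue column + numeric columns)."""
    df = pd.read_csv(path, sep="\t")
    residue_col = df.columns[0]
    df = df.set_index(residue_col)
    return validate_property_table(df)


def validate_property_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the 20-row / no-missing-value invariants; return a sorted copy."""
    missing = set(AMINO_ACIDS) - set(table.index)
    if missing:
        raise ValueError(f"property table lacks residues: {sorted(missing)}")
    extra = set(table.index) - set(AMINO_ACIDS)
    if extra:
        raise ValueError(f"property table has non-canonical rows: {sorted(extra)}")
    table = table.loc[list(AMINO_ACIDS)].astype(float)
    if table.isna().any().any():
        raise ValueError("property table contains missing values")
    if table.shape[1] < 1:
        raise ValueError("property table has no property columns")
    return table


def property_table_hash(table: pd.DataFrame) -> str:
    """Stable hash of a property table, recorded in model files for provenance."""
    canon = table.loc[list(AMINO_ACIDS)].astype(float)
    payload = canon.to_csv(float_format="%.10g").encode()
    return hashlib.sha256(payload).hexdigest()[:16]
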