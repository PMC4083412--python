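"""Amino-acid reference tables shared across the package."""

from __future__ import annotations

# Fixed alphabetical ordering of the 20 standard three-letter codes.  All
# one-hot blocks and composition vectors in the feature manifest index into
# this list; changing it invalidates serialized models.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AA)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Maximum accessible surface area per residue type (A^2), Rost & Sander (1994).
# Used to normalise absolute ASA into relative solvent accessibility.
MAX_ASA: dict[str, float] = {
    "ALA": 106.0, "ARG": 248.0, "ASN": 157.0, "ASP": 163.0, "CYS": 135.0,
    "GLN": 198.0, "GLU": 194.0, "GLY": 84.0, "HIS": 184.0, "ILE": 169.0,
    "LEU": 164.0, "LYS": 205.0, "MET": 188.0, "PHE": 197.0, "PRO": 136.0,
    "SER": 130.0, "THR": 142.0, "TRP": 227.0, "TYR": 222.0, "VAL": 142.0,
}

# Side-chain atoms defining charged groups for salt-bridge (IONIC) detection.
POSITIVE_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
}

# Aromatic ring atoms used for pi-system centroids.
AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# Cation atoms for pi-cation detection.
CATION_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("CZ",),
}

# Hydrophobic residues, used by the reference-statistics generator.
HYDROPHOBIC: frozenset[str] = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS"}
)


def is_standard(aa: str) -> bool:
    return aa in AA_INDEX
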