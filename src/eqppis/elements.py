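"""Chemical lookup tables for per-atom residue features.

Element constants: atomic mass (u, IUPAC 2021), electron count of the
neutral atom, and Bondi/Rowland van der Waals radii (Å). Hydrogen counts
are the number of hydrogens covalently bonded to each heavy atom in the
standard protonation state at pH 7; ring membership follows the aromatic /
pyrrolidine rings of His, Phe, Tyr, Trp and Pro. Maximum accessible surface
areas are the theoretical values of Tien et al. (2013), used to normalise
DSSP accessibility into relative solvent accessibility.
"""

from __future__ import annotations

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: element symbol -> (atomic mass, electron count, van der Waals radius in Å)
ELEMENT_PROPERTIES: dict[str, tuple[float, int, float]] = {
    "H": (1.008, 1, 1.20),
    "C": (12.011, 6, 1.70),
    "N": (14.007, 7, 1.55),
    "O": (15.999, 8, 1.52),
    "S": (32.06, 16, 1.80),
    "P": (30.974, 15, 1.80),
    "SE": (78.971, 34, 1.90),
}

#: residue -> atom name -> bonded hydrogen count (side-chain heavy atoms)
SIDECHAIN_H_COUNT: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {
        "CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1,
        "CE2": 0, "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1,
    },
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}

#: residue -> set of atom names that belong to a ring
RING_ATOMS: dict[str, frozenset[str]] = {
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "PRO": frozenset({"N", "CA", "CB", "CG", "CD"}),
}

#: maximum accessible surface area per residue (Å²), Tien et al. 2013
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def atom_h_count(residue_name: str, atom_name: str) -> int:
    """Bonded-hydrogen count for a heavy atom in a standard residue.

    Backbone amide N carries one hydrogen (none in proline), CA carries one
    (two in glycine), carbonyl C and O carry none. Unknown residue/atom
    combinations default to zero.
    """
    residue_name = residue_name.upper()
    if atom_name == "N":
        return 0 if residue_name == "PRO" else 1
    if atom_name == "CA":
        return 2 if residue_name == "GLY" else 1
    if atom_name in ("C", "O", "OXT"):
        return 0
    return SIDECHAIN_H_COUNT.get(residue_name, {}).get(atom_name, 0)


def atom_in_ring(residue_name: str, atom_name: str) -> bool:
    return atom_name in RING_ATOMS.get(residue_name.upper(), frozenset())
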