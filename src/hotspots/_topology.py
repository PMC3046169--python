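"""Standard amino-acid heavy-atom topology.

Heavy-atom names follow PDB v3 conventions. ``SIDE_CHAIN_ATOMS`` lists the
atoms removed by an alanine mutation, i.e. everything beyond the beta carbon;
the backbone set plus CB is shared by all residues (Gly lacks CB).
"""

from __future__ import annotations

BACKBONE_ATOMS = ("N", "CA", "C", "O")
STUB_ATOMS = BACKBONE_ATOMS + ("CB",)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Heavy atoms beyond CB (alanine-difference set).
SIDE_CHAIN_ATOMS = {
    "ALA": (),
    "ARG": ("CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CG", "OD1", "ND2"),
    "ASP": ("CG", "OD1", "OD2"),
    "CYS": ("SG",),
    "GLN": ("CG", "CD", "OE1", "NE2"),
    "GLU": ("CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CG1", "CG2", "CD1"),
    "LEU": ("CG", "CD1", "CD2"),
    "LYS": ("CG", "CD", "CE", "NZ"),
    "MET": ("CG", "SD", "CE"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CG", "CD"),
    "SER": ("OG",),
    "THR": ("OG1", "CG2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CG1", "CG2"),
}


def residue_heavy_atoms(res3: str) -> tuple[str, ...]:
    """Full heavy-atom name set of a standard residue (backbone + side chain)."""
    if res3 not in SIDE_CHAIN_ATOMS:
        raise KeyError(f"unknown residue name {res3!r}")
    stub = BACKBONE_ATOMS if res3 == "GLY" else STUB_ATOMS
    return stub + SIDE_CHAIN_ATOMS[res3]


# Residue types that cannot be alanine-scanned: Ala is the mutation target
# itself, Gly has no side chain, Pro is conformationally special.
NON_MUTABLE = frozenset({"A", "G", "P"})
MUTABLE_AA = tuple(sorted(set(ONE_TO_THREE) - NON_MUTABLE))


def atom_element(name: str) -> str:
    """Element symbol inferred from a PDB heavy-atom name."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")
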