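"""Shared amino-acid tables: letter codes and side-chain heavy-atom names."""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

#: upper-case 3-letter -> 1-letter for the 20 standard residues
THREE_TO_ONE: dict[str, str] = {
    three.upper(): one for one, three in protein_letters_1to3.items()
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_CODES = frozenset(THREE_TO_ONE)

# Backbone heavy-atom names; everything else heavy in a residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: side-chain heavy atoms per residue, in CB-outward order (PDB naming)
SIDE_CHAIN_ATOMS: dict[str, list[str]] = {
    "GLY": [],
    "ALA": ["CB"],
    "SER": ["CB", "OG"],
    "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1", "CG2"],
    "VAL": ["CB", "CG1", "CG2"],
    "PRO": ["CB", "CG", "CD"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "SD", "CE"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}


def element_of(atom_name: str) -> str:
    """Element symbol from a PDB atom name (first alphabetic character)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def one_letter(code3: str) -> str:
    """1-letter code for a standard 3-letter code; 'X' for anything else."""
    return THREE_TO_ONE.get(code3.upper(), "X")
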