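"""Atom-type and residue-type vocabularies.

Ligand atoms are typed by element over a fixed 26-entry vocabulary of the
elements commonly found in drug-like small molecules, plus three special
tokens: ``[UNK]`` for anything outside the vocabulary, ``[MASK]`` for the
masked-type pretraining task and ``[CLS]`` for the global summary token whose
coordinates sit at the molecular centroid.

Protein residues use the standard 20 amino-acid one-letter alphabet plus an
unknown symbol and the same ``[CLS]`` convention.
"""

from __future__ import annotations

# 26 common element types for small organic / drug-like molecules.
ELEMENTS: tuple[str, ...] = (
    "H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
    "B", "Si", "Se", "Na", "K", "Mg", "Ca", "Zn", "Fe", "Mn",
    "Cu", "Co", "Ni", "As", "Al", "Li",
)

UNK = "[UNK]"
MASK = "[MASK]"
CLS = "[CLS]"

ATOM_TOKENS: tuple[str, ...] = ELEMENTS + (UNK, MASK, CLS)
ATOM_INDEX: dict[str, int] = {t: i for i, t in enumerate(ATOM_TOKENS)}

#: size of the atom-type prediction target (elements + [UNK]; the model never
#: has to predict [MASK] or [CLS])
N_ATOM_CLASSES = len(ELEMENTS) + 1

AMINO_ACIDS: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)
AA_UNK = "X"
RESIDUE_TOKENS: tuple[str, ...] = AMINO_ACIDS + (AA_UNK, CLS)
RESIDUE_INDEX: dict[str, int] = {t: i for i, t in enumerate(RESIDUE_TOKENS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def atom_token(symbol: str) -> str:
    """Map an element symbol to its vocabulary token ([UNK] if absent)."""
    s = symbol.strip()
    if s in ATOM_INDEX:
        return s
    s = s.capitalize()
    return s if s in ATOM_INDEX else UNK


def encode_atom_types(types) -> list[int]:
    """Vocabulary indices for a sequence of atom tokens."""
    return [ATOM_INDEX[atom_token(t)] for t in types]


def encode_residue_types(types) -> list[int]:
    """Vocabulary indices for a sequence of one-letter residue codes."""
    return [RESIDUE_INDEX.get(t, RESIDUE_INDEX[AA_UNK]) for t in types]
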