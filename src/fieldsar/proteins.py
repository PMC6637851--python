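"""Receptor structure container: chains, residues, atoms with a backbone flag."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ProteinAtom:
    name: str
    element: str
    coords: np.ndarray  # Å
    backbone: bool = False


@dataclass
class Residue:
    chain: str
    name: str  # three-letter code, e.g. GLU
    number: int
    icode: str = ""
    atoms: list[ProteinAtom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        """One-letter + number label (E172) as used in occurrence plots."""
        one = _THREE_TO_ONE.get(self.name, "X")
        return f"{one}{self.number}{self.icode}"

    def atom(self, name: str) -> ProteinAtom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[ProteinAtom]:
        return [a for a in self.atoms if a.element != "H"]

    def side_chain_atoms(self) -> list[ProteinAtom]:
        return [a for a in self.atoms if not a.backbone and a.element != "H"]


@dataclass
class ProteinStructure:
    residues: list[Residue]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue {r.key}")
            seen.add(r.key)

    def residue(self, label_or_key) -> Residue:
        """Look up by (chain, number, icode) key or by a label like 'E172' / 'GLU172'."""
        if isinstance(label_or_key, tuple):
            for r in self.residues:
                if r.key == label_or_key:
                    return r
            raise KeyError(f"residue {label_or_key} not found")
        s = str(label_or_key)
        for r in self.residues:
            if r.label == s or f"{r.name}{r.number}{r.icode}" == s.upper():
                return r
        raise KeyError(f"residue {s} not found")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for r in self.residues for a in r.heavy_atoms()])


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
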