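"""Lightweight 3D molecule container used throughout the pipeline.

A :class:`Molecule` is a docked ligand pose: elements, Cartesian coordinates
in the receptor frame (Å), bonds with orders, formal charges, and partial
charges in elementary charge units.  It deliberately stores only what the
downstream stages need (common-graph RMSD, interaction fingerprints, field
evaluation) and can be built either from an RDKit mol (SDF input) or
directly from arrays (synthetic series).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

AROMATIC_BOND = 1.5  # internal encoding of an aromatic bond order


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # shape (3,), Å
    formal_charge: int = 0
    partial_charge: float = 0.0
    aromatic: bool = False
    n_hydrogens: int = 0  # explicit + implicit H attached


@dataclass
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or AROMATIC_BOND


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    _ring_sizes: dict[int, tuple[int, ...]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for a in self.atoms:
            a.coords = np.asarray(a.coords, dtype=float)
            if a.coords.shape != (3,) or not np.all(np.isfinite(a.coords)):
                raise ValueError(f"molecule {self.id}: atom coordinates must be finite 3-vectors")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"molecule {self.id}: bond ({b.i},{b.j}) out of range")
        self._ring_sizes = _ring_membership(n, self.bonds)

    # -- basic views -------------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def partial_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def heavy_indices(self) -> list[int]:
        return [k for k, a in enumerate(self.atoms) if a.element != "H"]

    @property
    def heavy_atom_count(self) -> int:
        return len(self.heavy_indices)

    def neighbors(self, k: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == k:
                out.append(b.j)
            elif b.j == k:
                out.append(b.i)
        return sorted(out)

    def bond_order(self, i: int, j: int) -> float | None:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b.order
        return None

    def ring_sizes(self, k: int) -> tuple[int, ...]:
        """Sizes of the smallest rings atom ``k`` belongs to (empty if acyclic)."""
        return self._ring_sizes.get(k, ())

    def in_ring(self, k: int) -> bool:
        return bool(self._ring_sizes.get(k))

    def translated(self, vec: Sequence[float]) -> "Molecule":
        v = np.asarray(vec, dtype=float)
        atoms = [Atom(a.element, a.coords + v, a.formal_charge, a.partial_charge,
                      a.aromatic, a.n_hydrogens) for a in self.atoms]
        return Molecule(self.id, atoms, list(self.bonds))

    def aromatic_rings(self) -> list[list[int]]:
        """Rings (as atom-index lists) in which every atom is flagged aromatic."""
        return [r for r in _sssr(len(self.atoms), self.bonds)
                if all(self.atoms[k].aromatic for k in r)]

    def ring_centroid(self, ring: Iterable[int]) -> np.ndarray:
        idx = list(ring)
        return self.coords[idx].mean(axis=0)


def _adjacency(n: int, bonds: list[Bond]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for b in bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    return adj


def _sssr(n: int, bonds: list[Bond]) -> list[list[int]]:
    """Small rings by per-bond shortest-cycle search; adequate for drug-sized graphs."""
    adj = _adjacency(n, bonds)
    rings: set[tuple[int, ...]] = set()
    for b in bonds:
        # shortest path i..j avoiding the direct edge closes the smallest ring through it
        adj[b.i].discard(b.j)
        adj[b.j].discard(b.i)
        path = _bfs_path(adj, b.i, b.j)
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
        if path is not None and len(path) <= 8:
            rings.add(tuple(sorted(path)))
    return [list(r) for r in sorted(rings)]


def _bfs_path(adj: list[set[int]], src: int, dst: int) -> list[int] | None:
    prev = {src: -1}
    queue = [src]
    while queue:
        nxt = []
        for u in queue:
            for v in sorted(adj[u]):
                if v not in prev:
                    prev[v] = u
                    if v == dst:
                        path = [v]
                        while path[-1] != src:
                            path.append(prev[path[-1]])
                        return path
                    nxt.append(v)
        queue = nxt
    return None


def _ring_membership(n: int, bonds: list[Bond]) -> dict[int, tuple[int, ...]]:
    member: dict[int, set[int]] = {}
    for ring in _sssr(n, bonds):
        for k in ring:
            member.setdefault(k, set()).add(len(ring))
    return {k: tuple(sorted(v)) for k, v in member.items()}


# -- RDKit bridge ----------------------------------------------------------

def from_rdkit(rdmol, mol_id: str | None = None,
               partial_charges: Sequence[float] | None = None) -> Molecule:
    """Convert an RDKit mol (with a 3D conformer) into a :class:`Molecule`."""
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(
            element=a.GetSymbol(),
            coords=np.array([p.x, p.y, p.z]),
            formal_charge=a.GetFormalCharge(),
            partial_charge=0.0,
            aromatic=a.GetIsAromatic(),
            n_hydrogens=a.GetTotalNumHs(includeNeighbors=True),
        ))
    if partial_charges is not None:
        if len(partial_charges) != len(atoms):
            raise ValueError("partial charge vector length mismatch")
        for a, q in zip(atoms, partial_charges):
            a.partial_charge = float(q)
    bonds = []
    for b in rdmol.GetBonds():
        order = AROMATIC_BOND if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = mol_id
    if name is None:
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "mol"
    return Molecule(name or "mol", atoms, bonds)
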