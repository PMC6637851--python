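"""Synthetic congeneric ligand series with known structure–activity truth.

Real inputs to the pipeline are docked 3D poses of a congeneric series plus
measured activities; neither is needed for testing because the statistical
structure the analysis exploits can be planted.  The generator builds
analogs on a fixed scaffold emulating the classic sigma-receptor
pharmacophore — a protonated amine flanked by a large (phenyl + chain) and a
small (N-methyl) hydrophobic side — all sharing one "receptor" frame, as
docked poses do.  Substituents from a small template library decorate two
attachment points with idealized geometry, so field occupancy differs
between analogs in a controlled way.

True activities are a linear function of field occupancy:

    pKi = base + Σ_regions w_r · occ_r + N(0, σ²)

where for a *steric* effect region occ_r counts heavy atoms inside the
region sphere and for a *charge* effect region occ_r sums partial charges
inside it.  A pipeline that recovers w_r's sign and location from the field
matrix therefore demonstrably works; pure-noise activities (all w_r = 0)
give the negative control.

A toy binding pocket can be generated around the series: a glutamate whose
carboxylate faces the ligand ammonium (the conserved salt-bridge anchor),
plus hydrophobic and aromatic residues lining the scaffold.  Geometry is
template-based, not energy-minimized: plausible, reproducible occupancy is
the goal, not physical accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import buw_scale, compute_field_matrix, pretreat, srd_group
from .io_dataset import ActivityTable, split_dataset
from .molecule import AROMATIC_BOND, Atom, Bond, Molecule
from .pls import contour_maps, fit_pls, select_model
from .proteins import ProteinAtom, ProteinStructure, Residue

# -- scaffold geometry (Å, fixed frame) -------------------------------------
# benzene ring in the xy-plane centered at the origin; chain along +x to the
# ammonium nitrogen; R1 grows from the para ring carbon along −x, R2 replaces
# one N-methyl along +x.

_RING_RADIUS = 1.39
_CHARGE_N = 0.35  # template partial charges, e
_CHARGE_NH = 0.30
_CHARGE_NC = 0.15  # carbons bonded to N+
_CHARGE_O = -0.40
_CHARGE_OH = 0.30
_CHARGE_CL = -0.15
_CHARGE_NAMINE = -0.50


@dataclass
class Effect:
    """One planted activity determinant: a spherical field region."""

    center: tuple[float, float, float]
    radius: float
    weight: float  # pKi units per heavy atom (steric) or per e (charge)
    kind: str = "steric"  # or "charge"

    def occupancy(self, mol: Molecule) -> float:
        c = np.asarray(self.center)
        d = np.linalg.norm(mol.coords - c, axis=1)
        inside = d <= self.radius
        if self.kind == "steric":
            heavy = np.array([a.element != "H" for a in mol.atoms])
            return float(np.sum(inside & heavy))
        if self.kind == "charge":
            return float(np.sum(mol.partial_charges[inside]))
        raise ValueError(f"unknown effect kind {self.kind!r}")


# R1 substituents grow around (−4.2, 0, 0); default effect region sits there.
DEFAULT_EFFECTS = (Effect(center=(-4.2, 0.0, 0.0), radius=2.5, weight=0.4),)


@dataclass
class SyntheticSpec:
    n_compounds: int = 40
    effects: tuple[Effect, ...] = DEFAULT_EFFECTS
    noise_sd: float = 0.3  # pKi units
    base_activity: float = 6.5
    seed: int = 0
    n_test: int = 8
    substituents_r1: tuple[str, ...] = ("H", "Me", "Et", "iPr", "tBu", "Ph",
                                        "OH", "OMe", "Cl", "NH2")
    substituents_r2: tuple[str, ...] = ("Me", "Et", "iPr")

    def __post_init__(self) -> None:
        if self.n_compounds < 5:
            raise ValueError("a congeneric series needs at least 5 compounds")
        if not all(np.isfinite(e.weight) for e in self.effects):
            raise ValueError("effect weights must be finite")


# -- substituent templates: (element, local coords, partial charge, n_H) -----
# local frame: +x is the growth direction away from the attachment atom.

_SUBSTITUENTS: dict[str, list[tuple[str, tuple[float, float, float], float, int]]] = {
    "H": [],
    "Me": [("C", (1.50, 0.0, 0.0), 0.0, 3)],
    "Et": [("C", (1.50, 0.0, 0.0), 0.0, 2), ("C", (2.25, 1.30, 0.0), 0.0, 3)],
    "iPr": [("C", (1.50, 0.0, 0.0), 0.0, 1),
            ("C", (2.25, 1.30, 0.0), 0.0, 3), ("C", (2.25, -1.30, 0.0), 0.0, 3)],
    "tBu": [("C", (1.50, 0.0, 0.0), 0.0, 0),
            ("C", (2.25, 1.30, 0.0), 0.0, 3), ("C", (2.25, -1.30, 0.0), 0.0, 3),
            ("C", (2.25, 0.0, 1.30), 0.0, 3)],
    "Ph": [("C", (1.50, 0.0, 0.0), 0.0, 0),
           ("C", (2.19, 1.20, 0.0), 0.0, 1), ("C", (3.58, 1.20, 0.0), 0.0, 1),
           ("C", (4.28, 0.0, 0.0), 0.0, 1), ("C", (3.58, -1.20, 0.0), 0.0, 1),
           ("C", (2.19, -1.20, 0.0), 0.0, 1)],
    "OH": [("O", (1.40, 0.0, 0.0), _CHARGE_O, 1)],
    "OMe": [("O", (1.40, 0.0, 0.0), _CHARGE_O, 0), ("C", (2.10, 1.25, 0.0), 0.1, 3)],
    "Cl": [("Cl", (1.75, 0.0, 0.0), _CHARGE_CL, 0)],
    "NH2": [("N", (1.45, 0.0, 0.0), _CHARGE_NAMINE, 2)],
}
_SUB_BONDS: dict[str, list[tuple[int, int, float]]] = {
    # bonds among template atoms (0-based within template); attachment bond
    # to the anchor atom is added automatically to template atom 0.
    "H": [], "Me": [], "OH": [], "Cl": [], "NH2": [],
    "Et": [(0, 1, 1.0)],
    "iPr": [(0, 1, 1.0), (0, 2, 1.0)],
    "tBu": [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)],
    "Ph": [(0, 1, AROMATIC_BOND), (1, 2, AROMATIC_BOND), (2, 3, AROMATIC_BOND),
           (3, 4, AROMATIC_BOND), (4, 5, AROMATIC_BOND), (5, 0, AROMATIC_BOND)],
    "OMe": [(0, 1, 1.0)],
}


def _scaffold() -> tuple[list[Atom], list[Bond], int, int, int]:
    """Returns (atoms, bonds, r1_anchor, r2_anchor(N), cation index)."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    # aromatic ring; atom 0 at +x (chain side), atom 3 at −x (R1 side)
    for k in range(6):
        ang = np.pi * k / 3.0
        atoms.append(Atom("C", np.array([_RING_RADIUS * np.cos(ang),
                                         _RING_RADIUS * np.sin(ang), 0.0]),
                          aromatic=True, n_hydrogens=0 if k in (0, 3) else 1))
    for k in range(6):
        bonds.append(Bond(k, (k + 1) % 6, AROMATIC_BOND))
    # chain: ring C0 — CH(CH3) — CH2 — N+(H)(Me)(R2)
    ca = len(atoms)
    atoms.append(Atom("C", np.array([2.89, 0.0, 0.0]), n_hydrogens=1))
    bonds.append(Bond(0, ca, 1.0))
    me = len(atoms)  # the 3-methyl of the 3-phenylbutyl motif
    atoms.append(Atom("C", np.array([3.45, -0.80, 1.20]), n_hydrogens=3))
    bonds.append(Bond(ca, me, 1.0))
    cb = len(atoms)
    atoms.append(Atom("C", np.array([3.64, 1.30, 0.0]), n_hydrogens=2))
    bonds.append(Bond(ca, cb, 1.0))
    n = len(atoms)
    atoms.append(Atom("N", np.array([5.10, 1.30, 0.0]), formal_charge=1,
                      partial_charge=_CHARGE_N, n_hydrogens=1))
    bonds.append(Bond(cb, n, 1.0))
    atoms[cb].partial_charge = _CHARGE_NC
    # explicit H on the ammonium (hydrogen-bond donor geometry)
    h = len(atoms)
    atoms.append(Atom("H", np.array([5.45, 1.30, 0.95]), partial_charge=_CHARGE_NH))
    bonds.append(Bond(n, h, 1.0))
    # one fixed N-methyl (the small hydrophobic side)
    nm = len(atoms)
    atoms.append(Atom("C", np.array([5.75, 0.05, -0.55]), partial_charge=_CHARGE_NC,
                      n_hydrogens=3))
    bonds.append(Bond(n, nm, 1.0))
    return atoms, bonds, 3, n, n


def _attach(atoms: list[Atom], bonds: list[Bond], anchor: int, name: str,
            direction: np.ndarray) -> None:
    """Place a substituent template at ``anchor`` growing along ``direction``."""
    template = _SUBSTITUENTS[name]
    if not template:
        return
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame (x' = growth direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    y_ax = np.cross(ref, direction)
    y_ax /= np.linalg.norm(y_ax)
    z_ax = np.cross(direction, y_ax)
    base = atoms[anchor].coords
    offset = len(atoms)
    for elem, local, q, n_h in template:
        xyz = base + local[0] * direction + local[1] * y_ax + local[2] * z_ax
        atoms.append(Atom(elem, xyz, partial_charge=q, n_hydrogens=n_h,
                          aromatic=(name == "Ph" and elem == "C")))
    for i, j, order in _SUB_BONDS[name]:
        bonds.append(Bond(offset + i, offset + j, order))
    bonds.append(Bond(anchor, offset, 1.0))


def build_analog(r1: str, r2: str, mol_id: str) -> Molecule:
    """One analog: scaffold + R1 (para ring position) + R2 (on the ammonium N)."""
    atoms, bonds, r1_anchor, r2_anchor, _ = _scaffold()
    if r1 != "H":
        atoms[r1_anchor].n_hydrogens = 0
    _attach(atoms, bonds, r1_anchor, r1, np.array([-1.0, 0.0, 0.0]))
    _attach(atoms, bonds, r2_anchor, r2, np.array([0.8, 0.6, 0.0]))
    mol = Molecule(mol_id, atoms, bonds)
    _check_clashes(mol)
    return mol


def _check_clashes(mol: Molecule) -> None:
    coords = mol.coords
    n = len(coords)
    bonded = {(b.i, b.j) for b in mol.bonds} | {(b.j, b.i) for b in mol.bonds}
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            if d[i, j] < 1.0:
                raise ValueError(f"{mol.id}: atoms {i},{j} clash ({d[i, j]:.2f} Å)")


def generate_series(spec: SyntheticSpec) -> tuple[list[Molecule], ActivityTable, dict]:
    """Build the analog series, its activities, and the planted-truth record."""
    rng = np.random.default_rng(spec.seed)
    combos = [(r1, r2) for r1 in spec.substituents_r1 for r2 in spec.substituents_r2]
    order = rng.permutation(len(combos))
    picks = [combos[order[k % len(combos)]] for k in range(spec.n_compounds)]

    mols: list[Molecule] = []
    rows = []
    rejected = []
    for k, (r1, r2) in enumerate(picks):
        mol_id = f"syn{k + 1:03d}"
        try:
            mol = build_analog(r1, r2, mol_id)
        except ValueError as exc:
            rejected.append({"id": mol_id, "reason": str(exc)})
            continue
        signal = sum(e.weight * e.occupancy(mol) for e in spec.effects)
        pki = spec.base_activity + signal + rng.normal(0.0, spec.noise_sd)
        mols.append(mol)
        rows.append({"id": mol_id, "r1": r1, "r2": r2, "pKi": round(pki, 4),
                     "signal": signal})
    table = ActivityTable(pd.DataFrame([{"id": r["id"], "pKi": r["pKi"]} for r in rows]))
    n_test = min(spec.n_test, len(table) // 5)  # keep ~80/20 even for tiny series
    if n_test:
        table = split_dataset(table, n_test, seed=spec.seed + 1)
    truth = {
        "effects": [{"center": list(e.center), "radius": e.radius,
                     "weight": e.weight, "kind": e.kind} for e in spec.effects],
        "base_activity": spec.base_activity,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "compounds": rows,
        "rejected": rejected,
    }
    return mols, table, truth


# ---------------------------------------------------------------------------
# toy pocket


def generate_pocket(series: list[Molecule], include_glu: bool = True,
                    include_leu: bool = True, include_phe: bool = True,
                    include_trp: bool = False) -> ProteinStructure:
    """Residues lining the series: a glutamate carboxylate 3–4 Å from every
    ligand's cationic N (constant scaffold frame makes this one placement),
    a leucine near the large hydrophobic side, a phenylalanine stacked on
    the scaffold ring, optionally a tryptophan."""
    n_pos = np.array([5.10, 1.30, 0.0])  # scaffold ammonium (shared frame)
    residues: list[Residue] = []
    num = 170

    def backbone(offset: np.ndarray) -> list[ProteinAtom]:
        return [
            ProteinAtom("N", "N", offset + np.array([0.0, 0.0, 0.0]), backbone=True),
            ProteinAtom("CA", "C", offset + np.array([1.46, 0.0, 0.0]), backbone=True),
            ProteinAtom("C", "C", offset + np.array([2.20, 1.30, 0.0]), backbone=True),
            ProteinAtom("O", "O", offset + np.array([1.65, 2.40, 0.0]), backbone=True),
        ]

    if include_glu:
        # carboxylate oxygens approach the ammonium from above (+z), on the
        # N-H donor vector, ~3.2 Å from the nitrogen
        oe1 = n_pos + np.array([0.3, 0.2, 3.2])
        oe2 = n_pos + np.array([1.6, 0.1, 3.4])
        cd = n_pos + np.array([1.0, 0.8, 3.9])
        cg = cd + np.array([0.0, 1.2, 0.8])
        cb = cg + np.array([0.0, 1.2, 0.9])
        off = cb + np.array([0.5, 1.3, 0.5])
        atoms = backbone(off) + [
            ProteinAtom("CB", "C", cb), ProteinAtom("CG", "C", cg),
            ProteinAtom("CD", "C", cd), ProteinAtom("OE1", "O", oe1),
            ProteinAtom("OE2", "O", oe2),
        ]
        residues.append(Residue("A", "GLU", num, "", atoms))
        num += 2
    if include_leu:
        cg = np.array([-4.2, 0.0, 3.9])
        atoms = backbone(cg + np.array([1.0, 1.0, 2.5])) + [
            ProteinAtom("CB", "C", cg + np.array([0.5, 0.5, 1.3])),
            ProteinAtom("CG", "C", cg),
            ProteinAtom("CD1", "C", cg + np.array([1.2, -0.7, -0.6])),
            ProteinAtom("CD2", "C", cg + np.array([-1.2, -0.7, -0.6])),
        ]
        residues.append(Residue("A", "LEU", num, "", atoms))
        num += 2
    if include_phe:
        # ring parallel to and 3.8 Å above the scaffold benzene
        center = np.array([0.0, 0.0, 3.8])
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring = []
        for k, nm in enumerate(names):
            ang = np.pi * k / 3.0
            ring.append(ProteinAtom(nm, "C", center + np.array(
                [_RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang), 0.0])))
        cb = center + np.array([2.4, 0.0, 0.8])
        atoms = backbone(cb + np.array([1.2, 0.8, 1.2])) + [
            ProteinAtom("CB", "C", cb)] + ring
        residues.append(Residue("A", "PHE", num, "", atoms))
        num += 2
    if include_trp:
        center = np.array([7.6, 0.0, -3.6])
        five = ("CG", "CD1", "NE1", "CE2", "CD2")
        atoms = backbone(center + np.array([2.0, 2.0, 1.0]))
        for k, nm in enumerate(five):
            ang = 2 * np.pi * k / 5.0
            atoms.append(ProteinAtom(nm, "N" if nm.startswith("N") else "C",
                                     center + np.array([1.17 * np.cos(ang),
                                                        1.17 * np.sin(ang), 0.0])))
        residues.append(Residue("A", "TRP", num, "", atoms))
    structure = ProteinStructure(residues)
    _check_pocket_clash(structure, series)
    return structure


def _check_pocket_clash(structure: ProteinStructure, series: list[Molecule]) -> None:
    prot = structure.heavy_coords()
    for mol in series:
        lig = mol.coords[mol.heavy_indices]
        d = np.linalg.norm(prot[:, None, :] - lig[None, :, :], axis=2)
        if d.min() < 1.8:
            raise ValueError(f"pocket clashes with ligand {mol.id} "
                             f"(min distance {d.min():.2f} Å)")


# ---------------------------------------------------------------------------
# file output


def write_series_sdf(mols: list[Molecule], path: str | Path) -> None:
    """Write the series as V2000 SDF (RDKit writer), partial charges in the
    PARTIAL_CHARGES property."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for mol in mols:
            rw = Chem.RWMol()
            explicit_h = [sum(1 for n in mol.neighbors(k) if mol.atoms[n].element == "H")
                          for k in range(len(mol.atoms))]
            for k, a in enumerate(mol.atoms):
                at = Chem.Atom(a.element)
                at.SetFormalCharge(a.formal_charge)
                if a.element != "H":
                    at.SetNumExplicitHs(max(a.n_hydrogens - explicit_h[k], 0))
                    at.SetNoImplicit(True)
                rw.AddAtom(at)
            for b in mol.bonds:
                order = (Chem.BondType.AROMATIC if b.order == AROMATIC_BOND
                         else Chem.BondType.values[int(b.order)])
                rw.AddBond(b.i, b.j, order)
            m = rw.GetMol()
            Chem.SanitizeMol(m)
            conf = Chem.Conformer(m.GetNumAtoms())
            for k, a in enumerate(mol.atoms):
                conf.SetAtomPosition(k, Point3D(*a.coords))
            m.AddConformer(conf)
            m.SetProp("_Name", mol.id)
            m.SetProp("PARTIAL_CHARGES",
                      " ".join(f"{a.partial_charge:.4f}" for a in mol.atoms))
            writer.write(m)
    finally:
        writer.close()


def write_pocket_pdb(structure: ProteinStructure, path: str | Path) -> None:
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("pocket")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for res in structure.residues:
        sb.init_residue(res.name, " ", res.number, " ")
        for atom in res.atoms:
            sb.init_atom(atom.name, np.asarray(atom.coords, dtype=float), 0.0,
                         1.0, " ", atom.name.ljust(3), None, atom.element.upper())
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def write_outputs(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, str]:
    """Write poses.sdf, pocket.pdb, activities.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mols, table, truth = generate_series(spec)
    pocket = generate_pocket(mols)
    write_series_sdf(mols, out / "poses.sdf")
    write_pocket_pdb(pocket, out / "pocket.pdb")
    table.write_csv(out / "activities.csv")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return {k: str(out / v) for k, v in
            {"poses": "poses.sdf", "pocket": "pocket.pdb",
             "activities": "activities.csv", "truth": "truth.json"}.items()}


# ---------------------------------------------------------------------------
# recovery experiment


def recovery_experiment(spec: SyntheticSpec, spacing: float = 1.0,
                        padding: float = 4.0, nc_range: range = range(1, 6),
                        use_srd: bool = False, region_margin: float = 2.0) -> dict:
    """Full fields→pretreat→BUW→(SRD)→PLS run against the planted truth.

    Reports Q², Rtest², R² and whether the strongest steric coefficient
    region overlaps a planted effect sphere (within ``region_margin`` Å).
    """
    mols, table, truth = generate_series(spec)
    fm = compute_field_matrix(mols, spacing=spacing, padding=padding)
    fm = buw_scale(pretreat(fm))
    if use_srd:
        train_ids = [str(i) for i in table.subset("train")["id"]] or table.ids
        idx = {cid: k for k, cid in enumerate(fm.compound_ids)}
        rows = [idx[i] for i in train_ids]
        sub_y = table.frame.set_index("id").loc[train_ids, "pKi"].to_numpy(dtype=float)
        pre = fit_pls(fm.modeling_matrix()[rows], sub_y,
                      min(3, len(rows) - 1))
        fm = srd_group(fm, np.abs(pre.coef))
    report = select_model(fm, table, nc_range=nc_range)

    maps = contour_maps(report)
    recovered = None
    if "steric" in maps:
        values = maps["steric"]
        nodes = report.matrix.grid.node_coords()
        top = nodes[int(np.argmax(np.abs(values)))]
        top_value = float(values[int(np.argmax(np.abs(values)))])
        recovered = False
        for e in spec.effects:
            if e.kind != "steric":
                continue
            dist = float(np.linalg.norm(top - np.asarray(e.center)))
            if dist <= e.radius + region_margin and np.sign(top_value) == np.sign(e.weight):
                recovered = True
        if not any(e.kind == "steric" for e in spec.effects):
            recovered = None
    return {
        "fields": report.label,
        "n_components": report.n_components,
        "r2": report.r2,
        "q2": report.q2,
        "rtest2": report.rtest2,
        "s_test": report.s_test,
        "contributions": report.contributions,
        "planted_region_recovered": recovered,
        "truth": truth,
    }
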