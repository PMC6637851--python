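"""Dataset I/O: docked poses (SDF), receptor (PDB), activity tables, splits.

Activities are modeled on the pKi scale, pKi = −log10(Ki·10⁻⁶) for Ki in μM.
The train/test split is stratified on activity so both subsets span the full
potency range: rows are rank-ordered by pKi, cut into ``n_test`` equal-rank
bins, and one test compound is drawn per bin with a seeded generator.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .molecule import Molecule, from_rdkit
from .proteins import BACKBONE_NAMES, ProteinAtom, ProteinStructure, Residue

CHARGE_PROPERTY = "PARTIAL_CHARGES"  # SDF property: whitespace-separated e values


def ki_to_pki(ki_um: float) -> float:
    """Convert an inhibition constant in μM to pKi = −log10(Ki in M)."""
    if not (isinstance(ki_um, (int, float)) and math.isfinite(ki_um)) or ki_um <= 0:
        raise ValueError(f"Ki must be a positive finite concentration in μM, got {ki_um!r}")
    return -math.log10(ki_um * 1e-6)


# ---------------------------------------------------------------------------
# SDF poses


def load_poses(sdf_path: str | Path, charge_scheme: str = "mmff94") -> list[Molecule]:
    """Read docked poses from a V2000 SDF, one :class:`Molecule` per record.

    Partial charges come from the ``PARTIAL_CHARGES`` SDF property when
    present; otherwise they are assigned by ``charge_scheme`` ("mmff94" via
    RDKit's MMFF94 bond-charge increments, "gasteiger", or "none").
    Records without 3D coordinates are rejected.
    """
    from rdkit import Chem

    path = Path(sdf_path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Molecule] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"unparsable SDF record at index {idx} in {path.name}")
        if rdmol.GetNumConformers() == 0 or not rdmol.GetConformer().Is3D():
            raise ValueError(f"SDF record {idx} ({_title(rdmol, idx)}) lacks 3D coordinates")
        charges = None
        if rdmol.HasProp(CHARGE_PROPERTY):
            charges = [float(x) for x in rdmol.GetProp(CHARGE_PROPERTY).split()]
        else:
            charges = _assign_charges(rdmol, charge_scheme)
        out.append(from_rdkit(rdmol, mol_id=_title(rdmol, idx), partial_charges=charges))
    return out


def _title(rdmol, idx: int) -> str:
    if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip():
        return rdmol.GetProp("_Name").strip()
    return f"mol_{idx}"


def _assign_charges(rdmol, scheme: str) -> list[float]:
    from rdkit.Chem import AllChem

    n = rdmol.GetNumAtoms()
    if scheme == "none":
        return [0.0] * n
    if scheme == "gasteiger":
        AllChem.ComputeGasteigerCharges(rdmol)
        return [float(a.GetDoubleProp("_GasteigerCharge")) for a in rdmol.GetAtoms()]
    if scheme == "mmff94":
        props = AllChem.MMFFGetMoleculeProperties(rdmol)
        if props is None:  # outside MMFF94 coverage — fall back rather than fail
            AllChem.ComputeGasteigerCharges(rdmol)
            return [float(a.GetDoubleProp("_GasteigerCharge")) for a in rdmol.GetAtoms()]
        return [props.GetMMFFPartialCharge(i) for i in range(n)]
    raise ValueError(f"unknown charge scheme {scheme!r}")


# ---------------------------------------------------------------------------
# PDB receptor


def load_protein(pdb_path: str | Path) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Alternate locations keep the highest-occupancy conformer; backbone flags
    are set for N/CA/C/O/OXT.  A CA-only chain loads with a warning (the
    side-chain-dependent fingerprint bits are then undefined).
    """
    from Bio.PDB import PDBParser

    path = Path(pdb_path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython PDBConstructionWarnings
        structure = PDBParser(QUIET=True).get_structure("receptor", str(path))
    residues: list[Residue] = []
    for model in structure:
        for chain in model:
            for res in chain:
                het, num, icode = res.id
                if het.strip():  # waters / heteroatoms are not receptor residues
                    continue
                atoms = []
                for atom in res:
                    if atom.is_disordered():
                        atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                    name = atom.get_name()
                    atoms.append(ProteinAtom(
                        name=name,
                        element=(atom.element or name[0]).capitalize(),
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        backbone=name in BACKBONE_NAMES,
                    ))
                residues.append(Residue(chain.id, res.get_resname(), num, icode.strip(), atoms))
        break  # first model only
    if not residues:
        raise ValueError(f"{path.name}: no ATOM records found")
    for r in residues:
        if [a.name for a in r.heavy_atoms()] == ["CA"]:
            warnings.warn(f"residue {r.label} has only CA: side-chain-dependent "
                          "fingerprint bits will be undefined", stacklevel=2)
    return ProteinStructure(residues)


# ---------------------------------------------------------------------------
# Activity tables


@dataclass
class ActivityTable:
    """Compound activities with optional train/test split labels.

    Backed by a DataFrame with columns ``id``, ``ki_uM`` (optional, NaN
    allowed), ``pKi`` and ``split`` ∈ {train, test, unassigned}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"id", "pKi"}
        if not required.issubset(df.columns):
            raise ValueError(f"activity table needs columns {sorted(required)}")
        if "split" not in df.columns:
            df = df.assign(split="unassigned")
        if "ki_uM" not in df.columns:
            df = df.assign(ki_uM=np.nan)
        if not np.all(np.isfinite(df["pKi"].to_numpy(dtype=float))):
            raise ValueError("pKi values must be finite")
        bad = set(df["split"]) - {"train", "test", "unassigned"}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")
        both = df.dropna(subset=["ki_uM"])
        if len(both):
            expect = [-math.log10(k * 1e-6) for k in both["ki_uM"]]
            if not np.allclose(both["pKi"], expect, atol=5e-3):
                raise ValueError("pKi inconsistent with Ki: expected pKi = -log10(Ki·1e-6)")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_ki(cls, ids, ki_um) -> "ActivityTable":
        pki = [ki_to_pki(k) for k in ki_um]
        return cls(pd.DataFrame({"id": list(ids), "ki_uM": list(ki_um), "pKi": pki}))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pki(self) -> np.ndarray:
        return self.frame["pKi"].to_numpy(dtype=float)

    @property
    def ids(self) -> list[str]:
        return [str(x) for x in self.frame["id"]]

    def subset(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == split]

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ActivityTable":
        return cls(pd.read_csv(path, dtype={"id": str}))


def split_dataset(table: ActivityTable, n_test: int, seed: int) -> ActivityTable:
    """Stratified activity split: one test compound per equal-rank pKi bin."""
    n = len(table)
    if n_test < 0 or n_test >= n:
        raise ValueError(f"n_test must satisfy 0 <= n_test < {n}, got {n_test}")
    df = table.frame.copy()
    df["split"] = "train"
    if n_test > 0:
        rng = np.random.default_rng(seed)
        order = np.argsort(df["pKi"].to_numpy(), kind="stable")
        bins = np.array_split(order, n_test)
        test_idx = [rng.choice(b) for b in bins]
        df.loc[df.index[test_idx], "split"] = "test"
    return ActivityTable(df)


def load_table1() -> pd.DataFrame:
    """Packaged fixture: the published 80-compound activity table with
    experimental pKi, model-predicted pKi, and the 16-compound test split."""
    ref = importlib.resources.files("fieldsar.data") / "table1.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={"id": str})
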