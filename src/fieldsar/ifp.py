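"""Per-residue protein–ligand interaction fingerprints and pose filtering.

The fingerprint assigns each binding-site residue a set of boolean chemotype
bits per complex: C (any heavy-atom contact), B/S (the contact involves
backbone/side-chain atoms), P (polar), H (hydrophobic), A (hydrogen bond
with the residue as acceptor), D (residue as donor), Ar (aromatic, including
π-cation), Ch (electrostatic between oppositely charged groups).  Occurrence
profiles aggregate the bits over a set of complexes as percentages, which is
how conserved anchoring interactions (e.g. a ligand ammonium salt-bridged to
a glutamate in 100% of poses) are read off.

Pose filtering follows the essential-interaction rule used for congeneric
analog series: among poses satisfying every required interaction, keep the
best-scored one; if none qualifies, keep the overall best scorer but flag it.

All distance cutoffs are configurable; defaults are conventional
structural-bioinformatics values (see :class:`IfpConfig`).  Hydrogen-bond
angle checks apply only where explicit hydrogen coordinates exist; otherwise
the distance criterion alone decides, which is the common situation for
crystallographic receptors stripped of hydrogens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .molecule import Molecule
from .proteins import ProteinStructure, Residue

BIT_NAMES = ("C", "B", "S", "P", "H", "A", "D", "Ar", "Ch")

# side-chain chemistry by residue name
NEGATIVE_SIDECHAIN = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
POSITIVE_SIDECHAIN = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1",), "MET": ("SD",),
}
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "ASN": ("ND2",),
    "GLN": ("NE2",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "TRP": ("NE1",), "HIS": ("NE2",),
}
AROMATIC_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}


@dataclass
class IfpConfig:
    """Distance cutoffs in Å (angle in degrees)."""

    contact: float = 4.5
    hydrophobic: float = 4.5
    polar: float = 4.0
    hbond: float = 3.5
    hbond_angle: float = 120.0
    aromatic: float = 5.0
    pi_cation: float = 4.5
    charged: float = 4.5
    protonate_amines: bool = False  # treat neutral sp3 amines as cationic

    @classmethod
    def from_dict(cls, d: dict) -> "IfpConfig":
        known = {f.name for f in dc_fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown IFP config keys: {sorted(bad)}")
        return cls(**d)


@dataclass
class InteractionBits:
    C: bool = False
    B: bool = False
    S: bool = False
    P: bool = False
    H: bool = False
    A: bool = False
    D: bool = False
    Ar: bool = False
    Ch: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {k: getattr(self, k) for k in BIT_NAMES}

    def any(self) -> bool:
        return any(self.as_dict().values())

    def finalize(self) -> "InteractionBits":
        """Enforce the bit-implication hierarchy (chemotype ⇒ contact, HB ⇒ polar)."""
        if self.A or self.D:
            self.P = True
        if self.P or self.H or self.Ar or self.Ch or self.B or self.S:
            self.C = True
        return self


@dataclass
class ComplexPose:
    protein: ProteinStructure
    ligand: Molecule
    score: float = 0.0  # docking score, kcal/mol, lower is better

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")


@dataclass
class SelectedPose:
    pose: ComplexPose
    compliant: bool


# ---------------------------------------------------------------------------
# ligand chemistry helpers


def cationic_nitrogens(mol: Molecule, protonate_amines: bool = False) -> list[int]:
    out = [k for k, a in enumerate(mol.atoms) if a.element == "N" and a.formal_charge > 0]
    if protonate_amines and not out:
        for k, a in enumerate(mol.atoms):
            if a.element == "N" and a.formal_charge == 0 and not a.aromatic:
                heavy_deg = sum(1 for n in mol.neighbors(k) if mol.atoms[n].element != "H")
                if heavy_deg <= 3:
                    out.append(k)
    return out


def _ligand_donors(mol: Molecule) -> list[int]:
    return [k for k, a in enumerate(mol.atoms)
            if a.element in ("N", "O") and a.n_hydrogens >= 1]


def _ligand_acceptors(mol: Molecule) -> list[int]:
    return [k for k, a in enumerate(mol.atoms)
            if (a.element == "O") or (a.element == "N" and a.formal_charge <= 0)]


def _explicit_h_positions(mol: Molecule, donor: int) -> list[np.ndarray]:
    return [mol.atoms[n].coords for n in mol.neighbors(donor)
            if mol.atoms[n].element == "H"]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b, degrees."""
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _hbond_ok(donor_xyz: np.ndarray, h_positions: list[np.ndarray],
              acceptor_xyz: np.ndarray, cutoff: float, min_angle: float) -> bool:
    if float(np.linalg.norm(donor_xyz - acceptor_xyz)) > cutoff:
        return False
    if not h_positions:
        return True  # no explicit H — distance criterion decides
    return any(_angle_deg(donor_xyz, h, acceptor_xyz) >= min_angle
               for h in h_positions)


# ---------------------------------------------------------------------------
# operations


def detect_salt_bridge(pose: ComplexPose, residue: str | tuple,
                       cutoff: float = 4.5,
                       protonate_amines: bool = False) -> bool:
    """True iff a ligand cationic N lies within ``cutoff`` of the residue's
    charged side-chain oxygens/nitrogens (e.g. a glutamate carboxylate)."""
    res = pose.protein.residue(residue)
    charged_names = NEGATIVE_SIDECHAIN.get(res.name) or POSITIVE_SIDECHAIN.get(res.name)
    if charged_names is None:
        raise ValueError(f"residue {res.label} ({res.name}) has no charged side chain")
    targets = [res.atom(n) for n in charged_names]
    targets = [t for t in targets if t is not None]
    if not targets:
        raise ValueError(f"residue {res.label} is missing its side-chain charged atoms")
    cations = cationic_nitrogens(pose.ligand, protonate_amines)
    if not cations:
        warnings.warn(f"ligand {pose.ligand.id} has no cationic nitrogen; "
                      "salt bridge reported False", stacklevel=2)
        return False
    lc = pose.ligand.coords
    dmin = min(float(np.linalg.norm(lc[k] - t.coords)) for k in cations for t in targets)
    return dmin <= cutoff


def select_pose(poses: list[ComplexPose], essential: list) -> SelectedPose:
    """Best-scored pose among those satisfying all essential-interaction
    predicates; falls back to the overall best scorer, flagged non-compliant."""
    if not poses:
        raise ValueError("no poses supplied")
    ranked = sorted(poses, key=lambda p: (p.score, p.ligand.id))
    for pose in ranked:
        if all(pred(pose) for pred in essential):
            return SelectedPose(pose, True)
    return SelectedPose(ranked[0], False)


def compute_ifp(pose: ComplexPose, config: IfpConfig | None = None
                ) -> dict[str, InteractionBits]:
    """Chemotyped interaction bits for every residue of the complex."""
    cfg = config or IfpConfig()
    lig = pose.ligand
    lig_heavy = lig.heavy_indices
    lc = lig.coords
    lig_cations = cationic_nitrogens(lig, cfg.protonate_amines)
    lig_anions = [k for k in lig_heavy if lig.atoms[k].formal_charge < 0]
    lig_donors = _ligand_donors(lig)
    lig_acceptors = _ligand_acceptors(lig)
    lig_rings = [r for r in lig.aromatic_rings()]

    out: dict[str, InteractionBits] = {}
    for res in pose.protein.residues:
        bits = _residue_bits(res, lig, lc, lig_heavy, lig_cations, lig_anions,
                             lig_donors, lig_acceptors, lig_rings, cfg)
        out[res.label] = bits.finalize()
    return out


def _residue_bits(res: Residue, lig: Molecule, lc, lig_heavy, lig_cations,
                  lig_anions, lig_donors, lig_acceptors, lig_rings,
                  cfg: IfpConfig) -> InteractionBits:
    bits = InteractionBits()
    heavy = res.heavy_atoms()
    if not heavy:
        return bits
    rcoords = np.array([a.coords for a in heavy])
    dmat = np.linalg.norm(rcoords[:, None, :] - lc[None, lig_heavy, :], axis=2)
    within = dmat.min(axis=1) <= cfg.contact
    if within.any():
        bits.C = True
        for a, w in zip(heavy, within):
            if not w:
                continue
            if a.backbone:
                bits.B = True
            else:
                bits.S = True

    # hydrophobic: C/S atoms on both sides
    res_cs = [a for a in heavy if a.element in ("C", "S")]
    lig_cs = [k for k in lig_heavy if lig.atoms[k].element in ("C", "S")]
    if res_cs and lig_cs:
        d = np.linalg.norm(
            np.array([a.coords for a in res_cs])[:, None, :] - lc[None, lig_cs, :], axis=2)
        bits.H = bool(d.min() <= cfg.hydrophobic)

    # polar: residue N/O near ligand N/O or charged atom
    res_no = [a for a in heavy if a.element in ("N", "O")]
    lig_polar = sorted(set(k for k in lig_heavy if lig.atoms[k].element in ("N", "O"))
                       | set(lig_cations) | set(lig_anions))
    if res_no and lig_polar:
        d = np.linalg.norm(
            np.array([a.coords for a in res_no])[:, None, :] - lc[None, lig_polar, :], axis=2)
        bits.P = bool(d.min() <= cfg.polar)

    # hydrogen bonds
    res_acceptors = [a for a in heavy if (a.backbone and a.name in ("O", "OXT"))
                     or a.name in SIDECHAIN_ACCEPTORS.get(res.name, ())]
    res_donors = [a for a in heavy if (a.backbone and a.name == "N" and res.name != "PRO")
                  or a.name in SIDECHAIN_DONORS.get(res.name, ())]
    for acc in res_acceptors:
        if any(_hbond_ok(lc[d], _explicit_h_positions(lig, d), acc.coords,
                         cfg.hbond, cfg.hbond_angle) for d in lig_donors):
            bits.A = True
            break
    for don in res_donors:
        # receptor hydrogens are rarely present; distance-only criterion
        if any(float(np.linalg.norm(don.coords - lc[k])) <= cfg.hbond
               for k in lig_acceptors):
            bits.D = True
            break

    # aromatic / π-cation
    for names in AROMATIC_RING_ATOMS.get(res.name, []):
        ring_atoms = [res.atom(n) for n in names]
        if any(a is None for a in ring_atoms):
            continue
        centroid = np.mean([a.coords for a in ring_atoms], axis=0)
        if any(float(np.linalg.norm(centroid - lig.ring_centroid(r))) <= cfg.aromatic
               for r in lig_rings):
            bits.Ar = True
        if any(float(np.linalg.norm(centroid - lc[k])) <= cfg.pi_cation
               for k in lig_cations):
            bits.Ar = True
    # ligand ring vs residue cation (π-cation, ligand side)
    res_cations = [res.atom(n) for n in POSITIVE_SIDECHAIN.get(res.name, ())]
    for r in lig_rings:
        centroid = lig.ring_centroid(r)
        if any(a is not None and float(np.linalg.norm(centroid - a.coords)) <= cfg.pi_cation
               for a in res_cations):
            bits.Ar = True

    # electrostatic between oppositely charged groups
    res_neg = [res.atom(n) for n in NEGATIVE_SIDECHAIN.get(res.name, ())]
    res_pos = [res.atom(n) for n in POSITIVE_SIDECHAIN.get(res.name, ())]
    pairs = [(res_neg, lig_cations), (res_pos, lig_anions)]
    for res_atoms, lig_idx in pairs:
        for a in res_atoms:
            if a is None:
                continue
            if any(float(np.linalg.norm(a.coords - lc[k])) <= cfg.charged
                   for k in lig_idx):
                bits.Ch = True
    return bits


def occurrence_profile(ifps: list[dict[str, InteractionBits]]) -> pd.DataFrame:
    """Percent of complexes (rows: residues, columns: bits) with each bit set;
    residues never interacting are omitted."""
    if not ifps:
        raise ValueError("need at least one fingerprint")
    residues = sorted({r for f in ifps for r in f},
                      key=lambda s: (int("".join(c for c in s if c.isdigit()) or 0), s))
    rows = {}
    n = len(ifps)
    for r in residues:
        counts = {b: 0 for b in BIT_NAMES}
        for f in ifps:
            bits = f.get(r)
            if bits is None:
                continue
            for b in BIT_NAMES:
                counts[b] += bool(getattr(bits, b))
        pct = {b: 100.0 * c / n for b, c in counts.items()}
        if any(v > 0 for v in pct.values()):
            rows[r] = pct
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BIT_NAMES))
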