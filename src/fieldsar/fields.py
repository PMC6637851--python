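"""Molecular interaction fields on a rectilinear grid (CoMFA-style).

For every aligned compound, a probe — an sp³ carbon bearing a +1 charge —
is evaluated at every node of a regular grid enclosing the whole series:

* steric block: Lennard-Jones 6-12 energy
      E(r) = Σ_i ε_pair [(Rmin_pair / r_i)^12 − 2 (Rmin_pair / r_i)^6]
  with Lorentz–Berthelot-style combination Rmin_pair = Rmin_i/2 + Rmin_p/2,
  ε_pair = sqrt(ε_i ε_p) over the per-element parameter table below;
* electrostatic block: Coulomb energy with a distance-dependent dielectric
      E(r) = Σ_i 332.0637 · q_probe · q_i / (ε(r_i) · r_i),  ε(r) = r,
  q_probe = +1 e, charges in e, distances in Å, energies in kcal/mol.

Pretreatment truncates extreme values (cap +30 kcal/mol; electrostatics also
floored at −30), zeroes values below 0.05 kcal/mol, and kills variables with
few distinct values (n-level) or zero variance.  Block Unscaled Weighting
(BUW) rescales each field block to unit total column variance so neither
block dominates the regression by sheer magnitude.  Smart Region Definition
(SRD) groups grid variables into spatially contiguous regions around
high-weight seed variables, merges collinear neighbouring regions, and drops
unassigned variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .molecule import Molecule

COULOMB_K = 332.0637  # kcal·Å/(mol·e²)

# per-element vdW parameters: (Rmin/2 in Å, ε in kcal/mol).
# Values are a pinned, documented table of conventional force-field magnitudes
# (well depths and minimum-energy radii of common organic elements); the
# probe row ("C.3") doubles as the sp3-carbon probe parameters.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.022),
    "C": (1.95, 0.070),
    "N": (1.85, 0.170),
    "O": (1.70, 0.120),
    "F": (1.70, 0.061),
    "S": (2.00, 0.250),
    "Cl": (1.98, 0.227),
    "Br": (2.13, 0.320),
    "I": (2.26, 0.400),
    "P": (2.10, 0.200),
}
PROBE_VDW = VDW_PARAMS["C"]
PROBE_CHARGE = 1.0


@dataclass
class Grid:
    origin: np.ndarray  # Å
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 3) Cartesian coordinates, x fastest-varying last axis order."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return self.origin + idx * self.spacing

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "spacing": self.spacing,
                "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(np.array(d["origin"]), float(d["spacing"]), tuple(d["shape"]))


def build_grid(molecules: list[Molecule], spacing: float = 1.0,
               padding: float = 5.0) -> Grid:
    """Grid box enclosing every atom of the series plus ``padding`` Å."""
    if not molecules:
        raise ValueError("cannot build a grid around an empty molecule set")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = tuple(int(np.floor((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return Grid(lo, spacing, shape)


# ---------------------------------------------------------------------------
# probe energies


def steric_energy(nodes: np.ndarray, mol: Molecule) -> np.ndarray:
    """Lennard-Jones probe energy at each node, kcal/mol (uncapped)."""
    elements = mol.elements
    missing = sorted({e for e in elements if e not in VDW_PARAMS})
    if missing:
        raise ValueError(f"no vdW parameters for element(s): {missing}")
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    coords = mol.coords
    r = np.linalg.norm(nodes[:, None, :] - coords[None, :, :], axis=2)
    r = np.maximum(r, 1e-6)
    rmin = np.array([VDW_PARAMS[e][0] + PROBE_VDW[0] for e in elements])
    eps = np.array([np.sqrt(VDW_PARAMS[e][1] * PROBE_VDW[1]) for e in elements])
    x6 = (rmin[None, :] / r) ** 6
    return np.sum(eps[None, :] * (x6 * x6 - 2.0 * x6), axis=1)


def electrostatic_energy(nodes: np.ndarray, mol: Molecule) -> np.ndarray:
    """Coulomb probe energy with distance-dependent dielectric ε(r)=r."""
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    q = mol.partial_charges
    coords = mol.coords
    r = np.linalg.norm(nodes[:, None, :] - coords[None, :, :], axis=2)
    r = np.maximum(r, 1e-6)
    return np.sum(COULOMB_K * PROBE_CHARGE * q[None, :] / (r * r), axis=1)


# ---------------------------------------------------------------------------
# the data matrix


@dataclass
class FieldMatrix:
    """compounds × grid-variables energy matrix, two blocks (steric, electrostatic).

    ``X`` keeps all variables; ``alive`` masks the ones used for modeling.
    ``block`` holds the field label per column; ``node`` the grid-node index.
    """

    compound_ids: list[str]
    X: np.ndarray
    block: np.ndarray  # str per column: "steric" | "electrostatic"
    node: np.ndarray  # grid node index per column
    grid: Grid
    alive: np.ndarray = field(default=None)  # type: ignore[assignment]
    block_weights: dict = field(default_factory=dict)
    region: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.alive is None:
            self.alive = np.ones(self.X.shape[1], dtype=bool)
        if self.region is None:
            self.region = np.full(self.X.shape[1], -1, dtype=int)

    @property
    def blocks(self) -> list[str]:
        seen = []
        for b in self.block:
            if b not in seen:
                seen.append(b)
        return seen

    def restrict(self, fields_: list[str]) -> "FieldMatrix":
        keep = np.isin(self.block, fields_)
        return FieldMatrix(self.compound_ids, self.X[:, keep], self.block[keep],
                           self.node[keep], self.grid, self.alive[keep],
                           dict(self.block_weights), self.region[keep])

    def modeling_matrix(self) -> np.ndarray:
        return self.X[:, self.alive]


def compute_field_matrix(molecules: list[Molecule], grid: Grid | None = None,
                         spacing: float = 1.0, padding: float = 5.0,
                         fields_: tuple[str, ...] = ("steric", "electrostatic"),
                         ) -> FieldMatrix:
    """Evaluate the probe energies of every compound on the shared grid."""
    if grid is None:
        grid = build_grid(molecules, spacing=spacing, padding=padding)
    nodes = grid.node_coords()
    blocks, cols, node_idx = [], [], []
    for name in fields_:
        fn = steric_energy if name == "steric" else electrostatic_energy
        block = np.stack([fn(nodes, m) for m in molecules])
        cols.append(block)
        blocks.extend([name] * grid.n_nodes)
        node_idx.extend(range(grid.n_nodes))
    X = np.hstack(cols)
    return FieldMatrix([m.id for m in molecules], X, np.array(blocks),
                       np.array(node_idx), grid)


def pretreat(matrix: FieldMatrix, cap: float = 30.0, zero_threshold: float = 0.05,
             nlevel_max: int = 4) -> FieldMatrix:
    """Cap extremes, zero near-zero energies, kill n-level/constant variables."""
    if cap <= zero_threshold:
        raise ValueError("cap must exceed the zero threshold")
    X = matrix.X.copy()
    X[X > cap] = cap
    elec = matrix.block == "electrostatic"
    X[:, elec] = np.maximum(X[:, elec], -cap)
    X[np.abs(X) < zero_threshold] = 0.0
    alive = matrix.alive.copy()
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        if len(vals) <= nlevel_max or np.ptp(X[:, j]) == 0.0:
            alive[j] = False
    return FieldMatrix(matrix.compound_ids, X, matrix.block, matrix.node,
                       matrix.grid, alive, dict(matrix.block_weights),
                       matrix.region.copy())


def buw_scale(matrix: FieldMatrix) -> FieldMatrix:
    """Block Unscaled Weighting: each block scaled to unit total column variance."""
    X = matrix.X.copy()
    weights: dict[str, float] = {}
    for b in matrix.blocks:
        cols = (matrix.block == b) & matrix.alive
        if not cols.any():
            raise ValueError(f"block {b!r} has no alive variables")
        total_var = float(np.var(X[:, cols], axis=0, ddof=1).sum())
        if total_var <= 0:
            raise ValueError(f"block {b!r} has zero total variance")
        w = 1.0 / np.sqrt(total_var)
        X[:, matrix.block == b] *= w
        weights[b] = w
    return FieldMatrix(matrix.compound_ids, X, matrix.block, matrix.node,
                       matrix.grid, matrix.alive.copy(), weights,
                       matrix.region.copy())


# ---------------------------------------------------------------------------
# Smart Region Definition


def srd_group(matrix: FieldMatrix, weights: np.ndarray, n_seeds: int | None = None,
              critical_distance: float = 2.0, collinearity_cutoff: float = 0.8,
              ) -> FieldMatrix:
    """Group alive variables into spatial regions around high-|weight| seeds.

    ``weights`` is a per-alive-variable importance from a preliminary PLS fit
    (e.g. |coefficients|).  Seeds are picked per block; alive variables within
    ``critical_distance`` of a seed join the nearest one (Voronoi); adjacent
    regions whose compound profiles correlate above ``collinearity_cutoff``
    are merged; variables in no region are dropped (alive set to False).
    """
    alive_idx = np.flatnonzero(matrix.alive)
    if len(weights) != len(alive_idx):
        raise ValueError("one weight per alive variable required")
    nodes = matrix.grid.node_coords()
    region = np.full(matrix.X.shape[1], -1, dtype=int)

    seed_cols: list[int] = []
    for b in matrix.blocks:
        in_block = [k for k, col in enumerate(alive_idx) if matrix.block[col] == b]
        if not in_block:
            continue
        nb = n_seeds if n_seeds is not None else max(1, min(200, len(in_block) // 10))
        if nb < 1 or nb > len(in_block):
            raise ValueError(f"n_seeds must be in 1..{len(in_block)} for block {b!r}")
        order = sorted(in_block, key=lambda k: (-abs(weights[k]), alive_idx[k]))
        seed_cols.extend(alive_idx[k] for k in order[:nb])

    seed_xyz = nodes[matrix.node[seed_cols]]
    seed_block = matrix.block[seed_cols]
    for rid, col in enumerate(seed_cols):
        region[col] = rid
    for col in alive_idx:
        if region[col] >= 0:
            continue
        same = seed_block == matrix.block[col]
        if not same.any():
            continue
        d = np.linalg.norm(seed_xyz - nodes[matrix.node[col]], axis=1)
        d[~same] = np.inf
        k = int(np.argmin(d))
        if d[k] <= critical_distance:
            region[col] = k

    region = _merge_collinear(matrix, region, nodes, collinearity_cutoff)

    alive = matrix.alive & (region >= 0)
    return FieldMatrix(matrix.compound_ids, matrix.X.copy(), matrix.block,
                       matrix.node, matrix.grid, alive,
                       dict(matrix.block_weights), region)


def _merge_collinear(matrix: FieldMatrix, region: np.ndarray, nodes: np.ndarray,
                     cutoff: float) -> np.ndarray:
    """Union spatially adjacent regions whose mean profiles correlate ≥ cutoff."""
    spacing = matrix.grid.spacing
    ids = sorted(set(region[region >= 0]))
    parent = {r: r for r in ids}

    def find(r):
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    profiles = {}
    coords = {}
    for r in ids:
        cols = np.flatnonzero(region == r)
        profiles[r] = matrix.X[:, cols].mean(axis=1)
        coords[r] = nodes[matrix.node[cols]]
    for a_i, ra in enumerate(ids):
        for rb in ids[a_i + 1:]:
            if matrix.block[np.flatnonzero(region == ra)[0]] != \
               matrix.block[np.flatnonzero(region == rb)[0]]:
                continue
            dmin = np.min(np.linalg.norm(
                coords[ra][:, None, :] - coords[rb][None, :, :], axis=2))
            if dmin > 1.5 * spacing:
                continue
            pa, pb = profiles[ra], profiles[rb]
            if np.std(pa) == 0 or np.std(pb) == 0:
                continue
            if abs(np.corrcoef(pa, pb)[0, 1]) >= cutoff:
                parent[find(rb)] = find(ra)
    out = region.copy()
    for r in ids:
        out[region == r] = find(r)
    return out


# ---------------------------------------------------------------------------
# OpenDX export


def write_dx(path: str | Path, grid: Grid, values: np.ndarray,
             name: str = "field") -> None:
    """Write a scalar grid in OpenDX volumetric text format."""
    nx, ny, nz = grid.shape
    v = np.asarray(values, dtype=float).reshape(nx * ny * nz)
    with open(path, "w") as f:
        f.write(f"# {name}\n")
        f.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        f.write("origin {:.4f} {:.4f} {:.4f}\n".format(*grid.origin))
        f.write(f"delta {grid.spacing:.4f} 0 0\n")
        f.write(f"delta 0 {grid.spacing:.4f} 0\n")
        f.write(f"delta 0 0 {grid.spacing:.4f}\n")
        f.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        f.write(f"object 3 class array type double rank 0 items {v.size} data follows\n")
        for i in range(0, v.size, 3):
            f.write(" ".join(f"{x:.6e}" for x in v[i:i + 3]) + "\n")
        f.write('attribute "dep" string "positions"\n')
        f.write(f'object "{name}" class field\n')
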