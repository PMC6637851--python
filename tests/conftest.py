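import numpy as np
import pytest

from fieldsar import Atom, Bond, Molecule
from fieldsar.synthetic import SyntheticSpec, generate_pocket, generate_series


@pytest.fixture(scope="session")
def small_series():
    """Deterministic 20-compound synthetic series with the default planted effect."""
    spec = SyntheticSpec(n_compounds=20, seed=11)
    mols, table, truth = generate_series(spec)
    return mols, table, truth


@pytest.fixture(scope="session")
def pocket(small_series):
    mols, _, _ = small_series
    return generate_pocket(mols, include_trp=True)


def linear_molecule(mol_id, elements, spacing=1.5, orders=None, charges=None):
    """A chain molecule along +x with uniform bond length; test helper."""
    atoms = [Atom(e, np.array([k * spacing, 0.0, 0.0]),
                  partial_charge=(charges[k] if charges else 0.0))
             for k, e in enumerate(elements)]
    bonds = [Bond(k, k + 1, (orders[k] if orders else 1.0))
             for k in range(len(elements) - 1)]
    return Molecule(mol_id, atoms, bonds)


def ring_molecule(mol_id, n, element="C", radius=None, aromatic=False):
    """A planar n-membered carbon ring; test helper."""
    from fieldsar.molecule import AROMATIC_BOND

    r = radius if radius is not None else 1.5 / (2 * np.sin(np.pi / n))
    atoms = [Atom(element, np.array([r * np.cos(2 * np.pi * k / n),
                                     r * np.sin(2 * np.pi * k / n), 0.0]),
                  aromatic=aromatic) for k in range(n)]
    order = AROMATIC_BOND if aromatic else 1.0
    bonds = [Bond(k, (k + 1) % n, order) for k in range(n)]
    return Molecule(mol_id, atoms, bonds)


def random_molecule(rng, n_heavy, extra_edge_prob=0.3):
    """Random connected molecular graph (tree + optional ring-closing edge)
    with random 3D coordinates; used against brute-force oracles."""
    elements = rng.choice(["C", "C", "C", "N", "O"], size=n_heavy)
    coords = rng.normal(scale=3.0, size=(n_heavy, 3))
    atoms = [Atom(str(e), c) for e, c in zip(elements, coords)]
    bonds = [Bond(int(rng.integers(0, k)), k, 1.0) for k in range(1, n_heavy)]
    if n_heavy >= 4 and rng.random() < extra_edge_prob:
        existing = {(b.i, b.j) for b in bonds} | {(b.j, b.i) for b in bonds}
        i, j = sorted(rng.choice(n_heavy, size=2, replace=False))
        if (int(i), int(j)) not in existing:
            bonds.append(Bond(int(i), int(j), 1.0))
    return Molecule("rand", atoms, bonds)
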