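import numpy as np
import pytest

from fieldsar import Atom, Bond, Molecule, build_grid, buw_scale, compute_field_matrix, electrostatic_energy, pretreat, srd_group, steric_energy
from fieldsar.fields import COULOMB_K, PROBE_VDW, VDW_PARAMS, FieldMatrix, Grid

from .conftest import linear_molecule


def point_molecule(element="C", pos=(0.0, 0.0, 0.0), q=0.0):
    return Molecule("pt", [Atom(element, np.array(pos), partial_charge=q)], [])


class TestBuildGrid:
    def test_single_atom_padding_5(self):
        g = build_grid([point_molecule()], spacing=1.0, padding=5.0)
        assert g.shape == (11, 11, 11)
        assert np.allclose(g.origin, [-5, -5, -5])

    def test_doubling_spacing_halves_counts(self):
        mols = [linear_molecule("m", ["C"] * 8, spacing=1.5)]
        g1 = build_grid(mols, spacing=1.0, padding=5.0)
        g2 = build_grid(mols, spacing=2.0, padding=5.0)
        for a, b in zip(g1.shape, g2.shape):
            assert abs(b - (a + 1) // 2) <= 1

    def test_zero_padding_single_atom(self):
        g = build_grid([point_molecule()], spacing=1.0, padding=0.0)
        assert g.shape == (1, 1, 1)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestStericEnergy:
    def test_asymptotic_decay(self):
        e = steric_energy(np.array([[20.0, 0.0, 0.0]]), point_molecule())[0]
        assert abs(e) < 0.01

    def test_minimum_is_minus_well_depth(self):
        # closed-form LJ minimum for the C(probe)–C pair
        rmin = VDW_PARAMS["C"][0] + PROBE_VDW[0]
        eps = np.sqrt(VDW_PARAMS["C"][1] * PROBE_VDW[1])
        e = steric_energy(np.array([[rmin, 0.0, 0.0]]), point_molecule())[0]
        assert e == pytest.approx(-eps, rel=1e-9)

    def test_steeply_positive_at_contact(self):
        e = steric_energy(np.array([[0.5, 0.0, 0.0]]), point_molecule())[0]
        assert e > 1e3  # capped to +30 by pretreatment downstream

    def test_unparameterized_element_errors(self):
        with pytest.raises(ValueError, match="Xx"):
            steric_energy(np.zeros((1, 3)), point_molecule(element="Xx"))


class TestElectrostaticEnergy:
    def test_hand_value_distance_dependent_dielectric(self):
        # q=+0.5 e at 4 Å with ε(r)=r: 332.0637·0.5/16
        mol = point_molecule(q=0.5)
        e = electrostatic_energy(np.array([[4.0, 0.0, 0.0]]), mol)[0]
        assert e == pytest.approx(COULOMB_K * 0.5 / 16.0, rel=1e-12)

    def test_neutral_molecule_is_zero(self):
        mol = linear_molecule("m", ["C", "C", "C"])
        e = electrostatic_energy(np.array([[3.0, 1.0, 0.0]]), mol)
        assert np.allclose(e, 0.0)

    def test_odd_in_charge(self):
        plus = point_molecule(q=0.3)
        minus = point_molecule(q=-0.3)
        node = np.array([[2.5, 1.0, 0.5]])
        assert electrostatic_energy(node, plus)[0] == pytest.approx(
            -electrostatic_energy(node, minus)[0], rel=1e-12)


def toy_matrix(X, blocks=None, grid=None):
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    blocks = np.array(blocks if blocks is not None else ["steric"] * p)
    if grid is None:
        n = int(np.ceil(p ** (1 / 3))) + 1
        grid = Grid(np.zeros(3), 1.0, (n, n, n))
    return FieldMatrix([f"c{i}" for i in range(X.shape[0])], X, blocks,
                       np.arange(p), grid)


class TestPretreat:
    def test_cap_and_floor(self):
        fm = toy_matrix(np.array([[50.0, -50.0], [1.0, 2.0], [0.5, -1.0], [2.0, 3.0],
                                  [3.0, 1.5]]),
                        blocks=["steric", "electrostatic"])
        out = pretreat(fm)
        assert out.X[0, 0] == 30.0
        assert out.X[0, 1] == -30.0  # electrostatic floor

    def test_steric_not_floored(self):
        fm = toy_matrix(np.array([[-50.0], [1.0], [2.0], [0.5], [3.0]]))
        assert pretreat(fm).X[0, 0] == -50.0

    def test_zero_threshold(self):
        fm = toy_matrix(np.array([[0.04], [-0.04], [1.0], [2.0], [3.0]]))
        out = pretreat(fm)
        assert out.X[0, 0] == 0.0 and out.X[1, 0] == 0.0

    def test_nlevel_variable_dies(self):
        col = np.array([0.0, 0.0, 30.0, 30.0, 0.0, 30.0])[:, None]
        varied = np.linspace(1, 6, 6)[:, None]
        fm = toy_matrix(np.hstack([col, varied]))
        out = pretreat(fm)
        assert not out.alive[0] and out.alive[1]

    def test_bad_config_errors(self):
        with pytest.raises(ValueError):
            pretreat(toy_matrix(np.ones((3, 2))), cap=0.01, zero_threshold=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_on_fuzzed_matrices(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(scale=30, size=(12, 40))
        out = pretreat(toy_matrix(X))
        assert out.X.max() <= 30.0
        nz = out.X[out.X != 0]
        assert np.all(np.abs(nz) >= 0.05)
        for j in np.flatnonzero(out.alive):
            assert len(np.unique(out.X[:, j])) > 4


class TestBuwScale:
    def test_block_weights_from_total_variance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        a *= np.sqrt(4.0 / np.var(a, ddof=1, axis=0).sum())
        b = rng.normal(size=(20, 2))
        b *= np.sqrt(9.0 / np.var(b, ddof=1, axis=0).sum())
        fm = toy_matrix(np.hstack([a, b]),
                        blocks=["steric"] * 3 + ["electrostatic"] * 2)
        out = buw_scale(fm)
        assert out.block_weights["steric"] == pytest.approx(0.5, rel=1e-9)
        assert out.block_weights["electrostatic"] == pytest.approx(1 / 3, rel=1e-9)

    def test_unit_total_variance_per_block(self):
        rng = np.random.default_rng(2)
        fm = toy_matrix(rng.normal(scale=7, size=(15, 8)),
                        blocks=["steric"] * 5 + ["electrostatic"] * 3)
        out = buw_scale(fm)
        for b in out.blocks:
            cols = (out.block == b) & out.alive
            assert np.var(out.X[:, cols], ddof=1, axis=0).sum() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        fm = toy_matrix(rng.normal(size=(10, 6)))
        once = buw_scale(fm)
        twice = buw_scale(once)
        assert np.allclose(once.X, twice.X, atol=1e-12)

    def test_zero_variance_block_errors(self):
        fm = toy_matrix(np.ones((5, 3)))
        with pytest.raises(ValueError):
            buw_scale(fm)


class TestEquivariance:
    def test_rigid_transform_of_molecules_and_grid(self, small_series):
        mols, _, _ = small_series
        mols = mols[:4]
        fm = compute_field_matrix(mols, spacing=2.0, padding=3.0)
        # rotate 90° about z then translate — grid rebuilt around the set
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        shift = np.array([3.0, -2.0, 7.0])
        moved = []
        for m in mols:
            atoms = [Atom(a.element, rot @ a.coords + shift, a.formal_charge,
                          a.partial_charge, a.aromatic, a.n_hydrogens) for a in m.atoms]
            moved.append(Molecule(m.id, atoms, list(m.bonds)))
        g = fm.grid
        new_origin = rot @ g.origin + shift
        # rotating the box by 90° about z permutes the x/y axes
        new_shape = (g.shape[1], g.shape[0], g.shape[2])
        corner = new_origin - np.array([(g.shape[1] - 1) * g.spacing, 0.0, 0.0])
        moved_grid = Grid(corner, g.spacing, new_shape)
        fm2 = compute_field_matrix(moved, grid=moved_grid)
        # same multiset of energies per compound per block
        for b in ("steric", "electrostatic"):
            a = np.sort(fm.X[:, fm.block == b], axis=1)
            c = np.sort(fm2.X[:, fm2.block == b], axis=1)
            assert np.allclose(a, c, atol=1e-6)


class TestSrdGroup:
    def _clustered_matrix(self):
        rng = np.random.default_rng(5)
        grid = Grid(np.zeros(3), 1.0, (12, 1, 1))
        # two well-separated variable clusters along x: nodes 0-2 and 9-11
        n = 16
        base1 = rng.normal(size=n)
        base2 = rng.normal(size=n)
        X = np.zeros((n, 6))
        cols = [0, 1, 2, 9, 10, 11]
        for k, node in enumerate(cols):
            src = base1 if node < 5 else base2
            X[:, k] = src + 0.01 * rng.normal(size=n)
        fm = FieldMatrix([f"c{i}" for i in range(n)], X,
                         np.array(["steric"] * 6), np.array(cols), grid)
        return fm

    def test_two_clusters_two_seeds(self):
        fm = self._clustered_matrix()
        w = np.array([1.0, 0.1, 0.1, 1.0, 0.1, 0.1])
        out = srd_group(fm, w, n_seeds=2, critical_distance=2.5)
        regions = out.region[out.alive]
        assert len(set(regions)) == 2
        # the clusters stay intact
        left = set(out.region[:3])
        right = set(out.region[3:])
        assert left.isdisjoint(right)

    def test_identical_adjacent_regions_merge(self):
        rng = np.random.default_rng(6)
        grid = Grid(np.zeros(3), 1.0, (4, 1, 1))
        prof = rng.normal(size=10)
        X = np.column_stack([prof, prof * 2.0, prof * 0.5, prof])
        fm = FieldMatrix([f"c{i}" for i in range(10)], X,
                         np.array(["steric"] * 4), np.arange(4), grid)
        out = srd_group(fm, np.array([1.0, 0.9, 0.8, 0.7]), n_seeds=4,
                        critical_distance=1.0, collinearity_cutoff=0.99)
        assert len(set(out.region[out.alive])) == 1

    def test_zero_critical_distance_keeps_seeds_only(self):
        fm = self._clustered_matrix()
        w = np.ones(6)
        out = srd_group(fm, w, n_seeds=2, critical_distance=0.0,
                        collinearity_cutoff=1.1)  # no merging
        assert int(out.alive.sum()) == 2

    def test_orphans_dropped_from_modeling(self):
        fm = self._clustered_matrix()
        w = np.array([1.0, 0.1, 0.1, 0.9, 0.1, 0.1])
        out = srd_group(fm, w, n_seeds=1, critical_distance=1.5)
        assert out.alive.sum() < fm.alive.sum()

    def test_deterministic(self):
        fm = self._clustered_matrix()
        w = np.ones(6)
        a = srd_group(fm, w, n_seeds=2)
        b = srd_group(fm, w, n_seeds=2)
        assert np.array_equal(a.region, b.region)

    def test_bad_n_seeds(self):
        fm = self._clustered_matrix()
        with pytest.raises(ValueError):
            srd_group(fm, np.ones(6), n_seeds=0)
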