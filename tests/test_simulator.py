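import dataclasses

import numpy as np
import pytest

from hicpoly.preprocess import distance_normalize, compartment_pc1
from hicpoly.simulator import (
    GridAssignment,
    InteractionParams,
    PolymerConfig,
    StructureEnsemble,
    assign_grid,
    bonded_energy,
    contact_map_from_ensemble,
    mean_distance_matrix,
    nonbonded_energy,
    sample_ensemble,
    toeplitz_from_diagonals,
)


class TestInteractionParams:
    def test_u_is_sum(self):
        L = np.array([[1.0, 2.0], [2.0, 1.0]])
        T = np.array([[0.5, -1.0], [-1.0, 0.5]])
        p = InteractionParams(L, T)
        np.testing.assert_array_equal(p.U, L + T)

    def test_non_toeplitz_rejected(self):
        L = np.zeros((3, 3))
        T = np.diag([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="Toeplitz"):
            InteractionParams(L, T)

    def test_asymmetric_L_rejected(self):
        L = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            InteractionParams(L, np.zeros((2, 2)))

    def test_from_chi_rank(self):
        rng = np.random.default_rng(0)
        Psi = rng.standard_normal((20, 3))
        chi = rng.standard_normal((3, 3))
        p = InteractionParams.from_chi(Psi, chi, np.zeros(20))
        assert np.linalg.matrix_rank(p.L, tol=1e-10) <= 3


class TestBondedEnergy:
    def test_coincident_beads_zero(self):
        assert bonded_energy(np.zeros((5, 3)), b=200.0) == 0.0

    def test_two_beads_at_bond_length(self):
        coords = np.array([[0.0, 0.0, 0.0], [200.0, 0.0, 0.0]])
        assert bonded_energy(coords, b=200.0) == pytest.approx(1.5)

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        coords = rng.standard_normal((10, 3)) * 100
        e1 = bonded_energy(coords, b=200.0)
        e2 = bonded_energy(2.0 * coords, b=200.0)
        assert e2 == pytest.approx(4.0 * e1)

    def test_nonfinite_rejected(self):
        coords = np.zeros((3, 3))
        coords[1, 1] = np.inf
        with pytest.raises(ValueError):
            bonded_energy(coords, b=200.0)


class TestGridAssignment:
    def test_nearby_beads_same_cell(self):
        coords = np.array([[50.0, 50.0, 50.0], [70.0, 50.0, 50.0]])
        a = assign_grid(coords, 200.0, np.zeros(3))
        assert np.array_equal(a.cells[0], a.cells[1])

    def test_boundary_straddle_offset(self):
        # beads at 190 and 210 straddle the cell edge at 200 for zero
        # offset; a half-cell offset places both in one cell
        coords = np.array([[190.0, 0.0, 0.0], [210.0, 0.0, 0.0]])
        a0 = assign_grid(coords, 200.0, np.zeros(3))
        assert not np.array_equal(a0.cells[0], a0.cells[1])
        a1 = assign_grid(coords, 200.0, np.array([100.0, 0.0, 0.0]))
        assert np.array_equal(a1.cells[0], a1.cells[1])
        # direct floor computation oracle
        assert a0.cells[0, 0] == np.floor(190.0 / 200.0)
        assert a0.cells[1, 0] == np.floor(210.0 / 200.0)

    def test_indicator_symmetric_reflexive(self):
        rng = np.random.default_rng(2)
        coords = rng.random((12, 3)) * 1000
        I = assign_grid(coords, 200.0, rng.random(3) * 200).indicator()
        np.testing.assert_array_equal(I, I.T)
        np.testing.assert_array_equal(np.diag(I), np.ones(12))


class TestNonbondedEnergy:
    def test_zero_U(self):
        coords = np.zeros((5, 3))
        a = assign_grid(coords, 200.0, np.zeros(3))
        assert nonbonded_energy(a, np.zeros((5, 5))) == 0.0

    def test_single_pair(self):
        coords = np.array([[10.0, 10, 10], [20.0, 10, 10], [500.0, 500, 500]])
        a = assign_grid(coords, 200.0, np.zeros(3))
        U = np.zeros((3, 3))
        U[0, 1] = U[1, 0] = -1.0
        assert nonbonded_energy(a, U) == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            coords = rng.random((10, 3)) * 600
            U = rng.standard_normal((10, 10))
            U = 0.5 * (U + U.T)
            a = assign_grid(coords, 200.0, rng.random(3) * 200)
            expected = 0.0
            for i in range(10):
                for j in range(i + 1, 10):
                    if np.array_equal(a.cells[i], a.cells[j]):
                        expected += U[i, j]
            assert nonbonded_energy(a, U) == pytest.approx(expected)


class TestSampling:
    def test_determinism(self, fast_poly_cfg):
        params = InteractionParams.zeros(fast_poly_cfg.m)
        e1 = sample_ensemble(params, fast_poly_cfg)
        e2 = sample_ensemble(params, fast_poly_cfg)
        np.testing.assert_array_equal(e1.coords, e2.coords)
        np.testing.assert_array_equal(e1.offsets, e2.offsets)

    def test_coords_in_box(self, fast_poly_cfg):
        params = InteractionParams.zeros(fast_poly_cfg.m)
        ens = sample_ensemble(params, fast_poly_cfg)
        assert ens.coords.min() >= 0.0
        assert ens.coords.max() <= fast_poly_cfg.box_nm

    def test_gaussian_chain_bond_length(self):
        # detailed balance proxy: with U = 0 mean squared bond length = b^2
        cfg = PolymerConfig(
            m=32, volume_um3=8000.0, n_structures=400,
            n_equilibration_sweeps=50, n_sweeps_between_samples=3, seed=5,
        )
        ens = sample_ensemble(InteractionParams.zeros(32), cfg)
        d = np.diff(ens.coords, axis=1)
        bsq = (d**2).sum(-1)
        mean = bsq.mean()
        se = bsq.mean(axis=1).std(ddof=1) / np.sqrt(len(bsq))
        b2 = cfg.bond_length_nm**2
        assert abs(mean - b2) < 3 * max(se, 0.01 * b2)

    def test_energy_bookkeeping_debug_mode(self):
        rng = np.random.default_rng(8)
        m = 24
        L = rng.standard_normal((m, m)) * 0.3
        L = 0.5 * (L + L.T)
        params = InteractionParams(L, toeplitz_from_diagonals(-0.3 / (1.0 + np.arange(m))))
        cfg = PolymerConfig(
            m=m, n_structures=50, n_equilibration_sweeps=30,
            n_sweeps_between_samples=2, seed=6, debug_energy_every=1000,
        )
        # raises AssertionError if incremental energy drifts > 1e-6 kT
        sample_ensemble(params, cfg)

    def test_attraction_increases_contact(self):
        m = 32
        base = PolymerConfig(
            m=m, n_structures=600, n_equilibration_sweeps=150,
            n_sweeps_between_samples=3, seed=7,
        )
        H0 = contact_map_from_ensemble(sample_ensemble(InteractionParams.zeros(m), base))
        L = np.zeros((m, m))
        i, j = 4, 28
        L[i, j] = L[j, i] = -6.0
        Ha = contact_map_from_ensemble(sample_ensemble(InteractionParams(L, np.zeros((m, m))), base))
        assert Ha.values[i, j] > H0.values[i, j]

    def test_mismatched_m_rejected(self, fast_poly_cfg):
        with pytest.raises(ValueError, match="match"):
            sample_ensemble(InteractionParams.zeros(8), fast_poly_cfg)

    def test_nonfinite_U_rejected(self, fast_poly_cfg):
        m = fast_poly_cfg.m
        L = np.zeros((m, m))
        L[0, 1] = L[1, 0] = np.nan
        T = np.zeros((m, m))
        with pytest.raises((ValueError, FloatingPointError)):
            sample_ensemble(InteractionParams(L, T), fast_poly_cfg)


class TestContactMap:
    def test_single_structure_one_cell(self):
        cfg = PolymerConfig(m=4, n_structures=1)
        coords = np.full((1, 4, 3), 100.0)
        ens = StructureEnsemble(coords=coords, offsets=np.zeros((1, 3)), config=cfg)
        H = contact_map_from_ensemble(ens)
        np.testing.assert_array_equal(H.values, np.ones((4, 4)))

    def test_half_contact(self):
        cfg = PolymerConfig(m=2, n_structures=2)
        coords = np.zeros((2, 2, 3))
        coords[0] = [[10.0, 10, 10], [20.0, 10, 10]]  # co-celled
        coords[1] = [[10.0, 10, 10], [700.0, 10, 10]]  # apart
        ens = StructureEnsemble(coords=coords, offsets=np.zeros((2, 3)), config=cfg)
        H = contact_map_from_ensemble(ens)
        assert H.values[0, 1] == pytest.approx(0.5)

    def test_range_and_symmetry(self, fast_poly_cfg):
        ens = sample_ensemble(InteractionParams.zeros(fast_poly_cfg.m), fast_poly_cfg)
        H = contact_map_from_ensemble(ens)
        assert H.values.min() >= 0.0
        assert H.values.max() <= 1.0
        np.testing.assert_array_equal(H.values, H.values.T)
        np.testing.assert_array_equal(np.diag(H.values), np.ones(fast_poly_cfg.m))


class TestMeanDistance:
    def test_duplicate_structures(self):
        rng = np.random.default_rng(9)
        one = rng.random((1, 6, 3)) * 500
        two = np.concatenate([one, one])
        cfg = PolymerConfig(m=6, n_structures=2)
        d1 = mean_distance_matrix(
            StructureEnsemble(coords=one, offsets=np.zeros((1, 3)), config=cfg)
        )
        d2 = mean_distance_matrix(
            StructureEnsemble(coords=two, offsets=np.zeros((2, 3)), config=cfg)
        )
        np.testing.assert_allclose(d1, d2)

    def test_two_bead_average(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 1.0
        coords[1, 1, 0] = 3.0
        cfg = PolymerConfig(m=2, n_structures=2)
        d = mean_distance_matrix(StructureEnsemble(coords=coords, offsets=np.zeros((2, 3)), config=cfg))
        assert d[0, 1] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        coords = rng.random((5, 7, 3)) * 300
        cfg = PolymerConfig(m=7, n_structures=5)
        d = mean_distance_matrix(StructureEnsemble(coords=coords, offsets=np.zeros((5, 3)), config=cfg))
        for i in range(7):
            for j in range(7):
                expect = np.mean(
                    [np.linalg.norm(coords[s, i] - coords[s, j]) for s in range(5)]
                )
                assert d[i, j] == pytest.approx(expect)


def test_ensemble_xyz_export(tmp_path, fast_poly_cfg):
    ens = sample_ensemble(InteractionParams.zeros(fast_poly_cfg.m), fast_poly_cfg)
    path = tmp_path / "frames.xyz"
    ens.to_xyz(path, max_frames=3)
    lines = path.read_text().splitlines()
    assert lines[0] == str(fast_poly_cfg.m)
    assert len(lines) == 3 * (fast_poly_cfg.m + 2)


def test_ensemble_save(tmp_path, fast_poly_cfg):
    ens = sample_ensemble(InteractionParams.zeros(fast_poly_cfg.m), fast_poly_cfg)
    ens.save(tmp_path / "ens.npz")
    with np.load(tmp_path / "ens.npz") as z:
        assert z["coords"].shape == ens.coords.shape
        assert int(z["m"]) == fast_poly_cfg.m


def test_ideal_chain_contact_scaling_slope():
    # free chain: log-log contact-probability slope over mid-range
    # separations near the ideal-chain -1.5 (grid/confinement shift it)
    from hicpoly.preprocess import contact_scaling

    cfg = PolymerConfig(
        m=64, volume_um3=8000.0, n_structures=1500,
        n_equilibration_sweeps=100, n_sweeps_between_samples=5, seed=31,
    )
    H = contact_map_from_ensemble(sample_ensemble(InteractionParams.zeros(64), cfg))
    curve = contact_scaling(H).probabilities
    s = np.arange(2, 33)
    slope = np.polyfit(np.log(s), np.log(curve[2:33]), 1)[0]
    assert -1.8 < slope < -1.2


def test_two_block_plaid_pc1():
    # two-block L with attractive intra-block, repulsive inter-block
    # energies produces a plaid map whose PC1 separates the blocks
    m = 32
    Psi = np.zeros((m, 2))
    Psi[: m // 2, 0] = 1.0
    Psi[m // 2 :, 1] = 1.0
    chi = np.array([[-0.8, 0.8], [0.8, -0.8]])
    params = InteractionParams.from_chi(Psi, chi, np.zeros(m))
    cfg = PolymerConfig(
        m=m, n_structures=800, n_equilibration_sweeps=200,
        n_sweeps_between_samples=4, seed=21,
    )
    H = contact_map_from_ensemble(sample_ensemble(params, cfg))
    pc1 = compartment_pc1(distance_normalize(H))
    first = np.sign(np.median(pc1[: m // 2]))
    second = np.sign(np.median(pc1[m // 2 :]))
    assert first != second
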