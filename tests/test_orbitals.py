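"""Orbital gradient and optimization: full-space density embedding,
finite-difference agreement, Brillouin convergence, CASSCF oracle."""

import numpy as np
import pytest
import scipy.linalg

from dmrgfq import (
    MPS,
    build_mpo,
    compute_rdms,
    h4_cas_region,
    optimize_mps,
    optimize_orbitals,
    orbital_gradient,
    sector_penalty_mpo,
    transform_to_active,
)
from dmrgfq.orbitals import _mo_integrals, fixed_density_energy, full_space_rdms

from _oracles import casscf_oracle_energy, fci_energies


def _dmrg_solver(M=16, seed=1, n_sweeps=16):
    def solve(asi):
        H = build_mpo(asi)
        pen = sector_penalty_mpo(
            asi.n_orbitals_active, asi.n_electrons_active,
            asi.spin_projection, 10.0,
        )
        psi = MPS.random_sector(
            asi.n_orbitals_active, asi.n_electrons_active,
            asi.spin_projection, M, np.random.default_rng(seed),
        )
        res = optimize_mps(H, psi, max_bond=M, n_sweeps=n_sweeps, tol=1e-12,
                           penalty_mpo=pen)
        dm = compute_rdms(res.mps)
        return dm.energy(asi), dm

    return solve


def _cas_setup(seed, scramble=0.0, scramble_seed=0):
    region = h4_cas_region(seed)
    _, C, _ = region.rhf()
    if scramble:
        rng = np.random.default_rng(scramble_seed)
        A = rng.normal(0.0, scramble, (4, 4))
        C = C @ scipy.linalg.expm(A - A.T)
    orbs = region.orbital_set(C, 1, 2)
    return region, orbs


def test_full_space_rdms_reproduce_energy():
    region, orbs = _cas_setup(0)
    asi = transform_to_active(region.hcore, region.eri, orbs, 2,
                              nuclear_repulsion=region.nuclear_repulsion)
    E, dm = _dmrg_solver(M=8)(asi)
    h_mo, g_mo = _mo_integrals(region, orbs.coefficients)
    gamma, d = full_space_rdms(dm.one_particle, dm.two_particle,
                               orbs.inactive, orbs.active, 4)
    E_full = fixed_density_energy(gamma, d, h_mo, g_mo,
                                  region.nuclear_repulsion)
    assert E_full == pytest.approx(E, abs=1e-10)
    assert np.trace(gamma) == pytest.approx(4.0, abs=1e-10)
    assert np.einsum("pqrr->pq", d) == pytest.approx(3.0 * gamma, abs=1e-9)


def test_gradient_matches_fixed_density_finite_differences():
    region, orbs = _cas_setup(1, scramble=0.05, scramble_seed=5)
    asi = transform_to_active(region.hcore, region.eri, orbs, 2,
                              nuclear_repulsion=region.nuclear_repulsion)
    _, dm = _dmrg_solver(M=8)(asi)
    C = orbs.coefficients
    h_mo, g_mo = _mo_integrals(region, C)
    grad = orbital_gradient(dm.one_particle, dm.two_particle, h_mo, g_mo, orbs)
    gamma, d = full_space_rdms(dm.one_particle, dm.two_particle,
                               orbs.inactive, orbs.active, 4)
    eps = 1e-5
    for (i, j) in grad.pairs:
        vals = []
        for s in (eps, -eps):
            A = np.zeros((4, 4))
            A[i, j], A[j, i] = s, -s
            h2, g2 = _mo_integrals(region, C @ scipy.linalg.expm(A))
            vals.append(fixed_density_energy(gamma, d, h2, g2))
        fd = (vals[0] - vals[1]) / (2 * eps)
        assert fd == pytest.approx(grad.matrix[i, j], abs=1e-7)


def test_gradient_zero_on_redundant_pairs():
    region, orbs = _cas_setup(2, scramble=0.1, scramble_seed=9)
    asi = transform_to_active(region.hcore, region.eri, orbs, 2,
                              nuclear_repulsion=region.nuclear_repulsion)
    _, dm = _dmrg_solver(M=8)(asi)
    h_mo, g_mo = _mo_integrals(region, orbs.coefficients)
    grad = orbital_gradient(dm.one_particle, dm.two_particle, h_mo, g_mo, orbs)
    t, u = orbs.active
    assert grad.matrix[t, u] == 0.0
    assert np.max(np.abs(grad.matrix + grad.matrix.T)) == 0.0


def test_all_active_gradient_vanishes(h2_region):
    # full-space CAS: the exact energy is invariant under any rotation
    _, C, _ = h2_region.rhf()
    rng = np.random.default_rng(3)
    A = rng.normal(0, 0.2, (2, 2))
    C = C @ scipy.linalg.expm(A - A.T)
    orbs = h2_region.orbital_set(C, 0, 2)
    asi = transform_to_active(h2_region.hcore, h2_region.eri, orbs, 2,
                              nuclear_repulsion=h2_region.nuclear_repulsion)
    _, dm = _dmrg_solver(M=8)(asi)
    h_mo, g_mo = _mo_integrals(h2_region, orbs.coefficients)
    grad = orbital_gradient(dm.one_particle, dm.two_particle, h_mo, g_mo, orbs)
    assert grad.pairs == []
    assert grad.norm == 0.0


def test_optimize_orbitals_converges_to_oracle():
    region, orbs = _cas_setup(0)
    res = optimize_orbitals(region, orbs, 2, _dmrg_solver(M=8), tol=1e-6,
                            max_macro=100)
    assert res.converged
    e_oracle, _ = casscf_oracle_energy(
        region.hcore, region.eri, region.overlap, region.nuclear_repulsion,
        region.rhf()[1], 1, 2, 2,
    )
    assert res.energy == pytest.approx(e_oracle, abs=1e-8)
    assert res.orbital_set.orthonormality_deviation() < 1e-8


def test_optimize_orbitals_energy_non_increasing():
    region, orbs = _cas_setup(3, scramble=0.05, scramble_seed=11)
    res = optimize_orbitals(region, orbs, 2, _dmrg_solver(M=8), tol=1e-6,
                            max_macro=100)
    for a, b in zip(res.energy_trace, res.energy_trace[1:]):
        assert b <= a + 1e-10


def test_optimize_orbitals_immediate_return_at_convergence():
    region, orbs = _cas_setup(0)
    first = optimize_orbitals(region, orbs, 2, _dmrg_solver(M=8), tol=1e-6,
                              max_macro=100)
    again = optimize_orbitals(region, first.orbital_set, 2, _dmrg_solver(M=8),
                              tol=1e-6, max_macro=100)
    assert again.n_macro == 1
    assert again.energy == pytest.approx(first.energy, abs=1e-10)


def test_scramble_basin_recovery():
    region, _ = _cas_setup(1)
    e_oracle, C_opt = casscf_oracle_energy(
        region.hcore, region.eri, region.overlap, region.nuclear_repulsion,
        region.rhf()[1], 1, 2, 2,
    )
    rng = np.random.default_rng(13)
    A = rng.normal(0, 0.05, (4, 4))
    orbs = region.orbital_set(C_opt @ scipy.linalg.expm(A - A.T), 1, 2)
    res = optimize_orbitals(region, orbs, 2, _dmrg_solver(M=8), tol=1e-6,
                            max_macro=150)
    assert res.energy == pytest.approx(e_oracle, abs=1e-8)


def test_active_active_rotation_energy_invariant():
    # at exact bond dimension the energy does not depend on rotations
    # within the active block once the wave function is re-solved
    region, orbs = _cas_setup(0)
    solver = _dmrg_solver(M=8)
    asi = transform_to_active(region.hcore, region.eri, orbs, 2,
                              nuclear_repulsion=region.nuclear_repulsion)
    E0, _ = solver(asi)
    A = np.zeros((4, 4))
    t, u = orbs.active
    A[t, u], A[u, t] = 0.3, -0.3
    orbs2 = orbs.rotated(scipy.linalg.expm(A))
    asi2 = transform_to_active(region.hcore, region.eri, orbs2, 2,
                               nuclear_repulsion=region.nuclear_repulsion)
    E1, _ = solver(asi2)
    assert E1 == pytest.approx(E0, abs=1e-9)


def test_gas_phase_casci_matches_fci_at_fixed_orbitals():
    region, orbs = _cas_setup(4)
    asi = transform_to_active(region.hcore, region.eri, orbs, 2,
                              nuclear_repulsion=region.nuclear_repulsion)
    E, _ = _dmrg_solver(M=8)(asi)
    assert E == pytest.approx(fci_energies(asi, 1)[0], abs=1e-10)
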