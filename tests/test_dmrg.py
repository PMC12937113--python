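"""Two-site DMRG sweeps, excited states, density matrices, orbital
ordering, and checkpointing — validated against dense diagonalization."""

import numpy as np
import pytest

from dmrgfq import (
    MPS,
    build_mpo,
    compute_rdms,
    exchange_weights,
    expectation,
    fiedler_order,
    h2like_integrals,
    load_mps,
    load_orbitals,
    optimize_mps,
    permute_integrals,
    random_integrals,
    s2_mpo,
    save_mps,
    save_orbitals,
    sector_penalty_mpo,
)
from dmrgfq.dmrg.rdm import operator_string_expectation

from _oracles import dense_hamiltonian, fci_energies


def _solve(asi, M=16, seeds=(1,), n_sweeps=16, orthogonal_to=(), mu=10.0):
    H = build_mpo(asi)
    pen = sector_penalty_mpo(asi.n_orbitals_active, asi.n_electrons_active,
                             asi.spin_projection, mu)
    best = None
    for seed in seeds:
        psi = MPS.random_sector(
            asi.n_orbitals_active, asi.n_electrons_active,
            asi.spin_projection, M, np.random.default_rng(seed),
        )
        res = optimize_mps(H, psi, max_bond=M, n_sweeps=n_sweeps, tol=1e-12,
                           orthogonal_to=list(orthogonal_to), penalty_mpo=pen)
        if best is None or res.energy < best.energy:
            best = res
    return best


def test_ground_state_h2_exact():
    asi = h2like_integrals()
    res = _solve(asi, M=8)
    assert res.energy == pytest.approx(fci_energies(asi, 1)[0], abs=1e-10)


@pytest.mark.parametrize("L,nel,seed", [(3, 2, 21), (4, 4, 22)])
def test_ground_state_random_fixture(L, nel, seed):
    asi = random_integrals(L, nel, seed=seed)
    res = _solve(asi, M=4 ** (L // 2) * 2)
    assert res.energy == pytest.approx(fci_energies(asi, 1)[0], abs=1e-9)


def test_excited_state_orthogonal_projection():
    asi = random_integrals(3, 4, seed=31)
    gs = _solve(asi, M=16)
    es = _solve(asi, M=16, orthogonal_to=[gs.mps])
    w = fci_energies(asi, 2)
    assert gs.energy == pytest.approx(w[0], abs=1e-9)
    assert es.energy == pytest.approx(w[1], abs=1e-9)
    assert abs(gs.mps.overlap(es.mps)) < 1e-6


def test_sweep_energies_monotone_and_variational():
    asi = random_integrals(4, 4, seed=41)
    res = _solve(asi, M=32)
    e_exact = fci_energies(asi, 1)[0]
    for a, b in zip(res.trace, res.trace[1:]):
        assert b <= a + 1e-9
    assert res.energy >= e_exact - 1e-9


def test_energy_non_increasing_in_bond_dimension():
    asi = random_integrals(5, 4, seed=43)
    energies = []
    for M in (2, 4, 8, 16):
        energies.append(_solve(asi, M=M, seeds=(1, 2)).energy)
    for a, b in zip(energies, energies[1:]):
        assert b <= a + 1e-9
    assert energies[-1] >= fci_energies(asi, 1)[0] - 1e-9


def test_penalty_free_sweeps_agree_when_sector_hosts_global_gs():
    # when the target (N, 2Sz) sector contains the global ground state,
    # penalty-free sweeps from a sector-pure start give the same energy as
    # the penalized path (the penalty is a safety net, not a bias)
    asi = h2like_integrals()
    with_pen = _solve(asi, M=8).energy
    psi = MPS.random_sector(2, 2, 0, 8, np.random.default_rng(1))
    bare = optimize_mps(build_mpo(asi), psi, max_bond=8, n_sweeps=16,
                        tol=1e-12)
    assert bare.energy == pytest.approx(with_pen, abs=1e-9)
    assert bare.energy == pytest.approx(fci_energies(asi, 1)[0], abs=1e-9)


def test_rdm_consistency_and_energy():
    asi = random_integrals(4, 4, seed=51)
    res = _solve(asi, M=32)
    dm = compute_rdms(res.mps)
    assert dm.trace_error(4) < 1e-10
    assert dm.contraction_error(4) < 1e-10
    assert dm.energy(asi) == pytest.approx(res.energy, abs=1e-9)
    D, P = dm.one_particle, dm.two_particle
    assert np.max(np.abs(D - D.T)) < 1e-10
    # chemist-pairing permutational symmetries of the 2-RDM
    assert np.max(np.abs(P - P.transpose(2, 3, 0, 1))) < 1e-10
    assert np.max(np.abs(P - P.transpose(1, 0, 3, 2))) < 1e-10


def test_rdm_against_dense_eigenvector():
    from _oracles import sector_indices

    asi = random_integrals(3, 2, seed=53)
    Hd = dense_hamiltonian(asi)
    idx = sector_indices(3, 2, 0)
    w, V = np.linalg.eigh(Hd[np.ix_(idx, idx)])
    vec = np.zeros(4**3)
    vec[idx] = V[:, 0]
    mps = MPS.from_dense(vec, 3)
    dm = compute_rdms(mps)
    # energy reconstruction equals the dense eigenvalue
    assert dm.energy(asi) == pytest.approx(w[0], abs=1e-10)


def test_operator_string_expectation_matches_rdm():
    asi = random_integrals(3, 3, seed=57)
    res = _solve(asi, M=16)
    dm = compute_rdms(res.mps)
    val = sum(
        operator_string_expectation(res.mps, [(1, "c", s), (2, "a", s)])
        for s in (0, 1)
    )
    assert val == pytest.approx(dm.one_particle[1, 2], abs=1e-10)


def test_s2_of_singlet_and_triplet():
    asi = h2like_integrals()
    H = build_mpo(asi)
    S2 = s2_mpo(2)
    gs = _solve(asi, M=8)
    assert expectation(gs.mps, S2) == pytest.approx(0.0, abs=1e-8)
    # first excited state in the Sz=0 sector of H2 is the triplet
    es = _solve(asi, M=8, orthogonal_to=[gs.mps])
    assert expectation(es.mps, S2) == pytest.approx(2.0, abs=1e-8)


def test_fiedler_recovers_chain_order():
    # construct integrals whose exchange graph is a chain in scrambled order
    L = 5
    rng = np.random.default_rng(61)
    perm = rng.permutation(L)
    g = np.zeros((L, L, L, L))
    for a in range(L - 1):
        i, j = perm[a], perm[a + 1]
        for (p, q) in ((i, j), (j, i)):
            g[p, q, q, p] = 1.0
    asi = random_integrals(L, 4, seed=0)
    asi.g = g
    order = fiedler_order(asi)
    chain_pos = {orb: k for k, orb in enumerate(order)}
    positions = [chain_pos[perm[a]] for a in range(L)]
    diffs = np.diff(positions)
    assert np.all(diffs == 1) or np.all(diffs == -1)


def test_permute_integrals_preserves_spectrum():
    asi = random_integrals(3, 2, seed=63)
    order = [2, 0, 1]
    permuted = permute_integrals(asi, order)
    w0 = np.linalg.eigvalsh(dense_hamiltonian(asi))
    w1 = np.linalg.eigvalsh(dense_hamiltonian(permuted))
    assert np.max(np.abs(np.sort(w0) - np.sort(w1))) < 1e-10


def test_exchange_weights_symmetric_nonnegative():
    asi = random_integrals(4, 4, seed=65)
    K = exchange_weights(asi)
    assert np.allclose(K, K.T)
    assert np.all(K >= 0)
    assert np.all(np.diag(K) == 0)


def test_mps_checkpoint_round_trip(tmp_path, h2_region):
    asi = h2like_integrals()
    res = _solve(asi, M=8)
    path = tmp_path / "state.h5"
    save_mps(path, res.mps, metadata={"state": "gs"})
    back, meta = load_mps(path)
    assert meta["state"] == "gs"
    assert abs(abs(back.overlap(res.mps)) - 1.0) < 1e-12


def test_orbital_checkpoint_round_trip(tmp_path, h2_region):
    _, C, _ = h2_region.rhf()
    orbs = h2_region.orbital_set(C, 0, 2)
    path = tmp_path / "orbs.h5"
    save_orbitals(path, orbs, metadata={"basis": "sto-3g"})
    back = load_orbitals(path)
    if isinstance(back, tuple):
        back = back[0]
    assert np.max(np.abs(back.coefficients - orbs.coefficients)) < 1e-14
    assert back.active == orbs.active
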