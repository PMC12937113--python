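"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the production tensor-network path:
the dense Hamiltonian is built from qubit-level Jordan–Wigner operators
(2 qubits per orbital, scipy.sparse kron chains), and exact eigenvalues
come from dense diagonalization in the targeted particle/spin sector.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.sparse as sp

SIGMA_MINUS = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
PAULI_Z = sp.csr_matrix(np.diag([1.0, -1.0]))
ID2 = sp.identity(2, format="csr")

# per-site permutation mapping the package's local digit (0,up,down,updown)
# to the qubit pair value 2*n_up + n_down
_DIGIT_TO_QUBITS = np.array([0, 2, 1, 3])


def _annihilation(k, n_qubits):
    ops = [PAULI_Z] * k + [SIGMA_MINUS] + [ID2] * (n_qubits - k - 1)
    out = ops[0]
    for o in ops[1:]:
        out = sp.kron(out, o, format="csr")
    return out


def _digit_permutation(L):
    """Index array perm with vec_qubit[perm] = vec_digit."""
    idx = np.arange(4**L)
    digits = np.empty((L, idx.size), dtype=np.int64)
    rest = idx.copy()
    for l in range(L - 1, -1, -1):
        digits[l] = rest % 4
        rest //= 4
    out = np.zeros_like(idx)
    for l in range(L):
        out = out * 4 + _DIGIT_TO_QUBITS[digits[l]]
    return out


def dense_hamiltonian(integrals):
    """4^L x 4^L matrix of the active-space Hamiltonian in the package's
    digit basis (site 0 slowest, local order |0>,|up>,|down>,|updown>)."""
    h, g = integrals.h, integrals.g
    L = integrals.n_orbitals_active
    nq = 2 * L
    a = [_annihilation(k, nq) for k in range(nq)]
    c = [op.conj().T.tocsr() for op in a]

    def so(p, s):  # spin orbital index
        return 2 * p + s

    H = sp.csr_matrix((4**L, 4**L))
    for p in range(L):
        for q in range(L):
            if abs(h[p, q]) < 1e-14:
                continue
            for s in (0, 1):
                H = H + h[p, q] * (c[so(p, s)] @ a[so(q, s)])
    for p in range(L):
        for q in range(L):
            for r in range(L):
                for s_ in range(L):
                    coef = 0.5 * g[p, q, r, s_]
                    if abs(coef) < 1e-14:
                        continue
                    for s1 in (0, 1):
                        for s2 in (0, 1):
                            H = H + coef * (
                                c[so(p, s1)]
                                @ c[so(r, s2)]
                                @ a[so(s_, s2)]
                                @ a[so(q, s1)]
                            )
    Hd = np.asarray(H.todense())
    perm = _digit_permutation(L)
    Hd = Hd[np.ix_(perm, perm)]
    return Hd + integrals.core_energy * np.eye(4**L)


def digit_vector_from_qubit(vec, L):
    return vec[_digit_permutation(L)]


def sector_indices(L, n_electrons, two_sz):
    """Fock-space indices (digit convention) in the (N, 2Sz) sector."""
    digit_n = np.array([0, 1, 1, 2])
    digit_sz = np.array([0, 1, -1, 0])
    idx = np.arange(4**L)
    n = np.zeros(idx.size, dtype=np.int64)
    sz = np.zeros(idx.size, dtype=np.int64)
    rest = idx.copy()
    for _ in range(L):
        d = rest % 4
        n += digit_n[d]
        sz += digit_sz[d]
        rest //= 4
    return idx[(n == n_electrons) & (sz == two_sz)]


def fci_energies(integrals, n_states=2, two_sz=None, return_vectors=False):
    """Exact sector eigenvalues by dense diagonalization."""
    L = integrals.n_orbitals_active
    if two_sz is None:
        two_sz = integrals.spin_projection
    H = dense_hamiltonian(integrals)
    idx = sector_indices(L, integrals.n_electrons_active, two_sz)
    Hs = H[np.ix_(idx, idx)]
    w, V = np.linalg.eigh(Hs)
    if return_vectors:
        full = np.zeros((4**L, min(n_states, len(w))))
        for k in range(full.shape[1]):
            full[idx, k] = V[:, k]
        return w[:n_states], full
    return w[:n_states]


def dense_s2(L):
    """Dense total-spin operator S^2 in the digit basis, built from qubit
    Jordan-Wigner ladder operators (independent of the MPO path)."""
    nq = 2 * L
    a = [_annihilation(k, nq) for k in range(nq)]
    c = [op.conj().T.tocsr() for op in a]
    sz = sp.csr_matrix((4**L, 4**L))
    sp_op = sp.csr_matrix((4**L, 4**L))
    for p in range(L):
        up, dn = 2 * p, 2 * p + 1
        sz = sz + 0.5 * (c[up] @ a[up] - c[dn] @ a[dn])
        sp_op = sp_op + c[up] @ a[dn]
    sm_op = sp_op.conj().T.tocsr()
    S2 = sz @ sz + 0.5 * (sp_op @ sm_op + sm_op @ sp_op)
    out = np.asarray(S2.todense())
    perm = _digit_permutation(L)
    return out[np.ix_(perm, perm)]


def fci_singlet_energies(integrals, n_states=2, s2_tol=1e-6):
    """Lowest sector eigenvalues with <S^2> ~ 0 (singlets), by dense
    diagonalization and spin filtering."""
    L = integrals.n_orbitals_active
    H = dense_hamiltonian(integrals)
    idx = sector_indices(L, integrals.n_electrons_active,
                         integrals.spin_projection)
    Hs = H[np.ix_(idx, idx)]
    w, V = np.linalg.eigh(Hs)
    S2 = dense_s2(L)[np.ix_(idx, idx)]
    out = []
    for k in range(len(w)):
        if V[:, k] @ S2 @ V[:, k] < s2_tol:
            out.append(w[k])
        if len(out) >= n_states:
            break
    return np.array(out)


# ---------------------------------------------------------------------------
# FQ constrained-minimization oracle


def fq_minimize_oracle(kernel, chi, groups, total_charges, potential=None):
    """Brute-force constrained quadratic minimization via SLSQP (with an
    analytic gradient), independent of the bordered linear solve."""
    n = len(chi)
    V = np.zeros(n) if potential is None else np.asarray(potential)

    def f(q):
        return float(q @ (chi + V) + 0.5 * q @ kernel @ q)

    def grad(q):
        return chi + V + kernel @ q

    constraints = []
    for g, Q in zip(groups, total_charges):
        arr = np.zeros(n)
        arr[list(g)] = 1.0
        constraints.append(
            {"type": "eq", "fun": (lambda q, a=arr, Q=Q: a @ q - Q),
             "jac": (lambda q, a=arr: a)}
        )
    res = scipy.optimize.minimize(
        f, np.zeros(n), jac=grad, constraints=constraints, method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-16},
    )
    # polish with a few projected-Newton steps on the active constraints
    q = res.x
    C = np.zeros((n, len(groups)))
    for a_, g in enumerate(groups):
        C[list(g), a_] = 1.0
    for _ in range(5):
        r = grad(q)
        lam = np.linalg.lstsq(C, -r, rcond=None)[0]
        kkt = r + C @ lam
        A = np.block([[kernel, C], [C.T, np.zeros((C.shape[1], C.shape[1]))]])
        rhs = np.concatenate([-kkt, np.zeros(C.shape[1])])
        step = np.linalg.solve(A, rhs)[:n]
        q = q + step
    return q


# ---------------------------------------------------------------------------
# CASSCF oracle: numerical minimization over orbital rotations with dense
# sector-FCI energies (no MPS, no analytic orbital gradient).


def casscf_oracle_energy(
    hcore_ao, eri_ao, overlap_ao, nuclear_repulsion,
    C0, n_inactive, n_active, n_electrons_active,
    oei_embedding=None, scalar_embedding=0.0, seed=0,
):
    """min over orbital rotations of the sector-FCI energy of the active
    Hamiltonian; returns (energy, C_opt)."""
    from dmrgfq.integrals.active_space import OrbitalSet, transform_to_active

    n_mo = C0.shape[1]
    h_ao = hcore_ao if oei_embedding is None else hcore_ao + oei_embedding
    pairs = [
        (i, j)
        for i in range(n_mo)
        for j in range(i + 1, n_mo)
        # skip active-active (redundant at FCI level) but keep all others
        if not (n_inactive <= i < n_inactive + n_active
                and n_inactive <= j < n_inactive + n_active)
        and not (i < n_inactive and j < n_inactive)
        and not (i >= n_inactive + n_active and j >= n_inactive + n_active)
    ]

    def energy_of(x):
        A = np.zeros((n_mo, n_mo))
        for val, (i, j) in zip(x, pairs):
            A[i, j] = val
            A[j, i] = -val
        C = C0 @ scipy.linalg.expm(A)
        orbs = OrbitalSet(
            coefficients=C,
            inactive=list(range(n_inactive)),
            active=list(range(n_inactive, n_inactive + n_active)),
            virtual=list(range(n_inactive + n_active, n_mo)),
            overlap=overlap_ao,
        )
        asi = transform_to_active(
            h_ao, eri_ao, orbs, n_electrons_active,
            nuclear_repulsion=nuclear_repulsion + scalar_embedding,
        )
        return fci_energies(asi, n_states=1)[0]

    best = scipy.optimize.minimize(
        energy_of, np.zeros(len(pairs)), method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    # rebuild optimal orbitals
    A = np.zeros((n_mo, n_mo))
    for val, (i, j) in zip(best.x, pairs):
        A[i, j] = val
        A[j, i] = -val
    return float(best.fun), C0 @ scipy.linalg.expm(A)


import scipy.linalg  # noqa: E402  (used inside casscf_oracle_energy)
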