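"""Active-space Hamiltonians: AO -> MO transformation, core folding, and
insertion of classical point charges into the one-electron integrals.

The electronic Hamiltonian over active molecular orbitals is

    H = E_core + sum_pq h_pq E_pq + 1/2 sum_pqrs g_pqrs (E_pq E_rs - d_rq E_ps)

with g in chemist notation (pq|rs).  E_core collects nuclear repulsion, the
doubly-occupied inactive shell (folded into a core Fock contribution to h),
and — in embedded runs — the interaction of the nuclei and the inactive
density with the environment charges.

Sign convention for embedding: the per-site electrostatic potential of the
quantum region is V_i(D) = V_i^nuc - Tr[D V^FQ_i] with V^FQ_i the
positive-definite matrix <p|1/|r-r_i||q>.  The single assembly routine
:func:`fold_fq_into_oei` owns the minus sign on the electronic part.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ActiveSpaceIntegrals",
    "OrbitalSet",
    "ActiveESP",
    "transform_to_active",
    "fold_fq_into_oei",
]


@dataclass
class ActiveSpaceIntegrals:
    """One-/two-electron integrals over an active orbital set.

    h is symmetric, g has 8-fold permutational symmetry (chemist notation),
    core_energy includes everything outside the active space.
    """

    h: np.ndarray
    g: np.ndarray
    core_energy: float
    n_electrons_active: int
    spin_projection: int = 0  # 2*Sz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        L = self.h.shape[0]
        if self.h.shape != (L, L) or self.g.shape != (L, L, L, L):
            raise ValueError("inconsistent integral shapes")
        if L < 1:
            raise ValueError("need at least one active orbital")
        if not 0 <= self.n_electrons_active <= 2 * L:
            raise ValueError("electron count outside [0, 2L]")
        if np.max(np.abs(self.h - self.h.T)) > 1e-8:
            raise ValueError("h is not symmetric")

    @property
    def n_orbitals_active(self) -> int:
        return self.h.shape[0]

    def g_asymmetry(self) -> float:
        """Max deviation of g from 8-fold permutational symmetry."""
        g = self.g
        perms = [
            g.transpose(1, 0, 2, 3), g.transpose(0, 1, 3, 2),
            g.transpose(1, 0, 3, 2), g.transpose(2, 3, 0, 1),
            g.transpose(3, 2, 0, 1), g.transpose(2, 3, 1, 0),
            g.transpose(3, 2, 1, 0),
        ]
        return float(max(np.max(np.abs(g - p)) for p in perms))


@dataclass
class OrbitalSet:
    """AO->MO coefficient matrix with an (inactive, active, virtual)
    partition and the AO overlap it is orthonormal against."""

    coefficients: np.ndarray
    inactive: list[int]
    active: list[int]
    virtual: list[int]
    overlap: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.coefficients, dtype=float)
        S = np.asarray(self.overlap, dtype=float)
        self.coefficients = C
        self.overlap = S
        all_idx = sorted([*self.inactive, *self.active, *self.virtual])
        if all_idx != list(range(C.shape[1])):
            raise ValueError("partition must cover every MO exactly once")
        dev = np.max(np.abs(C.T @ S @ C - np.eye(C.shape[1])))
        if dev > 1e-6:
            raise ValueError(f"orbitals not orthonormal (deviation {dev:.2e})")

    @property
    def n_mo(self) -> int:
        return self.coefficients.shape[1]

    def orthonormality_deviation(self) -> float:
        C, S = self.coefficients, self.overlap
        return float(np.max(np.abs(C.T @ S @ C - np.eye(C.shape[1]))))

    def rotated(self, U: np.ndarray) -> "OrbitalSet":
        return replace(self, coefficients=self.coefficients @ U)


@dataclass
class ActiveESP:
    """Environment-site electrostatics projected onto the active space.

    static_potential[i] = V_i^nuc - Tr[D_core V^FQ_i]  (Hartree/e) collects
    the charge-independent part; active_matrices[i] is the positive
    electronic ESP matrix over active MOs.
    """

    static_potential: np.ndarray
    active_matrices: np.ndarray  # (n_sites, L, L)
    site_positions: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.static_potential)

    def potential_of_density(self, D_active: np.ndarray) -> np.ndarray:
        """Total QM potential V(D) at each site for an active 1-RDM."""
        return self.static_potential - np.einsum(
            "ipq,pq->i", self.active_matrices, D_active
        )


def _ao_to_mo_2e(g_ao, C):
    g = np.einsum("pqrs,pi->iqrs", g_ao, C, optimize=True)
    g = np.einsum("iqrs,qj->ijrs", g, C, optimize=True)
    g = np.einsum("ijrs,rk->ijks", g, C, optimize=True)
    return np.einsum("ijks,sl->ijkl", g, C, optimize=True)


def transform_to_active(
    hcore_ao: np.ndarray,
    eri_ao: np.ndarray,
    orbital_set: OrbitalSet,
    n_electrons_active: int,
    nuclear_repulsion: float = 0.0,
    spin_projection: int = 0,
) -> ActiveSpaceIntegrals:
    """Fold the inactive shell into an active-space Hamiltonian.

    The active one-electron matrix is the inactive (core) Fock matrix;
    core_energy = E_nn + sum_i (h_ii + F_ii) over doubly-occupied inactive
    orbitals.  With an empty inactive space this is a plain 4-index
    transform with core_energy = E_nn.
    """
    C = orbital_set.coefficients
    Ci = C[:, orbital_set.inactive]
    Ca = C[:, orbital_set.active]
    D_core_ao = 2.0 * Ci @ Ci.T
    J = np.einsum("pqrs,rs->pq", eri_ao, D_core_ao, optimize=True)
    K = np.einsum("prqs,rs->pq", eri_ao, D_core_ao, optimize=True)
    F_core_ao = hcore_ao + J - 0.5 * K
    h_act = Ca.T @ F_core_ao @ Ca
    g_act = _ao_to_mo_2e(eri_ao, Ca)
    core = nuclear_repulsion + 0.5 * np.sum(D_core_ao * (hcore_ao + F_core_ao))
    return ActiveSpaceIntegrals(
        h=0.5 * (h_act + h_act.T),
        g=g_act,
        core_energy=float(core),
        n_electrons_active=n_electrons_active,
        spin_projection=spin_projection,
    )


def fold_fq_into_oei(
    integrals: ActiveSpaceIntegrals,
    charges: np.ndarray,
    esp: ActiveESP,
) -> ActiveSpaceIntegrals:
    """Insert classical point charges into the one-electron Hamiltonian.

    h_eff = h - sum_i q_i V^FQ_i (active block) and core_energy gains
    sum_i q_i * static_potential_i, so that <H_eff> - <H> equals the
    electrostatic interaction energy sum_i q_i V_i(D) for any state.
    The map is linear in the charges.
    """
    q = np.asarray(charges, dtype=float)
    if q.shape != (esp.n_sites,):
        raise ValueError(
            f"charge vector length {q.shape} does not match {esp.n_sites} sites"
        )
    if esp.active_matrices.shape[1:] != integrals.h.shape:
        raise ValueError("ESP active matrices do not match the active space")
    h_eff = integrals.h - np.einsum("i,ipq->pq", q, esp.active_matrices)
    core = integrals.core_energy + float(q @ esp.static_potential)
    return replace(integrals, h=0.5 * (h_eff + h_eff.T), core_energy=core)
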