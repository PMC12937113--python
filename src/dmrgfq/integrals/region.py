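"""Quantum-region container: geometry + basis + cached AO matrices, with a
restricted Hartree–Fock solver for starting orbitals.

The Fock operator can include an embedding term -sum_i q_i V^FQ_i from
fixed environment charges, giving HF-in-FQ starting orbitals.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from ..units import angstrom_to_bohr
from ..io import read_xyz
from .gaussian import build_basis, ao_matrices
from .active_space import OrbitalSet

__all__ = ["QMRegion"]

NUCLEAR_CHARGES = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10,
}


class QMRegion:
    """Molecule treated quantum mechanically.

    Coordinates are given in Ångström and stored in Bohr.  AO integral
    matrices (overlap, core Hamiltonian, ERI) are computed once on first
    access.
    """

    def __init__(self, elements, coords_angstrom, basis="sto-3g", charge=0):
        self.elements = list(elements)
        self.coords = angstrom_to_bohr(np.asarray(coords_angstrom, dtype=float))
        self.charge = int(charge)
        self.basis_spec = basis
        self.basis = build_basis(self.elements, self.coords, basis)
        self._cache = {}

    @classmethod
    def from_xyz(cls, path, basis="sto-3g", charge=0):
        elements, coords, _ = read_xyz(path)
        return cls(elements, coords, basis=basis, charge=charge)

    @property
    def nuclei(self):
        return [
            (float(NUCLEAR_CHARGES[el]), pos)
            for el, pos in zip(self.elements, self.coords)
        ]

    @property
    def n_electrons(self) -> int:
        return int(sum(z for z, _ in self.nuclei)) - self.charge

    @property
    def nuclear_repulsion(self) -> float:
        e = 0.0
        nuc = self.nuclei
        for a in range(len(nuc)):
            for b in range(a):
                Za, Ra = nuc[a]
                Zb, Rb = nuc[b]
                e += Za * Zb / np.linalg.norm(Ra - Rb)
        return e

    def _mats(self):
        return ao_matrices(self.basis)

    @property
    def overlap(self):
        if "S" not in self._cache:
            self._cache["S"] = self._mats().overlap()
        return self._cache["S"]

    @property
    def hcore(self):
        if "h" not in self._cache:
            m = self._mats()
            self._cache["h"] = m.kinetic() + m.nuclear_attraction(self.nuclei)
        return self._cache["h"]

    @property
    def eri(self):
        if "g" not in self._cache:
            self._cache["g"] = self._mats().eri()
        return self._cache["g"]

    @property
    def n_ao(self) -> int:
        return self.basis.n

    # ------------------------------------------------------------------
    def rhf(self, embedding_oei=None, embedding_scalar=0.0,
            max_iter=200, tol=1e-10):
        """Closed-shell restricted HF; returns (energy, C, orbital_energies).

        ``embedding_oei`` is an optional AO matrix added to the core
        Hamiltonian (e.g. -sum q_i V^FQ_i) and ``embedding_scalar`` a
        constant (e.g. nuclear–charge interaction).
        """
        n_occ, rem = divmod(self.n_electrons, 2)
        if rem:
            raise ValueError("RHF requires an even electron count")
        S, g = self.overlap, self.eri
        h = self.hcore.copy()
        if embedding_oei is not None:
            h = h + embedding_oei
        # symmetric orthogonalization
        w, U = np.linalg.eigh(S)
        X = U @ np.diag(w**-0.5) @ U.T
        F = h
        E_old, D = None, np.zeros_like(h)
        diis_F, diis_err = [], []
        for _ in range(max_iter):
            Fp = X.T @ F @ X
            eps, Cp = np.linalg.eigh(Fp)
            C = X @ Cp
            Cocc = C[:, :n_occ]
            D = 2.0 * Cocc @ Cocc.T
            J = np.einsum("pqrs,rs->pq", g, D, optimize=True)
            K = np.einsum("prqs,rs->pq", g, D, optimize=True)
            F = h + J - 0.5 * K
            E = 0.5 * np.sum(D * (h + F)) + self.nuclear_repulsion + embedding_scalar
            err = F @ D @ S - S @ D @ F
            diis_F.append(F.copy())
            diis_err.append(err.copy())
            if len(diis_F) > 8:
                diis_F.pop(0)
                diis_err.pop(0)
            if len(diis_F) > 1:
                m = len(diis_F)
                B = -np.ones((m + 1, m + 1))
                B[m, m] = 0.0
                for a in range(m):
                    for b in range(m):
                        B[a, b] = np.sum(diis_err[a] * diis_err[b])
                rhs = np.zeros(m + 1)
                rhs[m] = -1.0
                try:
                    c = np.linalg.solve(B, rhs)[:m]
                    F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
                except np.linalg.LinAlgError:
                    pass
            if E_old is not None and abs(E - E_old) < tol and np.max(np.abs(err)) < 1e-7:
                break
            E_old = E
        return float(E), C, eps

    def orbital_set(self, C, n_inactive, n_active) -> OrbitalSet:
        n = C.shape[1]
        return OrbitalSet(
            coefficients=C,
            inactive=list(range(n_inactive)),
            active=list(range(n_inactive, n_inactive + n_active)),
            virtual=list(range(n_inactive + n_active, n)),
            overlap=self.overlap,
        )
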