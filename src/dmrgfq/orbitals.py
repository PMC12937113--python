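"""Orbital optimization under the extended Brillouin condition.

For a CAS-type state with active-space density matrices (D, P), the total
energy is stationary with respect to orbital rotations when the gradient

    g_rs = dE/dA_rs = 2(F_sr - F_rs),   C <- C exp(A)

vanishes on the non-redundant rotation pairs (inactive-active,
inactive-virtual, active-virtual).  F is the generalized Fock matrix built
from the full-space one- and two-particle density matrices.  Environment
point charges enter exactly through the folded one-electron integrals, so
their gradient contribution is the one-electron term of the same formula.

The optimizer alternates wave-function re-solution (a callback, typically
a DMRG sweep run) with orbital rotation steps C <- C exp(A), A antisymmetric
over non-redundant pairs, bounded by a trust region.  The rotation step
minimizes the fixed-density energy, which agrees with the true energy to
first order at A = 0; re-solving the wave function afterwards can only
lower the energy further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .integrals.active_space import (
    ActiveSpaceIntegrals,
    OrbitalSet,
    transform_to_active,
)

__all__ = [
    "OrbitalGradient",
    "full_space_rdms",
    "orbital_gradient",
    "optimize_orbitals",
    "OrbitalOptimizationResult",
]


@dataclass
class OrbitalGradient:
    """Antisymmetric orbital-rotation gradient; zero on redundant pairs."""

    matrix: np.ndarray
    pairs: list[tuple[int, int]]

    @property
    def norm(self) -> float:
        return float(np.sqrt(sum(self.matrix[i, j] ** 2 for i, j in self.pairs)))


def _nonredundant_pairs(inactive, active, virtual):
    pairs = []
    for i in inactive:
        for t in active:
            pairs.append((i, t))
        for a in virtual:
            pairs.append((i, a))
    for t in active:
        for a in virtual:
            pairs.append((t, a))
    return pairs


def full_space_rdms(D, P, inactive, active, n_mo):
    """Embed active-space (D, P) into full-space (gamma, d) with a closed
    inactive shell; d is in chemist pairing (energy = sum gamma h
    + 1/2 sum d (pq|rs))."""
    gamma = np.zeros((n_mo, n_mo))
    for i in inactive:
        gamma[i, i] = 2.0
    act = np.asarray(active)
    gamma[np.ix_(act, act)] = D
    d = np.zeros((n_mo, n_mo, n_mo, n_mo))
    for i in inactive:
        for j in inactive:
            d[i, i, j, j] += 4.0
            d[i, j, j, i] += -2.0
    for i in inactive:
        d[np.ix_(act, act, [i], [i])] += 2.0 * D[:, :, None, None]
        d[np.ix_([i], [i], act, act)] += 2.0 * D[None, None, :, :]
        d[np.ix_(act, [i], [i], act)] += -D[:, None, None, :]
        d[np.ix_([i], act, act, [i])] += -D.T[None, :, :, None]
    d[np.ix_(act, act, act, act)] = P
    return gamma, d


def _generalized_fock(gamma, d, h_mo, g_mo):
    return gamma @ h_mo.T + np.einsum("mqrs,nqrs->mn", d, g_mo, optimize=True)


def fixed_density_energy(gamma, d, h_mo, g_mo, scalar=0.0) -> float:
    return float(
        np.sum(gamma * h_mo)
        + 0.5 * np.einsum("pqrs,pqrs->", d, g_mo, optimize=True)
        + scalar
    )


def orbital_gradient(
    D: np.ndarray,
    P: np.ndarray,
    h_mo: np.ndarray,
    g_mo: np.ndarray,
    orbital_set: OrbitalSet,
) -> OrbitalGradient:
    """Brillouin gradient 2(F_rs - F_sr) over non-redundant pairs.

    ``h_mo`` must already contain any environment-charge folding
    (-sum_i q_i V^FQ); the classical contribution to the gradient then
    appears automatically through the generalized Fock matrix.
    """
    n_mo = h_mo.shape[0]
    gamma, d = full_space_rdms(D, P, orbital_set.inactive, orbital_set.active,
                               n_mo)
    F = _generalized_fock(gamma, d, h_mo, g_mo)
    G = 2.0 * (F.T - F)
    pairs = _nonredundant_pairs(orbital_set.inactive, orbital_set.active,
                                orbital_set.virtual)
    out = np.zeros_like(G)
    for i, j in pairs:
        out[i, j] = G[i, j]
        out[j, i] = -G[i, j]
    return OrbitalGradient(matrix=out, pairs=pairs)


def _mo_integrals(ao_ham, C, embedding_oei=None):
    h_ao = ao_ham.hcore if embedding_oei is None else ao_ham.hcore + embedding_oei
    h_mo = C.T @ h_ao @ C
    g = ao_ham.eri
    g_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", g, C, C, C, C, optimize=True)
    return h_mo, g_mo


@dataclass
class OrbitalOptimizationResult:
    orbital_set: OrbitalSet
    energy: float
    gradient_norm: float
    converged: bool
    n_macro: int
    energy_trace: list[float] = field(default_factory=list)
    density: object = None
    active_integrals: ActiveSpaceIntegrals | None = None


def optimize_orbitals(
    ao_ham,
    orbital_set: OrbitalSet,
    n_electrons_active: int,
    solve_active,
    embedding_oei: np.ndarray | None = None,
    embedding_scalar: float = 0.0,
    max_macro: int = 40,
    tol: float = 1e-6,
    trust_radius: float = 0.25,
) -> OrbitalOptimizationResult:
    """Alternate wave-function solution and orbital rotations until the
    Brillouin gradient norm drops below ``tol``.

    ``ao_ham`` provides hcore/eri/overlap/nuclear_repulsion (a QMRegion
    fits); ``solve_active(asi) -> (energy, DensityMatrices)`` re-solves the
    active-space problem.  Returns the best orbitals found with a
    convergence flag; the energy is non-increasing across accepted steps.
    """
    orbs = orbital_set
    energy_trace = []
    trust = trust_radius
    best = None
    E_prev = None
    for macro in range(max_macro):
        asi = transform_to_active(
            ao_ham.hcore if embedding_oei is None
            else ao_ham.hcore + embedding_oei,
            ao_ham.eri, orbs, n_electrons_active,
            nuclear_repulsion=ao_ham.nuclear_repulsion + embedding_scalar,
        )
        E, dm = solve_active(asi)
        energy_trace.append(E)
        h_mo, g_mo = _mo_integrals(ao_ham, orbs.coefficients, embedding_oei)
        grad = orbital_gradient(dm.one_particle, dm.two_particle, h_mo, g_mo,
                                orbs)
        best = OrbitalOptimizationResult(
            orbital_set=orbs, energy=E, gradient_norm=grad.norm,
            converged=grad.norm < tol, n_macro=macro + 1,
            energy_trace=energy_trace, density=dm, active_integrals=asi,
        )
        if grad.norm < tol:
            return best
        # fixed-density rotation step within the trust region
        n_mo = h_mo.shape[0]
        gamma, d = full_space_rdms(
            dm.one_particle, dm.two_particle, orbs.inactive, orbs.active, n_mo
        )
        pairs = grad.pairs
        scalar = ao_ham.nuclear_repulsion + embedding_scalar

        def energy_of(x):
            A = np.zeros((n_mo, n_mo))
            for v, (i, j) in zip(x, pairs):
                A[i, j] = v
                A[j, i] = -v
            C = orbs.coefficients @ scipy.linalg.expm(A)
            h2, g2 = _mo_integrals(ao_ham, C, embedding_oei)
            return fixed_density_energy(gamma, d, h2, g2, scalar)

        res = scipy.optimize.minimize(
            energy_of, np.zeros(len(pairs)), method="L-BFGS-B",
            bounds=[(-trust, trust)] * len(pairs),
            options={"maxiter": 100, "ftol": 1e-14, "gtol": 1e-10},
        )
        A = np.zeros((n_mo, n_mo))
        for v, (i, j) in zip(res.x, pairs):
            A[i, j] = v
            A[j, i] = -v
        if np.max(np.abs(res.x)) < 1e-14:
            # no productive step available at this trust radius
            trust *= 0.5
            if trust < 1e-8:
                return best
            continue
        orbs = orbs.rotated(scipy.linalg.expm(A))
        if E_prev is not None and E > E_prev + 1e-10:
            trust *= 0.5
        E_prev = E
    return best
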