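"""Reduced density matrices from an MPS.

D_pq = <E_pq> and P_pqrs = <E_pq E_rs - d_rq E_ps> are evaluated as sums of
spin-orbital operator strings contracted through the state.  The MPS is
left-canonicalized once; each string is contracted only over the sites it
touches, closed with a cached right density environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .local_ops import fermion_string
from .mps import MPS

__all__ = ["DensityMatrices", "compute_rdms", "operator_string_expectation"]


@dataclass
class DensityMatrices:
    one_particle: np.ndarray
    two_particle: np.ndarray

    @property
    def n_orbitals(self) -> int:
        return self.one_particle.shape[0]

    def trace_error(self, n_electrons: int) -> float:
        return abs(float(np.trace(self.one_particle)) - n_electrons)

    def contraction_error(self, n_electrons: int) -> float:
        """Max deviation of sum_r P_pqrr from (N-1) D_pq (chemist pairing)."""
        lhs = np.einsum("pqrr->pq", self.two_particle)
        rhs = (n_electrons - 1) * self.one_particle
        return float(np.max(np.abs(lhs - rhs)))

    def energy(self, integrals) -> float:
        """E = sum h D + 1/2 sum g P + core."""
        return float(
            np.sum(integrals.h * self.one_particle)
            + 0.5 * np.einsum("pqrs,pqrs->", integrals.g, self.two_particle)
            + integrals.core_energy
        )


class _StringEvaluator:
    def __init__(self, mps: MPS):
        self.mps = mps.canonicalize(center=mps.L - 1)
        self.mps.normalize()
        L = self.mps.L
        # right density environments for a left-canonical chain
        self.rho = [None] * (L + 1)
        self.rho[L] = np.ones((1, 1))
        for l in range(L - 1, -1, -1):
            t = self.mps.tensors[l]
            self.rho[l] = np.einsum("asb,csd,bd->ac", t, t, self.rho[l + 1],
                                    optimize=True)

    def expect(self, site_mats, first, last):
        """<psi| prod_l O_l |psi> for identity outside [first, last]."""
        d0 = self.mps.tensors[first].shape[0]
        T = np.eye(d0)
        for l in range(first, last + 1):
            t = self.mps.tensors[l]
            T = np.einsum("ab,asc,st,btd->cd", T, t, site_mats[l], t,
                          optimize=True)
        return float(np.sum(T * self.rho[last + 1]))


def operator_string_expectation(mps: MPS, ops) -> float:
    """<psi| c+...c |psi> for a single elementary-operator string
    (site, 'c'|'a', spin) given in operator order."""
    ev = _StringEvaluator(mps)
    mats = fermion_string(mps.L, ops)
    sites = [s for s, _, _ in ops]
    return ev.expect(mats, 0, max(sites))


def compute_rdms(mps: MPS) -> DensityMatrices:
    """Spin-summed one- and two-particle density matrices.

    Exploits hermiticity (D_pq = D_qp) and the two-particle symmetries
    P_pqrs = P_rspq = P_qpsr.
    """
    L = mps.L
    ev = _StringEvaluator(mps)

    def string_val(ops):
        mats = fermion_string(L, ops)
        sites = [s for s, _, _ in ops]
        # parity strings extend from site 0 up to each operator site, so the
        # contraction must start at 0 unless all parities cancel left of the
        # first operator site.  They do: an even number of operators sit at
        # or right of any cut left of min(sites).
        return ev.expect(mats, min(sites), max(sites))

    D = np.zeros((L, L))
    for p in range(L):
        for q in range(p + 1):
            val = sum(
                string_val([(p, "c", s), (q, "a", s)]) for s in (0, 1)
            )
            D[p, q] = D[q, p] = val

    # P_pqrs = sum_st <c+_ps c+_rt c_st c_qs>, the normal-ordered form of
    # E_pq E_rs - d_rq E_ps; symmetric under pair exchange (pq)<->(rs) and
    # simultaneous transposition p<->q, r<->s.
    P = np.full((L, L, L, L), np.nan)
    for p in range(L):
        for q in range(L):
            for r in range(L):
                for s_ in range(L):
                    if not np.isnan(P[p, q, r, s_]):
                        continue
                    val = 0.0
                    for s1 in (0, 1):
                        for s2 in (0, 1):
                            ops = [
                                (p, "c", s1), (r, "c", s2),
                                (s_, "a", s2), (q, "a", s1),
                            ]
                            val += string_val(ops)
                    P[p, q, r, s_] = val
                    P[r, s_, p, q] = val
                    P[q, p, s_, r] = val
                    P[s_, r, q, p] = val
    return DensityMatrices(one_particle=D, two_particle=P)
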