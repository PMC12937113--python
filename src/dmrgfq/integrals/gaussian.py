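"""Minimal Gaussian-orbital integral backend (McMurchie–Davidson scheme).

Provides AO overlap, kinetic, nuclear-attraction, electron-repulsion and
point-charge potential matrices over contracted Cartesian Gaussians.  It is
written for the small quantum regions this package targets (tens of basis
functions); shell-pair Hermite coefficients are cached but the primitive
loops are plain Python.

All lengths in Bohr, energies in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import hyp1f1

__all__ = ["Shell", "AOBasis", "build_basis", "STO3G"]


def boys(n, x):
    """Boys function F_n(x) via the confluent hypergeometric representation."""
    return hyp1f1(n + 0.5, n + 1.5, -x) / (2.0 * n + 1.0)


_DFACT = {-1: 1.0, 0: 1.0, 1: 1.0, 2: 3.0, 3: 15.0, 4: 105.0, 5: 945.0}


def _cart_components(l):
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def _prim_norm(a, lx, ly, lz):
    l = lx + ly + lz
    return (
        (2.0 * a / np.pi) ** 0.75
        * (4.0 * a) ** (l / 2.0)
        / np.sqrt(_DFACT[2 * lx - 1] * _DFACT[2 * ly - 1] * _DFACT[2 * lz - 1])
    )


@dataclass
class Shell:
    """Contracted Cartesian Gaussian shell: angular momentum l, center
    (Bohr), primitive exponents and contraction coefficients."""

    l: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)


class AOBasis:
    """Flat list of Cartesian AO functions built from shells.

    ``functions[i] = (shell, (lx, ly, lz), norm_coefs)`` where norm_coefs
    fold primitive and contraction normalization into the coefficients.
    """

    def __init__(self, shells: list[Shell]):
        self.shells = shells
        self.functions = []
        for sh in shells:
            for lx, ly, lz in _cart_components(sh.l):
                c = sh.coefs * np.array(
                    [_prim_norm(a, lx, ly, lz) for a in sh.exps]
                )
                self.functions.append((sh.center, (lx, ly, lz), sh.exps, c))
        # contraction normalization: scale so <phi|phi> = 1
        for idx, (A, lmn, exps, c) in enumerate(self.functions):
            s = _contracted_overlap(A, lmn, exps, c, A, lmn, exps, c)
            self.functions[idx] = (A, lmn, exps, c / np.sqrt(s))

    @property
    def n(self) -> int:
        return len(self.functions)


def _E(i, j, t, Qx, a, b):
    """Hermite expansion coefficient E_t^{ij} for a 1D Gaussian product."""
    p = a + b
    mu = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return np.exp(-mu * Qx * Qx)
    if j == 0:
        return (
            _E(i - 1, j, t - 1, Qx, a, b) / (2 * p)
            - (mu * Qx / a) * _E(i - 1, j, t, Qx, a, b)
            + (t + 1) * _E(i - 1, j, t + 1, Qx, a, b)
        )
    return (
        _E(i, j - 1, t - 1, Qx, a, b) / (2 * p)
        + (mu * Qx / b) * _E(i, j - 1, t, Qx, a, b)
        + (t + 1) * _E(i, j - 1, t + 1, Qx, a, b)
    )


def _prim_overlap(a, lmn1, A, b, lmn2, B):
    p = a + b
    s = (np.pi / p) ** 1.5
    for d in range(3):
        s *= _E(lmn1[d], lmn2[d], 0, A[d] - B[d], a, b)
    return s


def _contracted_overlap(A, lmn1, exps1, c1, B, lmn2, exps2, c2):
    s = 0.0
    for a, ca in zip(exps1, c1):
        for b, cb in zip(exps2, c2):
            s += ca * cb * _prim_overlap(a, lmn1, A, b, lmn2, B)
    return s


def _prim_kinetic(a, lmn1, A, b, lmn2, B):
    lx, ly, lz = lmn2

    def S(dl):
        lmn = list(lmn2)
        lmn[dl[0]] += dl[1]
        if lmn[dl[0]] < 0:
            return 0.0
        return _prim_overlap(a, lmn1, A, b, tuple(lmn), B)

    t = b * (2 * (lx + ly + lz) + 3) * _prim_overlap(a, lmn1, A, b, lmn2, B)
    t -= 2 * b * b * (S((0, 2)) + S((1, 2)) + S((2, 2)))
    t -= 0.5 * (
        lx * (lx - 1) * S((0, -2))
        + ly * (ly - 1) * S((1, -2))
        + lz * (lz - 1) * S((2, -2))
    )
    return t


def _R(t, u, v, n, p, PC, memo=None):
    """Hermite Coulomb auxiliary integrals R^n_{tuv}."""
    if memo is None:
        memo = {}
    key = (t, u, v, n)
    if key in memo:
        return memo[key]
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t == u == v == 0:
        val = (-2.0 * p) ** n * boys(n, p * (PC @ PC))
    elif t > 0:
        val = (t - 1) * _R(t - 2, u, v, n + 1, p, PC, memo) + PC[0] * _R(
            t - 1, u, v, n + 1, p, PC, memo
        )
    elif u > 0:
        val = (u - 1) * _R(t, u - 2, v, n + 1, p, PC, memo) + PC[1] * _R(
            t, u - 1, v, n + 1, p, PC, memo
        )
    else:
        val = (v - 1) * _R(t, u, v - 2, n + 1, p, PC, memo) + PC[2] * _R(
            t, u, v - 1, n + 1, p, PC, memo
        )
    memo[key] = val
    return val


def _prim_coulomb_1e(a, lmn1, A, b, lmn2, B, C):
    """<g_a| 1/|r-C| |g_b> for primitives (positive-definite operator)."""
    p = a + b
    P = (a * A + b * B) / p
    PC = P - C
    memo = {}
    val = 0.0
    l1, m1, n1 = lmn1
    l2, m2, n2 = lmn2
    Ex = [_E(l1, l2, t, A[0] - B[0], a, b) for t in range(l1 + l2 + 1)]
    Ey = [_E(m1, m2, u, A[1] - B[1], a, b) for u in range(m1 + m2 + 1)]
    Ez = [_E(n1, n2, v, A[2] - B[2], a, b) for v in range(n1 + n2 + 1)]
    for t in range(l1 + l2 + 1):
        for u in range(m1 + m2 + 1):
            for v in range(n1 + n2 + 1):
                val += Ex[t] * Ey[u] * Ez[v] * _R(t, u, v, 0, p, PC, memo)
    return 2.0 * np.pi / p * val


def _prim_eri(a, lmn1, A, b, lmn2, B, c, lmn3, C, d, lmn4, D):
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    PQ = P - Q
    l1, m1, n1 = lmn1
    l2, m2, n2 = lmn2
    l3, m3, n3 = lmn3
    l4, m4, n4 = lmn4
    E1x = [_E(l1, l2, t, A[0] - B[0], a, b) for t in range(l1 + l2 + 1)]
    E1y = [_E(m1, m2, u, A[1] - B[1], a, b) for u in range(m1 + m2 + 1)]
    E1z = [_E(n1, n2, v, A[2] - B[2], a, b) for v in range(n1 + n2 + 1)]
    E2x = [_E(l3, l4, t, C[0] - D[0], c, d) for t in range(l3 + l4 + 1)]
    E2y = [_E(m3, m4, u, C[1] - D[1], c, d) for u in range(m3 + m4 + 1)]
    E2z = [_E(n3, n4, v, C[2] - D[2], c, d) for v in range(n3 + n4 + 1)]
    memo = {}
    val = 0.0
    for t in range(l1 + l2 + 1):
        for u in range(m1 + m2 + 1):
            for v in range(n1 + n2 + 1):
                e1 = E1x[t] * E1y[u] * E1z[v]
                if e1 == 0.0:
                    continue
                for tt in range(l3 + l4 + 1):
                    for uu in range(m3 + m4 + 1):
                        for vv in range(n3 + n4 + 1):
                            e2 = E2x[tt] * E2y[uu] * E2z[vv]
                            if e2 == 0.0:
                                continue
                            val += (
                                e1
                                * e2
                                * (-1.0) ** (tt + uu + vv)
                                * _R(t + tt, u + uu, v + vv, 0, alpha, PQ, memo)
                            )
    return val * 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))


def _contract_pair(f1, f2, prim_fn):
    A, lmn1, exps1, c1 = f1
    B, lmn2, exps2, c2 = f2
    s = 0.0
    for a, ca in zip(exps1, c1):
        for b, cb in zip(exps2, c2):
            s += ca * cb * prim_fn(a, lmn1, A, b, lmn2, B)
    return s


class _Matrices:
    """Integral matrices over an AOBasis (overlap, kinetic, potentials, ERI)."""

    def __init__(self, basis: AOBasis):
        self.basis = basis

    def overlap(self):
        n = self.basis.n
        S = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1):
                S[i, j] = S[j, i] = _contract_pair(
                    self.basis.functions[i], self.basis.functions[j], _prim_overlap
                )
        return S

    def kinetic(self):
        n = self.basis.n
        T = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1):
                T[i, j] = T[j, i] = _contract_pair(
                    self.basis.functions[i], self.basis.functions[j], _prim_kinetic
                )
        return T

    def point_potential(self, center):
        """Positive-definite matrix <phi_p| 1/|r - center| |phi_q> (Bohr)."""
        C = np.asarray(center, dtype=float)
        n = self.basis.n
        V = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1):
                V[i, j] = V[j, i] = _contract_pair(
                    self.basis.functions[i],
                    self.basis.functions[j],
                    lambda a, l1, A, b, l2, B: _prim_coulomb_1e(a, l1, A, b, l2, B, C),
                )
        return V

    def nuclear_attraction(self, nuclei):
        """-sum_N Z_N <p|1/|r-R_N||q> over (Z, position_bohr) pairs."""
        n = self.basis.n
        V = np.zeros((n, n))
        for Z, R in nuclei:
            V -= Z * self.point_potential(R)
        return V

    def eri(self):
        """Chemist-notation two-electron integrals (pq|rs), 8-fold symmetric."""
        n = self.basis.n
        g = np.zeros((n, n, n, n))
        fns = self.basis.functions

        def pair_iter():
            for i in range(n):
                for j in range(i + 1):
                    yield i, j

        pairs = list(pair_iter())
        for pi, (i, j) in enumerate(pairs):
            for k, l in pairs[: pi + 1]:
                val = 0.0
                Ai, l1, e1, c1 = fns[i]
                Aj, l2, e2, c2 = fns[j]
                Ak, l3, e3, c3 = fns[k]
                Al, l4, e4, c4 = fns[l]
                for a, ca in zip(e1, c1):
                    for b, cb in zip(e2, c2):
                        for c, cc in zip(e3, c3):
                            for d, cd in zip(e4, c4):
                                val += ca * cb * cc * cd * _prim_eri(
                                    a, l1, Ai, b, l2, Aj, c, l3, Ak, d, l4, Al
                                )
                for p, q in ((i, j), (j, i)):
                    for r, s in ((k, l), (l, k)):
                        g[p, q, r, s] = g[r, s, p, q] = val
        return g


# ---------------------------------------------------------------------------
# Built-in basis data

# STO-3G exponents/coefficients (s and sp rows) for the light main-group
# elements this package's toy systems use.
_STO3G_S_COEF = [0.15432897, 0.53532814, 0.44463454]
_STO3G_SP_SCOEF = [-0.09996723, 0.39951283, 0.70011547]
_STO3G_SP_PCOEF = [0.15591627, 0.60768372, 0.39195739]

STO3G = {
    "H": [("s", [3.42525091, 0.62391373, 0.16885540], _STO3G_S_COEF)],
    "He": [("s", [6.36242139, 1.15892300, 0.31364979], _STO3G_S_COEF)],
    "C": [
        ("s", [71.6168370, 13.0450960, 3.5305122], _STO3G_S_COEF),
        ("sp", [2.9412494, 0.6834831, 0.2222899], (_STO3G_SP_SCOEF, _STO3G_SP_PCOEF)),
    ],
    "N": [
        ("s", [99.1061690, 18.0523120, 4.8856602], _STO3G_S_COEF),
        ("sp", [3.7804559, 0.8784966, 0.2857144], (_STO3G_SP_SCOEF, _STO3G_SP_PCOEF)),
    ],
    "O": [
        ("s", [130.7093200, 23.8088610, 6.4436083], _STO3G_S_COEF),
        ("sp", [5.0331513, 1.1695961, 0.3803890], (_STO3G_SP_SCOEF, _STO3G_SP_PCOEF)),
    ],
    "F": [
        ("s", [166.6791300, 30.3608120, 8.2168207], _STO3G_S_COEF),
        ("sp", [6.4648032, 1.5022812, 0.4885885], (_STO3G_SP_SCOEF, _STO3G_SP_PCOEF)),
    ],
}

_L_OF = {"s": 0, "p": 1, "d": 2}


def build_basis(elements, coords_bohr, basis="sto-3g"):
    """Assemble an AOBasis for a geometry.

    ``basis`` is either the name ``"sto-3g"`` or a dict mapping element
    label -> list of shells ``(l_letter, exps, coefs)`` (``"sp"`` rows take
    a (s_coefs, p_coefs) pair).
    """
    if isinstance(basis, str):
        name = basis.lower()
        if name != "sto-3g":
            raise ValueError(f"unknown basis '{basis}' (built-in: sto-3g)")
        table = STO3G
    else:
        table = basis
    shells = []
    for el, R in zip(elements, np.asarray(coords_bohr, dtype=float)):
        if el not in table:
            raise ValueError(f"no basis functions for element '{el}'")
        for row in table[el]:
            lab, exps, coefs = row
            if lab == "sp":
                cs, cp = coefs
                shells.append(Shell(0, R, np.asarray(exps), np.asarray(cs)))
                shells.append(Shell(1, R, np.asarray(exps), np.asarray(cp)))
            else:
                shells.append(Shell(_L_OF[lab], R, np.asarray(exps), np.asarray(coefs)))
    return AOBasis(shells)


def ao_matrices(basis: AOBasis) -> _Matrices:
    return _Matrices(basis)
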