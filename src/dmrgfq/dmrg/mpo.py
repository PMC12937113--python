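"""Matrix product operators for the active-space Hamiltonian.

The second-quantized Hamiltonian

    H = sum_pq h_pq E_pq + 1/2 sum_pqrs g_pqrs (E_pq E_rs - d_rq E_ps)
      = sum_pq,s h_pq c+_ps c_qs + 1/2 sum_pqrs,st g_pqrs c+_ps c+_rt c_st c_qs

is assembled as a direct sum of Jordan–Wigner product strings, compressed
exactly (SVD with a near-machine relative cutoff) into an MPO of bond
dimension polynomial in L.  The internal layout is not prescribed; its
contract is equality with the dense Fock-space operator.
"""

from __future__ import annotations

import numpy as np

from .local_ops import IDN, N_TOT, SZ, S_PLUS, S_MINUS, fermion_string

__all__ = [
    "MPO",
    "build_mpo",
    "mpo_from_matrix_strings",
    "identity_mpo",
    "sector_penalty_mpo",
    "s2_mpo",
]

_COMPRESS_CUTOFF = 3e-14


class MPO:
    """Per-site operator tensors W[l] with index order
    (left bond, right bond, ket physical, bra physical)."""

    def __init__(self, tensors: list[np.ndarray]):
        self.tensors = [np.asarray(t, dtype=float) for t in tensors]
        if self.tensors[0].shape[0] != 1 or self.tensors[-1].shape[1] != 1:
            raise ValueError("boundary MPO bonds must have dimension 1")
        for a, b in zip(self.tensors, self.tensors[1:]):
            if a.shape[1] != b.shape[0]:
                raise ValueError("mismatched MPO bond dimensions")

    @property
    def L(self) -> int:
        return len(self.tensors)

    @property
    def bond_dimensions(self) -> list[int]:
        return [t.shape[1] for t in self.tensors[:-1]]

    def __add__(self, other: "MPO") -> "MPO":
        if self.L != other.L:
            raise ValueError("site-count mismatch")
        out = []
        for l, (A, B) in enumerate(zip(self.tensors, other.tensors)):
            al, ar = A.shape[:2]
            bl, br = B.shape[:2]
            if l == 0:
                W = np.concatenate([A, B], axis=1)
            elif l == self.L - 1:
                W = np.concatenate([A, B], axis=0)
            else:
                W = np.zeros((al + bl, ar + br, 4, 4))
                W[:al, :ar] = A
                W[al:, ar:] = B
            out.append(W)
        return MPO(out)

    def scaled(self, c: float) -> "MPO":
        out = [t.copy() for t in self.tensors]
        out[0] = out[0] * c
        return MPO(out)

    def compress(self, cutoff: float = _COMPRESS_CUTOFF) -> "MPO":
        """Exact-rank compression: SVD sweeps treating the MPO as an MPS of
        physical dimension 16, dropping singular values below
        cutoff * s_max of each decomposition."""
        ts = [t.copy() for t in self.tensors]
        L = self.L
        # left-to-right
        for l in range(L - 1):
            bl, br = ts[l].shape[:2]
            mat = ts[l].transpose(0, 2, 3, 1).reshape(bl * 16, br)
            U, s, Vt = np.linalg.svd(mat, full_matrices=False)
            keep = max(1, int(np.sum(s > cutoff * (s[0] if s.size else 1.0))))
            U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
            ts[l] = U.reshape(bl, 4, 4, keep).transpose(0, 3, 1, 2)
            ts[l + 1] = np.einsum("i,ij,jkab->ikab", s, Vt, ts[l + 1])
        # right-to-left
        for l in range(L - 1, 0, -1):
            bl, br = ts[l].shape[:2]
            mat = ts[l].reshape(bl, br * 16)
            U, s, Vt = np.linalg.svd(mat, full_matrices=False)
            keep = max(1, int(np.sum(s > cutoff * (s[0] if s.size else 1.0))))
            U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
            ts[l] = Vt.reshape(keep, br, 4, 4)
            ts[l - 1] = np.einsum("ijab,jk,k->ikab", ts[l - 1], U, s)
        return MPO(ts)

    def to_dense(self) -> np.ndarray:
        """Contract to the dense 4^L x 4^L Fock-space matrix (small L only).

        Site 0 is the slowest-varying index of the composite basis.
        """
        L = self.L
        if L > 7:
            raise ValueError("dense conversion limited to L <= 7")
        half = L // 2

        def contract(ts):
            d0 = ts[0].shape[0]
            res = np.eye(d0).reshape(d0, d0, 1, 1)  # (bond_l, bond_r, ket, bra)
            for W in ts:
                res = np.einsum("lrkb,rsKB->lskKbB", res, W)
                sh = res.shape
                res = res.reshape(sh[0], sh[1], sh[2] * sh[3], sh[4] * sh[5])
            return res

        left = contract(self.tensors[:half])[0]        # (b, kL, bL)
        right = contract(self.tensors[half:])[:, 0]    # (b, kR, bR)
        dl = left.shape[1]
        dr = right.shape[1]
        out = np.zeros((dl * dr, dl * dr))
        for b in range(left.shape[0]):
            out += np.kron(left[b], right[b])
        return out


def identity_mpo(L: int) -> MPO:
    return MPO([IDN.reshape(1, 1, 4, 4).copy() for _ in range(L)])


def _product_mpo(L: int, mats: list[np.ndarray], coeff: float = 1.0) -> MPO:
    ts = [m.reshape(1, 1, 4, 4).copy() for m in mats]
    ts[0] = ts[0] * coeff
    return MPO(ts)


def _sum_strings(L, string_iter, cutoff, batch=96):
    acc = None
    block = None
    nblock = 0
    for coeff, mats in string_iter:
        term = _product_mpo(L, mats, coeff)
        block = term if block is None else block + term
        nblock += 1
        if nblock >= batch:
            block = block.compress(cutoff)
            acc = block if acc is None else (acc + block).compress(cutoff)
            block, nblock = None, 0
    if block is not None:
        block = block.compress(cutoff)
        acc = block if acc is None else (acc + block).compress(cutoff)
    if acc is None:
        raise ValueError("no operator strings supplied")
    return acc


def mpo_from_matrix_strings(L, strings, cutoff=_COMPRESS_CUTOFF) -> MPO:
    """Build an MPO from ``(coeff, [(site, 4x4 matrix), ...])`` products of
    even (string-free) local operators; same-site factors multiply in the
    order given."""

    def gen():
        for coeff, factors in strings:
            mats = [IDN.copy() for _ in range(L)]
            for site, m in factors:
                mats[site] = mats[site] @ m
            yield coeff, mats

    return _sum_strings(L, gen(), cutoff)


def build_mpo(integrals, cutoff=_COMPRESS_CUTOFF, tol_sym=1e-8) -> MPO:
    """Hamiltonian MPO from active-space integrals (chemist-notation g)."""
    h, g = integrals.h, integrals.g
    L = integrals.n_orbitals_active
    if np.max(np.abs(h - h.T)) > tol_sym:
        raise ValueError("one-electron matrix not symmetric")
    if integrals.g_asymmetry() > tol_sym:
        raise ValueError("two-electron tensor lacks 8-fold symmetry")

    def gen():
        if abs(integrals.core_energy) > 0.0:
            yield integrals.core_energy, [IDN.copy() for _ in range(L)]
        for p in range(L):
            for q in range(L):
                if abs(h[p, q]) < 1e-14:
                    continue
                for s in (0, 1):
                    yield h[p, q], fermion_string(
                        L, [(p, "c", s), (q, "a", s)]
                    )
        for p in range(L):
            for q in range(L):
                for r in range(L):
                    for s_ in range(L):
                        c = 0.5 * g[p, q, r, s_]
                        if abs(c) < 1e-14:
                            continue
                        for s1 in (0, 1):
                            for s2 in (0, 1):
                                yield c, fermion_string(
                                    L,
                                    [
                                        (p, "c", s1),
                                        (r, "c", s2),
                                        (s_, "a", s2),
                                        (q, "a", s1),
                                    ],
                                )

    return _sum_strings(L, gen(), cutoff)


def sector_penalty_mpo(L: int, n_electrons: int, two_sz: int, mu: float) -> MPO:
    """mu * [(N - N0)^2 + (Sz - Sz0)^2]: a positive operator vanishing on
    the targeted (N, 2Sz) particle/spin sector, used as an optional safety
    net to pin dense sweeps inside the sector."""
    sz0 = 0.5 * two_sz
    strings = []
    for i in range(L):
        for j in range(L):
            strings.append((mu, [(i, N_TOT), (j, N_TOT)]))
            strings.append((mu, [(i, SZ), (j, SZ)]))
        strings.append((-2.0 * mu * n_electrons, [(i, N_TOT)]))
        strings.append((-2.0 * mu * sz0, [(i, SZ)]))
    strings.append((mu * (n_electrons**2 + sz0**2), [(0, IDN)]))
    return mpo_from_matrix_strings(L, strings)


def s2_mpo(L: int) -> MPO:
    """Total-spin operator S^2 = Sz^2 + (S+S- + S-S+)/2 as an MPO."""
    strings = []
    for i in range(L):
        for j in range(L):
            strings.append((1.0, [(i, SZ), (j, SZ)]))
            strings.append((0.5, [(i, S_PLUS), (j, S_MINUS)]))
            strings.append((0.5, [(i, S_MINUS), (j, S_PLUS)]))
    return mpo_from_matrix_strings(L, strings)
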