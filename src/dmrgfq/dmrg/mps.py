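"""Matrix product states over the 4-dimensional orbital occupation basis.

Site tensors M[l] have index order (left bond, physical, right bond) with
local basis |0>, |up>, |down>, |updown>.  The gauge center tracks mixed
canonical form: tensors strictly left of it are left-orthogonal, tensors
right of it right-orthogonal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MPS", "sector_configurations"]

_DIGIT_N = np.array([0, 1, 1, 2])
_DIGIT_2SZ = np.array([0, 1, -1, 0])


def sector_configurations(L, n_electrons, two_sz):
    """All length-L local-basis digit strings with the given particle number
    and spin projection."""
    out = []

    def rec(prefix, n, sz):
        l = len(prefix)
        if n > n_electrons or abs(two_sz - sz) > 2 * (L - l):
            return
        if n_electrons - n > 2 * (L - l):
            return
        if l == L:
            if n == n_electrons and sz == two_sz:
                out.append(tuple(prefix))
            return
        for d in range(4):
            prefix.append(d)
            rec(prefix, n + _DIGIT_N[d], sz + _DIGIT_2SZ[d])
            prefix.pop()

    rec([], 0, 0)
    return out


class MPS:
    def __init__(self, tensors, gauge_center=None):
        self.tensors = [np.asarray(t, dtype=float) for t in tensors]
        if self.tensors[0].shape[0] != 1 or self.tensors[-1].shape[2] != 1:
            raise ValueError("boundary bonds must have dimension 1")
        for a, b in zip(self.tensors, self.tensors[1:]):
            if a.shape[2] != b.shape[0]:
                raise ValueError("mismatched bond dimensions")
        self.gauge_center = gauge_center

    # ------------------------------------------------------------------
    @property
    def L(self) -> int:
        return len(self.tensors)

    @property
    def bond_dimensions(self):
        return [t.shape[2] for t in self.tensors[:-1]]

    def copy(self) -> "MPS":
        return MPS([t.copy() for t in self.tensors], self.gauge_center)

    # ------------------------------------------------------------------
    @classmethod
    def from_dense(cls, vec, L=None, cutoff=1e-14, max_bond=None) -> "MPS":
        vec = np.asarray(vec, dtype=float)
        if L is None:
            L = int(round(np.log(vec.size) / np.log(4)))
        if 4**L != vec.size:
            raise ValueError("vector length is not 4^L")
        tensors = []
        rest = vec.reshape(1, -1)
        for l in range(L - 1):
            al = rest.shape[0]
            mat = rest.reshape(al * 4, -1)
            U, s, Vt = np.linalg.svd(mat, full_matrices=False)
            keep = int(np.sum(s > cutoff * (s[0] if s.size else 1.0)))
            keep = max(1, keep if max_bond is None else min(keep, max_bond))
            tensors.append(U[:, :keep].reshape(al, 4, keep))
            rest = (s[:keep, None] * Vt[:keep]).reshape(keep, -1)
        tensors.append(rest.reshape(-1, 4, 1))
        return cls(tensors, gauge_center=L - 1)

    @classmethod
    def from_occupations(cls, digits) -> "MPS":
        ts = []
        for d in digits:
            t = np.zeros((1, 4, 1))
            t[0, d, 0] = 1.0
            ts.append(t)
        return cls(ts, gauge_center=0)

    @classmethod
    def random_sector(cls, L, n_electrons, two_sz, max_bond, rng,
                      max_dense_L=10) -> "MPS":
        """Normalized random state confined to the (N, 2Sz) sector."""
        configs = sector_configurations(L, n_electrons, two_sz)
        if not configs:
            raise ValueError("empty particle/spin sector")
        if L <= max_dense_L:
            vec = np.zeros(4**L)
            pows = 4 ** np.arange(L - 1, -1, -1)
            for cfg in configs:
                vec[int(np.dot(cfg, pows))] = rng.standard_normal()
            mps = cls.from_dense(vec, L, max_bond=max_bond)
        else:
            take = min(len(configs), 4 * max_bond)
            idx = rng.choice(len(configs), size=take, replace=False)
            mps = None
            for i in idx:
                term = cls.from_occupations(configs[i])
                term.tensors[0] *= rng.standard_normal()
                mps = term if mps is None else mps + term
            mps = mps.compressed(max_bond=max_bond)
        mps.normalize()
        return mps

    # ------------------------------------------------------------------
    def to_dense(self) -> np.ndarray:
        res = np.ones((1, 1))
        for t in self.tensors:
            res = np.einsum("ia,asb->isb", res, t).reshape(-1, t.shape[2])
        return res[:, 0]

    def norm(self) -> float:
        T = np.ones((1, 1))
        for t in self.tensors:
            T = np.einsum("ab,asc,bsd->cd", T, t, t, optimize=True)
        return float(np.sqrt(max(T[0, 0], 0.0)))

    def normalize(self) -> None:
        n = self.norm()
        if n == 0:
            raise ValueError("cannot normalize the zero state")
        c = self.gauge_center if self.gauge_center is not None else 0
        self.tensors[c] = self.tensors[c] / n

    def overlap(self, other: "MPS") -> float:
        T = np.ones((1, 1))
        for a, b in zip(self.tensors, other.tensors):
            T = np.einsum("ab,asc,bsd->cd", T, a, b, optimize=True)
        return float(T[0, 0])

    # ------------------------------------------------------------------
    def __add__(self, other: "MPS") -> "MPS":
        if self.L != other.L:
            raise ValueError("site-count mismatch")
        out = []
        for l, (A, B) in enumerate(zip(self.tensors, other.tensors)):
            al, _, ar = A.shape
            bl, _, br = B.shape
            if l == 0:
                T = np.concatenate([A, B], axis=2)
            elif l == self.L - 1:
                T = np.concatenate([A, B], axis=0)
            else:
                T = np.zeros((al + bl, 4, ar + br))
                T[:al, :, :ar] = A
                T[al:, :, ar:] = B
            out.append(T)
        return MPS(out, gauge_center=None)

    def compressed(self, cutoff=1e-14, max_bond=None) -> "MPS":
        ts = [t.copy() for t in self.tensors]
        L = self.L
        for l in range(L - 1):  # left sweep: orthogonalize
            al, _, ar = ts[l].shape
            Q, R = np.linalg.qr(ts[l].reshape(al * 4, ar))
            ts[l] = Q.reshape(al, 4, -1)
            ts[l + 1] = np.einsum("ij,jsk->isk", R, ts[l + 1])
        for l in range(L - 1, 0, -1):  # right sweep: truncate
            al, _, ar = ts[l].shape
            U, s, Vt = np.linalg.svd(ts[l].reshape(al, 4 * ar),
                                     full_matrices=False)
            keep = int(np.sum(s > cutoff * (s[0] if s.size else 1.0)))
            keep = max(1, keep if max_bond is None else min(keep, max_bond))
            ts[l] = Vt[:keep].reshape(keep, 4, ar)
            ts[l - 1] = np.einsum("isj,jk,k->isk", ts[l - 1], U[:, :keep],
                                  s[:keep])
        return MPS(ts, gauge_center=0)

    # ------------------------------------------------------------------
    def move_gauge_right(self, l: int) -> None:
        """QR step making site l left-orthogonal, absorbing R into l+1."""
        al, _, ar = self.tensors[l].shape
        Q, R = np.linalg.qr(self.tensors[l].reshape(al * 4, ar))
        self.tensors[l] = Q.reshape(al, 4, -1)
        self.tensors[l + 1] = np.einsum("ij,jsk->isk", R, self.tensors[l + 1])
        self.gauge_center = l + 1

    def move_gauge_left(self, l: int) -> None:
        """Make site l right-orthogonal, absorbing the factor into l-1."""
        al, _, ar = self.tensors[l].shape
        mat = self.tensors[l].reshape(al, 4 * ar)
        Q, R = np.linalg.qr(mat.T)
        self.tensors[l] = Q.T.reshape(-1, 4, ar)
        self.tensors[l - 1] = np.einsum("isj,kj->isk", self.tensors[l - 1], R)
        self.gauge_center = l - 1

    def canonicalize(self, center: int = 0) -> "MPS":
        """Return a copy in mixed-canonical form with the given center."""
        out = self.copy()
        out.gauge_center = None
        for l in range(center):
            out.move_gauge_right(l)
        for l in range(self.L - 1, center, -1):
            out.move_gauge_left(l)
        out.gauge_center = center
        return out

    # ------------------------------------------------------------------
    def orthogonality_errors(self):
        """(left, right) orthogonality deviations w.r.t. the gauge center."""
        c = self.gauge_center
        left_err = 0.0
        right_err = 0.0
        for l in range(self.L):
            t = self.tensors[l]
            if c is not None and l < c:
                G = np.einsum("asb,asc->bc", t, t)
                left_err = max(left_err, np.max(np.abs(G - np.eye(G.shape[0]))))
            elif c is not None and l > c:
                G = np.einsum("asb,csb->ac", t, t)
                right_err = max(right_err,
                                np.max(np.abs(G - np.eye(G.shape[0]))))
        return left_err, right_err

    def sector_expectations(self):
        """(<N>, <2Sz>) from on-site number/spin operators."""
        from .local_ops import N_TOT, SZ

        nval, szval = 0.0, 0.0
        for which, op in (("n", N_TOT), ("sz", SZ)):
            total = 0.0
            for site in range(self.L):
                T = np.ones((1, 1))
                for l, t in enumerate(self.tensors):
                    if l == site:
                        T = np.einsum("ab,asc,st,btd->cd", T, t, op, t,
                                      optimize=True)
                    else:
                        T = np.einsum("ab,asc,bsd->cd", T, t, t, optimize=True)
                total += T[0, 0]
            if which == "n":
                nval = total
            else:
                szval = total
        return nval, 2.0 * szval
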