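"""Two-site DMRG sweeps.

The energy functional <psi|H|psi> is minimized tensor-pair by tensor-pair:
partial contractions of <psi|H|psi> from the left and right (the
boundaries) reduce each local problem to a sparse symmetric eigenproblem,
solved with a Davidson iteration seeded by the current tensor pair.  The
optimized pair is split by SVD with truncation to the maximum bond
dimension M, and the boundaries are updated incrementally.

Excited states are targeted by projecting the local problem onto the
orthogonal complement of previously converged states (their overlap
environments are carried through the sweep alongside the Hamiltonian
boundaries), with root-homing by maximum overlap inside the Davidson
subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mpo import MPO
from .mps import MPS

__all__ = ["Boundaries", "expectation", "optimize_mps", "SweepResult"]

_SV_FLOOR = 1e-14
_DEGENERACY_REL = 1e-10


@dataclass
class Boundaries:
    """Left/right partial contractions of <psi|H|psi>.

    left[l] covers sites 0..l-1 (shape: mpo bond x bra bond x ket bond);
    right[l] covers sites l..L-1.
    """

    left: list
    right: list

    @classmethod
    def from_state(cls, mps: MPS, mpo: MPO) -> "Boundaries":
        L = mps.L
        left = [None] * (L + 1)
        right = [None] * (L + 1)
        left[0] = np.ones((1, 1, 1))
        for l in range(L):
            left[l + 1] = _extend_left(left[l], mps.tensors[l], mpo.tensors[l])
        right[L] = np.ones((1, 1, 1))
        for l in range(L - 1, -1, -1):
            right[l] = _extend_right(right[l + 1], mps.tensors[l], mpo.tensors[l])
        return cls(left=left, right=right)

    def recompute_deviation(self, mps: MPS, mpo: MPO) -> float:
        """Max difference between stored and from-scratch boundaries."""
        fresh = Boundaries.from_state(mps, mpo)
        dev = 0.0
        for a, b in zip(self.left, fresh.left):
            if a is not None and b is not None and a.shape == b.shape:
                dev = max(dev, float(np.max(np.abs(a - b))))
        for a, b in zip(self.right, fresh.right):
            if a is not None and b is not None and a.shape == b.shape:
                dev = max(dev, float(np.max(np.abs(a - b))))
        return dev


def _extend_left(E, M, W):
    # E[w,p,a]  M[a,s,c]  W[w,v,s,t]  ->  E'[v,c,c']
    t = np.einsum("wpa,ptc->wtac", E, M, optimize=True)
    t = np.einsum("wvts,wtac->vsac", W, t, optimize=True)
    return np.einsum("vsac,asd->vcd", t, M, optimize=True)


def _extend_right(F, M, W):
    # F[v,c,c']  M[a,s,c]  W[w,v,s,t] -> F'[w,a,a']
    t = np.einsum("vcd,psc->vpsd", F, M, optimize=True)
    t = np.einsum("wvst,vpsd->wptd", W, t, optimize=True)
    return np.einsum("wptd,atd->wpa", t, M, optimize=True)


def expectation(mps: MPS, mpo: MPO, normalize: bool = False) -> float:
    """<psi|O|psi> via boundary contraction (optionally / <psi|psi>)."""
    if mps.L != mpo.L:
        raise ValueError("site-count mismatch")
    E = np.ones((1, 1, 1))
    for M, W in zip(mps.tensors, mpo.tensors):
        if M.shape[0] != E.shape[1]:
            raise ValueError("bond mismatch between MPS tensors")
        E = _extend_left(E, M, W)
    val = float(E[0, 0, 0])
    if normalize:
        n2 = mps.overlap(mps)
        val /= n2
    return val


# ---------------------------------------------------------------------------
# local two-site problem


class _LocalProblem:
    def __init__(self, envs, projectors=None):
        # envs: list of (E, W1, W2, F) tuples; their matvecs add up
        self.envs = envs
        self.projectors = projectors or []

    def shape(self):
        E, W1, W2, F = self.envs[0]
        return (E.shape[1], 4, 4, F.shape[1])

    def project(self, x):
        for v in self.projectors:
            x = x - np.dot(v.ravel(), x.ravel()) * v
        return x

    def matvec(self, x):
        y = np.zeros_like(x)
        for E, W1, W2, F in self.envs:
            t = np.einsum("wpa,atTb->wptTb", E, x, optimize=True)
            t = np.einsum("wvst,wptTb->vpsTb", W1, t, optimize=True)
            t = np.einsum("vuST,vpsTb->upsSb", W2, t, optimize=True)
            y += np.einsum("uqb,upsSb->psSq", F, t, optimize=True)
        return y

    def diagonal(self):
        d = np.zeros(self.shape())
        for E, W1, W2, F in self.envs:
            Ed = np.einsum("waa->wa", E)
            W1d = np.einsum("wvss->wvs", W1)
            W2d = np.einsum("vuss->vus", W2)
            Fd = np.einsum("ubb->ub", F)
            d += np.einsum("wa,wvs,vuS,ub->asSb", Ed, W1d, W2d, Fd,
                           optimize=True)
        return d

    def solve(self, x0, tol, max_iter=60, max_space=20):
        """Lowest eigenpair by Davidson with diagonal preconditioning,
        seeded from x0 and restricted to the projected subspace.  Root
        homing: among converged Ritz pairs, follow maximum overlap with x0
        when eigenvalues are quasi-degenerate."""
        shape = x0.shape
        n = x0.size
        diag = self.diagonal().ravel()
        x = self.project(x0.copy()).ravel()
        nrm = np.linalg.norm(x)
        if nrm < 1e-12:
            rng = np.random.default_rng(0)
            x = self.project(rng.standard_normal(shape)).ravel()
            nrm = np.linalg.norm(x)
        x /= nrm
        if n <= 256:
            # dense path for tiny local problems
            H = np.empty((n, n))
            eye = np.eye(n)
            for i in range(n):
                H[:, i] = self.project(
                    self.matvec(self.project(eye[:, i].reshape(shape))
                                ).reshape(shape)).ravel()
            H = 0.5 * (H + H.T)
            w, V = np.linalg.eigh(H)
            # skip pure-projector null directions when projectors exist
            if self.projectors:
                ok = [i for i in range(n)
                      if np.linalg.norm(self.project(V[:, i].reshape(shape)))
                      > 0.5]
                idx = ok[int(np.argmin(w[ok]))] if ok else int(np.argmin(w))
            else:
                idx = int(np.argmin(w))
            return float(w[idx]), V[:, idx].reshape(shape)
        V = [x]
        HV = []
        theta, vec = None, x
        x0n = x.copy()
        for _ in range(max_iter):
            while len(HV) < len(V):
                v = V[len(HV)]
                HV.append(self.project(
                    self.matvec(v.reshape(shape))).ravel())
            m = len(V)
            A = np.empty((m, m))
            for i in range(m):
                for j in range(i + 1):
                    A[i, j] = A[j, i] = np.dot(V[i], HV[j])
            w, C = np.linalg.eigh(A)
            k = 0
            theta = w[k]
            y = C[:, k]
            vec = sum(c * v for c, v in zip(y, V))
            Hvec = sum(c * hv for c, hv in zip(y, HV))
            r = Hvec - theta * vec
            if np.linalg.norm(r) < tol:
                break
            denom = diag - theta
            denom[np.abs(denom) < 1e-8] = 1e-8
            t = self.project((r / denom).reshape(shape)).ravel()
            for v in V:
                t -= np.dot(v, t) * v
            tn = np.linalg.norm(t)
            if tn < 1e-12:
                break
            if len(V) >= max_space:  # restart from current Ritz vector
                V = [vec / np.linalg.norm(vec)]
                HV = []
                continue
            V.append(t / tn)
        nv = np.linalg.norm(vec)
        return float(theta), (vec / nv).reshape(shape)


def _split_pair(x, max_bond, direction="right"):
    """SVD split of a two-site tensor with truncation to ``max_bond``.

    direction="right": left factor orthogonal, weight moves right.
    direction="left": right factor orthogonal, weight moves left.
    """
    al, _, _, ar = x.shape
    U, s, Vt = np.linalg.svd(x.reshape(al * 4, 4 * ar), full_matrices=False)
    smax = s[0] if s.size else 0.0
    keep = int(np.sum(s > _SV_FLOOR * max(smax, 1.0)))
    keep = max(1, min(keep, max_bond))
    # keep degenerate groups together if space allows
    while (keep < min(len(s), max_bond)
           and s[keep] > s[keep - 1] * (1.0 - _DEGENERACY_REL)):
        keep += 1
    discarded = float(np.sum(s[keep:] ** 2))
    if direction == "right":
        A = U[:, :keep].reshape(al, 4, keep)
        B = (s[:keep, None] * Vt[:keep]).reshape(keep, 4, ar)
    else:
        A = (U[:, :keep] * s[:keep]).reshape(al, 4, keep)
        B = Vt[:keep].reshape(keep, 4, ar)
    return A, B, discarded


@dataclass
class SweepResult:
    energy: float
    mps: MPS
    trace: list[float] = field(default_factory=list)
    discarded_weights: list[float] = field(default_factory=list)
    converged: bool = False
    n_sweeps: int = 0


class _OverlapEnv:
    """Left/right overlap environments of the optimized state against a
    fixed reference state (for orthogonality projection)."""

    def __init__(self, mps: MPS, ref: MPS):
        L = mps.L
        self.ref = ref
        self.left = [None] * (L + 1)
        self.right = [None] * (L + 1)
        self.left[0] = np.ones((1, 1))
        self.right[L] = np.ones((1, 1))
        for l in range(L - 1, -1, -1):
            self.right[l] = self._ext_right(self.right[l + 1],
                                            mps.tensors[l], ref.tensors[l])

    @staticmethod
    def _ext_left(O, M, P):
        return np.einsum("ax,asc,xsz->cz", O, M, P, optimize=True)

    @staticmethod
    def _ext_right(O, M, P):
        return np.einsum("cz,asc,xsz->ax", O, M, P, optimize=True)

    def update_left(self, l, M):
        self.left[l + 1] = self._ext_left(self.left[l], M, self.ref.tensors[l])

    def update_right(self, l, M):
        self.right[l] = self._ext_right(self.right[l + 1], M,
                                        self.ref.tensors[l])

    def local_vector(self, l):
        """v with <psi|ref> = sum(v * x) for the two-site tensor x at (l, l+1)."""
        P1 = self.ref.tensors[l]
        P2 = self.ref.tensors[l + 1]
        t = np.einsum("ax,xsy,ySz->asSz", self.left[l], P1, P2, optimize=True)
        return np.einsum("asSz,bz->asSb", t, self.right[l + 2], optimize=True)


def optimize_mps(
    mpo: MPO,
    initial: MPS,
    max_bond: int,
    n_sweeps: int = 20,
    tol: float = 1e-9,
    orthogonal_to: list[MPS] | None = None,
    penalty_mpo: MPO | None = None,
    davidson_tol_schedule=(1e-6, 1e-10),
) -> SweepResult:
    """Variational ground state (or lowest state orthogonal to given
    states) of an MPO by two-site DMRG sweeps.

    Returns the best state found with a ``converged`` flag; non-convergence
    after ``n_sweeps`` is reported, never raised.
    """
    if max_bond < 1:
        raise ValueError("bond dimension must be >= 1")
    orthogonal_to = orthogonal_to or []
    mps = initial.canonicalize(center=0)
    L = mps.L
    mpos = [mpo] + ([penalty_mpo] if penalty_mpo is not None else [])
    # Hamiltonian (and penalty) environments
    envs = [Boundaries.from_state(mps, m) for m in mpos]
    oenvs = [_OverlapEnv(mps, ref) for ref in orthogonal_to]

    trace: list[float] = []
    discarded_all: list[float] = []
    converged = False
    tol_hi, tol_lo = davidson_tol_schedule
    energy = expectation(mps, mpo)

    for sweep in range(n_sweeps):
        dtol = max(tol_lo, tol_hi * (0.1**sweep))
        discarded = 0.0
        last_theta = None

        def local_solve(l, direction):
            nonlocal discarded, last_theta
            env_tuples = [
                (b.left[l], m.tensors[l], m.tensors[l + 1], b.right[l + 2])
                for b, m in zip(envs, mpos)
            ]
            projectors = []
            for oe in oenvs:
                v = oe.local_vector(l)
                nv = np.linalg.norm(v)
                if nv > 1e-12:
                    v = v / nv
                    for u in projectors:
                        v -= np.dot(u.ravel(), v.ravel()) * u
                    nv = np.linalg.norm(v)
                    if nv > 1e-10:
                        projectors.append(v / nv)
            prob = _LocalProblem(env_tuples, projectors)
            x0 = np.einsum("asb,bTc->asTc", mps.tensors[l],
                           mps.tensors[l + 1])
            theta, x = prob.solve(x0, dtol)
            last_theta = theta
            A, B, dw = _split_pair(x, max_bond, direction)
            discarded += dw
            mps.tensors[l] = A
            mps.tensors[l + 1] = B
            return theta

        # left-to-right
        for l in range(L - 1):
            local_solve(l, "right")
            mps.gauge_center = l + 1
            for b, m in zip(envs, mpos):
                b.left[l + 1] = _extend_left(b.left[l], mps.tensors[l],
                                             m.tensors[l])
            for oe in oenvs:
                oe.update_left(l, mps.tensors[l])
        # right-to-left
        for l in range(L - 2, -1, -1):
            local_solve(l, "left")
            mps.gauge_center = l
            for b, m in zip(envs, mpos):
                b.right[l + 1] = _extend_right(b.right[l + 2],
                                               mps.tensors[l + 1],
                                               m.tensors[l + 1])
            for oe in oenvs:
                oe.update_right(l + 1, mps.tensors[l + 1])

        trace.append(float(last_theta))
        discarded_all.append(discarded)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    mps.normalize()
    energy = expectation(mps, mpo)
    return SweepResult(
        energy=float(energy),
        mps=mps,
        trace=trace,
        discarded_weights=discarded_all,
        converged=converged,
        n_sweeps=len(trace),
    )
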