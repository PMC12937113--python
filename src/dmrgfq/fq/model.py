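"""Fluctuating-charge (FQ) polarizable force field.

Each classical atom carries a charge that responds to its environment.  The
energy is a second-order expansion in the charges,

    E_FQ(q) = sum_i q_i chi_i + 1/2 q^T T q,

with chi the atomic electronegativity and T the charge–charge interaction
kernel whose diagonal is the chemical hardness eta.  Charges are obtained
from the electronegativity-equalization principle: minimize E_FQ subject to
a fixed total charge per molecule, enforced through Lagrange multipliers.
An external electrostatic potential V (e.g. from a quantum region) enters
as an additional linear source term sum_i q_i V_i.

The off-diagonal kernel uses the Ohno functional form

    T_ij = eta_ij / sqrt(1 + eta_ij^2 r_ij^2),   eta_ij = (eta_i + eta_j)/2,

which interpolates between the bare hardness at r -> 0 (preventing the
polarization catastrophe) and the Coulomb 1/r tail at large separation.
It is applied to all pairs, intra- and inter-molecular alike.

Units: positions in Bohr, chi in Hartree/e, eta in Hartree/e^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "FQAtom",
    "FQMoleculeGroup",
    "FQSystem",
    "build_ohno_kernel",
    "solve_fq",
    "fq_energy",
]

_MIN_SEPARATION = 1e-8  # Bohr; below this the bordered system is singular


@dataclass
class FQAtom:
    """One polarizable site: position (Bohr), electronegativity chi
    (Hartree/e), hardness eta (Hartree/e^2) and an element label."""

    position: np.ndarray
    chi: float
    eta: float
    element_label: str = "X"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")
        if not self.eta > 0:
            raise ValueError(f"chemical hardness must be positive, got {self.eta}")


@dataclass
class FQMoleculeGroup:
    """Atoms constrained to share a fixed total charge (no intermolecular
    charge transfer)."""

    atom_indices: list[int]
    total_charge: float = 0.0

    def __post_init__(self):
        if len(self.atom_indices) == 0:
            raise ValueError("group must contain at least one atom")


@dataclass
class FQSystem:
    """A set of FQ atoms partitioned into charge-constrained molecules.

    ``kernel`` is built lazily from the Ohno form; ``charges`` and
    ``multipliers`` are populated by :func:`solve_fq`.
    """

    atoms: list[FQAtom]
    groups: list[FQMoleculeGroup]
    kernel: np.ndarray | None = None
    charges: np.ndarray | None = None
    multipliers: np.ndarray | None = None
    name: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        seen = [False] * n
        for g in self.groups:
            for i in g.atom_indices:
                if not 0 <= i < n:
                    raise ValueError(f"atom index {i} out of range")
                if seen[i]:
                    raise ValueError(f"atom {i} appears in more than one group")
                seen[i] = True
        if not all(seen):
            missing = [i for i, s in enumerate(seen) if not s]
            raise ValueError(f"atoms not covered by any group: {missing}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def chi(self) -> np.ndarray:
        return np.array([a.chi for a in self.atoms])

    @property
    def eta(self) -> np.ndarray:
        return np.array([a.eta for a in self.atoms])

    def ensure_kernel(self) -> np.ndarray:
        if self.kernel is None:
            self.kernel = build_ohno_kernel(self.atoms)
        return self.kernel

    def constraint_matrix(self) -> np.ndarray:
        """n_atoms x n_groups indicator matrix (the bordered-block columns)."""
        C = np.zeros((self.n_atoms, len(self.groups)))
        for a, g in enumerate(self.groups):
            C[g.atom_indices, a] = 1.0
        return C

    def translated(self, shift) -> "FQSystem":
        shift = np.asarray(shift, dtype=float)
        atoms = [
            FQAtom(a.position + shift, a.chi, a.eta, a.element_label)
            for a in self.atoms
        ]
        return FQSystem(atoms=atoms, groups=self.groups, name=self.name)


def build_ohno_kernel(atoms: list[FQAtom]) -> np.ndarray:
    """Symmetric charge–charge interaction matrix with Ohno-damped
    off-diagonal elements and the atomic hardnesses on the diagonal.

    Raises ``ValueError`` for coincident atoms (singular geometry) or
    non-positive hardness.
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    eta = np.array([a.eta for a in atoms])
    if np.any(eta <= 0):
        raise ValueError("all hardnesses must be positive")
    pos = np.array([a.position for a in atoms])
    n = len(atoms)
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < _MIN_SEPARATION):
        i, j = np.argwhere((r < _MIN_SEPARATION) & off)[0]
        raise ValueError(f"coincident atoms {i} and {j} (r < {_MIN_SEPARATION} Bohr)")
    eta_bar = 0.5 * (eta[:, None] + eta[None, :])
    T = eta_bar / np.sqrt(1.0 + eta_bar**2 * r**2)
    T[np.diag_indices(n)] = eta
    return T


def solve_fq(
    system: FQSystem,
    external_potential: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the constrained electronegativity-equalization linear system.

    Stationarity of E_FQ + q.V under the per-molecule charge constraints
    gives the bordered symmetric system

        [ T   C ] [ q ]   [ -chi - V ]
        [ C^T 0 ] [ l ] = [    Q     ]

    with C the group indicator matrix.  Returns ``(charges, multipliers)``
    and stores them on the system.  The solution is the unique constrained
    minimizer of the (convex) charge functional.
    """
    T = system.ensure_kernel()
    n = system.n_atoms
    chi = system.chi
    if external_potential is None:
        V = np.zeros(n)
    else:
        V = np.asarray(external_potential, dtype=float)
        if V.shape != (n,):
            raise ValueError(f"external potential has shape {V.shape}, expected ({n},)")
    C = system.constraint_matrix()
    ng = len(system.groups)
    A = np.zeros((n + ng, n + ng))
    A[:n, :n] = T
    A[:n, n:] = C
    A[n:, :n] = C.T
    rhs = np.concatenate([-chi - V, [g.total_charge for g in system.groups]])
    try:
        sol = scipy.linalg.solve(A, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(f"singular bordered FQ system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        bad = np.argwhere(~np.isfinite(sol)).ravel().tolist()
        raise ValueError(f"singular bordered FQ system (non-finite rows {bad})")
    q, lam = sol[:n], sol[n:]
    # sanity: constraints must hold to solver precision
    resid = C.T @ q - np.array([g.total_charge for g in system.groups])
    if np.max(np.abs(resid)) > 1e-8:
        raise ValueError(
            f"charge constraints violated (max residual {np.max(np.abs(resid)):.2e}); "
            "bordered system is ill-conditioned"
        )
    system.charges = q
    system.multipliers = lam
    return q, lam


def fq_energy(
    charges: np.ndarray,
    chi: np.ndarray,
    kernel: np.ndarray,
) -> float:
    """Second-order charge energy  q.chi + 1/2 q^T T q  (Hartree).

    The Lagrange term vanishes identically for feasible charges and is not
    included.
    """
    q = np.asarray(charges, dtype=float)
    chi = np.asarray(chi, dtype=float)
    T = np.asarray(kernel, dtype=float)
    if q.shape != chi.shape or T.shape != (q.size, q.size):
        raise ValueError(
            f"dimension mismatch: q {q.shape}, chi {chi.shape}, kernel {T.shape}"
        )
    return float(q @ chi + 0.5 * q @ T @ q)
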