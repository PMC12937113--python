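"""Local operators on the 4-dimensional orbital Fock space.

Basis ordering |0>, |up>, |down>, |updown> with |updown> = c_up^+ c_down^+ |0>.
Fermionic anticommutation between sites is handled by Jordan–Wigner parity
strings along the orbital chain; within a site the down operators carry the
up-occupation parity explicitly in their matrices.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDN", "PARITY", "A_UP", "A_DN", "C_UP", "C_DN",
    "N_UP", "N_DN", "N_TOT", "SZ", "S_PLUS", "S_MINUS",
    "fermion_string",
]

IDN = np.eye(4)
PARITY = np.diag([1.0, -1.0, -1.0, 1.0])

A_UP = np.zeros((4, 4))
A_UP[0, 1] = 1.0
A_UP[2, 3] = 1.0

A_DN = np.zeros((4, 4))
A_DN[0, 2] = 1.0
A_DN[1, 3] = -1.0  # passes the up electron

C_UP = A_UP.T.copy()
C_DN = A_DN.T.copy()

N_UP = np.diag([0.0, 1.0, 0.0, 1.0])
N_DN = np.diag([0.0, 0.0, 1.0, 1.0])
N_TOT = N_UP + N_DN
SZ = 0.5 * (N_UP - N_DN)
S_PLUS = C_UP @ A_DN   # |up><down|
S_MINUS = S_PLUS.T.copy()

_ELEMENTARY = {
    ("c", 0): C_UP,
    ("c", 1): C_DN,
    ("a", 0): A_UP,
    ("a", 1): A_DN,
}


def fermion_string(L: int, ops) -> list[np.ndarray]:
    """Per-site 4x4 matrices for a product of elementary fermion operators.

    ``ops`` is a list of ``(site, kind, spin)`` with kind in {"c", "a"} and
    spin 0 (up) / 1 (down), given in operator order (leftmost acts last on
    the ket).  Jordan–Wigner parity is inserted on all sites left of each
    operator's site.
    """
    mats = [IDN.copy() for _ in range(L)]
    # rightmost elementary operator is applied to the ket first, so build
    # the product left-to-right as given: total = m(ops[0]) @ m(ops[1]) ...
    for site, kind, spin in ops:
        local = _ELEMENTARY[(kind, spin)]
        for s in range(L):
            if s < site:
                mats[s] = mats[s] @ PARITY
            elif s == site:
                mats[s] = mats[s] @ local
    return mats
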