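"""Orbital ordering for the DMRG chain.

Orbitals that interact strongly should sit close together on the
one-dimensional lattice.  The ordering is taken from the Fiedler vector of
the graph Laplacian built on exchange-integral magnitudes
w_pq = |K_pq| = |g_pqqp|: orbitals are sorted by their component of the
eigenvector belonging to the second-smallest Laplacian eigenvalue, with
ties broken by ascending orbital index.  Disconnected components of the
coupling graph are ordered independently and concatenated.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["fiedler_order", "exchange_weights"]


def exchange_weights(integrals) -> np.ndarray:
    g = integrals.g
    L = integrals.n_orbitals_active
    K = np.array([[abs(g[p, q, q, p]) for q in range(L)] for p in range(L)])
    np.fill_diagonal(K, 0.0)
    return 0.5 * (K + K.T)


def _fiedler_component(W, nodes):
    n = len(nodes)
    if n == 1:
        return [nodes[0]]
    sub = W[np.ix_(nodes, nodes)]
    Lap = np.diag(sub.sum(axis=1)) - sub
    w, V = np.linalg.eigh(Lap)
    f = V[:, 1]
    # deterministic sign: first component of largest magnitude positive
    k = int(np.argmax(np.abs(f)))
    if f[k] < 0:
        f = -f
    order = np.lexsort((nodes, f))
    return [nodes[i] for i in order]


def fiedler_order(integrals, weights: np.ndarray | None = None) -> list[int]:
    """Permutation of active orbitals (new chain order) from the Fiedler
    vector of the exchange-coupling graph."""
    L = integrals.n_orbitals_active
    if L < 2:
        raise ValueError("ordering needs at least two orbitals")
    W = exchange_weights(integrals) if weights is None else np.asarray(weights)
    # connected components under nonzero coupling
    seen = [False] * L
    components = []
    for start in range(L):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(L):
                if not seen[v] and W[u, v] > 0:
                    seen[v] = True
                    stack.append(v)
        components.append(sorted(comp))
    if len(components) > 1:
        logger.warning(
            "coupling graph has %d disconnected components; ordering each "
            "independently", len(components),
        )
    order = []
    for comp in sorted(components, key=lambda c: c[0]):
        order.extend(_fiedler_component(W, comp))
    return order


def permute_integrals(integrals, order):
    """Reordered copy of active-space integrals (h, g) along ``order``."""
    from ..integrals.active_space import ActiveSpaceIntegrals

    idx = np.asarray(order)
    return ActiveSpaceIntegrals(
        h=integrals.h[np.ix_(idx, idx)],
        g=integrals.g[np.ix_(idx, idx, idx, idx)],
        core_energy=integrals.core_energy,
        n_electrons_active=integrals.n_electrons_active,
        spin_projection=integrals.spin_projection,
        metadata={**integrals.metadata, "orbital_order": list(map(int, idx))},
    )
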