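"""Electrostatic-potential operators at classical sites.

The potential a quantum region exerts on a point charge at r_i is

    V_i(D) = sum_N Z_N / |r_i - R_N|  -  sum_pq D_pq <p| 1/|r - r_i| |q>.

The electronic matrices are stored positive-definite, as written; the minus
sign is applied only at assembly points (see active_space.fold_fq_into_oei).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian import AOBasis, ao_matrices
from .active_space import ActiveESP, OrbitalSet

__all__ = ["ESPOperator", "nuclear_potential_at_sites", "electronic_esp_matrices"]

_MIN_SITE_NUCLEUS_DIST = 1e-6  # Bohr


@dataclass
class ESPOperator:
    """Nuclear potentials and AO-basis electronic ESP matrices at a set of
    classical sites (positions in Bohr)."""

    site_positions: np.ndarray
    nuclear_potential: np.ndarray          # (n_sites,)
    electronic_matrices_ao: np.ndarray     # (n_sites, nao, nao), positive

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def potential_of_ao_density(self, D_ao: np.ndarray) -> np.ndarray:
        """V_i(D) = nuclear - Tr[D V^FQ_i] for an AO-basis density."""
        return self.nuclear_potential - np.einsum(
            "ipq,pq->i", self.electronic_matrices_ao, D_ao
        )

    def to_active(self, orbital_set: OrbitalSet) -> ActiveESP:
        """Project onto an orbital partition: the inactive (core) density
        contribution joins the nuclear term as a static per-site potential,
        the active block stays as matrices."""
        C = orbital_set.coefficients
        Ci = C[:, orbital_set.inactive]
        Ca = C[:, orbital_set.active]
        D_core = 2.0 * Ci @ Ci.T
        static = self.nuclear_potential - np.einsum(
            "ipq,pq->i", self.electronic_matrices_ao, D_core
        )
        act = np.einsum("ipq,pa,qb->iab", self.electronic_matrices_ao, Ca, Ca,
                        optimize=True)
        act = 0.5 * (act + act.transpose(0, 2, 1))
        return ActiveESP(
            static_potential=static,
            active_matrices=act,
            site_positions=self.site_positions,
        )


def nuclear_potential_at_sites(nuclei, sites) -> np.ndarray:
    """sum_N Z_N/|r_i - R_N| at each site; nuclei = [(Z, position_bohr)]."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    out = np.zeros(len(sites))
    for Z, R in nuclei:
        d = np.linalg.norm(sites - np.asarray(R, dtype=float), axis=1)
        if np.any(d < _MIN_SITE_NUCLEUS_DIST):
            i = int(np.argmin(d))
            raise ValueError(
                f"site {i} lies on a nucleus (distance {d[i]:.2e} Bohr)"
            )
        out += Z / d
    return out


def electronic_esp_matrices(
    basis: AOBasis,
    sites,
    nuclei=None,
    orbital_set: OrbitalSet | None = None,
) -> ESPOperator | ActiveESP:
    """Electronic ESP matrices <p|1/|r-r_i||q> at each classical site.

    Returns an AO-basis :class:`ESPOperator`; if ``orbital_set`` is given
    the operator is projected to an :class:`ActiveESP` (which then requires
    ``nuclei``).
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    mats = ao_matrices(basis)
    V = np.array([mats.point_potential(r) for r in sites])
    nuc = (
        nuclear_potential_at_sites(nuclei, sites)
        if nuclei is not None
        else np.zeros(len(sites))
    )
    op = ESPOperator(
        site_positions=sites, nuclear_potential=nuc, electronic_matrices_ao=V
    )
    if orbital_set is not None:
        if nuclei is None:
            raise ValueError("projecting to an active space requires nuclei")
        return op.to_active(orbital_set)
    return op
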