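"""Deterministic synthetic fixtures: random active-space Hamiltonians with
known exact solutions, toy solute/solvent snapshot sets, and synthetic FQ
parameter sets.

Everything is seeded; the same seed reproduces byte-identical files.  The
random two-electron tensors are built as positive-semidefinite Coulomb-like
quadratic forms, so the spectra are bounded below and the 8-fold
permutational symmetry holds by construction.
"""

from __future__ import annotations

import os

import numpy as np

from .integrals.active_space import ActiveSpaceIntegrals, transform_to_active
from .integrals.fcidump import write_fcidump
from .integrals.region import QMRegion
from .io import write_multi_xyz
from .fq.io import save_fq_parameters

__all__ = [
    "random_integrals",
    "h2like_integrals",
    "h4_cas_region",
    "toy_snapshots",
    "synthetic_fq_parameters",
    "generate_fixtures",
]


def random_integrals(
    L: int,
    n_electrons: int,
    seed: int,
    correlation: float = 1.0,
    one_electron_scale: float = 1.0,
) -> ActiveSpaceIntegrals:
    """Seeded random Hamiltonian: symmetric h, PSD 8-fold-symmetric g.

    ``correlation`` scales the two-electron part relative to the
    one-electron part (0 gives an exactly solvable independent-orbital
    model).
    """
    rng = np.random.default_rng(seed)
    h = rng.standard_normal((L, L))
    h = 0.5 * (h + h.T) * one_electron_scale
    n_aux = max(2 * L, 4)
    g = np.zeros((L, L, L, L))
    for _ in range(n_aux):
        A = rng.standard_normal((L, L))
        A = 0.5 * (A + A.T)
        w = rng.uniform(0.0, 1.0) / n_aux
        g += w * np.einsum("pq,rs->pqrs", A, A)
    g *= correlation
    return ActiveSpaceIntegrals(
        h=h,
        g=g,
        core_energy=float(rng.standard_normal()),
        n_electrons_active=n_electrons,
        spin_projection=n_electrons % 2,
    )


def h2like_integrals(bond_length_angstrom: float = 0.74) -> ActiveSpaceIntegrals:
    """Minimal-basis H2: a genuine 2-orbital, 2-electron Hamiltonian whose
    exact spectrum is reachable at bond dimension 4."""
    region = QMRegion(
        ["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, bond_length_angstrom]]
    )
    _, C, _ = region.rhf()
    orbs = region.orbital_set(C, n_inactive=0, n_active=2)
    return transform_to_active(
        region.hcore, region.eri, orbs,
        n_electrons_active=2,
        nuclear_repulsion=region.nuclear_repulsion,
    )


def h4_cas_region(seed: int = 0, spread: float = 0.1) -> QMRegion:
    """Bent H4 chain in a minimal basis: a genuine 4-orbital molecule for
    CAS(2,2) work (1 inactive, 2 active, 1 virtual).

    ``seed`` jitters bond lengths and the bend angle so each fixture is a
    distinct molecule; spacings stay near 0.9-1.1 Å (well-conditioned RHF).
    """
    rng = np.random.default_rng(seed)
    d = 0.9 + spread * rng.random(3)
    bend = rng.uniform(0.0, 0.3)
    coords = [[0.0, 0.0, 0.0]]
    z = 0.0
    for k, dk in enumerate(d):
        z += dk
        coords.append([bend * np.sin(1.7 * (k + 1)), bend * np.cos(1.1 * k), z])
    return QMRegion(["H"] * 4, coords)


def synthetic_fq_parameters(seed: int, elements=("O", "H", "X")) -> dict:
    """Synthetic per-element (chi, eta) sets in Hartree-based units."""
    rng = np.random.default_rng(seed)
    table = {}
    for el in elements:
        chi = float(rng.uniform(0.0, 0.3))
        eta = float(rng.uniform(0.3, 0.8))
        table[el] = (chi, eta)
    return {"name": f"synthetic_{seed}", "elements": table}


def toy_snapshots(
    n_frames: int,
    seed: int,
    n_solvent: int = 3,
    solvent_distances=None,
    jitter: float = 0.05,
    solute_bond: float = 0.74,
):
    """Toy solute + solvent frames with seeded positional noise.

    The solute is a rigid H2-like diatomic at the origin; each solvent
    molecule is a rigid 3-site water-like bent triatomic placed at a
    programmed distance from the solute along a random direction, jittered
    by a Gaussian of width ``jitter`` (Å).  Returns a list of frames
    ``(elements, coords_angstrom, comment)`` plus grouping metadata
    ``{"solute": [...], "solvent_molecules": [[...], ...]}``.
    """
    rng = np.random.default_rng(seed)
    if solvent_distances is None:
        solvent_distances = [3.0 + 2.0 * k for k in range(n_solvent)]
    solute_elements = ["H", "H"]
    solute = np.array([[0.0, 0.0, -solute_bond / 2], [0.0, 0.0, solute_bond / 2]])
    # water-like template: O at origin, two H at 0.96 A, 104.5 deg
    ang = np.deg2rad(104.5 / 2)
    water = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.96 * np.sin(ang), 0.0, 0.96 * np.cos(ang)],
            [-0.96 * np.sin(ang), 0.0, 0.96 * np.cos(ang)],
        ]
    )
    water_elements = ["O", "H", "H"]
    frames = []
    for f in range(n_frames):
        elements = list(solute_elements)
        coords = [solute.copy()]
        for d in solvent_distances:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            center = u * (d + rng.normal(0.0, jitter))
            block = water + center + rng.normal(0.0, jitter, size=(3, 3))
            elements.extend(water_elements)
            coords.append(block)
        frames.append((elements, np.vstack(coords), f"frame {f}"))
    n_sol = len(solute_elements)
    grouping = {
        "solute": list(range(n_sol)),
        "solvent_molecules": [
            list(range(n_sol + 3 * k, n_sol + 3 * (k + 1)))
            for k in range(len(solvent_distances))
        ],
    }
    return frames, grouping


_KINDS = ("fcidump_random", "fcidump_h2like", "toy_snapshots", "fq_params")


def generate_fixtures(kind: str, seed: int, params: dict | None = None,
                      outdir: str = ".") -> list[str]:
    """Write fixture files; returns the paths written (deterministic under
    ``seed``)."""
    params = dict(params or {})
    os.makedirs(outdir, exist_ok=True)
    written = []
    if kind == "fcidump_random":
        L = int(params.get("L", 4))
        nel = int(params.get("n_electrons", L))
        asi = random_integrals(
            L, nel, seed, correlation=float(params.get("correlation", 1.0))
        )
        path = os.path.join(outdir, f"random_L{L}_seed{seed}.fcidump")
        write_fcidump(path, asi)
        written.append(path)
    elif kind == "fcidump_h2like":
        asi = h2like_integrals(float(params.get("bond_length", 0.74)))
        path = os.path.join(outdir, "h2like.fcidump")
        write_fcidump(path, asi)
        written.append(path)
    elif kind == "toy_snapshots":
        frames, grouping = toy_snapshots(
            int(params.get("n_frames", 3)),
            seed,
            n_solvent=int(params.get("n_solvent", 3)),
            solvent_distances=params.get("solvent_distances"),
            jitter=float(params.get("jitter", 0.05)),
        )
        xyz = os.path.join(outdir, f"toy_snapshots_seed{seed}.xyz")
        write_multi_xyz(xyz, frames)
        grp = os.path.join(outdir, f"toy_snapshots_seed{seed}.groups")
        with open(grp, "w") as fh:
            fh.write("# solute\n")
            fh.write(" ".join(map(str, grouping["solute"])) + "\n")
            fh.write("# solvent molecules\n")
            for mol in grouping["solvent_molecules"]:
                fh.write(" ".join(map(str, mol)) + "\n")
        written.extend([xyz, grp])
    elif kind == "fq_params":
        table = synthetic_fq_parameters(seed, params.get("elements", ("O", "H", "X")))
        path = os.path.join(outdir, f"fq_params_seed{seed}.yaml")
        save_fq_parameters(path, table)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind '{kind}' (choose from {_KINDS})")
    return written
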