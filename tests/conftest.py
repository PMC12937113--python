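import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # expose tests/_oracles.py

from dmrgfq import (  # noqa: E402
    FQAtom,
    FQMoleculeGroup,
    FQSystem,
    QMRegion,
    toy_snapshots,
)
from dmrgfq.units import BOHR_PER_ANGSTROM  # noqa: E402

# synthetic water-like FQ parameters (Hartree-based), used across suites
WATER_FQ_PARAMS = {"O": (0.189194, 0.523700), "H": (0.012767, 0.537512)}


def make_random_fq_system(seed, n_groups=None, max_atoms=30,
                          min_separation=1.5):
    """Seeded random FQ system: up to 5 groups of 2-6 atoms each, positions
    rejected closer than ``min_separation`` Bohr (well-conditioned kernel)."""
    rng = np.random.default_rng(seed)
    if n_groups is None:
        n_groups = int(rng.integers(1, 6))
    atoms, groups = [], []
    positions = []
    k = 0
    for _ in range(n_groups):
        size = int(rng.integers(2, 7))
        if k + size > max_atoms:
            size = max(1, max_atoms - k)
        idx = []
        for _ in range(size):
            while True:
                pos = rng.uniform(-8.0, 8.0, 3)
                if all(np.linalg.norm(pos - p) > min_separation
                       for p in positions):
                    break
            positions.append(pos)
            atoms.append(FQAtom(pos, float(rng.uniform(-0.2, 0.3)),
                                float(rng.uniform(0.3, 0.9))))
            idx.append(k)
            k += 1
        groups.append(FQMoleculeGroup(idx, float(rng.choice([0.0, 0.0, 1.0, -1.0]))))
        if k >= max_atoms:
            break
    return FQSystem(atoms=atoms, groups=groups)


def make_water_environment(seed, n_solvent=3):
    """Rigid water-like FQ environment + H2-like solute from the toy
    snapshot generator; returns (solute_elements, solute_xyz_angstrom,
    FQSystem)."""
    frames, grouping = toy_snapshots(1, seed, n_solvent=n_solvent)
    elements, coords, _ = frames[0]
    atoms, groups = [], []
    k = 0
    for mol in grouping["solvent_molecules"]:
        idx = []
        for a in mol:
            chi, eta = WATER_FQ_PARAMS[elements[a]]
            atoms.append(
                FQAtom(coords[a] * BOHR_PER_ANGSTROM, chi, eta, elements[a])
            )
            idx.append(k)
            k += 1
        groups.append(FQMoleculeGroup(idx, 0.0))
    solute_el = [elements[i] for i in grouping["solute"]]
    solute_xyz = coords[grouping["solute"]]
    return solute_el, solute_xyz, FQSystem(atoms=atoms, groups=groups)


@pytest.fixture(scope="session")
def h2_region():
    return QMRegion(["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, 0.74]])


@pytest.fixture(scope="session")
def water_region():
    return QMRegion(
        ["O", "H", "H"],
        [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]],
    )
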