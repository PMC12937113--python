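"""FQ parameter files and classical-region assembly.

A parameter file is YAML mapping element labels to electronegativity chi
(Hartree/e) and hardness eta (Hartree/e^2), with a parameterization name:

    name: fq_a
    elements:
      O: {chi: 0.189194, eta: 0.523700}
      H: {chi: 0.012767, eta: 0.537512}

Published FQ parameter sets are not bundled; users transcribe them into
this format (or generate synthetic sets with the fixture generator).
"""

from __future__ import annotations

import yaml
import numpy as np

from ..units import angstrom_to_bohr
from ..io import read_xyz
from .model import FQAtom, FQMoleculeGroup, FQSystem

__all__ = [
    "load_fq_parameters",
    "save_fq_parameters",
    "fq_system_from_arrays",
    "fq_system_from_xyz",
]


def load_fq_parameters(path) -> dict:
    """Load {element -> (chi, eta)} plus the set's name from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "elements" not in raw:
        raise ValueError(f"{path}: missing 'elements' mapping")
    params = {
        el: (float(d["chi"]), float(d["eta"])) for el, d in raw["elements"].items()
    }
    return {"name": raw.get("name", "custom"), "elements": params}


def save_fq_parameters(path, params: dict) -> None:
    data = {
        "name": params.get("name", "custom"),
        "elements": {
            el: {"chi": float(c), "eta": float(e)}
            for el, (c, e) in params["elements"].items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _groups_from_spec(n_atoms, group_sizes=None, group_indices=None, total_charges=None):
    if group_indices is not None:
        groups = [list(g) for g in group_indices]
    elif group_sizes is not None:
        if isinstance(group_sizes, int):
            if n_atoms % group_sizes:
                raise ValueError(
                    f"{n_atoms} atoms not divisible into blocks of {group_sizes}"
                )
            sizes = [group_sizes] * (n_atoms // group_sizes)
        else:
            sizes = list(group_sizes)
        groups, start = [], 0
        for s in sizes:
            groups.append(list(range(start, start + s)))
            start += s
        if start != n_atoms:
            raise ValueError("group sizes do not cover all atoms")
    else:
        groups = [list(range(n_atoms))]
    if total_charges is None:
        total_charges = [0.0] * len(groups)
    return [
        FQMoleculeGroup(atom_indices=g, total_charge=float(Q))
        for g, Q in zip(groups, total_charges)
    ]


def fq_system_from_arrays(
    elements,
    coords_angstrom,
    parameters: dict,
    group_sizes=None,
    group_indices=None,
    total_charges=None,
    name: str = "",
) -> FQSystem:
    """Build an FQSystem from element labels + Å coordinates + a parameter set.

    Molecule grouping comes either from explicit index lists
    (``group_indices``) or connectivity-free fixed-size blocks
    (``group_sizes``, e.g. 3 for water).
    """
    table = parameters["elements"]
    atoms = []
    for el, xyz in zip(elements, np.asarray(coords_angstrom, dtype=float)):
        if el not in table:
            raise KeyError(f"element '{el}' missing from FQ parameter set")
        chi, eta = table[el]
        atoms.append(FQAtom(angstrom_to_bohr(xyz), chi, eta, el))
    groups = _groups_from_spec(len(atoms), group_sizes, group_indices, total_charges)
    return FQSystem(atoms=atoms, groups=groups, name=name or parameters.get("name", ""))


def fq_system_from_xyz(xyz_path, parameters, group_sizes=None, group_file=None,
                       total_charges=None) -> FQSystem:
    """Read the classical region from an XYZ file.

    ``group_file`` is an optional companion text file: one line per molecule,
    whitespace-separated 0-based atom indices, optionally ending in
    ``charge=<Q>``.
    """
    elements, coords, _ = read_xyz(xyz_path)
    group_indices = None
    if group_file is not None:
        group_indices, total_charges = [], []
        with open(group_file) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                Q = 0.0
                if parts[-1].startswith("charge="):
                    Q = float(parts[-1].split("=", 1)[1])
                    parts = parts[:-1]
                group_indices.append([int(p) for p in parts])
                total_charges.append(Q)
    return fq_system_from_arrays(
        elements, coords, parameters,
        group_sizes=group_sizes, group_indices=group_indices,
        total_charges=total_charges,
    )
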