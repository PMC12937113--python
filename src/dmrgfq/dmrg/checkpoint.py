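"""HDF5 checkpoints for MPS states and orbital sets."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .mps import MPS

__all__ = ["save_mps", "load_mps", "save_orbitals", "load_orbitals"]


def save_mps(path, mps: MPS, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("mps")
        grp.attrs["L"] = mps.L
        grp.attrs["gauge_center"] = -1 if mps.gauge_center is None else mps.gauge_center
        grp.attrs["metadata"] = json.dumps(metadata or {})
        for l, t in enumerate(mps.tensors):
            grp.create_dataset(f"site_{l:04d}", data=t)


def load_mps(path) -> tuple[MPS, dict]:
    with h5py.File(path, "r") as fh:
        grp = fh["mps"]
        L = int(grp.attrs["L"])
        gc = int(grp.attrs["gauge_center"])
        meta = json.loads(grp.attrs["metadata"])
        tensors = [np.array(grp[f"site_{l:04d}"]) for l in range(L)]
    return MPS(tensors, gauge_center=None if gc < 0 else gc), meta


def save_orbitals(path, orbital_set, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("orbitals")
        grp.create_dataset("coefficients", data=orbital_set.coefficients)
        grp.create_dataset("overlap", data=orbital_set.overlap)
        grp.attrs["inactive"] = orbital_set.inactive
        grp.attrs["active"] = orbital_set.active
        grp.attrs["virtual"] = orbital_set.virtual
        grp.attrs["metadata"] = json.dumps(metadata or {})


def load_orbitals(path):
    from ..integrals.active_space import OrbitalSet

    with h5py.File(path, "r") as fh:
        grp = fh["orbitals"]
        obs = OrbitalSet(
            coefficients=np.array(grp["coefficients"]),
            overlap=np.array(grp["overlap"]),
            inactive=list(grp.attrs["inactive"]),
            active=list(grp.attrs["active"]),
            virtual=list(grp.attrs["virtual"]),
        )
        meta = json.loads(grp.attrs["metadata"])
    return obs, meta
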