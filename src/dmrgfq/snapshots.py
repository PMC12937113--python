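"""Snapshot pipeline: droplet extraction, per-frame excitation energies,
ensemble statistics, and solvatochromic shifts.

A snapshot is one frame of a solute + explicit-solvent geometry.  The
droplet rule keeps the full solute and every solvent molecule with at least
one atom within a cutoff radius of the nearest solute atom — whole
molecules only, never fragments.  Frames are independent jobs; results are
identical regardless of execution order.

Sign convention: solvatochromic shift = solution-phase minus gas-phase
excitation energy, so a positive shift is a blue shift.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import read_multi_xyz
from .units import BOHR_PER_ANGSTROM
from .fq.model import FQAtom, FQMoleculeGroup, FQSystem
from .integrals.region import QMRegion
from .scf import DMRGFQ, DMRGFQConfig

__all__ = [
    "Snapshot",
    "EnsembleResult",
    "load_snapshots",
    "extract_droplet",
    "ensemble_statistics",
    "convergence_check",
    "solvatochromic_shift",
    "snapshot_fq_system",
    "run_snapshot",
    "run_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass
class Snapshot:
    """One solute + solvent frame (positions in Å)."""

    frame_id: int
    elements: list
    coords: np.ndarray
    solute_atom_indices: list
    solvent_molecules: list  # list of atom-index lists

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.solute_atom_indices:
            raise ValueError("solute must be non-empty")
        seen = set(self.solute_atom_indices)
        for mol in self.solvent_molecules:
            for a in mol:
                if a in seen:
                    raise ValueError(f"atom {a} assigned to two groups")
                seen.add(a)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class EnsembleResult:
    """Statistics of per-frame excitation energies (eV)."""

    per_frame_energies: list
    mean: float
    median: float
    mode: float
    standard_error: float
    spread: float
    bin_width: float = 0.05

    @property
    def n(self) -> int:
        return len(self.per_frame_energies)


def load_snapshots(xyz_path, groups_path) -> list[Snapshot]:
    """Multi-frame XYZ plus a grouping sidecar file.

    The sidecar lists the solute atom indices on the first non-comment
    line, then one solvent molecule (atom indices) per line; the same
    grouping applies to every frame.
    """
    frames = read_multi_xyz(xyz_path)
    rows = []
    with open(groups_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([int(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"no atom groups found in {groups_path}")
    solute, solvent = rows[0], rows[1:]
    return [
        Snapshot(
            frame_id=i, elements=els, coords=xyz,
            solute_atom_indices=list(solute),
            solvent_molecules=[list(m) for m in solvent],
        )
        for i, (els, xyz, _comment) in enumerate(frames)
    ]


def extract_droplet(snapshot: Snapshot, radius: float,
                    rule: str = "nearest-atom") -> Snapshot:
    """Solute-centered droplet: keep solvent molecules with any atom within
    ``radius`` (Å) of the solute; whole molecules only.

    ``rule`` selects the distance reference: "nearest-atom" (default,
    distance to the nearest solute atom) or "center-of-mass" (distance to
    the solute centroid).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if rule not in ("nearest-atom", "center-of-mass"):
        raise ValueError(f"unknown droplet rule '{rule}'")
    sol = snapshot.coords[snapshot.solute_atom_indices]
    kept_mols = []
    for mol in snapshot.solvent_molecules:
        pts = snapshot.coords[mol]
        if rule == "nearest-atom":
            dmin = np.min(
                np.linalg.norm(pts[:, None, :] - sol[None, :, :], axis=-1)
            )
        else:
            dmin = np.min(np.linalg.norm(pts - sol.mean(axis=0), axis=-1))
        if dmin <= radius:
            kept_mols.append(mol)
    if not kept_mols:
        logger.info("droplet of frame %d retains no solvent molecules",
                    snapshot.frame_id)
    keep = list(snapshot.solute_atom_indices) + [a for m in kept_mols for a in m]
    remap = {old: new for new, old in enumerate(keep)}
    return Snapshot(
        frame_id=snapshot.frame_id,
        elements=[snapshot.elements[a] for a in keep],
        coords=snapshot.coords[keep],
        solute_atom_indices=[remap[a] for a in snapshot.solute_atom_indices],
        solvent_molecules=[[remap[a] for a in m] for m in kept_mols],
    )


def ensemble_statistics(energies, bin_width: float = 0.05) -> EnsembleResult:
    """Mean/median/mode/standard-error/spread of excitation energies (eV).

    The mode is the center of the most populated histogram bin (width
    ``bin_width``); the standard error is sample-stdev/sqrt(n) (0 for a
    single frame).
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise ValueError("need at least one energy")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = np.floor(e.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((e.max() - lo) / bin_width)) or 1)
    counts, edges = np.histogram(e, bins=nbins, range=(lo, lo + nbins * bin_width))
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    se = float(np.std(e, ddof=1) / np.sqrt(e.size)) if e.size > 1 else 0.0
    return EnsembleResult(
        per_frame_energies=e.tolist(),
        mean=float(np.mean(e)),
        median=float(np.median(e)),
        mode=float(mode),
        standard_error=se,
        spread=float(e.max() - e.min()),
        bin_width=bin_width,
    )


def convergence_check(energies, checkpoints=(50, 100, 150, 200),
                      threshold: float = 0.02) -> dict:
    """Running means at snapshot-count checkpoints.

    Returns {"checkpoints": [...], "means": [...], "converged": bool};
    converged when every pair of successive checkpoint means differs by
    less than ``threshold`` (eV).  Checkpoints beyond the sample size are
    truncated with a warning entry.
    """
    e = np.asarray(list(energies), dtype=float)
    used, means, truncated = [], [], False
    for c in checkpoints:
        if c > e.size:
            truncated = True
            c = e.size
        if c == 0 or (used and c == used[-1]):
            continue
        used.append(int(c))
        means.append(float(np.mean(e[:c])))
    diffs = [abs(b - a) for a, b in zip(means, means[1:])]
    converged = bool(diffs) and all(d < threshold for d in diffs)
    if len(means) == 1:
        converged = True
    return {
        "checkpoints": used,
        "means": means,
        "successive_differences": diffs,
        "converged": converged,
        "truncated": truncated,
    }


def solvatochromic_shift(mean_solution: float, gas_reference: float) -> float:
    """Shift (eV) = solution-phase minus gas-phase excitation energy;
    positive values are blue shifts."""
    if not (np.isfinite(mean_solution) and np.isfinite(gas_reference)):
        raise ValueError("inputs must be finite")
    return float(mean_solution - gas_reference)


def snapshot_fq_system(snapshot: Snapshot, parameters: dict) -> FQSystem:
    """FQ environment from a snapshot's solvent molecules.

    ``parameters`` maps element -> (chi, eta) [Hartree-based units], either
    directly or wrapped as {"name": ..., "elements": {...}} as produced by
    the FQ parameter-file reader.  Solvent molecules are neutral groups.
    """
    table = parameters.get("elements", parameters)
    atoms, groups = [], []
    k = 0
    for mol in snapshot.solvent_molecules:
        idx = []
        for a in mol:
            el = snapshot.elements[a]
            if el not in table:
                raise KeyError(f"no FQ parameters for element '{el}'")
            chi, eta = table[el]
            atoms.append(
                FQAtom(snapshot.coords[a] * BOHR_PER_ANGSTROM, chi, eta, el)
            )
            idx.append(k)
            k += 1
        groups.append(FQMoleculeGroup(idx, 0.0))
    return FQSystem(atoms=atoms, groups=groups)


def run_snapshot(
    snapshot: Snapshot,
    fq_parameters: dict | None,
    config: DMRGFQConfig,
    basis: str = "sto-3g",
    radius: float | None = None,
) -> dict:
    """Excitation energy of one frame: droplet -> QM solute + FQ solvent ->
    state-specific GS/ES -> gap (eV)."""
    if radius is not None:
        snapshot = extract_droplet(snapshot, radius)
    qm = QMRegion(
        [snapshot.elements[a] for a in snapshot.solute_atom_indices],
        snapshot.coords[snapshot.solute_atom_indices],
        basis=basis,
    )
    fq = None
    if fq_parameters is not None and snapshot.solvent_molecules:
        fq = snapshot_fq_system(snapshot, fq_parameters)
    cfg = config if fq is not None else replace(config, embedding="none")
    result = DMRGFQ(qm, fq_system=fq, config=cfg).fit(states=("gs", "es"))
    return {
        "frame_id": snapshot.frame_id,
        "excitation_energy_ev": result.excitation_energy_ev,
        "root_flip": result.root_flip,
        "energy_gs": result.states["gs"].energy_total,
        "energy_es": result.states["es"].energy_total,
        "converged": all(st.converged for st in result.states.values()),
        "n_solvent_molecules": len(snapshot.solvent_molecules),
    }


def run_ensemble(
    snapshots,
    fq_parameters: dict | None,
    config: DMRGFQConfig,
    basis: str = "sto-3g",
    radius: float | None = None,
    bin_width: float = 0.05,
    csv_path=None,
    json_path=None,
) -> tuple[EnsembleResult, list]:
    """Per-frame excitation energies for an ensemble plus statistics.

    Optionally writes a CSV of per-frame records and a JSON ensemble
    summary.  Frames are processed independently (order-invariant results).
    """
    records = [
        run_snapshot(s, fq_parameters, config, basis=basis, radius=radius)
        for s in snapshots
    ]
    stats = ensemble_statistics(
        [r["excitation_energy_ev"] for r in records], bin_width=bin_width
    )
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
            writer.writeheader()
            writer.writerows(records)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "n_frames": stats.n,
                    "mean": stats.mean,
                    "median": stats.median,
                    "mode": stats.mode,
                    "standard_error": stats.standard_error,
                    "spread": stats.spread,
                    "bin_width": stats.bin_width,
                    "per_frame": records,
                },
                fh, indent=2,
            )
    return stats, records
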