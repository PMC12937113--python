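"""Self-consistent coupling of a DMRG active-space wave function, CASSCF
orbital optimization, and a fluctuating-charge (FQ) polarizable environment.

The total energy functional is

    E_total = E_DMRG + E_FQ + E_int,
    E_DMRG  = <Psi|H|Psi>  (bare Hamiltonian expectation + core),
    E_FQ    = q.chi + 1/2 q^T T q,
    E_int   = sum_i q_i V_i(D),

with V_i(D) the quantum-region electrostatic potential at classical site i.
A macro-iteration updates, in order: the MPS against the charge-dressed
effective Hamiltonian, the orbitals against the Brillouin gradient (with the
charges folded into the one-electron integrals), and the charges against
the electronegativity-equalization system driven by V(D).  At convergence
the energy is stationary in all three sets of variables.

Excited states are state-specific: the first excited singlet gets its own
orbitals and charges, initialized from the converged ground state; at each
effective Hamiltonian the ground state is re-solved and projected out, and
a spin penalty pins the singlet.  Energies are always assembled from
density matrices with the physical integrals, so the sector/spin penalty
operators never bias reported numbers.

Top-level entry points follow a model/fit/results pattern: build a
:class:`DMRGFQ` model, call ``fit()``, inspect a :class:`DMRGFQResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .units import EV_PER_HARTREE
from .integrals.active_space import (
    ActiveESP,
    OrbitalSet,
    transform_to_active,
)
from .integrals.esp import electronic_esp_matrices
from .integrals.region import QMRegion
from .dmrg import (
    MPS,
    build_mpo,
    compute_rdms,
    exchange_weights,
    fiedler_order,
    optimize_mps,
    permute_integrals,
    s2_mpo,
    sector_penalty_mpo,
)
from .fq.model import FQSystem, fq_energy, solve_fq
from .orbitals import optimize_orbitals

__all__ = [
    "DMRGFQConfig",
    "CouplingState",
    "DMRGFQ",
    "DMRGFQResults",
    "run_dmrgscf_fq",
    "excitation_energy",
]


@dataclass
class DMRGFQConfig:
    """Run parameters for a DMRG/FQ calculation.

    ``bond_schedule`` is a warm-up ladder [(M1, n1), (M2, n2), ...]: each
    stage runs up to n sweeps at bond dimension M, chaining the MPS.
    """

    n_active_electrons: int
    n_active_orbitals: int
    n_inactive: int = 0
    bond_schedule: list = field(default_factory=lambda: [(32, 20)])
    spin_projection: int = 0
    target_singlet: bool = True
    tol_energy: float = 1e-8
    tol_charges: float = 1e-6
    max_macro: int = 50
    orbital_tol: float = 1e-6
    orbital_max_macro: int = 60
    orbital_trust_radius: float = 0.25
    sweep_tol: float = 1e-10
    penalty_mu: float = 10.0
    embedding: str = "polarizable"  # polarizable | frozen | none
    damping: float = 1.0  # charge mixing q <- (1-a) q_old + a q_new
    charge_update_first: bool = False
    orbital_ordering: str = "none"  # none | fiedler
    seed: int = 7

    def __post_init__(self):
        if self.embedding not in ("polarizable", "frozen", "none"):
            raise ValueError(f"unknown embedding mode '{self.embedding}'")
        if self.orbital_ordering not in ("none", "fiedler"):
            raise ValueError(f"unknown ordering '{self.orbital_ordering}'")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")


@dataclass
class CouplingState:
    """Converged (or best-effort) state of one DMRG/FQ calculation."""

    state_label: str
    density: object
    charges: np.ndarray
    multipliers: np.ndarray
    orbitals: OrbitalSet
    mps: MPS
    energy_dmrg: float
    energy_fq: float
    energy_interaction: float
    energy_total: float
    convergence_trace: list
    converged: bool
    n_macro: int
    damping_engaged: bool = False
    orbital_gradient_norm: float = float("nan")
    active_integrals: object = None
    esp: ActiveESP | None = None

    def energy_decomposition_error(self) -> float:
        return abs(
            self.energy_total
            - (self.energy_dmrg + self.energy_fq + self.energy_interaction)
        )


class _ActiveSolver:
    """Warm-started DMRG solve of the current active-space Hamiltonian.

    Always applies a particle/spin-projection sector penalty; optionally a
    mu*S^2 spin penalty pinning singlets.  ``excited=True`` re-solves the
    ground state of the same Hamiltonian and returns the lowest state
    orthogonal to it (state-specific second root).
    """

    def __init__(self, config: DMRGFQConfig, excited: bool = False):
        self.cfg = config
        self.excited = excited
        self.rng = np.random.default_rng(config.seed)
        self._warm = {}  # role -> MPS
        self._penalty = None
        self.last_sweep_trace = []

    def _penalty_mpo(self, asi):
        if self._penalty is None:
            L = asi.n_orbitals_active
            pen = sector_penalty_mpo(
                L, asi.n_electrons_active, asi.spin_projection,
                self.cfg.penalty_mu,
            )
            if self.cfg.target_singlet and L > 1:
                pen = (pen + s2_mpo(L).scaled(self.cfg.penalty_mu)).compress()
            self._penalty = pen
        return self._penalty

    def _initial(self, role, asi, max_bond):
        mps = self._warm.get(role)
        if mps is None:
            mps = MPS.random_sector(
                asi.n_orbitals_active, asi.n_electrons_active,
                asi.spin_projection, max_bond, self.rng,
            )
        return mps

    def _run(self, role, H, asi, orthogonal_to=()):
        cfg = self.cfg
        pen = self._penalty_mpo(asi)
        mps = self._initial(role, asi, cfg.bond_schedule[0][0])
        res = None
        for M, n_sweeps in cfg.bond_schedule:
            res = optimize_mps(
                H, mps, max_bond=M, n_sweeps=n_sweeps, tol=cfg.sweep_tol,
                orthogonal_to=list(orthogonal_to), penalty_mpo=pen,
            )
            mps = res.mps
        self._warm[role] = mps
        self.last_sweep_trace = res.trace if res is not None else []
        return mps

    def __call__(self, asi):
        """solve_active callback: returns (energy, DensityMatrices) of the
        targeted state, with energies assembled from the physical
        integrals."""
        order = None
        work = asi
        if self.cfg.orbital_ordering == "fiedler" and asi.n_orbitals_active > 2:
            order = fiedler_order(asi, weights=exchange_weights(asi))
            work = permute_integrals(asi, order)
        H = build_mpo(work)
        gs = self._run("gs", H, work)
        if self.excited:
            target = self._run("es", H, work, orthogonal_to=[gs])
        else:
            target = gs
        dm = compute_rdms(target)
        if order is not None:
            inv = np.argsort(order)
            from .dmrg.rdm import DensityMatrices

            dm = DensityMatrices(
                one_particle=dm.one_particle[np.ix_(inv, inv)],
                two_particle=dm.two_particle[np.ix_(inv, inv, inv, inv)],
            )
        self.mps = target
        return dm.energy(asi), dm


def _embedding_arrays(esp_op, charges):
    """(AO one-electron term, scalar) for fixed charges:
    -sum_i q_i V^FQ_i  and  sum_i q_i V_i^nuc."""
    oei = -np.einsum("i,ipq->pq", charges, esp_op.electronic_matrices_ao)
    scalar = float(charges @ esp_op.nuclear_potential)
    return oei, scalar


def run_dmrgscf_fq(
    qm: QMRegion,
    fq_system: FQSystem | None,
    config: DMRGFQConfig,
    state: str = "gs",
    initial_orbitals: OrbitalSet | None = None,
    initial_charges: np.ndarray | None = None,
    log=None,
) -> CouplingState:
    """One state-specific DMRG/FQ macro-iteration loop.

    Steps: starting orbitals (RHF unless provided) -> initial MPS and
    densities on the bare Hamiltonian -> initial charges from V(D) ->
    iterate {MPS update with the charge-dressed Hamiltonian; orbital
    update; charge update} until |dE_total| < tol_energy and
    max|dq| < tol_charges.  Oscillating energies engage charge damping.
    """
    cfg = config
    logf = log if log is not None else (lambda msg: None)
    embedding = cfg.embedding if fq_system is not None else "none"
    solver = _ActiveSolver(cfg, excited=(state == "es"))
    n_act_el = cfg.n_active_electrons

    esp_op = None
    if embedding != "none":
        esp_op = electronic_esp_matrices(
            qm.basis, fq_system.positions, nuclei=qm.nuclei
        )
        fq_system.ensure_kernel()

    # step 1: starting orbitals
    if initial_orbitals is None:
        emb = (None, 0.0)
        if embedding != "none" and initial_charges is not None:
            emb = _embedding_arrays(esp_op, initial_charges)
        _, C, _ = qm.rhf(embedding_oei=emb[0], embedding_scalar=emb[1])
        orbs = qm.orbital_set(C, cfg.n_inactive, cfg.n_active_orbitals)
    else:
        orbs = initial_orbitals

    def orbital_cycle(charges):
        """MPS + orbital update at fixed charges; returns optimization
        result with converged densities and integrals."""
        if embedding == "none" or charges is None:
            oei, scalar = None, 0.0
        else:
            oei, scalar = _embedding_arrays(esp_op, charges)
        return optimize_orbitals(
            qm, orbs, n_act_el, solver,
            embedding_oei=oei, embedding_scalar=scalar,
            max_macro=cfg.orbital_max_macro, tol=cfg.orbital_tol,
            trust_radius=cfg.orbital_trust_radius,
        )

    def assemble(dm, orbs_now, charges):
        """(E_dmrg, E_fq, E_int, E_total) from the state-specific density."""
        asi_gas = transform_to_active(
            qm.hcore, qm.eri, orbs_now, n_act_el,
            nuclear_repulsion=qm.nuclear_repulsion,
        )
        e_dmrg = dm.energy(asi_gas)
        if embedding == "none" or charges is None:
            return e_dmrg, 0.0, 0.0, e_dmrg, asi_gas, None
        esp_act = esp_op.to_active(orbs_now)
        v = esp_act.potential_of_density(dm.one_particle)
        e_int = float(charges @ v)
        e_fq = fq_energy(charges, fq_system.chi, fq_system.kernel)
        return e_dmrg, e_fq, e_int, e_dmrg + e_fq + e_int, asi_gas, esp_act

    # gas phase / frozen: a single orbital cycle at fixed charges
    if embedding in ("none", "frozen"):
        charges = None
        multipliers = np.zeros(0)
        if embedding == "frozen":
            if initial_charges is not None:
                charges = np.asarray(initial_charges, dtype=float)
                multipliers = np.zeros(len(fq_system.groups))
            else:
                charges, multipliers = solve_fq(fq_system)
        res = orbital_cycle(charges)
        dm = res.density
        e_dmrg, e_fq, e_int, e_tot, asi_gas, esp_act = assemble(
            dm, res.orbital_set, charges
        )
        logf(f"[{state}] single-cycle ({embedding}): E_total={e_tot:.12f} "
             f"grad={res.gradient_norm:.2e}")
        return CouplingState(
            state_label=state, density=dm,
            charges=(np.zeros(0) if charges is None else charges),
            multipliers=multipliers, orbitals=res.orbital_set,
            mps=solver.mps, energy_dmrg=e_dmrg, energy_fq=e_fq,
            energy_interaction=e_int, energy_total=e_tot,
            convergence_trace=[{"macro": 1, "energy_total": e_tot,
                                "gradient_norm": res.gradient_norm}],
            converged=res.converged, n_macro=1,
            orbital_gradient_norm=res.gradient_norm,
            active_integrals=asi_gas, esp=esp_act,
        )

    # polarizable loop
    charges = None
    if initial_charges is not None:
        charges = np.asarray(initial_charges, dtype=float)
        multipliers = np.zeros(len(fq_system.groups))
    else:
        # steps 2-3: bare-Hamiltonian densities seed the first charges
        asi0 = transform_to_active(
            qm.hcore, qm.eri, orbs, n_act_el,
            nuclear_repulsion=qm.nuclear_repulsion,
        )
        _, dm0 = solver(asi0)
        esp_act0 = esp_op.to_active(orbs)
        v0 = esp_act0.potential_of_density(dm0.one_particle)
        charges, multipliers = solve_fq(fq_system, external_potential=v0)
        logf(f"[{state}] initial charges from bare densities: "
             f"max|q|={np.max(np.abs(charges)):.4f}")

    trace = []
    e_prev = None
    alpha = cfg.damping
    damping_engaged = alpha < 1.0
    converged = False
    n_increases = 0
    dm = None
    res = None
    for macro in range(1, cfg.max_macro + 1):
        if cfg.charge_update_first and dm is not None:
            esp_act = esp_op.to_active(orbs)
            v = esp_act.potential_of_density(dm.one_particle)
            q_new, multipliers = solve_fq(fq_system, external_potential=v)
            charges = (1 - alpha) * charges + alpha * q_new

        # steps: MPS update with H_eff(q), orbital update at fixed q
        res = orbital_cycle(charges)
        orbs = res.orbital_set
        dm = res.density

        # charge update from the new density
        esp_act = esp_op.to_active(orbs)
        v = esp_act.potential_of_density(dm.one_particle)
        q_new, multipliers = solve_fq(fq_system, external_potential=v)
        dq = float(np.max(np.abs(q_new - charges)))
        charges = (1 - alpha) * charges + alpha * q_new

        e_dmrg, e_fq, e_int, e_tot, asi_gas, esp_act = assemble(
            dm, orbs, charges
        )
        trace.append({
            "macro": macro, "energy_total": e_tot, "energy_dmrg": e_dmrg,
            "energy_fq": e_fq, "energy_interaction": e_int,
            "max_charge_change": dq, "gradient_norm": res.gradient_norm,
        })
        logf(f"[{state}] macro {macro}: E_total={e_tot:.12f} "
             f"max|dq|={dq:.2e} grad={res.gradient_norm:.2e}")
        if e_prev is not None:
            if e_tot > e_prev + 1e-12:
                n_increases += 1
                if n_increases >= 2 and alpha > 0.45:
                    alpha = 0.5
                    damping_engaged = True
                    logf(f"[{state}] oscillation detected -> damping 0.5")
            if abs(e_tot - e_prev) < cfg.tol_energy and dq < cfg.tol_charges:
                converged = True
                e_prev = e_tot
                break
        e_prev = e_tot

    if not converged:
        warnings.warn(
            f"DMRG/FQ macro-iteration limit reached for state '{state}' "
            f"({cfg.max_macro} iterations); returning best-effort result"
        )
    e_dmrg, e_fq, e_int, e_tot, asi_gas, esp_act = assemble(dm, orbs, charges)
    return CouplingState(
        state_label=state, density=dm, charges=charges,
        multipliers=multipliers, orbitals=orbs, mps=solver.mps,
        energy_dmrg=e_dmrg, energy_fq=e_fq, energy_interaction=e_int,
        energy_total=e_tot, convergence_trace=trace, converged=converged,
        n_macro=len(trace), damping_engaged=damping_engaged,
        orbital_gradient_norm=res.gradient_norm,
        active_integrals=asi_gas, esp=esp_act,
    )


def excitation_energy(gs: CouplingState, es: CouplingState) -> float:
    """Vertical excitation energy (eV) between two converged states.

    Negative gaps indicate a root flip (the targeted excited state fell
    below the ground state) and are flagged with a warning.
    """
    if not (gs.converged and es.converged):
        raise ValueError("both states must be converged")
    gap = (es.energy_total - gs.energy_total) * EV_PER_HARTREE
    if gap < 0.0:
        warnings.warn(
            f"negative excitation energy {gap:.6f} eV: root flip between "
            "state-specific solutions"
        )
    return float(gap)


class DMRGFQResults:
    """Fitted DMRG/FQ model: per-state results and the excitation energy."""

    def __init__(self, model: "DMRGFQ", states: dict):
        self.model = model
        self.states = states
        self.excitation_energy_ev = None
        self.root_flip = False
        if "gs" in states and "es" in states:
            with warnings.catch_warnings(record=True) as rec:
                warnings.simplefilter("always")
                self.excitation_energy_ev = excitation_energy(
                    states["gs"], states["es"]
                )
                self.root_flip = any("root flip" in str(w.message) for w in rec)
            if self.root_flip:
                warnings.warn(
                    f"root flip: excitation energy "
                    f"{self.excitation_energy_ev:.6f} eV is negative"
                )

    def summary(self) -> str:
        lines = ["DMRG/FQ results", "=" * 64]
        for label, st in self.states.items():
            lines.append(
                f"state {label:>3}: E_total = {st.energy_total:+.10f} Ha  "
                f"(dmrg {st.energy_dmrg:+.10f}, fq {st.energy_fq:+.10f}, "
                f"int {st.energy_interaction:+.10f})"
            )
            lines.append(
                f"           macro iterations: {st.n_macro}, converged: "
                f"{st.converged}, |orbital gradient| = "
                f"{st.orbital_gradient_norm:.2e}"
            )
            if st.charges.size:
                lines.append(
                    f"           charges: n={st.charges.size}, "
                    f"sum={np.sum(st.charges):+.6f}, "
                    f"max|q|={np.max(np.abs(st.charges)):.6f}"
                )
        if self.excitation_energy_ev is not None:
            lines.append("-" * 64)
            lines.append(
                f"excitation energy: {self.excitation_energy_ev:.6f} eV"
                + ("  [ROOT FLIP]" if self.root_flip else "")
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"excitation_energy_ev": self.excitation_energy_ev,
               "root_flip": self.root_flip, "states": {}}
        for label, st in self.states.items():
            out["states"][label] = {
                "energy_total": st.energy_total,
                "energy_dmrg": st.energy_dmrg,
                "energy_fq": st.energy_fq,
                "energy_interaction": st.energy_interaction,
                "converged": st.converged,
                "n_macro": st.n_macro,
                "damping_engaged": st.damping_engaged,
                "orbital_gradient_norm": st.orbital_gradient_norm,
                "charges": st.charges.tolist(),
                "convergence_trace": st.convergence_trace,
            }
        return out

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_checkpoints(self, prefix) -> None:
        from .dmrg.checkpoint import save_mps, save_orbitals

        for label, st in self.states.items():
            save_mps(f"{prefix}_{label}_mps.h5", st.mps,
                     metadata={"state": label})
            save_orbitals(f"{prefix}_{label}_orbitals.h5", st.orbitals,
                          metadata={"state": label})


class DMRGFQ:
    """DMRG/FQ model: a quantum region, an optional FQ environment, and a
    run configuration.  ``fit()`` runs the state-specific calculations."""

    def __init__(self, qm: QMRegion, fq_system: FQSystem | None = None,
                 config: DMRGFQConfig | None = None, **overrides):
        if config is None:
            if "n_active_electrons" not in overrides or \
                    "n_active_orbitals" not in overrides:
                raise ValueError(
                    "provide a DMRGFQConfig or n_active_electrons/"
                    "n_active_orbitals keyword arguments"
                )
            config = DMRGFQConfig(**overrides)
        elif overrides:
            config = DMRGFQConfig(**{**asdict(config), **overrides})
        self.qm = qm
        self.fq_system = fq_system
        self.config = config
        self.log_lines: list[str] = []

    def _log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def fit(self, states=("gs", "es")) -> DMRGFQResults:
        results = {}
        gs = None
        for label in states:
            if label == "gs":
                gs = run_dmrgscf_fq(
                    self.qm, self.fq_system, self.config, state="gs",
                    log=self._log,
                )
                results["gs"] = gs
            elif label == "es":
                kwargs = {}
                if gs is not None:
                    kwargs = {
                        "initial_orbitals": gs.orbitals,
                        "initial_charges":
                            gs.charges if gs.charges.size else None,
                    }
                results["es"] = run_dmrgscf_fq(
                    self.qm, self.fq_system, self.config, state="es",
                    log=self._log, **kwargs,
                )
            else:
                raise ValueError(f"unknown state label '{label}'")
        return DMRGFQResults(self, results)

    def save_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
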