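"""DMRG/FQ coupling: state-specific energies, stationarity, embedding
limits, and the model/fit/results interface."""

import numpy as np
import pytest

from dmrgfq import (
    DMRGFQ,
    DMRGFQConfig,
    FQAtom,
    FQMoleculeGroup,
    FQSystem,
    QMRegion,
    excitation_energy,
    fq_energy,
    h2like_integrals,
    run_dmrgscf_fq,
    solve_fq,
)
from dmrgfq.units import EV_PER_HARTREE

from conftest import make_water_environment
from _oracles import fci_singlet_energies


H2_CFG = dict(n_active_electrons=2, n_active_orbitals=2, bond_schedule=[(8, 20)])


@pytest.fixture(scope="module")
def gas_result(h2_region):
    cfg = DMRGFQConfig(embedding="none", **H2_CFG)
    return DMRGFQ(h2_region, config=cfg).fit(states=("gs", "es"))


@pytest.fixture(scope="module")
def solvated():
    sol_el, sol_xyz, fq = make_water_environment(5)
    region = QMRegion(sol_el, sol_xyz)
    cfg = DMRGFQConfig(**H2_CFG)
    res = DMRGFQ(region, fq_system=fq, config=cfg).fit(states=("gs", "es"))
    return region, fq, cfg, res


def test_gas_phase_singlet_energies_match_fci(gas_result):
    w = fci_singlet_energies(h2like_integrals(0.74), n_states=2)
    assert gas_result.states["gs"].energy_total == pytest.approx(w[0], abs=1e-9)
    assert gas_result.states["es"].energy_total == pytest.approx(w[1], abs=1e-9)


def test_gas_phase_gap_matches_fci(gas_result):
    w = fci_singlet_energies(h2like_integrals(0.74), n_states=2)
    fci_gap_ev = (w[1] - w[0]) * EV_PER_HARTREE
    assert gas_result.excitation_energy_ev == pytest.approx(fci_gap_ev,
                                                            abs=1e-7)
    assert not gas_result.root_flip


def test_energy_decomposition_invariant(solvated):
    _, _, _, res = solvated
    for st in res.states.values():
        assert st.energy_decomposition_error() < 1e-10


def test_group_charges_conserved(solvated):
    _, fq, _, res = solvated
    for st in res.states.values():
        for g in fq.groups:
            assert np.sum(st.charges[g.atom_indices]) == pytest.approx(
                g.total_charge, abs=1e-9
            )


def test_charge_stationarity(solvated):
    # at convergence, feasible charge perturbations change E only at
    # second order
    _, fq, _, res = solvated
    st = res.states["gs"]
    v = st.esp.potential_of_density(st.density.one_particle)

    def total(q):
        return st.energy_dmrg + float(q @ v) + fq_energy(q, fq.chi, fq.kernel)

    eps = 1e-4
    for (i, j) in [(0, 1), (1, 2), (3, 5), (6, 7)]:
        dq = np.zeros(len(st.charges))
        dq[i], dq[j] = eps, -eps
        first_order = abs(total(st.charges + dq) - total(st.charges - dq)) / 2
        assert first_order < 1e-7


def test_state_specific_charges_differ_and_cross_assembly(solvated):
    _, fq, _, res = solvated
    gs, es = res.states["gs"], res.states["es"]
    assert np.max(np.abs(gs.charges - es.charges)) > 1e-6

    def total(st, q):
        v = st.esp.potential_of_density(st.density.one_particle)
        return st.energy_dmrg + float(q @ v) + fq_energy(q, fq.chi, fq.kernel)

    # swapping the converged charge vectors never lowers either state
    assert total(gs, es.charges) >= gs.energy_total - 1e-12
    assert total(es, gs.charges) >= es.energy_total - 1e-12


def test_convergence_trace_monotone(solvated):
    _, _, _, res = solvated
    for st in res.states.values():
        energies = [rec["energy_total"] for rec in st.convergence_trace]
        for a, b in zip(energies[1:], energies[2:]):
            assert b <= a + 1e-9


def test_gas_limit(h2_region):
    sol_el, sol_xyz, fq = make_water_environment(5)
    region = QMRegion(sol_el, sol_xyz)
    cfg = DMRGFQConfig(**H2_CFG)
    far = fq.translated([1e4, 0.0, 0.0])
    st_far = run_dmrgscf_fq(region, far, cfg, state="gs")
    st_gas = run_dmrgscf_fq(
        region, None, DMRGFQConfig(embedding="none", **H2_CFG), state="gs"
    )
    iso = FQSystem(atoms=far.atoms, groups=far.groups)
    q_iso, _ = solve_fq(iso)
    e_fq_iso = fq_energy(q_iso, iso.chi, iso.kernel)
    assert st_far.energy_total - e_fq_iso == pytest.approx(
        st_gas.energy_total, abs=1e-8
    )
    assert np.max(np.abs(st_far.charges - q_iso)) < 1e-8


def test_translation_invariance():
    sol_el, sol_xyz, fq = make_water_environment(9)
    shift_ang = np.array([3.1, -2.2, 1.7])
    cfg = DMRGFQConfig(**H2_CFG)
    st1 = run_dmrgscf_fq(QMRegion(sol_el, sol_xyz), fq, cfg, state="gs")
    st2 = run_dmrgscf_fq(
        QMRegion(sol_el, sol_xyz + shift_ang),
        fq.translated(shift_ang * 1.8897261254578281),
        cfg, state="gs",
    )
    assert st2.energy_total == pytest.approx(st1.energy_total, abs=1e-9)


def test_frozen_mode_equals_static_folding(solvated):
    region, fq, cfg, res = solvated
    from dataclasses import replace

    frozen_cfg = replace(cfg, embedding="frozen")
    st = run_dmrgscf_fq(region, fq, frozen_cfg, state="gs",
                        initial_charges=res.states["gs"].charges)
    assert st.energy_total == pytest.approx(
        res.states["gs"].energy_total, abs=1e-9
    )


def test_polarizable_no_higher_than_frozen_initial_charges(solvated):
    # relaxing the charges variationally can only lower the total energy
    # relative to freezing them at the classical-only solution
    region, fq, cfg, res = solvated
    q0, _ = solve_fq(FQSystem(atoms=fq.atoms, groups=fq.groups))
    from dataclasses import replace

    st_frozen = run_dmrgscf_fq(region, fq, replace(cfg, embedding="frozen"),
                               state="gs", initial_charges=q0)
    assert res.states["gs"].energy_total <= st_frozen.energy_total + 1e-10


def test_excitation_energy_requires_convergence(gas_result):
    from dataclasses import replace

    broken = replace(gas_result.states["es"], converged=False)
    with pytest.raises(ValueError, match="converged"):
        excitation_energy(gas_result.states["gs"], broken)


def test_excitation_energy_identical_states_zero(gas_result):
    gs = gas_result.states["gs"]
    assert excitation_energy(gs, gs) == 0.0


def test_root_flip_flagged(gas_result):
    import warnings

    gs, es = gas_result.states["gs"], gas_result.states["es"]
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        val = excitation_energy(es, gs)  # deliberately swapped
    assert val < 0
    assert any("root flip" in str(w.message) for w in rec)


def test_results_summary_and_json(tmp_path, gas_result):
    text = gas_result.summary()
    assert "excitation energy" in text
    assert "E_total" in text
    path = tmp_path / "out.json"
    gas_result.save_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["states"]["gs"]["converged"]
    assert data["excitation_energy_ev"] == pytest.approx(
        gas_result.excitation_energy_ev
    )


def test_config_validation():
    with pytest.raises(ValueError, match="embedding"):
        DMRGFQConfig(n_active_electrons=2, n_active_orbitals=2,
                     embedding="bogus")
    with pytest.raises(ValueError, match="damping"):
        DMRGFQConfig(n_active_electrons=2, n_active_orbitals=2, damping=0.0)


def test_model_requires_active_space(h2_region):
    with pytest.raises(ValueError, match="n_active"):
        DMRGFQ(h2_region)
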