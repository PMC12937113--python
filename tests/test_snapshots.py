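"""Snapshot pipeline: droplet extraction, ensemble statistics, shifts,
fixture determinism, and the end-to-end toy ensemble."""

import filecmp
import os

import numpy as np
import pytest

from dmrgfq import (
    DMRGFQConfig,
    EnsembleResult,
    Snapshot,
    convergence_check,
    ensemble_statistics,
    extract_droplet,
    generate_fixtures,
    load_snapshots,
    run_ensemble,
    solvatochromic_shift,
    toy_snapshots,
)

from conftest import WATER_FQ_PARAMS


def _constructed_snapshot(distances=(5.0, 14.0, 16.0)):
    """H2 solute at origin + water-like triatomics at given minimum
    distances along x."""
    elements = ["H", "H"]
    coords = [[0.0, 0.0, -0.37], [0.0, 0.0, 0.37]]
    solvent = []
    k = 2
    for d in distances:
        mol = [k, k + 1, k + 2]
        # nearest atom exactly at distance d from the solute atom line
        coords.extend([[d, 0.0, 0.37], [d + 0.8, 0.5, 0.37],
                       [d + 0.8, -0.5, 0.37]])
        elements.extend(["O", "H", "H"])
        solvent.append(mol)
        k += 3
    return Snapshot(frame_id=0, elements=elements, coords=np.array(coords),
                    solute_atom_indices=[0, 1], solvent_molecules=solvent)


def test_droplet_radius_15_keeps_two():
    snap = _constructed_snapshot((5.0, 14.0, 16.0))
    drop = extract_droplet(snap, 15.0)
    assert len(drop.solvent_molecules) == 2
    assert len(drop.elements) == 2 + 6


def test_droplet_huge_radius_keeps_all():
    snap = _constructed_snapshot()
    drop = extract_droplet(snap, 1e6)
    assert len(drop.solvent_molecules) == 3


def test_droplet_straddling_molecule_fully_retained():
    # one atom inside the radius, two outside: whole molecule kept
    snap = _constructed_snapshot((9.9,))
    drop = extract_droplet(snap, 10.0)
    assert len(drop.solvent_molecules) == 1
    assert drop.coords.shape == (5, 3)


def test_droplet_idempotent():
    snap = _constructed_snapshot()
    once = extract_droplet(snap, 15.0)
    twice = extract_droplet(once, 15.0)
    assert twice.elements == once.elements
    assert np.array_equal(twice.coords, once.coords)
    assert twice.solvent_molecules == once.solvent_molecules


def test_droplet_empty_solvent_allowed():
    snap = _constructed_snapshot((20.0,))
    drop = extract_droplet(snap, 5.0)
    assert drop.solvent_molecules == []
    assert drop.solute_atom_indices == [0, 1]


def test_droplet_validation():
    snap = _constructed_snapshot()
    with pytest.raises(ValueError, match="radius"):
        extract_droplet(snap, -1.0)
    with pytest.raises(ValueError, match="rule"):
        extract_droplet(snap, 5.0, rule="bogus")


def test_snapshot_disjoint_groups_enforced():
    with pytest.raises(ValueError, match="two groups"):
        Snapshot(frame_id=0, elements=["H", "H", "O"],
                 coords=np.zeros((3, 3)), solute_atom_indices=[0, 1],
                 solvent_molecules=[[1, 2]])


def test_ensemble_statistics_single_value():
    res = ensemble_statistics([2.0])
    assert res.mean == 2.0 and res.spread == 0.0 and res.standard_error == 0.0


def test_ensemble_statistics_simple():
    res = ensemble_statistics([1.0, 2.0, 3.0])
    assert res.mean == pytest.approx(2.0)
    assert res.median == pytest.approx(2.0)
    assert res.spread == pytest.approx(2.0)


def test_ensemble_statistics_standard_error():
    rng = np.random.default_rng(123)
    sample = rng.normal(3.0, 0.2, 200)
    res = ensemble_statistics(sample)
    expected = 0.2 / np.sqrt(200)
    assert abs(res.standard_error - expected) < 0.2 * expected
    assert res.mode == pytest.approx(3.0, abs=0.15)


def test_ensemble_statistics_permutation_invariant():
    rng = np.random.default_rng(7)
    vals = rng.normal(2.0, 0.3, 50)
    a = ensemble_statistics(vals)
    b = ensemble_statistics(vals[rng.permutation(50)])
    for attr in ("mean", "median", "mode", "standard_error", "spread"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)


def test_ensemble_statistics_errors():
    with pytest.raises(ValueError):
        ensemble_statistics([])
    with pytest.raises(ValueError):
        ensemble_statistics([1.0], bin_width=0.0)


def test_convergence_check_constant():
    out = convergence_check([1.5] * 200)
    assert out["converged"]
    assert all(m == 1.5 for m in out["means"])


def test_convergence_check_alternating():
    vals = [(-1.0) ** k for k in range(200)]
    out = convergence_check(vals)
    assert abs(out["means"][-1]) < 0.01
    diffs = out["successive_differences"]
    assert all(b <= a + 1e-12 for a, b in zip(diffs, diffs[1:]))


def test_convergence_check_matches_prefix_means():
    rng = np.random.default_rng(17)
    vals = rng.normal(3.0, 0.1, 200)
    out = convergence_check(vals)
    for c, m in zip(out["checkpoints"], out["means"]):
        assert m == pytest.approx(float(np.mean(vals[:c])), abs=1e-12)


def test_convergence_check_truncation():
    out = convergence_check([1.0] * 60)
    assert out["truncated"]
    assert out["checkpoints"][-1] == 60


def test_solvatochromic_shift_red_example():
    assert solvatochromic_shift(3.32, 3.73) == pytest.approx(-0.41)


def test_solvatochromic_shift_sign_convention():
    assert solvatochromic_shift(5.0, 4.8) == pytest.approx(0.2)
    assert solvatochromic_shift(4.0, 4.0) == 0.0
    with pytest.raises(ValueError):
        solvatochromic_shift(float("nan"), 1.0)


def test_fixture_determinism(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for kind, params in (
        ("fcidump_random", {"L": 4}),
        ("toy_snapshots", {"n_frames": 2}),
        ("fq_params", None),
        ("fcidump_h2like", None),
    ):
        p1 = generate_fixtures(kind, 77, params=params, outdir=str(d1))
        p2 = generate_fixtures(kind, 77, params=params, outdir=str(d2))
        for a, b in zip(p1, p2):
            assert filecmp.cmp(a, b, shallow=False), (kind, a)


def test_fixture_unknown_kind(tmp_path):
    with pytest.raises(ValueError, match="unknown fixture kind"):
        generate_fixtures("bogus", 1, outdir=str(tmp_path))


def test_snapshot_file_round_trip(tmp_path):
    paths = generate_fixtures("toy_snapshots", 31,
                              params={"n_frames": 3}, outdir=str(tmp_path))
    xyz, groups = paths
    snaps = load_snapshots(xyz, groups)
    assert len(snaps) == 3
    frames, grouping = toy_snapshots(3, 31)
    assert snaps[0].solute_atom_indices == grouping["solute"]
    assert snaps[0].solvent_molecules == grouping["solvent_molecules"]
    assert np.max(np.abs(snaps[1].coords - frames[1][1])) < 1e-6


def test_end_to_end_toy_ensemble(tmp_path):
    """5-frame toy ensemble through the full DMRG/FQ pipeline."""
    frames, grouping = toy_snapshots(5, 3)
    snaps = [
        Snapshot(frame_id=i, elements=els, coords=xyz,
                 solute_atom_indices=grouping["solute"],
                 solvent_molecules=grouping["solvent_molecules"])
        for i, (els, xyz, _) in enumerate(frames)
    ]
    cfg = DMRGFQConfig(n_active_electrons=2, n_active_orbitals=2,
                       bond_schedule=[(8, 20)])
    csv_path, json_path = tmp_path / "e.csv", tmp_path / "e.json"
    stats, records = run_ensemble(
        snaps, WATER_FQ_PARAMS, cfg, radius=20.0,
        csv_path=csv_path, json_path=json_path,
    )
    assert isinstance(stats, EnsembleResult)
    assert stats.n == 5
    assert all(np.isfinite(r["excitation_energy_ev"]) for r in records)
    assert all(r["converged"] for r in records)
    assert all(not r["root_flip"] for r in records)
    assert stats.spread >= 0
    assert os.path.getsize(csv_path) > 0 and os.path.getsize(json_path) > 0
    # frames are independent: subset order does not matter
    stats2, _ = run_ensemble(list(reversed(snaps)), WATER_FQ_PARAMS, cfg,
                             radius=20.0)
    assert stats2.mean == pytest.approx(stats.mean, abs=1e-10)
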