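"""Shell/contact counting: boundary conventions, oracles and invariances.

The independent oracle here is a from-definition O(N*M) numpy recount
written in this file, not the package's own brute-force path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fameshell.core import AtomRecord, Frame, LabeledSystem, Role, Trajectory
from fameshell.proximity import (
    ShellParams,
    count_chain_waters,
    count_intrachain_contacts,
    count_role_contacts,
    residue_water_counts,
    series_statistics,
)
from conftest import make_random_system


# ----------------------------------------------------------------------
# from-definition oracles
# ----------------------------------------------------------------------

def _mi(d, box):
    return d - box * np.round(d / box) if box is not None else d


def oracle_chain_waters(frame, system, params):
    solute = [
        i for i, a in enumerate(system.atoms)
        if a.role in (Role.LIPIDATION_SITE, Role.ELP)
        and (params.solute_atoms == "all" or a.is_heavy)
    ]
    counted = set()
    for res in system.water_residues:
        for i in range(res.start, res.stop):
            a = system.atoms[i]
            if params.counting_atom == "water_oxygen" and a.element != "O":
                continue
            for j in solute:
                d = _mi(frame.positions[i] - frame.positions[j], frame.box)
                if float(d @ d) < params.water_cutoff**2:
                    counted.add(res.index)
                    break
            if res.index in counted:
                break
    return len(counted)


def oracle_contacts(frame, system, params):
    residues = system.peptide_residues
    pairs = 0
    for x in range(len(residues)):
        for y in range(x + params.min_sequence_separation, len(residues)):
            hit = False
            for i in range(residues[x].start, residues[x].stop):
                if not system.atoms[i].is_heavy:
                    continue
                for j in range(residues[y].start, residues[y].stop):
                    if not system.atoms[j].is_heavy:
                        continue
                    d = _mi(frame.positions[i] - frame.positions[j], frame.box)
                    if float(d @ d) < params.contact_cutoff**2:
                        hit = True
                        break
                if hit:
                    break
            pairs += hit
    return pairs


# ----------------------------------------------------------------------
# boundary and semantics
# ----------------------------------------------------------------------

def _two_atom_system(water_x: float):
    atoms = [
        AtomRecord(1, "CA", "C", 0, "GLY", Role.ELP, (0.0, 0.0, 0.0)),
        AtomRecord(2, "OW", "O", 1, "SOL", Role.WATER, (water_x, 0.0, 0.0)),
    ]
    system = LabeledSystem(atoms)
    return system, Frame(positions=system.reference_positions)


def test_no_waters_counts_zero():
    atoms = [AtomRecord(1, "CA", "C", 0, "GLY", Role.ELP, (0, 0, 0))]
    system = LabeledSystem(atoms)
    frame = Frame(positions=system.reference_positions)
    assert count_chain_waters(frame, system) == 0


def test_water_exactly_at_cutoff_not_counted():
    """The shell uses strict '<': 3.15 A exactly is outside."""
    system, frame = _two_atom_system(3.15)
    assert count_chain_waters(frame, system) == 0
    system, frame = _two_atom_system(3.1499)
    assert count_chain_waters(frame, system) == 1


def test_water_shared_between_residues_counted_for_each():
    atoms = [
        AtomRecord(1, "CA", "C", 0, "GLY", Role.ELP, (-3.0, 0.0, 0.0)),
        AtomRecord(2, "CA", "C", 1, "GLY", Role.ELP, (3.0, 0.0, 0.0)),
        AtomRecord(3, "OW", "O", 2, "SOL", Role.WATER, (0.0, 0.0, 0.0)),
    ]
    system = LabeledSystem(atoms)
    frame = Frame(positions=system.reference_positions)
    prof = residue_water_counts(frame, system)
    np.testing.assert_array_equal(prof.per_residue_counts, [1.0, 1.0])
    assert count_chain_waters(frame, system) == 1


def test_per_residue_sum_bounds_chain_count():
    rng = np.random.default_rng(0)
    for _ in range(10):
        system, frame = make_random_system(rng, 6, 40, None)
        prof = residue_water_counts(frame, system)
        assert prof.per_residue_counts.sum() >= count_chain_waters(frame, system)


def test_adjacent_residues_excluded_from_contacts():
    atoms = [
        AtomRecord(i + 1, "CA", "C", i, "GLY", Role.ELP, (i * 3.0, 0.0, 0.0))
        for i in range(4)
    ]
    system = LabeledSystem(atoms)
    frame = Frame(positions=system.reference_positions)
    # residues 0-1 at 3 A: inside 6 A but |i-j| < 3, so not counted;
    # residues 0-3 at 9 A: separated enough but outside the cutoff
    assert count_intrachain_contacts(frame, system) == 0


def test_too_few_residues_warns_and_returns_zero():
    atoms = [
        AtomRecord(i + 1, "CA", "C", i, "GLY", Role.ELP, (i * 1.0, 0, 0))
        for i in range(2)
    ]
    system = LabeledSystem(atoms)
    frame = Frame(positions=system.reference_positions)
    with pytest.warns(UserWarning):
        assert count_intrachain_contacts(frame, system) == 0


def test_lipid_excluded_from_npp_but_reachable_by_role_filter(small_construct):
    frame = Frame(positions=small_construct.reference_positions)
    npp = count_intrachain_contacts(frame, small_construct)
    lipid_pep = count_role_contacts(frame, small_construct)
    assert lipid_pep >= 1  # the acyl chain is attached at the N terminus
    assert isinstance(npp, int)


def test_missing_water_oxygen_raises():
    atoms = [
        AtomRecord(1, "CA", "C", 0, "GLY", Role.ELP, (0, 0, 0)),
        AtomRecord(2, "HW1", "H", 1, "SOL", Role.WATER, (1, 0, 0)),
    ]
    system = LabeledSystem(atoms)
    frame = Frame(positions=system.reference_positions)
    with pytest.raises(ValueError, match="oxygen"):
        count_chain_waters(frame, system)


# ----------------------------------------------------------------------
# oracle equivalence and invariances
# ----------------------------------------------------------------------

@pytest.mark.parametrize("use_box", [False, True])
def test_tree_equals_from_definition_oracle(use_box):
    rng = np.random.default_rng(42)
    params = ShellParams()
    for _ in range(20):
        box = rng.uniform(22.0, 35.0, 3) if use_box else None
        system, frame = make_random_system(
            rng, int(rng.integers(4, 10)), int(rng.integers(10, 60)), box
        )
        expected_w = oracle_chain_waters(frame, system, params)
        expected_c = oracle_contacts(frame, system, params)
        for method in ("brute", "kdtree"):
            assert count_chain_waters(frame, system, params, method) == expected_w
            assert count_intrachain_contacts(frame, system, params, method) == expected_c


def test_rigid_motion_invariance_without_box():
    rng = np.random.default_rng(7)
    system, frame = make_random_system(rng, 8, 30, None)
    params = ShellParams()
    w0 = count_chain_waters(frame, system, params)
    c0 = count_intrachain_contacts(frame, system, params)
    # random rotation + translation
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = Frame(positions=frame.positions @ q.T + rng.normal(0, 50, 3))
    assert count_chain_waters(moved, system, params) == w0
    assert count_intrachain_contacts(moved, system, params) == c0


def test_translation_invariance_modulo_box():
    rng = np.random.default_rng(8)
    box = np.array([28.0, 30.0, 26.0])
    system, frame = make_random_system(rng, 8, 30, box)
    params = ShellParams()
    w0 = count_chain_waters(frame, system, params, method="kdtree")
    c0 = count_intrachain_contacts(frame, system, params, method="kdtree")
    shift = rng.uniform(-100, 100, 3)
    moved = Frame(positions=frame.positions + shift, box=box)
    assert count_chain_waters(moved, system, params, method="kdtree") == w0
    assert count_intrachain_contacts(moved, system, params, method="kdtree") == c0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    cut_lo=st.floats(1.0, 4.0),
    cut_hi=st.floats(4.0, 8.0),
)
def test_counts_monotone_in_cutoff(seed, cut_lo, cut_hi):
    rng = np.random.default_rng(seed)
    system, frame = make_random_system(rng, 6, 25, None)
    lo = ShellParams(water_cutoff=cut_lo, contact_cutoff=cut_lo)
    hi = ShellParams(water_cutoff=cut_hi, contact_cutoff=cut_hi)
    assert count_chain_waters(frame, system, lo) <= count_chain_waters(frame, system, hi)
    assert count_intrachain_contacts(frame, system, lo) <= count_intrachain_contacts(
        frame, system, hi
    )


def test_cutoff_must_be_below_half_box():
    rng = np.random.default_rng(9)
    box = np.array([10.0, 10.0, 10.0])
    system, frame = make_random_system(rng, 4, 5, box)
    with pytest.raises(ValueError, match="half the smallest box edge"):
        count_intrachain_contacts(frame, system, ShellParams(contact_cutoff=6.0))


# ----------------------------------------------------------------------
# series statistics
# ----------------------------------------------------------------------

class TestSeriesStatistics:
    def _traj_of_values(self, values):
        atoms = [AtomRecord(1, "CA", "C", 0, "GLY", Role.ELP, (0, 0, 0))]
        system = LabeledSystem(atoms)
        frames = [Frame(positions=np.zeros((1, 3)), meta={"v": v}) for v in values]
        return Trajectory(system, frames)

    def test_constant_metric(self):
        traj = self._traj_of_values([7.0] * 10)
        assert series_statistics(traj, lambda fr: fr.meta["v"]) == (7.0, 0.0, 10)

    def test_population_sd_closed_form(self):
        traj = self._traj_of_values([1.0, 2.0, 3.0])
        mean, sd, n = series_statistics(traj, lambda fr: fr.meta["v"])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))
        assert n == 3

    def test_poisson_sd_tracks_sqrt_mean(self):
        rng = np.random.default_rng(12)
        values = rng.poisson(9.0, 500).astype(float)
        traj = self._traj_of_values(values)
        mean, sd, _ = series_statistics(traj, lambda fr: fr.meta["v"])
        assert sd == pytest.approx(np.sqrt(mean), rel=0.2)

    def test_empty_trajectory_raises(self):
        traj = self._traj_of_values([1.0])
        traj.frames = []
        with pytest.raises(ValueError):
            series_statistics(traj, lambda fr: 0.0)
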