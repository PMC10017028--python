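"""Generator determinism, construction counts and generator/counter oracles."""

import numpy as np
import pytest

from fameshell.core import Role
from fameshell.proximity import (
    ShellParams,
    count_chain_waters,
    count_intrachain_contacts,
    residue_water_counts,
)
from fameshell.synth import (
    GenerationError,
    HydrationModel,
    ScanModel,
    build_fame_topology,
    build_peptide,
    simulate_annealing_series,
    simulate_dihedral_ensemble,
    simulate_hydration_frames,
    simulate_temperature_scan,
)


class TestTopology:
    def test_construct_residue_counts(self):
        system = build_fame_topology(20)
        assert system.peptide_length == 120
        assert system.residues[0].role is Role.LIPID
        assert system.residues[0].n_atoms == 14
        ls = [r for r in system.residues if r.role is Role.LIPIDATION_SITE]
        assert len(ls) == 20  # GLYASKLFSNLG + 8x His

    def test_single_residue_degenerate(self):
        system = build_fame_topology(0, ls_sequence="G", include_lipid=False)
        assert len(system.residues) == 1
        assert system.peptide_length == 1
        assert not any(r.role is Role.LIPID for r in system.residues)

    def test_negative_pentads_rejected(self):
        with pytest.raises(ValueError):
            build_fame_topology(-1)

    def test_determinism(self):
        a = build_fame_topology(2, seed=42)
        b = build_fame_topology(2, seed=42)
        np.testing.assert_array_equal(a.reference_positions, b.reference_positions)

    def test_backbone_atoms_present(self):
        system = build_fame_topology(1)
        for res in system.peptide_residues:
            names = {a.name for a in system.atoms_of(res)}
            assert {"N", "CA", "C", "O"} <= names


class TestHydrationFrames:
    def test_zero_occupancy_counts_zero(self, small_construct):
        n = small_construct.peptide_length
        model = HydrationModel(np.zeros(n), np.full(n, 325.0), 5.0)
        traj = simulate_hydration_frames(small_construct, model, 300.0, 5, seed=1)
        for fr in traj.frames:
            assert count_chain_waters(fr, traj.system) == 0

    def test_ground_truth_matches_recount(self, small_construct,
                                          flat_hydration_model):
        """The planted per-residue and chain water counts must be exactly
        recovered by proximity recounting on all 50 frames."""
        traj = simulate_hydration_frames(
            small_construct, flat_hydration_model, 310.0, 50, seed=2
        )
        for fr in traj.frames:
            assert count_chain_waters(fr, traj.system) == fr.meta["true_chain_waters"]
            prof = residue_water_counts(fr, traj.system)
            np.testing.assert_array_equal(
                prof.per_residue_counts, fr.meta["true_residue_waters"]
            )

    def test_poisson_mean_at_logistic_midpoint(self, small_construct):
        """At T = T50 the expected occupancy is baseline/2."""
        n = small_construct.peptide_length
        model = HydrationModel(np.full(n, 8.0), np.full(n, 325.0), 5.0)
        traj = simulate_hydration_frames(small_construct, model, 325.0, 200, seed=3)
        counts = np.array([fr.meta["true_residue_waters"] for fr in traj.frames])
        grand_mean = counts.mean()
        se = np.sqrt(4.0 / counts.size)  # Poisson(4) standard error
        assert abs(grand_mean - 4.0) < 3 * se

    def test_determinism(self, small_construct, flat_hydration_model):
        t1 = simulate_hydration_frames(
            small_construct, flat_hydration_model, 300.0, 3, seed=9
        )
        t2 = simulate_hydration_frames(
            small_construct, flat_hydration_model, 300.0, 3, seed=9
        )
        for a, b in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_infeasible_box_raises(self, small_construct, flat_hydration_model):
        with pytest.raises((GenerationError, ValueError)):
            simulate_hydration_frames(
                small_construct, flat_hydration_model, 250.0, 1,
                box=np.array([8.0, 8.0, 8.0]), seed=0,
            )


class TestAnnealingSeries:
    def test_occupancy_decreases_with_temperature(self, small_construct):
        n = small_construct.peptide_length
        model = HydrationModel(np.full(n, 8.0), np.full(n, 325.0), 5.0)
        series = simulate_annealing_series(
            small_construct, model, [250.0, 400.0], 20, seed=4
        )
        means = [
            np.mean([fr.meta["true_chain_waters"] for fr in traj.frames])
            for _, traj in series
        ]
        assert means[0] > means[1]

    def test_solute_rigid_across_series(self, small_construct,
                                        flat_hydration_model):
        series = simulate_annealing_series(
            small_construct, flat_hydration_model, [250.0, 300.0, 350.0], 2, seed=5
        )
        n_solute = small_construct.n_atoms
        ref = series[0][1].frames[0].positions[:n_solute]
        for _, traj in series:
            for fr in traj.frames:
                np.testing.assert_array_equal(fr.positions[:n_solute], ref)

    def test_grid_validation(self, small_construct, flat_hydration_model):
        with pytest.raises(ValueError):
            simulate_annealing_series(
                small_construct, flat_hydration_model, [300.0, 300.0], 2, seed=0
            )
        with pytest.raises(ValueError):
            simulate_annealing_series(
                small_construct, flat_hydration_model, [200.0, 300.0], 2, seed=0
            )

    def test_determinism(self, small_construct, flat_hydration_model):
        s1 = simulate_annealing_series(
            small_construct, flat_hydration_model, [260.0, 340.0], 2, seed=6
        )
        s2 = simulate_annealing_series(
            small_construct, flat_hydration_model, [260.0, 340.0], 2, seed=6
        )
        for (_, a), (_, b) in zip(s1, s2):
            for fa, fb in zip(a.frames, b.frames):
                np.testing.assert_array_equal(fa.positions, fb.positions)


class TestTemperatureScan:
    def test_noiseless_counts_match_linear_model_exactly(self, small_construct):
        model = ScanModel(60.0, -0.1, 2.0, 0.02, noise_sd=0.0)
        scan = simulate_temperature_scan(
            small_construct, model, [260.0, 340.0], 4, seed=7
        )
        for T, traj in scan:
            for fr in traj.frames:
                assert count_chain_waters(fr, traj.system) == round(
                    model.expected_nw(T)
                )
                assert count_intrachain_contacts(fr, traj.system) == round(
                    model.expected_npp(T)
                )

    def test_negative_expected_count_rejected(self, small_construct):
        model = ScanModel(10.0, -0.1, 2.0, 0.02)
        with pytest.raises(ValueError):
            simulate_temperature_scan(small_construct, model, [250.0, 400.0], 1)

    def test_ground_truth_matches_recount_with_noise(self, small_construct):
        model = ScanModel(50.0, -0.08, 0.5, 0.015, noise_sd=1.0)
        scan = simulate_temperature_scan(
            small_construct, model, [250.0, 300.0, 350.0], 10, seed=8
        )
        for _, traj in scan:
            for fr in traj.frames:
                assert count_chain_waters(fr, traj.system) == fr.meta["true_nw"]
                assert (
                    count_intrachain_contacts(fr, traj.system) == fr.meta["true_npp"]
                )


class TestDihedralEnsemble:
    def test_drawn_angles_recovered_from_coordinates(self):
        from fameshell.dihedrals import backbone_dihedrals

        traj = simulate_dihedral_ensemble(
            ["alpha_R", "beta", "coil", "alpha_L", "beta"], 10.0, 20, seed=9
        )
        series = backbone_dihedrals(traj)
        for k, fr in enumerate(traj.frames):
            for res, arr in series.angles.items():
                assert arr[k, 0] == pytest.approx(fr.meta["true_phi"][res], abs=1e-3)
                assert arr[k, 1] == pytest.approx(fr.meta["true_psi"][res], abs=1e-3)

    def test_high_concentration_classifies_alpha_r(self):
        from fameshell.dihedrals import backbone_dihedrals, classify_conformation

        traj = simulate_dihedral_ensemble(["alpha_R"] * 10, 400.0, 50, seed=10)
        series = backbone_dihedrals(traj)
        labels = [
            classify_conformation(phi, psi)
            for arr in series.angles.values()
            for phi, psi in arr
        ]
        assert labels.count("alpha_R") / len(labels) >= 0.95

    def test_coil_angles_in_principal_range(self):
        traj = simulate_dihedral_ensemble(["coil"] * 4, 1.0, 1, seed=11)
        phi = np.array(traj.frames[0].meta["true_phi"])
        psi = np.array(traj.frames[0].meta["true_psi"])
        assert np.all((phi > -180.0) & (phi <= 180.0))
        assert np.all((psi > -180.0) & (psi <= 180.0))

    def test_unknown_region_label_rejected(self):
        with pytest.raises(ValueError):
            simulate_dihedral_ensemble(["helix?"] * 5, 5.0, 1)


def test_extended_chain_has_no_contacts():
    """A fully extended chain (phi = psi = 180) has no residue pairs within
    6 A at sequence separation >= 3."""
    n = 20
    system = build_peptide("A" * n, np.full(n, 180.0), np.full(n, 180.0))
    from fameshell.core import Frame

    frame = Frame(positions=system.reference_positions)
    assert count_intrachain_contacts(frame, system, ShellParams()) == 0
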