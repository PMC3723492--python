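import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from memscale import fixtures as fx
from memscale.analysis import (MembraneFrame, bilayer_check, density_profile,
                               group_depth_summary, hbond_count, ils_map,
                               insertion_angle, insertion_depth,
                               membrane_frame, residue_depth_table,
                               rmsd_series, rmsf)
from memscale.reference import load_anchor_depth_table
from memscale.structure_io import Structure, Trajectory
from memscale.units import KB


@pytest.fixture(scope="module")
def bilayer():
    return fx.build_bilayer(fx.BilayerSpec(nx=4, ny=4, head_offset=14.0))


def lipid_groups(model):
    lip = np.arange(model.n_beads)
    return lip, np.asarray(model.phosphate_indices)


class TestMembraneFrame:
    def test_symmetric_bilayer_centered_at_zero(self, bilayer):
        lip, phos = lipid_groups(bilayer)
        mf = membrane_frame(bilayer.beads.xyz, lip, phos,
                            bilayer.beads.masses)
        assert mf.center_z == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self, bilayer):
        lip, phos = lipid_groups(bilayer)
        mf = membrane_frame(bilayer.beads.xyz + [0, 0, 5.0], lip, phos,
                            bilayer.beads.masses)
        assert mf.center_z == pytest.approx(5.0, abs=1e-9)

    def test_leaflet_means_equal_construction_offsets(self, bilayer):
        lip, phos = lipid_groups(bilayer)
        mf = membrane_frame(bilayer.beads.xyz, lip, phos)
        assert mf.phosphate_z_upper == pytest.approx(14.0, abs=1e-9)
        assert mf.phosphate_z_lower == pytest.approx(-14.0, abs=1e-9)

    def test_collapsed_leaflets_rejected(self, bilayer):
        lip, phos = lipid_groups(bilayer)
        flat = bilayer.beads.xyz.copy()
        flat[:, 2] = 0.0
        with pytest.raises(ValueError):
            membrane_frame(flat, lip, phos)


class TestInsertionAngle:
    def helix_ca_at_tilt(self, tilt_deg):
        # long helix: the helical-pitch contribution to the principal
        # axis falls off with length (0.4° at 36 residues)
        ca = fx.build_helix(fx.HelixSpec("A" * 36))
        idx = np.flatnonzero(ca.names == "CA")
        pts = ca.xyz[idx]            # axis along z (= 90° insertion)
        rot = Rotation.from_euler("y", 90 - tilt_deg, degrees=True)
        return pts @ rot.as_matrix().T

    @pytest.mark.parametrize("tilt", [0, 15, 30, 45, 60, 75, 90])
    def test_recovers_constructed_tilt_within_1_degree(self, tilt):
        mf = MembraneFrame(0.0, 14.0, -14.0)
        pts = self.helix_ca_at_tilt(tilt)
        got = insertion_angle(pts, np.arange(len(pts)), mf)
        assert got == pytest.approx(tilt, abs=1.0)

    def test_invariant_under_rotation_about_normal_and_translation(self):
        mf = MembraneFrame(0.0, 14.0, -14.0)
        pts = self.helix_ca_at_tilt(35)
        a0 = insertion_angle(pts, np.arange(len(pts)), mf)
        rot = Rotation.from_euler("z", 123, degrees=True).as_matrix()
        a1 = insertion_angle(pts @ rot.T + [7.0, -4.0, 0.0],
                             np.arange(len(pts)), mf)
        assert a1 == pytest.approx(a0, abs=1e-6)

    def test_degenerate_axis_rejected(self):
        mf = MembraneFrame(0.0, 14.0, -14.0)
        pts = np.zeros((5, 3))
        with pytest.raises(ValueError):
            insertion_angle(pts, np.arange(5), mf)


class TestInsertionDepth:
    def test_at_center_zero_and_at_19_gives_19(self):
        mf = MembraneFrame(0.0, 14.0, -14.0)
        pts = np.zeros((3, 3))
        assert insertion_depth(pts, [0, 1, 2], mf) == 0.0
        pts[:, 2] = 19.0
        assert insertion_depth(pts, [0, 1, 2], mf) == pytest.approx(19.0)

    def test_equals_brute_force_mass_weighted_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-20, 20, (10, 3))
        masses = rng.uniform(1, 20, 10)
        mf = MembraneFrame(2.0, 14.0, -14.0)
        got = insertion_depth(pts, np.arange(10), mf, masses)
        expected = abs(np.sum(pts[:, 2] * masses) / masses.sum() - 2.0)
        assert got == pytest.approx(expected, rel=1e-12)


class TestDepthTable:
    def make_traj(self, depth_lists):
        """Two residues with one side-chain atom each; depths scripted."""
        top = Structure(["CA", "CB", "CA", "CB"],
                        ["LEU", "LEU", "SER", "SER"], [1, 1, 2, 2],
                        ["A"] * 4, np.zeros((4, 3)))
        traj = Trajectory(top)
        for t, (d1, d2) in enumerate(depth_lists):
            c = np.zeros((4, 3))
            c[1, 2] = d1
            c[3, 2] = d2
            traj.append(c, time=float(t))
        mfs = [MembraneFrame(0.0, 10.0, -10.0)] * len(depth_lists)
        return traj, mfs

    def test_static_trajectory_gives_zero_sd(self):
        traj, mfs = self.make_traj([(15.0, 18.0)] * 4)
        dt = residue_depth_table(traj, [1, 2], mfs)
        assert np.all(dt["sd_depth"] == 0.0)
        assert dt["mean_depth"].tolist() == [15.0, 18.0]

    def test_two_frames_population_sd(self):
        traj, mfs = self.make_traj([(15.0, 15.0), (17.0, 17.0)])
        dt = residue_depth_table(traj, [1], mfs)
        assert dt.loc[0, "mean_depth"] == pytest.approx(16.0)
        assert dt.loc[0, "sd_depth"] == pytest.approx(1.0)   # ÷N convention

    def test_residue_classes_assigned(self):
        traj, mfs = self.make_traj([(15.0, 18.0)])
        dt = residue_depth_table(traj, [1, 2], mfs)
        assert dt["res_class"].tolist() == ["hydrophobic", "polar"]


class TestGroupSummary:
    def test_published_anchor_rows_reproduce_class_means(self):
        table = load_anchor_depth_table()
        summary = group_depth_summary(table)
        assert summary.loc["hydrophobic", "mean_depth"] == pytest.approx(
            16.0, abs=0.1)
        assert summary.loc["basic", "mean_depth"] == pytest.approx(18.6,
                                                                   abs=0.1)
        assert summary.loc["polar", "mean_depth"] == pytest.approx(19.3,
                                                                   abs=0.1)
        assert summary.loc["hydrophobic", "sd_depth"] == pytest.approx(
            1.8, abs=0.1)

    def test_single_row_class_equals_row(self):
        df = pd.DataFrame([{"res_id": 1, "res_class": "basic",
                            "mean_depth": 17.3, "sd_depth": 2.0}])
        out = group_depth_summary(df)
        assert out.loc["basic", "mean_depth"] == 17.3

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning):
            group_depth_summary(pd.DataFrame(
                columns=["res_class", "mean_depth", "sd_depth"]))


class TestHbond:
    def test_distance_beyond_cutoff_not_counted(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
        assert hbond_count(coords, [(0, 1)], [2]) == 0

    def test_ideal_linear_geometry_counted(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        assert hbond_count(coords, [(0, 1)], [2]) == 1

    def test_bent_geometry_rejected(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.5, 0]])
        assert hbond_count(coords, [(0, 1)], [2]) == 0

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 8, (30, 3))
        donors = [(i, i + 1) for i in range(0, 10, 2)]
        acceptors = list(range(20, 30))
        got = hbond_count(coords, donors, acceptors)
        expected = 0
        for d, h in donors:
            for a in acceptors:
                r = np.linalg.norm(coords[a] - coords[d])
                if r > 3.5 or r < 1e-6:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 150:
                    expected += 1
        assert got == expected

    def test_missing_hydrogen_suggests_heavy_atom_mode(self):
        coords = np.zeros((3, 3))
        with pytest.raises(ValueError, match="heavy-atom"):
            hbond_count(coords, [(0, None)], [2])
        coords = np.array([[0.0, 0, 0], [0, 0, 0], [3.0, 0, 0]])
        assert hbond_count(coords, [(0, None)], [2], angle_min=None) == 1


class TestRmsdRmsf:
    def test_identical_frames_zero(self, anchor_helix):
        traj = Trajectory(anchor_helix)
        for k in range(3):
            traj.append(anchor_helix.xyz, time=float(k))
        idx = np.arange(anchor_helix.n_atoms)
        assert np.all(rmsd_series(traj, anchor_helix.xyz, idx) < 1e-12)
        assert np.all(rmsf(traj, idx) < 1e-12)

    def test_rotation_removed_by_fit(self, anchor_helix):
        traj = Trajectory(anchor_helix)
        rot = Rotation.from_euler("x", 40, degrees=True).as_matrix()
        traj.append(anchor_helix.xyz @ rot.T + [3.0, 0, 0], time=0.0)
        idx = np.arange(anchor_helix.n_atoms)
        assert rmsd_series(traj, anchor_helix.xyz, idx, fit=True)[0] < 1e-8
        assert rmsd_series(traj, anchor_helix.xyz, idx, fit=False)[0] > 1.0

    def test_two_frame_hand_computed(self):
        top = Structure(["A", "B"], ["GLY", "GLY"], [1, 2], ["A", "A"],
                        np.zeros((2, 3)))
        traj = Trajectory(top)
        traj.append(np.zeros((2, 3)), time=0.0)
        c = np.zeros((2, 3))
        c[:, 0] = 2.0
        traj.append(c, time=1.0)
        series = rmsd_series(traj, np.zeros((2, 3)), [0, 1], fit=False)
        assert series.tolist() == [0.0, pytest.approx(2.0)]
        # RMSF about the mean (at x = 1): each atom fluctuates ±1
        assert np.allclose(rmsf(traj, [0, 1], fit=False), 1.0)


class TestDensityProfile:
    def test_point_mass_occupies_single_bin(self):
        top = Structure(["A"], ["GLY"], [1], ["A"], [[0.0, 0, 0]])
        traj = Trajectory(top)
        c = np.array([[0.0, 0.0, 3.2]])
        traj.append(c, box=np.array([20.0, 20, 20, 90, 90, 90]), time=0.0)
        mfs = [MembraneFrame(0.0, 5.0, -5.0)]
        centers, profs = density_profile(traj, {"solo": [0]}, mfs,
                                         bin_width=1.0)
        p = profs["solo"]
        assert np.count_nonzero(p) == 1
        assert centers[np.argmax(p)] == pytest.approx(3.5, abs=0.5)

    def test_bilayer_headgroup_peaks_at_construction_offset(self, bilayer):
        traj = Trajectory(bilayer.beads)
        traj.append(bilayer.beads.xyz, box=bilayer.beads.box, time=0.0)
        lip, phos = lipid_groups(bilayer)
        mfs = [membrane_frame(bilayer.beads.xyz, lip, phos)]
        centers, profs = density_profile(
            traj, {"heads": phos}, mfs, bin_width=1.0)
        p = profs["heads"]
        peaks = centers[p > 0.9 * p.max()]
        assert np.any(np.abs(peaks - 14.0) < 1.0)
        assert np.any(np.abs(peaks + 14.0) < 1.0)

    def test_profiles_normalized(self, bilayer):
        traj = Trajectory(bilayer.beads)
        traj.append(bilayer.beads.xyz, box=bilayer.beads.box, time=0.0)
        lip, phos = lipid_groups(bilayer)
        mfs = [membrane_frame(bilayer.beads.xyz, lip, phos)]
        _c, profs = density_profile(traj, {"all": lip, "heads": phos}, mfs)
        for p in profs.values():
            assert p.sum() * 1.0 == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_warns_flat_zero(self, bilayer):
        traj = Trajectory(bilayer.beads)
        traj.append(bilayer.beads.xyz, box=bilayer.beads.box, time=0.0)
        lip, phos = lipid_groups(bilayer)
        mfs = [membrane_frame(bilayer.beads.xyz, lip, phos)]
        with pytest.warns(UserWarning):
            _c, profs = density_profile(traj, {"none": []}, mfs)
        assert np.all(profs["none"] == 0)


class TestIlsMap:
    def test_single_atom_single_frame_equals_pairwise_lj(self):
        top = Structure(["C"], ["PRB"], [1], ["A"], [[5.0, 5.0, 5.0]])
        traj = Trajectory(top)
        traj.append(top.xyz, time=0.0)
        eps, sig = np.array([1.0]), np.array([4.0])
        origin, spacing, F = ils_map(traj, eps, sig, probe_eps=1.0,
                                     probe_sigma=4.0, spacing=2.0,
                                     temperature=300.0,
                                     origin=np.zeros(3), shape=(5, 5, 5))
        # closed form: single frame average is the energy itself
        centers = (np.arange(5) + 0.5) * spacing   # origin at 0
        vi = (1, 2, 3)
        vox = np.array([centers[vi[0]], centers[vi[1]], centers[vi[2]]])
        r = np.linalg.norm(vox - [5.0, 5.0, 5.0])
        sr6 = (4.0 / r) ** 6
        expected = 4 * 1.0 * (sr6 ** 2 - sr6) if r < 12 else 0.0
        assert F[vi] == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_frame_reorder_invariance(self):
        rng = np.random.default_rng(1)
        top = Structure(["C"] * 4, ["PRB"] * 4, [1, 2, 3, 4], ["A"] * 4,
                        rng.uniform(0, 10, (4, 3)))
        frames = [rng.uniform(0, 10, (4, 3)) for _ in range(3)]
        eps, sig = np.ones(4), np.full(4, 4.0)
        outs = []
        for order in ([0, 1, 2], [2, 0, 1]):
            traj = Trajectory(top)
            for k, o in enumerate(order):
                traj.append(frames[o], time=float(k))
            outs.append(ils_map(traj, eps, sig, spacing=2.5,
                                origin=np.zeros(3), shape=(4, 4, 4))[2])
        assert np.allclose(outs[0], outs[1], equal_nan=True)

    def test_resource_guard_on_fine_grid(self):
        top = Structure(["C"], ["PRB"], [1], ["A"], [[0.0, 0, 0]])
        traj = Trajectory(top)
        traj.append(top.xyz, time=0.0)
        with pytest.raises(ValueError, match="0.1"):
            ils_map(traj, [1.0], [4.0], spacing=0.05)


class TestBilayerCheck:
    def test_preformed_bilayer_passes(self, bilayer):
        rep = bilayer_check(bilayer)
        assert rep.ok
        assert rep.axis == 2
        assert rep.cluster_fraction == 1.0

    def test_scattered_lipids_fail(self):
        model = fx.random_box(24, 0, box=40.0, seed=0)
        rep = bilayer_check(model)
        assert not rep.ok
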