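"""Superposition, solvation shells, hydrogen bonds, energies, and SASA."""

import numpy as np
import pytest

from crowdsolv import structure as st
from crowdsolv.model import AtomRecord, Box, Frame, MoleculeClass, Trajectory


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _quaternion_rmsd(ref, mob, w=None):
    """Independent RMSD oracle: Theobald quaternion eigenvalue method."""
    n = len(ref)
    w = np.ones(n) if w is None else np.asarray(w, float)
    w = w / w.sum()
    x = ref - w @ ref
    y = mob - w @ mob
    M = (y * w[:, None]).T @ x
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    g = (w * (x ** 2).sum(1)).sum() + (w * (y ** 2).sum(1)).sum()
    return np.sqrt(max(g - 2 * lam, 0.0))


class TestKabsch:
    def test_identical_structures(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3))
        sp = st.kabsch_superpose(x, x)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sp.rotation, np.eye(3), atol=1e-10)

    def test_rigid_copy_has_zero_rmsd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        moved = x @ _random_rotation(rng).T + np.array([1.0, -2.0, 0.5])
        sp = st.kabsch_superpose(x, moved)
        assert sp.rmsd < 1e-9
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_oracle_on_perturbed_toy(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mob = ref.copy()
        mob[3] += [0.1, 0.0, 0.0]
        rng = np.random.default_rng(2)
        mob = mob @ _random_rotation(rng).T + 0.3
        sp = st.kabsch_superpose(ref, mob)
        assert sp.rmsd == pytest.approx(_quaternion_rmsd(ref, mob), abs=1e-6)

    def test_symmetric_in_reference_and_mobile(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(0, 0.05, (10, 3))
        assert st.kabsch_superpose(a, b).rmsd == pytest.approx(
            st.kabsch_superpose(b, a).rmsd, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            st.kabsch_superpose(line, line)
        with pytest.raises(ValueError, match=">= 3"):
            st.kabsch_superpose(line[:2], line[:2])


def _protein_toy_trajectory(n_frames=5, displace=None, rigid_motion=False,
                            seed=0):
    """A 10-atom 'backbone' (N/CA/C named) trajectory factory."""
    rng = np.random.default_rng(seed)
    names = ["N", "CA", "C"] * 4
    base = rng.normal(1.8, 0.4, (10, 3))
    topo = [AtomRecord(i, names[i], "ALA", 1 + i // 3, MoleculeClass.PROTEIN,
                       14.0 if names[i] == "N" else 12.0)
            for i in range(10)]
    box = Box.cubic(40.0)
    frames = []
    for f in range(n_frames):
        pos = base.copy()
        if rigid_motion:
            pos = pos @ _random_rotation(rng).T + rng.normal(0, 1.0, 3)
        if displace is not None and f == displace[0]:
            pos[displace[1]] += displace[2]
        frames.append(Frame(float(f), pos, box))
    return Trajectory(topo, frames), base


class TestRMSDSeries:
    def test_copies_of_reference_are_zero(self):
        traj, base = _protein_toy_trajectory()
        np.testing.assert_allclose(st.rmsd_series(traj, base), 0.0, atol=1e-12)

    def test_rigid_tumbling_is_invisible(self):
        traj, base = _protein_toy_trajectory(rigid_motion=True)
        assert st.rmsd_series(traj, base).max() < 1e-9

    def test_displaced_atom_matches_direct_superpose_and_measure(self):
        shift = np.array([0.2, 0.0, 0.0])
        traj, base = _protein_toy_trajectory(displace=(2, 4, shift))
        series = st.rmsd_series(traj, base)
        sel = st.backbone_selection(traj.topology)
        masses = np.array([traj.topology[i].mass for i in sel])
        direct = st.kabsch_superpose(base[sel],
                                     traj.frames[2].positions[sel],
                                     masses).rmsd
        assert series[2] == pytest.approx(direct, rel=1e-12)
        assert series[1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_selection_rejected(self):
        traj, base = _protein_toy_trajectory()
        with pytest.raises(ValueError, match="selection"):
            st.rmsd_series(traj, base, selection=np.array([], dtype=int))


class TestRMSF:
    def test_rigid_trajectory_zero(self):
        traj, _ = _protein_toy_trajectory(rigid_motion=False)
        assert max(st.rmsf(traj).values()) < 1e-12

    def test_oscillating_atom_two_frame_amplitude(self):
        """One atom at ±d around its mean has RMSF d.

        Superposition re-fits translation/rotation, absorbing O(1/N) of an
        isolated displacement, so a large structure is used to expose the
        hand value.
        """
        d = 0.05
        rng = np.random.default_rng(12)
        n = 150
        topo = [AtomRecord(i, "CA", "ALA", i + 1, MoleculeClass.PROTEIN, 12.0)
                for i in range(n)]
        base = rng.normal(5.0, 1.0, (n, 3))
        f0, f1 = base.copy(), base.copy()
        f0[0, 0] += d
        f1[0, 0] -= d
        traj = Trajectory(topo, [Frame(0.0, f0, Box.cubic(40.0)),
                                 Frame(1.0, f1, Box.cubic(40.0))])
        vals = st.rmsf(traj, selection=np.arange(n))
        assert vals[1] == pytest.approx(d, rel=0.05)

    def test_invariant_under_global_rotation(self):
        traj, _ = _protein_toy_trajectory(n_frames=6, seed=4)
        rng = np.random.default_rng(9)
        for fr in traj.frames:
            fr.positions += rng.normal(0, 0.02, fr.positions.shape)
        base_vals = st.rmsf(traj)
        R = _random_rotation(np.random.default_rng(5))
        rotated = Trajectory(traj.topology,
                             [Frame(fr.time, fr.positions @ R.T + 3.0, fr.box)
                              for fr in traj.frames])
        rot_vals = st.rmsf(rotated)
        for k in base_vals:
            assert rot_vals[k] == pytest.approx(base_vals[k], abs=1e-9)


def _gas_trajectory(rho=33.3, L=6.0, n_frames=12, seed=42, center_cls=None):
    rng = np.random.default_rng(seed)
    n = int(rho * L ** 3)
    box = Box.cubic(L)
    topo = [AtomRecord(0, "NA", "NA", 1, MoleculeClass.ION, 23.0)]
    topo += [AtomRecord(i + 1, "OW", "SOL", i + 2, MoleculeClass.WATER, 18.0)
             for i in range(n)]
    frames = [Frame(float(f),
                    np.vstack([[L / 2, L / 2, L / 2], rng.uniform(0, L, (n, 3))]),
                    box)
              for f in range(n_frames)]
    return Trajectory(topo, frames)


class TestSolvationShell:
    def test_ideal_gas_plateau_recovers_bulk_density(self):
        traj = _gas_trajectory()
        rdf = st.density_rdf(traj, [0], "water", bin_width=0.05, r_max=2.5)
        plateau = rdf.local_density[rdf.bin_centers > 0.5].mean()
        assert plateau == pytest.approx(33.3, rel=0.02)

    def test_empty_shell_group(self):
        traj = _gas_trajectory(rho=1.0)
        rdf = st.density_rdf(traj, [0], "peg4", bin_width=0.1, r_max=2.0)
        assert np.all(rdf.local_density == 0.0)

    def test_cumulative_matches_brute_force_count(self):
        traj = _gas_trajectory(rho=5.0, n_frames=4)
        rdf = st.density_rdf(traj, [0], "water", bin_width=0.01, r_max=2.0)
        # direct per-frame count within r_max
        counts = [float((st._shell_distances(fr, traj.topology, [0], "water")
                         < 2.0).sum()) for fr in traj.frames]
        assert rdf.cumulative_count[-1] == pytest.approx(np.mean(counts))

    def test_scripted_coordination_count(self, cubic_box):
        """5 waters at 1.0 nm and 3 at 2.5 nm: CN = 5 inside 1.87 nm."""
        topo = [AtomRecord(0, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0)]
        pos = [[2.0, 2.0, 2.0]]
        L = 8.0
        box = Box.cubic(L)
        topo = [AtomRecord(0, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0)]
        pos = [[4.0, 4.0, 4.0]]
        dirs = np.eye(3).tolist() + [[-1, 0, 0], [0, -1, 0], [0, 0, -1],
                                     [1, 1, 0], [0, 1, 1]]
        for i, (d, r) in enumerate(zip(dirs, [1.0] * 5 + [2.5] * 3)):
            u = np.asarray(d, float)
            u /= np.linalg.norm(u)
            pos.append((np.array([4.0, 4.0, 4.0]) + r * u).tolist())
            topo.append(AtomRecord(i + 1, "OW", "SOL", i + 2,
                                   MoleculeClass.WATER, 18.0))
        frame = Frame(0.0, np.array(pos), box)
        cn, err, counts = st.coordination_number(frame, [0], "water",
                                                 radius=1.87, topology=topo)
        assert cn == 5.0
        cn0, _, _ = st.coordination_number(frame, [0], "water", radius=0.0,
                                           topology=topo)
        assert cn0 == 0.0

    def test_cn_consistent_with_rdf_integral(self):
        traj = _gas_trajectory(n_frames=8, seed=3)
        cn, _, _ = st.coordination_number(traj, [0], "water", radius=1.87)
        rdf = st.density_rdf(traj, [0], "water", bin_width=0.01, r_max=2.5)
        k = int(round(1.87 / 0.01)) - 1
        integral = rdf.cumulative_count[k]
        assert cn == pytest.approx(integral, rel=0.01)

    def test_oversized_radius_rejected(self):
        traj = _gas_trajectory(rho=1.0)
        with pytest.raises(ValueError, match="half"):
            st.density_rdf(traj, [0], "water", bin_width=0.1, r_max=4.0)


def _hbond_fixture(acceptor_offset):
    topo = [AtomRecord(0, "O", "PRT", 1, MoleculeClass.PROTEIN, 16.0, -0.5),
            AtomRecord(1, "H", "PRT", 1, MoleculeClass.PROTEIN, 1.0, 0.4),
            AtomRecord(2, "OW", "SOL", 2, MoleculeClass.WATER, 16.0, -0.8)]
    donor = np.array([1.0, 1.0, 1.0])
    pos = np.array([donor, donor + [0.1, 0, 0], donor + acceptor_offset])
    return topo, Frame(0.0, pos, Box.cubic(4.0))


class TestHydrogenBonds:
    def test_colinear_within_cutoffs_counts_one(self):
        topo, fr = _hbond_fixture([0.29, 0.0, 0.0])
        assert st.hydrogen_bonds(fr, "prot-wat", topology=topo)[0] == 1

    def test_distance_cut(self):
        topo, fr = _hbond_fixture([0.40, 0.0, 0.0])
        assert st.hydrogen_bonds(fr, "prot-wat", topology=topo)[0] == 0

    def test_angle_cut_at_45_degrees(self):
        a = np.radians(45)
        topo, fr = _hbond_fixture([0.29 * np.cos(a), 0.29 * np.sin(a), 0.0])
        assert st.hydrogen_bonds(fr, "prot-wat", topology=topo)[0] == 0

    def test_invariant_under_rigid_transform(self):
        topo, fr = _hbond_fixture([0.29, 0.0, 0.0])
        R = _random_rotation(np.random.default_rng(6))
        moved = Frame(0.0, fr.positions @ R.T + 1.0, fr.box)
        assert st.hydrogen_bonds(moved, "prot-wat", topology=topo)[0] == 1

    def test_hydrogen_without_heavy_parent_is_configuration_error(self):
        topo = [AtomRecord(0, "H", "PRT", 1, MoleculeClass.PROTEIN, 1.0, 0.4)]
        fr = Frame(0.0, np.zeros((1, 3)), Box.cubic(4.0))
        with pytest.raises(ValueError, match="no preceding heavy atom"):
            st.hydrogen_bonds(fr, "prot-prot", topology=topo)


def _charged_pair(r, q=(1.0, 1.0), sigma=(0.0, 0.0), eps=(0.0, 0.0)):
    topo = [AtomRecord(0, "NA", "NA", 1, MoleculeClass.ION, 23.0, q[0],
                       sigma[0], eps[0]),
            AtomRecord(1, "NA", "NA", 2, MoleculeClass.ION, 23.0, q[1],
                       sigma[1], eps[1])]
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    return topo, Frame(0.0, pos, Box.cubic(6.0))


class TestInteractionEnergy:
    def test_unit_charges_at_one_nm(self):
        topo, fr = _charged_pair(1.0)
        e = st.interaction_energy(fr, [0], [1], topo)
        assert e.coulomb == pytest.approx(138.935458)
        assert e.vdw == 0.0
        assert e.total == e.coulomb

    def test_lj_landmarks(self):
        topo, fr = _charged_pair(0.3, q=(0, 0), sigma=(0.3, 0.3), eps=(1.0, 1.0))
        assert st.interaction_energy(fr, [0], [1], topo).vdw == \
            pytest.approx(0.0, abs=1e-12)
        topo, fr = _charged_pair(2 ** (1 / 6) * 0.3, q=(0, 0),
                                 sigma=(0.3, 0.3), eps=(1.0, 1.0))
        assert st.interaction_energy(fr, [0], [1], topo).vdw == \
            pytest.approx(-1.0, rel=1e-12)

    def test_pair_beyond_cutoff(self):
        topo, fr = _charged_pair(1.5)
        e = st.interaction_energy(fr, [0], [1], topo, cutoff=1.0)
        assert (e.coulomb, e.vdw) == (0.0, 0.0)

    def test_symmetric_and_additive_over_partition(self):
        rng = np.random.default_rng(8)
        n = 12
        topo = [AtomRecord(i, "NA", "NA", i + 1, MoleculeClass.ION, 23.0,
                           float(rng.normal(0, 0.5)), 0.3, 0.5)
                for i in range(n)]
        fr = Frame(0.0, rng.uniform(0, 3, (n, 3)), Box.cubic(3.0))
        a, b = [0, 1, 2, 3], list(range(4, 12))
        e_ab = st.interaction_energy(fr, a, b, topo)
        e_ba = st.interaction_energy(fr, b, a, topo)
        assert e_ab.coulomb == pytest.approx(e_ba.coulomb, rel=1e-12)
        assert e_ab.vdw == pytest.approx(e_ba.vdw, rel=1e-12)
        e1 = st.interaction_energy(fr, a, b[:4], topo)
        e2 = st.interaction_energy(fr, a, b[4:], topo)
        assert e_ab.total == pytest.approx(e1.total + e2.total, rel=1e-12)

    def test_overlapping_groups_rejected(self):
        topo, fr = _charged_pair(1.0)
        with pytest.raises(ValueError, match="disjoint"):
            st.interaction_energy(fr, [0], [0, 1], topo)


class TestSASA:
    def _single_atom(self, charge=-0.8):
        topo = [AtomRecord(0, "O", "SOL", 1, MoleculeClass.WATER, 16.0, charge)]
        fr = Frame(0.0, np.array([[2.0, 2.0, 2.0]]), Box.cubic(4.0))
        return topo, fr

    def test_single_sphere_closed_form(self):
        topo, fr = self._single_atom()
        res = st.sasa(fr, topo, selection=np.array([0]), radii={"O": 0.15})
        assert res.total == pytest.approx(4 * np.pi * 0.29 ** 2, rel=1e-9)

    def test_distant_spheres_do_not_occlude(self):
        topo = [AtomRecord(0, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0, 0.0),
                AtomRecord(1, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0, 0.0)]
        fr = Frame(0.0, np.array([[1.0, 1, 1], [3.0, 1, 1]]), Box.cubic(8.0))
        res = st.sasa(fr, topo)
        iso = 4 * np.pi * (st.BONDI_RADII_NM["C"] + 0.14) ** 2
        assert res.total == pytest.approx(2 * iso, rel=1e-9)

    def test_two_sphere_overlap_matches_spherical_cap_formula(self):
        """Closed-form oracle: two overlapping equal spheres at distance d."""
        r = st.BONDI_RADII_NM["C"] + 0.14
        d = 0.4
        topo = [AtomRecord(0, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0, 0.0),
                AtomRecord(1, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0, 0.0)]
        fr = Frame(0.0, np.array([[2.0, 2, 2], [2.0 + d, 2, 2]]), Box.cubic(8.0))
        res = st.sasa(fr, topo, n_sphere_points=4000)
        cap_height = r - d / 2
        exact = 2 * (4 * np.pi * r ** 2 - 2 * np.pi * r * cap_height)
        assert res.total == pytest.approx(exact, rel=5e-3)

    def test_partition_identity_on_mixed_charge_cluster(self):
        rng = np.random.default_rng(10)
        n = 20
        topo = [AtomRecord(i, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0,
                           float(rng.uniform(-0.5, 0.5)))
                for i in range(n)]
        fr = Frame(0.0, 2.0 + rng.normal(0, 0.2, (n, 3)), Box.cubic(8.0))
        res = st.sasa(fr, topo)
        assert res.hydrophilic + res.hydrophobic == pytest.approx(res.total,
                                                                  abs=1e-9)
        assert res.hydrophilic > 0 and res.hydrophobic > 0

    def test_point_density_convergence(self):
        rng = np.random.default_rng(11)
        n = 10
        topo = [AtomRecord(i, "C", "PRT", 1, MoleculeClass.PROTEIN, 12.0, 0.0)
                for i in range(n)]
        fr = Frame(0.0, 2.0 + rng.normal(0, 0.15, (n, 3)), Box.cubic(8.0))
        a = st.sasa(fr, topo, n_sphere_points=960).total
        b = st.sasa(fr, topo, n_sphere_points=1920).total
        assert abs(a - b) / b < 0.005

    def test_unknown_element_rejected(self):
        topo = [AtomRecord(0, "X1", "PRT", 1, MoleculeClass.PROTEIN, 12.0, 0.0)]
        fr = Frame(0.0, np.zeros((1, 3)), Box.cubic(4.0))
        with pytest.raises(ValueError, match="radius"):
            st.sasa(fr, topo, radii={"C": 0.17})
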