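"""Domain types, file formats, and unwrapping."""

import ast
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdsolv import io as cio
from crowdsolv import synthetic
from crowdsolv.model import (
    AtomRecord,
    Box,
    Frame,
    MoleculeClass,
    Trajectory,
    UnsupportedFeatureError,
    classify_residue,
)

GRO_3ATOM = """three waters, one site each
    3
    1SOL     OW    1   1.000   2.000   3.000
    2SOL     OW    2   0.500   0.500   0.500
    3SOL     OW    3   3.900   3.900   3.900
   4.00000   4.00000   4.00000
"""

PDB_3ATOM = """CRYST1   40.000   40.000   40.000  90.00  90.00  90.00 P 1           1
ATOM      1  OW  SOL     1      10.000  20.000  30.000  1.00  0.00           O
ATOM      2  OW  SOL     2       5.000   5.000   5.000  1.00  0.00           O
ATOM      3  OW  SOL     3      39.000  39.000  39.000  1.00  0.00           O
END
"""


class TestConfigurations:
    def test_gro_fields_and_box_volume(self, tmp_path):
        p = tmp_path / "w.gro"
        p.write_text(GRO_3ATOM)
        topo, frame = cio.read_configuration(p)
        assert len(topo) == 3
        assert topo[0].molecule_class is MoleculeClass.WATER
        assert frame.box.volume == pytest.approx(64.0)
        assert frame.positions[0] == pytest.approx([1.0, 2.0, 3.0])

    def test_pdb_matches_gro_coordinates(self, tmp_path):
        """Cross-format oracle: the same structure in PDB (Å) and GRO (nm)."""
        pg = tmp_path / "w.gro"
        pg.write_text(GRO_3ATOM)
        pp = tmp_path / "w.pdb"
        pp.write_text(PDB_3ATOM)
        _, f_gro = cio.read_configuration(pg)
        _, f_pdb = cio.read_configuration(pp)
        np.testing.assert_allclose(f_pdb.positions, f_gro.positions, atol=1e-4)
        assert f_pdb.box.lengths == pytest.approx(f_gro.box.lengths)

    def test_truncated_gro_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text("t\n    2\n    1SOL     OW    1   1.000   2.000   3.000\n"
                     "    2SOL     OW    2   1.0\n   4.0 4.0 4.0\n")
        with pytest.raises(cio.ParseError, match="line 4"):
            cio.read_configuration(p)

    def test_missing_pdb_box_instructs_override(self, tmp_path):
        p = tmp_path / "nobox.pdb"
        p.write_text("\n".join(PDB_3ATOM.splitlines()[1:]) + "\n")
        with pytest.raises(cio.ParseError, match="override"):
            cio.read_configuration(p)
        topo, frame = cio.read_configuration(p, box=Box.cubic(4.0))
        assert frame.box.volume == pytest.approx(64.0)

    def test_triclinic_inputs_rejected(self, tmp_path):
        p = tmp_path / "tri.pdb"
        p.write_text(PDB_3ATOM.replace("90.00  90.00  90.00",
                                       "90.00  90.00  60.00"))
        with pytest.raises(UnsupportedFeatureError):
            cio.read_configuration(p)
        g = tmp_path / "tri.gro"
        g.write_text(GRO_3ATOM.replace(
            "   4.00000   4.00000   4.00000",
            "   4.0   4.0   4.0   0.0   0.0   1.0   0.0   0.0   0.0"))
        with pytest.raises(UnsupportedFeatureError):
            cio.read_configuration(g)

    def test_gro_round_trip(self, tmp_path):
        res = synthetic.toy_solution(5, 1, 4, Box.cubic(3.0), seed=1)
        p = tmp_path / "toy.gro"
        cio.write_gro(p, res.topology, res.frame)
        topo, frame = cio.read_configuration(p)
        assert len(topo) == len(res.topology)
        np.testing.assert_allclose(frame.positions, res.frame.positions, atol=1e-3)

    def test_unmapped_residue_is_an_error(self):
        with pytest.raises(KeyError, match="XYZ"):
            classify_residue("XYZ")


class TestTrajectories:
    def _make_traj(self, n_frames=10, n_atoms=7, seed=0):
        rng = np.random.default_rng(seed)
        topo = [AtomRecord(i, "OW", "SOL", i + 1, MoleculeClass.WATER, 18.0)
                for i in range(n_atoms)]
        frames = [Frame(time=float(i),
                        positions=rng.uniform(0, 4, (n_atoms, 3)),
                        box=Box.cubic(4.0),
                        velocities=rng.normal(0, 0.1, (n_atoms, 3)))
                  for i in range(n_frames)]
        return Trajectory(topo, frames)

    def test_frames_text_round_trip(self, tmp_path):
        traj = self._make_traj()
        p = tmp_path / "t.frames"
        cio.write_frames_text(p, traj)
        back = cio.read_trajectory(p, traj.topology, format="frames_text")
        assert len(back) == 10
        np.testing.assert_allclose(back.positions_array(),
                                   traj.positions_array(), rtol=1e-9)
        np.testing.assert_allclose(back.frames[3].velocities,
                                   traj.frames[3].velocities, rtol=1e-9)

    def test_frames_text_single_frame(self, tmp_path):
        traj = self._make_traj(n_frames=1)
        p = tmp_path / "one.frames"
        cio.write_frames_text(p, traj)
        assert len(cio.read_trajectory(p, traj.topology)) == 1

    def test_xtc_round_trip_within_format_precision(self, tmp_path):
        traj = self._make_traj()
        p = tmp_path / "t.xtc"
        cio.write_xtc(p, traj)
        back = cio.read_trajectory(p, traj.topology, format="xtc")
        np.testing.assert_allclose(back.positions_array(),
                                   traj.positions_array(), atol=1e-3)

    def test_atom_count_mismatch_reports_both_counts(self, tmp_path):
        traj = self._make_traj(n_atoms=7)
        p = tmp_path / "t.xtc"
        cio.write_xtc(p, traj)
        short_topo = traj.topology[:5]
        with pytest.raises(ValueError, match="5.*7|7.*5"):
            cio.read_trajectory(p, short_topo, format="xtc")


class TestUnwrap:
    def test_boundary_crossing_minimum_image(self, cubic_box,
                                             single_particle_trajectory):
        traj = single_particle_trajectory([0.9 * 4.0, 0.05 * 4.0])
        unwrapped = cio.unwrap(traj)
        # 3.6 -> 0.2 across +x: minimum-image displacement +0.6, so 4.2
        assert unwrapped.frames[1].positions[0, 0] == pytest.approx(4.2)

    def test_stationary_particle_unchanged(self, single_particle_trajectory):
        traj = single_particle_trajectory([1.0] * 5)
        unwrapped = cio.unwrap(traj)
        np.testing.assert_array_equal(unwrapped.positions_array(),
                                      traj.positions_array())

    def test_idempotent_on_continuous_trajectories(self):
        res = synthetic.brownian_trajectory(4, 50, 1.0, Box.cubic(4.0), 1.0, seed=3)
        once = cio.unwrap(res.trajectory)
        twice = cio.unwrap(once)
        np.testing.assert_allclose(twice.positions_array(),
                                   once.positions_array(), atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_wrap_then_unwrap_recovers_random_walk(self, seed):
        """Generator-inversion oracle: unwrap inverts periodic wrapping."""
        res = synthetic.brownian_trajectory(3, 30, 1.0, Box.cubic(4.0), 1.0,
                                            seed=seed)
        rec = cio.unwrap(res.wrapped)
        np.testing.assert_allclose(rec.positions_array(),
                                   res.trajectory.positions_array(), atol=1e-9)

    def test_ambiguous_half_box_jump_warns_with_atom_and_frame(self,
                                                               single_particle_trajectory):
        traj = single_particle_trajectory([0.0, 2.0])  # exactly L/2
        with pytest.warns(UserWarning, match="frame 1.*atom\\(s\\) \\[0\\]"):
            cio.unwrap(traj)


class TestPressureSeries:
    def test_constant_zero_csv(self, tmp_path):
        p = tmp_path / "z.csv"
        lines = ["time_ps,Pxy,Pxz,Pyz,Pyx,Pzx,Pzy"]
        lines += [f"{i * 0.1},0,0,0,0,0,0" for i in range(100)]
        p.write_text("\n".join(lines) + "\n")
        s = cio.read_pressure_series(p, box_volume=64.0, temperature=300.0)
        assert len(s) == 100
        assert np.all(s.stacked() == 0.0)

    def test_xvg_legends_skipped_and_three_columns_mirrored(self, tmp_path):
        p = tmp_path / "p.xvg"
        p.write_text("# gmx energy output\n@ title \"P\"\n@ s0 legend \"Pxy\"\n"
                     "0.0 1.0 2.0 3.0\n1.0 4.0 5.0 6.0\n")
        s = cio.read_pressure_series(p, box_volume=64.0, temperature=300.0)
        assert len(s) == 2
        np.testing.assert_array_equal(s.components["xy"], s.components["yx"])
        assert s.components["xz"][1] == 5.0

    def test_round_trip_bit_identical(self, tmp_path):
        res = synthetic.ou_pressure_series(500, 0.1, 100.0, 1.0, 64.0, 300.0, seed=9)
        p = tmp_path / "ou.csv"
        cio.write_pressure_csv(p, res.pressure_series)
        back = cio.read_pressure_series(p, box_volume=64.0, temperature=300.0)
        np.testing.assert_array_equal(back.stacked(),
                                      res.pressure_series.stacked())
        np.testing.assert_array_equal(back.times, res.pressure_series.times)

    def test_too_few_columns_is_a_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,a\n0,1\n")
        with pytest.raises(cio.ParseError, match="columns"):
            cio.read_pressure_series(p, box_volume=1.0, temperature=300.0)


class TestTopologyTable:
    def test_round_trip_preserves_charges_and_lj(self, tmp_path):
        res = synthetic.toy_solution(3, 1, 4, Box.cubic(3.0), seed=2)
        p = tmp_path / "top.csv"
        cio.write_topology_table(p, res.topology)
        back = cio.read_topology_table(p)
        assert back == res.topology


def test_physical_constants_defined_exactly_once():
    """The Coulomb factor and k_B live only in the constants table."""
    src_dir = Path(cio.__file__).parent
    coulomb_hits, kb_hits = [], []
    for path in src_dir.glob("*.py"):
        text = path.read_text()
        if "138.935458" in text:
            coulomb_hits.append(path.name)
        if "1.380649e-23" in text:
            kb_hits.append(path.name)
    assert coulomb_hits == ["constants.py"]
    assert kb_hits == ["constants.py"]
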