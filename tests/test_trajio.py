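"""File I/O: LAMMPS dump, PSF, CHARMM PRM, time-series round trips."""

import json

import numpy as np
import pytest

from mdmech.errors import FormatError, IntegrityError
from mdmech.fixtures import (make_mock_membrane_stretch, make_spring_dimer,
                             write_lammps_dump, write_psf, write_prm)
from mdmech.trajio import (Box, read_charmm_prm, read_lammps_dump, read_psf,
                           read_timeseries, write_timeseries)

from conftest import make_frame


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------

class TestDump:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        pos = rng.uniform(-30, 30, size=(3, 3))
        vel = rng.normal(0, 0.01, size=(3, 3))
        frames = [make_frame(pos, velocities=vel, timestep=0),
                  make_frame(pos + 1.25, velocities=vel, timestep=10)]
        path = tmp_path / "two.dump"
        write_lammps_dump(frames, path)
        back = read_lammps_dump(path)
        assert [f.timestep for f in back] == [0, 10]
        for orig, rt in zip(frames, back):
            np.testing.assert_array_equal(rt.positions, orig.positions)
            np.testing.assert_array_equal(rt.velocities, orig.velocities)
            np.testing.assert_array_equal(rt.atom_ids, orig.atom_ids)

    def test_atoms_resorted_by_id_and_frames_by_timestep(self, tmp_path):
        text = """ITEM: TIMESTEP
5
ITEM: NUMBER OF ATOMS
3
ITEM: BOX BOUNDS pp pp pp
0 10
0 10
0 10
ITEM: ATOMS id type xu yu zu
3 1 3.0 0 0
1 1 1.0 0 0
2 1 2.0 0 0
ITEM: TIMESTEP
0
ITEM: NUMBER OF ATOMS
3
ITEM: BOX BOUNDS pp pp pp
0 10
0 10
0 10
ITEM: ATOMS id type xu yu zu
2 1 0.2 0 0
1 1 0.1 0 0
3 1 0.3 0 0
"""
        path = tmp_path / "shuffled.dump"
        path.write_text(text)
        frames = read_lammps_dump(path)
        assert [f.timestep for f in frames] == [0, 5]
        np.testing.assert_array_equal(frames[0].atom_ids, [1, 2, 3])
        np.testing.assert_allclose(frames[0].positions[:, 0], [0.1, 0.2, 0.3])
        np.testing.assert_allclose(frames[1].positions[:, 0], [1.0, 2.0, 3.0])

    def test_missing_required_column_names_it(self, tmp_path, rng):
        frames = [make_frame(rng.uniform(0, 5, (2, 3)))]
        path = tmp_path / "novel.dump"
        write_lammps_dump(frames, path)
        with pytest.raises(FormatError, match="vx"):
            read_lammps_dump(path, fields_required={"vx", "vy", "vz"})

    def test_duplicate_atom_id_rejected(self, tmp_path):
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n2\n"
                "ITEM: BOX BOUNDS pp pp pp\n0 1\n0 1\n0 1\n"
                "ITEM: ATOMS id type xu yu zu\n1 1 0 0 0\n1 1 1 1 1\n")
        path = tmp_path / "dup.dump"
        path.write_text(text)
        with pytest.raises(IntegrityError, match="duplicate"):
            read_lammps_dump(path)

    def test_zero_atom_frame_rejected(self, tmp_path):
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n0\n"
                "ITEM: BOX BOUNDS pp pp pp\n0 1\n0 1\n0 1\n"
                "ITEM: ATOMS id type xu yu zu\n")
        path = tmp_path / "empty.dump"
        path.write_text(text)
        with pytest.raises(IntegrityError, match="zero atoms"):
            read_lammps_dump(path)

    def test_image_flag_unwrapping_keeps_displacement_small(self, tmp_path):
        # an atom crosses the +x boundary between frames: unwrapped
        # displacement must be below half the box length
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
                "ITEM: BOX BOUNDS pp pp pp\n0 10\n0 10\n0 10\n"
                "ITEM: ATOMS id type x y z ix iy iz\n1 1 9.8 5 5 0 0 0\n"
                "ITEM: TIMESTEP\n1\nITEM: NUMBER OF ATOMS\n1\n"
                "ITEM: BOX BOUNDS pp pp pp\n0 10\n0 10\n0 10\n"
                "ITEM: ATOMS id type x y z ix iy iz\n1 1 0.3 5 5 1 0 0\n")
        path = tmp_path / "wrap.dump"
        path.write_text(text)
        frames = read_lammps_dump(path)
        assert all(f.unwrapped for f in frames)
        disp = np.linalg.norm(frames[1].positions[0] - frames[0].positions[0])
        assert disp < 5.0
        assert frames[1].positions[0, 0] == pytest.approx(10.3)

    def test_triclinic_box_and_minimum_image(self, tmp_path):
        # bounds include the tilt extremes; xy = 2
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
                "ITEM: BOX BOUNDS xy xz yz pp pp pp\n"
                "0 12 2\n0 10 0\n0 10 0\n"
                "ITEM: ATOMS id type xu yu zu\n1 1 1 1 1\n")
        path = tmp_path / "tri.dump"
        path.write_text(text)
        frame = read_lammps_dump(path)[0]
        np.testing.assert_allclose(frame.box.tilt, [2.0, 0.0, 0.0])
        np.testing.assert_allclose(frame.box.lengths, [10.0, 10.0, 10.0])
        # manual minimum image of a displacement crossing the y face: the
        # image shift is the tilted cell vector (xy, ly, 0)
        d = np.array([0.5, 9.0, 0.0])
        expected = d - np.array([2.0, 10.0, 0.0])
        np.testing.assert_allclose(frame.box.minimum_image(d), expected,
                                   atol=1e-12)

    def test_wrapped_without_image_flags_is_flagged(self, tmp_path):
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
                "ITEM: BOX BOUNDS pp pp pp\n0 10\n0 10\n0 10\n"
                "ITEM: ATOMS id type x y z\n1 1 5 5 5\n")
        path = tmp_path / "plain.dump"
        path.write_text(text)
        assert read_lammps_dump(path)[0].unwrapped is False


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

class TestPsf:
    def test_round_trip_counts_and_tuples(self, tmp_path):
        toy = make_spring_dimer()
        path = tmp_path / "dimer.psf"
        write_psf(toy.topo, path)
        topo = read_psf(path)
        assert topo.n_atoms == 2
        np.testing.assert_array_equal(topo.bonds, [[0, 1]])
        assert topo.dihedrals.shape == (0, 4)  # empty section, no error
        np.testing.assert_allclose(topo.masses, toy.topo.masses)
        np.testing.assert_allclose(topo.charges, toy.topo.charges)
        assert topo.atom_type_names == toy.topo.atom_type_names

    def test_four_atoms_three_bonds_two_angles(self, tmp_path):
        from mdmech.fixtures import _bare_topology
        topo = _bare_topology(4, ["A1", "A2", "A1", "A2"], 12.0,
                              bonds=[(0, 1), (1, 2), (2, 3)],
                              angles=[(0, 1, 2), (1, 2, 3)])
        path = tmp_path / "chain.psf"
        write_psf(topo, path)
        back = read_psf(path)
        np.testing.assert_array_equal(back.bonds, topo.bonds)
        np.testing.assert_array_equal(back.angles, topo.angles)

    def test_count_mismatch_is_format_error(self, tmp_path):
        toy = make_spring_dimer()
        path = tmp_path / "bad.psf"
        write_psf(toy.topo, path)
        text = path.read_text().replace("       1 !NBOND", "       2 !NBOND")
        path.write_text(text)
        with pytest.raises(FormatError, match="NBOND"):
            read_psf(path)

    def test_bond_index_beyond_natom_is_format_error(self, tmp_path):
        toy = make_spring_dimer()
        path = tmp_path / "bad2.psf"
        write_psf(toy.topo, path)
        text = path.read_text()
        # bond section currently "       1       2"; point it past NATOM
        idx = text.rindex("       2")
        path.write_text(text[:idx] + "       9" + text[idx + 8:])
        with pytest.raises(FormatError, match="outside"):
            read_psf(path)

    def test_cross_check_against_mdanalysis(self, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        run = make_mock_membrane_stretch(seed=3, n_frames=3, eps_max=0.3,
                                         rupture_strain=0.12)
        paths = run.write(tmp_path)
        u = mda.Universe(str(paths["psf"]), str(paths["dump"]),
                         format="LAMMPSDUMP")
        topo = read_psf(paths["psf"])
        frames = read_lammps_dump(paths["dump"])
        assert len(u.atoms) == topo.n_atoms
        np.testing.assert_allclose(u.atoms.masses, topo.masses)
        np.testing.assert_allclose(u.atoms.charges, topo.charges)
        mine = set(map(tuple, np.sort(topo.bonds, axis=1).tolist()))
        theirs = set(map(tuple, np.sort(u.bonds.indices, axis=1).tolist()))
        assert mine == theirs
        u.trajectory[1]
        # MDAnalysis re-origins dump coordinates to the box corner
        np.testing.assert_allclose(
            u.atoms.positions,
            (frames[1].positions - frames[1].box.lo).astype(np.float32),
            atol=5e-3)


# ---------------------------------------------------------------------------
# CHARMM PRM
# ---------------------------------------------------------------------------

class TestPrm:
    def test_minimal_bond_lookup(self, tmp_path):
        path = tmp_path / "min.prm"
        path.write_text("BONDS\nCT1 CT2 100.0 1.5\n"
                        "NONBONDED ctofnb 12.0 ctonnb 10.0\n"
                        "CT1 0.0 -0.1 2.0\nCT2 0.0 -0.2 1.9\nEND\n")
        params = read_charmm_prm(path)
        assert params.bond_param("CT2", "CT1") == (100.0, 1.5)
        assert params.cutoff == 12.0 and params.switch_start == 10.0
        assert params.nonbonded_param("CT1") == (0.1, 2.0, 0.1, 2.0)

    def test_duplicate_line_last_wins(self, tmp_path, caplog):
        path = tmp_path / "dup.prm"
        path.write_text("BONDS\nCA CB 100.0 1.5\nCA CB 120.0 1.6\n"
                        "NONBONDED\nCA 0.0 -0.1 2.0\nCB 0.0 -0.1 2.0\nEND\n")
        import logging
        with caplog.at_level(logging.WARNING):
            params = read_charmm_prm(path)
        assert params.bond_param("CA", "CB") == (120.0, 1.6)
        assert any("duplicate" in r.message for r in caplog.records)

    def test_multiterm_dihedral_both_retained(self, tmp_path):
        path = tmp_path / "multi.prm"
        path.write_text("DIHEDRALS\nA B C D 2.0 1 0.0\nA B C D 0.5 3 180.0\n"
                        "NONBONDED\nA 0.0 -0.1 2.0\nB 0.0 -0.1 2.0\n"
                        "C 0.0 -0.1 2.0\nD 0.0 -0.1 2.0\nEND\n")
        params = read_charmm_prm(path)
        terms = params.dihedral_terms("A", "B", "C", "D")
        assert terms == [(2.0, 1, 0.0), (0.5, 3, 180.0)]

    def test_full_round_trip_through_writer(self, tmp_path, allterm_system):
        _, _, params = allterm_system
        path = tmp_path / "rt.prm"
        write_prm(params, path)
        back = read_charmm_prm(path)
        assert back.bonds == pytest.approx(params.bonds)
        for key, terms in params.dihedrals.items():
            assert back.dihedrals[key] == pytest.approx(terms)
        assert back.nonbonded == pytest.approx(params.nonbonded)
        assert back.cutoff == pytest.approx(params.cutoff)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

class TestTimeseries:
    def test_csv_header_and_order(self, tmp_path):
        records = [{"frame": k, "strain": 0.01 * k, "stress_xx": 10.0 * k}
                   for k in range(3)]
        path = tmp_path / "series.csv"
        write_timeseries(records, path)
        assert path.read_text().splitlines()[0] == "frame,strain,stress_xx"
        back = read_timeseries(path)
        np.testing.assert_allclose(back["stress_xx"], [0.0, 10.0, 20.0])

    def test_tensor_flattening_order(self, tmp_path):
        sigma = np.arange(9, dtype=float).reshape(3, 3)
        path = tmp_path / "tens.csv"
        write_timeseries([{"s": sigma}], path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == ["s_xx", "s_yy", "s_zz", "s_xy", "s_xz", "s_yz"]
        row = [float(v) for v in path.read_text().splitlines()[1].split(",")]
        assert row == [0.0, 4.0, 8.0, 1.0, 2.0, 5.0]

    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_timeseries([], path, columns=["frame", "strain"])
        assert path.read_text().strip() == "frame,strain"

    def test_json_round_trip_full_precision(self, tmp_path, rng):
        records = [{"a": float(v)} for v in rng.uniform(-1, 1, 5)]
        path = tmp_path / "series.json"
        write_timeseries(records, path, format="json")
        back = read_timeseries(path)
        np.testing.assert_array_equal(back["a"].to_numpy(),
                                      [r["a"] for r in records])

    def test_inconsistent_schema_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="schema"):
            write_timeseries([{"a": 1.0}, {"b": 2.0}], tmp_path / "x.csv")
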