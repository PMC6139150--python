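import struct

import gemmi
import numpy as np
import pytest

from ddflex import grid_io
from ddflex.grid_io import (DensityMap, MapFormatError, ModelFormatError,
                            read_map, read_model, read_trajectory, write_map,
                            write_trajectory)

PDB_3RES = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.732   6.827  -4.175  1.00  0.00           C
ATOM      4  O   ALA A   1       9.580   6.444  -4.010  1.00  0.00           O
ATOM      5  CB  ALA A   1      13.050   6.630  -5.078  1.00  0.00           C
ATOM      6  N   GLY A   2      11.212   7.881  -3.541  1.00  0.00           N
ATOM      7  CA  GLY A   2      10.411   8.700  -2.633  1.00  0.00           C
ATOM      8  C   GLY A   2      11.197   9.946  -2.243  1.00  0.00           C
ATOM      9  O   GLY A   2      12.423   9.919  -2.108  1.00  0.00           O
ATOM     10  N   SER A   3      10.493  11.060  -2.078  1.00  0.00           N
ATOM     11  CA  SER A   3      11.119  12.320  -1.686  1.00  0.00           C
ATOM     12  C   SER A   3      10.183  13.510  -1.859  1.00  0.00           C
ATOM     13  O   SER A   3       9.037  13.361  -2.289  1.00  0.00           O
ATOM     14  CB  SER A   3      11.592  12.251  -0.228  1.00  0.00           C
ATOM     15  OG  SER A   3      12.417  13.357   0.094  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.460   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.500   2.500   0.000  1.00  0.00           O
END
"""

PDB_HETATM_ONLY = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
END
"""


class TestMapIO:
    def test_round_trip_identity(self, tmp_path):
        values = np.arange(64, dtype=np.float32).reshape(4, 4, 4).astype(float)
        m = DensityMap(values, origin=[1.0, -2.0, 3.0], voxel_size=[1, 1, 1])
        path = tmp_path / "m.mrc"
        write_map(m, path)
        m2 = read_map(path)
        np.testing.assert_allclose(m2.values, m.values, rtol=1e-6)
        np.testing.assert_allclose(m2.origin, m.origin, atol=1e-5)
        np.testing.assert_allclose(m2.voxel_size, m.voxel_size, atol=1e-6)

    def test_constant_zero_map_round_trips(self, tmp_path):
        m = DensityMap(np.zeros((3, 3, 3)), origin=[0, 0, 0], voxel_size=[2, 2, 2])
        write_map(m, tmp_path / "z.mrc")
        assert np.all(read_map(tmp_path / "z.mrc").values == 0)

    def test_anisotropic_voxels_preserved(self, tmp_path):
        m = DensityMap(np.random.default_rng(0).random((4, 5, 6)),
                       origin=[0, 0, 0], voxel_size=[1.0, 1.5, 2.0])
        write_map(m, tmp_path / "a.mrc")
        m2 = read_map(tmp_path / "a.mrc")
        np.testing.assert_allclose(m2.voxel_size, [1.0, 1.5, 2.0], atol=1e-6)
        np.testing.assert_allclose(m2.values, m.values, rtol=1e-6)

    def test_nstart_origin(self, tmp_path):
        # origin absent from ORIGIN fields -> derived from nstart * voxel size
        grid = gemmi.FloatGrid(4, 4, 4)
        grid.set_unit_cell(gemmi.UnitCell(4, 4, 4, 90, 90, 90))
        grid.array[:] = np.ones((4, 4, 4), dtype=np.float32)
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        for word in (5, 6, 7):
            ccp4.set_header_i32(word, -2)
        path = tmp_path / "n.mrc"
        ccp4.write_ccp4_map(str(path))
        m = read_map(path)
        np.testing.assert_allclose(m.origin, [-2.0, -2.0, -2.0], atol=1e-6)

    def test_unsupported_mode_rejected(self, tmp_path):
        m = DensityMap(np.zeros((3, 3, 3)), origin=[0, 0, 0], voxel_size=[1, 1, 1])
        path = tmp_path / "m3.mrc"
        write_map(m, path)
        raw = bytearray(path.read_bytes())
        raw[12:16] = struct.pack("<i", 3)  # header word 4: mode -> complex
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError):
            read_map(path)


class TestModelIO:
    def test_read_three_residues(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(PDB_3RES)
        model = read_model(path)
        assert len(model.atoms) == 15
        assert sorted(model.atoms["resid"].unique()) == [1, 2, 3]
        assert list(model.atoms["resname"].unique()) == ["ALA", "GLY", "SER"]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(PDB_ALTLOC)
        model = read_model(path)
        ca = model.atoms[model.atoms["name"] == "CA"]
        assert len(ca) == 1
        assert ca["x"].iloc[0] == pytest.approx(1.460, abs=1e-3)

    def test_hetatm_only_rejected(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(PDB_HETATM_ONLY)
        with pytest.raises(ModelFormatError):
            read_model(path)

    def test_sse_records_round_trip(self, tmp_path, hinge_small):
        path = tmp_path / "h.pdb"
        grid_io.write_model(hinge_small.start, path)
        back = read_model(path)
        assert [(h.chain, h.start, h.end) for h in back.helices] == \
               [(h.chain, h.start, h.end) for h in hinge_small.start.helices]


class TestTrajectoryIO:
    def test_two_frames_and_coordinate_precision(self, tmp_path, hinge_small):
        path = tmp_path / "t.pdb"
        write_trajectory([hinge_small.start, hinge_small.target], path)
        text = path.read_text()
        assert text.count("MODEL ") == 2
        assert text.count("ENDMDL") == 2
        frames = read_trajectory(path)
        assert len(frames) == 2
        assert np.abs(frames[0].coords - hinge_small.start.coords).max() < 1e-3
        assert np.abs(frames[1].coords - hinge_small.target.coords).max() < 1e-3

    def test_empty_trajectory_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_trajectory([], tmp_path / "e.pdb")


def test_constraints_tsv_round_trip(tmp_path):
    entries = [("A", 1, "CA", "A", 8, "CA", 4.75), ("A", 2, "CA", "A", 7, "CA", None)]
    path = tmp_path / "c.tsv"
    grid_io.write_constraints_tsv(entries, path)
    back = grid_io.read_constraints_tsv(path)
    assert back[0][:6] == entries[0][:6]
    assert back[0][6] == pytest.approx(4.75)
    assert back[1][6] is None
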