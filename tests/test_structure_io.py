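import json
import logging

import numpy as np
import pandas as pd
import pytest

from repeatgeom import structure_io as sio
from repeatgeom.errors import (RegionResolutionError, RegionValidationError,
                               StructureParseError, UnitTooShortError)
from repeatgeom.synthetic import SolenoidParams, generate_solenoid

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.000   8.000   9.500  1.00  0.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


class TestParseStructure:
    def test_minimal_pdb_echoes_coordinates(self, mini_pdb):
        st = sio.parse_structure(mini_pdb)
        assert len(st) == 3
        assert np.allclose(st.coords[sio.ResidueKey("A", 1)], [1, 2, 3])
        assert np.allclose(st.coords[sio.ResidueKey("A", 3)], [7, 8, 9.5])

    def test_pdb_and_mmcif_agree_exactly(self, tmp_path):
        res = generate_solenoid(SolenoidParams(n_units=5, yaw0=0.4, seed=7))
        pdb, cif = tmp_path / "s.pdb", tmp_path / "s.cif"
        sio.write_ca_pdb(res.structure, pdb)
        sio.write_ca_mmcif(res.structure, cif)
        a, b = sio.parse_structure(pdb), sio.parse_structure(cif)
        assert a.keys() == b.keys()
        assert np.array_equal(a.array(), b.array())

    def test_written_coordinates_roundtrip_bit_identically(self, tmp_path):
        res = generate_solenoid(SolenoidParams(n_units=5, yaw0=0.4, seed=7))
        path = tmp_path / "s.pdb"
        sio.write_ca_pdb(res.structure, path)
        parsed = sio.parse_structure(path)
        for key, xyz in res.structure.coords.items():
            assert np.array_equal(parsed.coords[key], np.round(xyz, 3))

    def test_residue_without_ca_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "gap.pdb"
        path.write_text(MINI_PDB.replace(
            "ATOM      3  CA  GLY A   2       4.000   5.000   6.000"
            "  1.00  0.00           C",
            "ATOM      3  N   GLY A   2       4.000   5.000   6.000"
            "  1.00  0.00           N"))
        with caplog.at_level(logging.WARNING):
            st = sio.parse_structure(path)
        assert len(st) == 2
        assert any("without a CA" in r.message for r in caplog.records)

    def test_calcium_ion_is_not_an_alpha_carbon(self, tmp_path):
        path = tmp_path / "ca.pdb"
        path.write_text(MINI_PDB.replace(
            "END\n",
            "HETATM    5 CA    CA A   9      11.000  12.000  13.000"
            "  1.00  0.00          CA\nEND\n"))
        st = sio.parse_structure(path)
        assert sio.ResidueKey("A", 9) not in st.coords

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000"
            "  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000"
            "  0.70  0.00           C\n"
            "ATOM      3  CA  GLY A   2       3.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      4  CA  SER A   3       4.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n")
        st = sio.parse_structure(path)
        assert st.coords[sio.ResidueKey("A", 1)][0] == pytest.approx(2.0)

    def test_no_ca_atoms_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("ATOM      1  N   ALA A   1       0.000   0.000"
                        "   0.000  1.00  0.00           N\nEND\n")
        with pytest.raises(StructureParseError, match="no Calpha"):
            sio.parse_structure(path)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(StructureParseError):
            sio.parse_structure(tmp_path / "nope.pdb")

    def test_chain_filter(self, mini_pdb):
        with pytest.raises(StructureParseError):
            sio.parse_structure(mini_pdb, chains=["B"])


def _region_json(tmp_path, regions):
    path = tmp_path / "regions.json"
    path.write_text(json.dumps(regions))
    return path


class TestRegionSpec:
    def test_json_three_units(self, tmp_path):
        path = _region_json(tmp_path, [{
            "region_id": "r1", "chain": "A",
            "units": [[1, 10], [11, 20], [21, 30]]}])
        regions = sio.parse_region_spec(path)
        assert len(regions) == 1
        assert regions[0].n_units == 3
        assert regions[0].units[1] == sio.UnitSpan("A", 11, 20)
        assert regions[0].insertions == []

    def test_json_with_insertion(self, tmp_path):
        path = _region_json(tmp_path, [{
            "region_id": "r1", "chain": "A",
            "units": [[1, 10], [11, 20], [21, 30]],
            "insertions": [[15, 16]]}])
        region = sio.parse_region_spec(path)[0]
        assert region.insertions == [sio.UnitSpan("A", 15, 16)]

    def test_overlapping_units_rejected(self, tmp_path):
        path = _region_json(tmp_path, [{
            "region_id": "bad", "chain": "A",
            "units": [[1, 10], [5, 20], [21, 30]]}])
        with pytest.raises(RegionValidationError, match="bad"):
            sio.parse_region_spec(path)

    def test_fewer_than_three_units_rejected(self, tmp_path):
        path = _region_json(tmp_path, [{
            "region_id": "short", "chain": "A", "units": [[1, 10], [11, 20]]}])
        with pytest.raises(RegionValidationError, match="at least 3"):
            sio.parse_region_spec(path)

    def test_insertion_outside_region_rejected(self, tmp_path):
        path = _region_json(tmp_path, [{
            "region_id": "r", "chain": "A",
            "units": [[1, 10], [11, 20], [21, 30]],
            "insertions": [[40, 45]]}])
        with pytest.raises(RegionValidationError, match="outside"):
            sio.parse_region_spec(path)

    def test_tsv_dialect_matches_json(self, tmp_path):
        tsv = tmp_path / "regions.tsv"
        tsv.write_text("region_id\tchain\tstart\tend\tis_insertion\n"
                       "r1\tA\t1\t10\t0\n"
                       "r1\tA\t11\t20\t0\n"
                       "r1\tA\t21\t30\t0\n"
                       "r1\tA\t15\t16\t1\n")
        jsn = _region_json(tmp_path, [{
            "region_id": "r1", "chain": "A",
            "units": [[1, 10], [11, 20], [21, 30]],
            "insertions": [[15, 16]]}])
        assert sio.parse_region_spec(tsv) == sio.parse_region_spec(jsn)


class TestExtractUnits:
    @pytest.fixture
    def structure(self):
        coords = {sio.ResidueKey("A", i): np.array([float(i), 0, 0])
                  for i in range(1, 31)}
        return sio.Structure(coords)

    def _region(self, insertions=()):
        units = [sio.UnitSpan("A", 1, 10), sio.UnitSpan("A", 11, 20),
                 sio.UnitSpan("A", 21, 30)]
        return sio.RegionSpec("r", units,
                              [sio.UnitSpan("A", s, e)
                               for s, e in insertions]).validate()

    def test_full_units(self, structure):
        units = sio.extract_unit_coordinates(structure, self._region())
        assert [len(u) for u in units] == [10, 10, 10]

    def test_insertion_excluded(self, structure):
        units = sio.extract_unit_coordinates(structure,
                                             self._region([(15, 16)]))
        assert [len(u) for u in units] == [10, 8, 10]
        # x-coordinates equal the residue number in this fixture
        assert 15.0 not in units[1][:, 0] and 16.0 not in units[1][:, 0]

    def test_absent_span_error_names_the_span(self, structure):
        region = sio.RegionSpec("r", [
            sio.UnitSpan("A", 1, 10), sio.UnitSpan("A", 11, 20),
            sio.UnitSpan("A", 100, 110)]).validate()
        with pytest.raises(RegionResolutionError, match="100-110"):
            sio.extract_unit_coordinates(structure, region)

    def test_too_short_unit_error(self, structure):
        region = sio.RegionSpec("r", [
            sio.UnitSpan("A", 1, 10), sio.UnitSpan("A", 11, 20),
            sio.UnitSpan("A", 29, 30)]).validate()
        with pytest.raises(UnitTooShortError):
            sio.extract_unit_coordinates(structure, region)


class TestGeometryCsv:
    def test_roundtrip_to_printed_precision(self, tmp_path, open_solenoid):
        from repeatgeom.pipeline import compute_region_geometry
        table = compute_region_geometry(open_solenoid.structure,
                                        open_solenoid.region)
        path = tmp_path / "out.csv"
        sio.write_geometry_csv(table, path)
        back = sio.read_geometry_csv(path)
        assert len(back.pairs) == len(table.pairs)
        for col in ("curvature", "twist", "pitch", "rmsd"):
            assert np.allclose(back.pairs[col], table.pairs[col],
                               rtol=1e-6, atol=1e-9)
        assert np.allclose(back.summary.loc["mean"],
                           table.summary.loc["mean"], rtol=1e-6)

    def test_five_units_give_four_pair_rows(self, tmp_path):
        from repeatgeom.pipeline import compute_region_geometry
        res = generate_solenoid(SolenoidParams(n_units=5, yaw0=0.4, seed=0))
        table = compute_region_geometry(res.structure, res.region)
        path = tmp_path / "five.csv"
        sio.write_geometry_csv(table, path)
        df = pd.read_csv(path)
        assert (df.row_type == "pair").sum() == 4
        assert set(df.row_type) == {"pair", "mean", "std"}

    def test_empty_table_writes_header_only(self, tmp_path):
        table = sio.GeometryTable(
            "empty", pd.DataFrame(columns=sio.PAIR_COLUMNS),
            pd.DataFrame(columns=["curvature", "twist", "pitch"]))
        path = tmp_path / "empty.csv"
        sio.write_geometry_csv(table, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("row_type,region_id")


class TestAxesExport:
    def test_counts_for_three_unit_ring(self, tmp_path):
        from repeatgeom.pipeline import region_frames
        res = generate_solenoid(SolenoidParams(n_units=3, yaw0=0.8, seed=2))
        frames = region_frames(res.structure, res.region)
        assert len(frames) == 2
        out = tmp_path / "axes.pml"
        pdb = tmp_path / "axes.pdb"
        sio.export_axes_visualization(res.structure, res.region, frames,
                                      out, pseudo_pdb=pdb)
        text = out.read_text()
        assert text.count("pseudoatom") == 2 * 3 * 2   # frames x axes x ends
        assert text.count("distance") == 2 * 3
        for color in ("red", "green", "blue"):
            assert text.count(f"color {color}") == 2
        assert len(sio.parse_structure(pdb)) == 2 * 3 * 2

    def test_axis_segments_have_configured_length(self, tmp_path):
        from repeatgeom.pipeline import region_frames
        res = generate_solenoid(SolenoidParams(n_units=4, yaw0=0.6, seed=2))
        frames = region_frames(res.structure, res.region)
        pdb = tmp_path / "axes.pdb"
        sio.export_axes_visualization(res.structure, res.region, frames,
                                      tmp_path / "axes.pml",
                                      axis_length=7.0, pseudo_pdb=pdb)
        pts = sio.parse_structure(pdb)
        xs = [k for k in pts.keys() if k.chain == "X"]
        seg = pts.coords[xs[1]] - pts.coords[xs[0]]
        assert np.linalg.norm(seg) == pytest.approx(7.0, abs=2e-3)

    def test_empty_frames_error(self, tmp_path, open_solenoid):
        with pytest.raises(ValueError, match="no frames"):
            sio.export_axes_visualization(
                open_solenoid.structure, open_solenoid.region, [],
                tmp_path / "axes.pml")
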