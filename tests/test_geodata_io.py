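"""Occurrence ingestion, covariate extraction, feature-table round trips."""

import numpy as np
import pandas as pd
import pytest

import nichecontrast as nc
from nichecontrast.geodata_io import FormatError
from nichecontrast.grids import GridGeometry

ROLES = {"inv": "invasive", "nat": "native"}


def constant_stack(value=5.0, rows=4, cols=4, variables=("T13", "P02"),
                   year=2011):
    geom = GridGeometry(rows=rows, cols=cols, cell_size=1.0)
    layers = {v: np.full((rows, cols), float(value)) for v in variables}
    return nc.ClimateStack(label=year, geometry=geom, layers=layers)


class TestReadOccurrences:
    def test_malformed_coordinate_row_is_dropped(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("species,year,x,y\n"
                     "inv,2011,1.5,2.5\n"
                     "inv,2011,not-a-number,2.5\n"
                     "inv,2012,3.5,0.5\n")
        records = nc.read_occurrences(p, ROLES)
        assert len(records) == 2
        assert {r.year for r in records} == {2011, 2012}

    def test_missing_required_column_names_it(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("species,year,x\ninv,2011,1.0\n")
        with pytest.raises(FormatError, match="'y'"):
            nc.read_occurrences(p, ROLES)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("species,year,x,y\n")
        assert nc.read_occurrences(p, ROLES) == []

    def test_species_from_filename_convention(self, tmp_path):
        """One-file-per-species exports carry no species column."""
        p = tmp_path / "inv.csv"
        p.write_text("year,x,y\n2011,1.0,1.0\n")
        (rec,) = nc.read_occurrences(p, ROLES, species_id="inv")
        assert rec.species_id == "inv"

    def test_xlsx_and_csv_load_identically(self, tmp_path):
        df = pd.DataFrame({"species": ["inv", "nat"], "year": [2011, 2012],
                           "x": [1.25, 2.75], "y": [0.5, 3.5]})
        df.to_csv(tmp_path / "occ.csv", index=False)
        df.to_excel(tmp_path / "occ.xlsx", index=False)
        assert (nc.read_occurrences(tmp_path / "occ.csv", ROLES)
                == nc.read_occurrences(tmp_path / "occ.xlsx", ROLES))


class TestAttachFeatures:
    def test_cell_center_gets_stored_value(self):
        stack = constant_stack()
        stack.layers["T13"][1, 2] = 42.0
        x, y = stack.geometry.cell_center(1, 2)
        rec = nc.OccurrenceRecord("inv", 2011, x, y)
        table = nc.attach_features([rec], {2011: stack}, ["T13"], ROLES)
        assert table.data.loc[0, "T13"] == 42.0

    def test_point_just_outside_extent_is_excluded(self):
        stack = constant_stack()
        xmax = stack.geometry.extent[1]
        rec = nc.OccurrenceRecord("inv", 2011, xmax + 1e-3, 0.5)
        table = nc.attach_features([rec], {2011: stack}, ["T13"], ROLES)
        assert len(table) == 0
        assert table.n_excluded_outside == 1

    def test_year_matched_join_uses_each_records_stack(self):
        s11 = constant_stack(value=1.0, year=2011)
        s12 = constant_stack(value=9.0, year=2012)
        recs = [nc.OccurrenceRecord("inv", 2011, 0.5, 0.5),
                nc.OccurrenceRecord("inv", 2012, 0.5, 0.5)]
        table = nc.attach_features(recs, {2011: s11, 2012: s12},
                                   ["T13"], ROLES)
        assert table.data["T13"].tolist() == [1.0, 9.0]

    def test_missing_year_error_lists_years(self):
        rec = nc.OccurrenceRecord("inv", 2013, 0.5, 0.5)
        with pytest.raises(Exception, match="2013"):
            nc.attach_features([rec], {2011: constant_stack()},
                               ["T13"], ROLES)

    def test_nodata_cell_is_excluded_and_counted(self):
        stack = constant_stack()
        stack.layers["P02"][0, 0] = np.nan
        x, y = stack.geometry.cell_center(0, 0)
        recs = [nc.OccurrenceRecord("inv", 2011, x, y),
                nc.OccurrenceRecord("nat", 2011, 2.5, 2.5)]
        table = nc.attach_features(recs, {2011: stack}, ["T13", "P02"],
                                   ROLES)
        assert len(table) == 1
        assert table.n_excluded_nodata == 1

    def test_constant_raster_attaches_constant(self):
        stack = constant_stack(value=7.25)
        rng = np.random.default_rng(0)
        recs = [nc.OccurrenceRecord("inv", 2011, float(x), float(y))
                for x, y in rng.uniform(0.01, 3.99, size=(30, 2))]
        table = nc.attach_features(recs, {2011: stack}, ["T13"], ROLES)
        assert (table.data["T13"] == 7.25).all()

    def test_idempotent_and_order_preserving(self):
        stack = constant_stack()
        rng = np.random.default_rng(1)
        recs = [nc.OccurrenceRecord("inv", 2011, float(x), float(y))
                for x, y in rng.uniform(0.01, 3.99, size=(10, 2))]
        t1 = nc.attach_features(recs, {2011: stack}, ["T13"], ROLES)
        t2 = nc.attach_features(recs, {2011: stack}, ["T13"], ROLES)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert t1.data["x"].tolist() == [r.x for r in recs]

    def test_join_reproduces_generator_values(self, small_world):
        """Synthetic occurrences joined back to their stack recover the
        generating cell values exactly."""
        stack = nc.generate_climate_stack(small_world, 2011)
        niche = nc.NicheSpec("inv", {"T13": nc.NicheResponse(8.5, 2.0, 0.6)},
                             abundance=100)
        recs = nc.generate_occurrences(small_world, niche, stack, seed=3,
                                       count=50)
        table = nc.attach_features(recs, {2011: stack},
                                   list(small_world.variables),
                                   {"inv": "invasive", "pad": "native"})
        geom = small_world.geometry
        for i, rec in enumerate(recs):
            row, col = geom.cell_of(rec.x, rec.y)
            for var in small_world.variables:
                assert table.data.loc[i, var] == stack.layers[var][row, col]


class TestFeatureTableRoundTrip:
    def _table(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({
            "species": ["inv"] * 5 + ["nat"] * 5,
            "year": [2011] * 10,
            "x": rng.uniform(0, 4, 10), "y": rng.uniform(0, 4, 10),
            "label": ["invasive"] * 5 + ["native"] * 5,
            "T13": rng.normal(8, 1, 10), "D15": rng.normal(12, 3, 10),
        })
        return nc.FeatureTable(data, ["T13", "D15"])

    def test_write_read_is_value_identical(self, tmp_path):
        table = self._table()
        nc.write_feature_table(table, tmp_path / "t.csv")
        back = nc.read_feature_table(tmp_path / "t.csv")
        assert back.variables == table.variables
        pd.testing.assert_frame_equal(back.data, table.data,
                                      check_dtype=False)

    def test_xlsx_and_csv_give_identical_tables(self, tmp_path):
        table = self._table()
        nc.write_feature_table(table, tmp_path / "t.csv")
        nc.write_feature_table(table, tmp_path / "t.xlsx")
        a = nc.read_feature_table(tmp_path / "t.csv")
        b = nc.read_feature_table(tmp_path / "t.xlsx")
        pd.testing.assert_frame_equal(a.data, b.data, check_dtype=False,
                                      check_exact=False)

    def test_missing_requested_variable_column(self, tmp_path):
        table = self._table()
        nc.write_feature_table(table, tmp_path / "t.csv")
        with pytest.raises(FormatError, match="P06"):
            nc.read_feature_table(tmp_path / "t.csv", variables=["T13", "P06"])

    def test_non_numeric_covariate_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,year,x,y,label,T13\n"
                     "inv,2011,1,1,invasive,8.0\n"
                     "nat,2011,2,2,native,oops\n")
        with pytest.raises(FormatError, match="row 1"):
            nc.read_feature_table(p)


class TestAsciiGrids:
    def test_round_trip_preserves_values_nodata_and_geometry(self, tmp_path):
        geom = GridGeometry(rows=3, cols=5, cell_size=2.0, x0=10.0)
        rng = np.random.default_rng(4)
        values = rng.normal(size=(3, 5))
        values[1, 3] = np.nan
        nc.write_ascii_grid(tmp_path / "g.asc", values, geom)
        back, geom2 = nc.read_ascii_grid(tmp_path / "g.asc")
        assert geom2 == geom
        np.testing.assert_allclose(back, values, rtol=1e-9)
        assert np.isnan(back[1, 3])

    def test_stack_manifest_round_trip(self, tmp_path, small_world):
        stacks = [nc.generate_climate_stack(small_world, y)
                  for y in small_world.years]
        manifest = nc.write_stacks(stacks, tmp_path)
        back = nc.read_stacks(manifest)
        assert set(back) == {str(y) for y in small_world.years}
        for stack in stacks:
            got = back[str(stack.label)]
            assert got.geometry == stack.geometry
            for var in stack.variables:
                np.testing.assert_allclose(got.layers[var],
                                           stack.layers[var], rtol=1e-9)
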