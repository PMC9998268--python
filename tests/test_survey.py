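import numpy as np
import pandas as pd
import pytest

from upslope import (
    apply_filters,
    collapse_to_presence,
    read_occurrences,
    surveyed_elevations,
)
from upslope.survey import (
    InputError,
    OccurrenceRecord,
    SchemaError,
    design_from_records,
    read_presence_tables,
    write_presence_tables,
)


def _write_csv(tmp_path, df, name="occ.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_csv_frame():
    return pd.DataFrame(
        {
            "region": ["A"] * 10,
            "road": ["r1"] * 10,
            "transect": [f"t{i % 5}" for i in range(10)],
            "elevation": np.linspace(500, 900, 10),
            "distance_class": [0, 50] * 5,
            "year": [2008] * 5 + [2013] * 5,
            "species": ["sp1", "sp2"] * 5,
        }
    )


class TestReadOccurrences:
    def test_reads_all_rows(self, tmp_path, toy_csv_frame):
        records = read_occurrences(_write_csv(tmp_path, toy_csv_frame))
        assert len(records) == 10
        assert records[0].region == "A"

    def test_bad_elevation_reported_with_row_index(self, tmp_path, toy_csv_frame):
        toy_csv_frame.loc[3, "elevation"] = "n/a"
        with pytest.raises(InputError, match="row 3"):
            read_occurrences(_write_csv(tmp_path, toy_csv_frame))

    def test_extra_columns_ignored(self, tmp_path, toy_csv_frame):
        toy_csv_frame["observer"] = "someone"
        records = read_occurrences(_write_csv(tmp_path, toy_csv_frame))
        assert len(records) == 10

    def test_missing_column_is_schema_error(self, tmp_path, toy_csv_frame):
        with pytest.raises(SchemaError, match="species"):
            read_occurrences(_write_csv(tmp_path, toy_csv_frame.drop(columns=["species"])))

    def test_empty_file_is_input_error(self, tmp_path, toy_csv_frame):
        with pytest.raises(InputError, match="empty"):
            read_occurrences(_write_csv(tmp_path, toy_csv_frame.iloc[:0]))

    def test_schema_mapping_renames_columns(self, tmp_path, toy_csv_frame):
        df = toy_csv_frame.rename(columns={"elevation": "elev_m", "species": "taxon"})
        records = read_occurrences(
            _write_csv(tmp_path, df), schema={"elevation": "elev_m", "species": "taxon"}
        )
        assert {r.species for r in records} == {"sp1", "sp2"}


class TestCollapse:
    def test_plots_collapse_to_single_presence(self, toy_tables):
        table = toy_tables[("A", 2008)]
        # speciesX recorded at 0 m and 50 m of transect t1 -> one presence
        assert table.frequency("speciesX") == 2  # t1 and t2
        assert len(table.occupancy[table.occupancy.species == "speciesX"]) == 2

    def test_frequency_counts_transects(self, toy_tables):
        assert toy_tables[("B", 2008)].frequency("c") == 3

    def test_distance_class_subsetting(self, toy_records):
        roadside = collapse_to_presence(toy_records, distance_classes=[0])
        assert roadside[("A", 2008)].frequency("speciesX") == 2
        with pytest.raises(ValueError):
            collapse_to_presence(toy_records, distance_classes=[25])

    def test_collapse_idempotent(self, toy_tables):
        again = collapse_to_presence(
            [r for t in toy_tables.values() for r in t.to_records()]
        )
        for key, table in toy_tables.items():
            pd.testing.assert_frame_equal(
                table.occupancy.reset_index(drop=True),
                again[key].occupancy.reset_index(drop=True),
            )

    def test_roundtrip_through_csv(self, toy_tables, tmp_path):
        path = tmp_path / "presence.csv"
        write_presence_tables(toy_tables, path)
        back = read_presence_tables(path)
        assert set(back) == set(toy_tables)
        for key in toy_tables:
            pd.testing.assert_frame_equal(
                toy_tables[key].occupancy.reset_index(drop=True),
                back[key].occupancy.reset_index(drop=True),
            )


def _freq_records(region, freqs, years=(2008, 2018)):
    """Records giving each species an exact per-year frequency."""
    rows = []
    for sp, per_year in freqs.items():
        for year, k in zip(years, per_year):
            for i in range(k):
                rows.append(
                    OccurrenceRecord(
                        region=region, road="r1", transect=f"t{i}",
                        elevation=500.0 + 10 * i, distance_class=0, year=year, species=sp,
                    )
                )
    return rows


class TestFilters:
    def test_singleton_excludes_once_recorded_species(self):
        tables = collapse_to_presence(
            _freq_records("A", {"once": (1, 0), "kept": (3, 3), "s2": (2, 2),
                                "s3": (1, 1), "s4": (2, 0), "s5": (0, 2)})
        )
        filtered, report = apply_filters(tables, "singleton")
        assert "once" in set(report["species"])
        assert "once" not in filtered[("A", 2008)].species

    @pytest.mark.parametrize(
        "filter_id,total,kept",
        [("f1", 5, False), ("f1", 6, True), ("f2", 10, False), ("f2", 11, True)],
    )
    def test_strict_inequality_thresholds(self, filter_id, total, kept):
        half = total // 2
        freqs = {"probe": (half, total - half)}
        # pad with common species so the region itself survives
        for j in range(5):
            freqs[f"common{j}"] = (8, 8)
        filtered, _ = apply_filters(collapse_to_presence(_freq_records("A", freqs)), filter_id)
        assert ("probe" in filtered[("A", 2008)].species) is kept

    def test_f3_requires_passing_both_years(self):
        freqs = {"both": (11, 11), "firstonly": (11, 2)}
        for j in range(5):
            freqs[f"common{j}"] = (12, 12)
        filtered, _ = apply_filters(collapse_to_presence(_freq_records("A", freqs)), "f3")
        assert "both" in filtered[("A", 2008)].species
        assert "firstonly" not in filtered[("A", 2008)].species

    def test_region_dropped_below_min_species(self):
        tables = collapse_to_presence(
            _freq_records("A", {f"sp{j}": (12, 12) for j in range(4)})
            + _freq_records("B", {f"sp{j}": (12, 12) for j in range(6)})
        )
        filtered, report = apply_filters(tables, "f3")
        assert not any(region == "A" for region, _ in filtered)
        assert ("B", 2008) in filtered
        dropped = report[report["species"] == "*"]
        assert list(dropped["region"]) == ["A"]

    def test_filters_are_monotone(self):
        freqs = {f"sp{j}": (j + 1, j + 1) for j in range(12)}
        tables = collapse_to_presence(_freq_records("A", freqs))
        f1, _ = apply_filters(tables, "f1")
        f2, _ = apply_filters(tables, "f2")
        s1 = set(f1[("A", 2008)].species)
        s2 = set(f2[("A", 2008)].species)
        assert s2 <= s1

    def test_unknown_filter_rejected(self, toy_tables):
        with pytest.raises(ValueError, match="filter_id"):
            apply_filters(toy_tables, "f9")


class TestSurveyedElevations:
    def test_region_scope_dedupes_and_sorts(self, toy_design):
        elevs = surveyed_elevations(toy_design, "R01")
        assert np.all(np.diff(elevs) > 0)
        # r1 and r2 coincide, r3 differs -> 20 shared + 20 distinct
        assert len(elevs) == 40

    def test_per_road_scope(self, toy_design):
        per_road = surveyed_elevations(toy_design, "R01", scope="per_road")
        assert set(per_road) == {"r1", "r2", "r3"}
        assert len(per_road["r1"]) == 20

    def test_unknown_region_raises(self, toy_design):
        with pytest.raises(KeyError):
            surveyed_elevations(toy_design, "Atlantis")


def test_design_from_records_infers_bounds_years_roads(toy_records):
    design = design_from_records(toy_records)
    assert design["A"].bounds == (600.0, 1000.0)
    assert design["A"].years == (2008, 2018)
    assert set(design["B"].roads) == {"r1"}
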