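"""Ingestion, filtering and decade-binning of occurrence records."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cjsdecline import (
    ConfigurationError,
    OccasionGrid,
    RecordSet,
    build_detection_histories,
    count_species_records,
    filter_by_years,
    read_records,
    summarize,
)


class TestReadRecords:
    def test_direct_parse(self):
        rs = read_records(
            io.StringIO(
                "species,locality_id,country,year\n"
                "A,L1,AT,1950\nA,L2,AT,1960\nB,L1,AT,1970\n"
            )
        )
        assert len(rs) == 3 and rs.n_undated == 0
        first = next(iter(rs))
        assert first == ("A", "L1", "AT", 1950)

    def test_blank_year_kept_and_flagged(self, small_records):
        assert len(small_records) == 9
        assert small_records.n_undated == 1

    def test_unparseable_year_warns(self):
        with pytest.warns(UserWarning, match="unparseable"):
            rs = read_records(
                io.StringIO("species,locality_id,country,year\nA,L1,AT,ca.1900\n")
            )
        assert len(rs) == 1 and rs.n_undated == 1

    @pytest.mark.parametrize("sep", [",", ";", "\t"])
    def test_delimiter_autodetect(self, sep):
        text = sep.join(["species", "locality_id", "country", "year"]) + "\n"
        text += sep.join(["A", "L1", "AT", "1950"]) + "\n"
        assert len(read_records(io.StringIO(text))) == 1

    def test_column_map(self):
        rs = read_records(
            io.StringIO("sp;site;land;jahr\nA;L1;AT;1950\n"),
            column_map={
                "species": "sp", "locality_id": "site",
                "country": "land", "year": "jahr",
            },
        )
        assert next(iter(rs)).locality_id == "L1"

    def test_missing_column_names_the_column(self):
        with pytest.raises(ConfigurationError, match="year"):
            read_records(io.StringIO("species,locality_id,country\nA,L1,AT\n"))

    def test_empty_file_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            rs = read_records(io.StringIO(""))
        assert len(rs) == 0

    def test_csv_round_trip(self, small_records, tmp_path):
        path = tmp_path / "rt.csv"
        small_records.to_csv(path)
        again = read_records(path)
        assert list(again) == list(small_records)

    def test_out_of_range_year_becomes_undated(self):
        with pytest.warns(UserWarning, match="outside"):
            rs = RecordSet(
                pd.DataFrame(
                    {"species": ["A"], "locality_id": ["L1"],
                     "country": ["AT"], "year": [1500]}
                )
            )
        assert rs.n_undated == 1


class TestFilterByYears:
    def test_hand_counted_window(self, small_records):
        # in 1900-2019: all but the 1880 record and the undated one
        out = filter_by_years(small_records, 1900, 2019)
        assert len(out) == 7
        assert out.n_undated == 0

    def test_idempotent(self, small_records):
        once = filter_by_years(small_records, 1900, 2019)
        twice = filter_by_years(once, 1900, 2019)
        assert once == twice

    def test_commutes_with_species_subset(self, small_records):
        sub_then_filter = filter_by_years(
            small_records.subset(
                small_records.frame["species"] == "Jordanita globulariae"
            ),
            1900, 2019,
        )
        filter_then_sub = filter_by_years(small_records, 1900, 2019)
        filter_then_sub = filter_then_sub.subset(
            filter_then_sub.frame["species"] == "Jordanita globulariae"
        )
        assert sub_then_filter == filter_then_sub

    def test_inverted_bounds(self, small_records):
        with pytest.raises(ValueError, match="inverted"):
            filter_by_years(small_records, 2000, 1900)

    def test_empty_input(self):
        empty = RecordSet(pd.DataFrame(columns=["species", "locality_id", "country", "year"]))
        assert len(filter_by_years(empty, 1900, 2019)) == 0


class TestCountSpecies:
    def test_hand_count(self, small_records):
        assert count_species_records(small_records, "Adscita statices") == 4

    def test_absent_species(self, small_records):
        assert count_species_records(small_records, "Zygaena filipendulae") == 0


class TestOccasionGrid:
    def test_decades_1900_2019(self):
        grid = OccasionGrid(1900, 2019, 10)
        assert grid.n_occasions == 12
        assert grid.occasions[0] == (1900, 1909)
        assert grid.labels[-1] == "2010-2019"
        assert grid.index_of(1909) == 0 and grid.index_of(1910) == 1

    def test_indivisible_span_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            OccasionGrid(1900, 2015, 10)

    def test_year_outside_span(self):
        with pytest.raises(ValueError, match="outside"):
            OccasionGrid(1900, 2019).index_of(1899)


class TestDetectionHistories:
    def test_hand_binning(self, small_records):
        rs = filter_by_years(small_records, 1900, 2019)
        hist = build_detection_histories(rs, OccasionGrid(1900, 2019))
        row = hist.matrix[hist.locality_ids.index("L1")]
        # records 1905 and 1963 -> occasions 1 and 7 (1-based)
        assert list(np.flatnonzero(row)) == [0, 6]

    def test_same_decade_collapses(self):
        rs = read_records(
            io.StringIO(
                "species,locality_id,country,year\n"
                "A,L1,AT,1954\nA,L1,AT,1956\nA,L1,AT,1958\n"
            )
        )
        hist = build_detection_histories(rs, OccasionGrid(1900, 2019))
        assert hist.matrix.sum() == 1
        assert hist.matrix[0, 5] == 1  # occasion 6, 1-based

    def test_empty_recordset(self):
        empty = RecordSet(pd.DataFrame(columns=["species", "locality_id", "country", "year"]))
        hist = build_detection_histories(empty, OccasionGrid(1900, 2019))
        assert hist.n_histories == 0 and hist.T == 12

    def test_out_of_span_record_rejected_with_rows(self, small_records):
        with pytest.raises(ValueError, match="rows"):
            build_detection_histories(small_records, OccasionGrid(1900, 2019))

    def test_record_order_invariance(self, small_records):
        rs = filter_by_years(small_records, 1900, 2019)
        shuffled = RecordSet(rs.frame.sample(frac=1.0, random_state=5))
        a = build_detection_histories(rs, OccasionGrid(1900, 2019))
        b = build_detection_histories(shuffled, OccasionGrid(1900, 2019))
        assert a.locality_ids == b.locality_ids
        assert np.array_equal(a.matrix, b.matrix)

    def test_stratified_shared_locality(self, small_records):
        rs = filter_by_years(small_records, 1900, 2019)
        hist = build_detection_histories(
            rs, OccasionGrid(1900, 2019), stratify_by=["species"]
        )
        # L3 appears under both species -> two separate histories
        assert hist.locality_ids.count("L3") == 2
        one_species = hist.for_stratum(species="Adscita statices")
        assert one_species.locality_ids.count("L3") == 1

    @given(
        years=st.lists(
            st.tuples(st.integers(0, 4), st.integers(1900, 2019)),
            min_size=1, max_size=30,
        )
    )
    @settings(deadline=None, max_examples=40)
    def test_detections_bounded_by_records(self, years):
        frame = pd.DataFrame(
            {
                "species": "A",
                "locality_id": [f"L{i}" for i, _ in years],
                "country": "AT",
                "year": [y for _, y in years],
            }
        )
        rs = RecordSet(frame)
        hist = build_detection_histories(rs, OccasionGrid(1900, 2019))
        assert hist.matrix.sum() <= len(rs)
        assert hist.matrix.any(axis=1).all()


class TestSummarize:
    def test_single_record(self):
        rs = read_records(io.StringIO("species,locality_id,country,year\nA,L1,AT,1950\n"))
        s = summarize(rs)
        assert (s.n_records, s.n_dated_records, s.n_localities) == (1, 1, 1)

    def test_shared_locality_counted_once_total(self, small_records):
        s = summarize(small_records)
        assert s.n_records == 9 and s.n_dated_records == 8
        assert s.n_localities == 6  # L3 shared across species counts once
        assert s.per_species.loc["Adscita statices", "localities"] == 3
        assert s.per_species.loc["Jordanita globulariae", "localities"] == 4
        assert s.per_species["localities"].max() <= s.n_localities
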