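"""Coordinate/date normalization and metadata assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coiref.integrate import MergedRecord
from coiref.io_formats import SequenceRecord, Source
from coiref.metadata import (
    build_metadata,
    format_dd,
    parse_collection_date,
    parse_coordinates,
)
from coiref.taxonomy import lineage_from_taxid


class TestCoordinates:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("45.5 N 9.2 E", (45.5, 9.2)),
            ("45.5 S 9.2 W", (-45.5, -9.2)),
            ("45 30 0 S 9 15 0 W", (-45.5, -9.25)),
            ("41.12 N 16.87 E", (41.12, 16.87)),
            ("-12.1, 44.9", (-12.1, 44.9)),
            ((-12.1, "44.9"), (-12.1, 44.9)),
        ],
    )
    def test_dialects(self, raw, expected):
        lat, lon = parse_coordinates(raw)
        assert (lat, lon) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "raw", ["91.0 N 9.2 E", "45.0 N 181.0 E", "not coordinates", "", None, ("x", "y")]
    )
    def test_out_of_range_or_garbage_yields_none(self, raw):
        assert parse_coordinates(raw) is None

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(min_value=-90, max_value=90, allow_nan=False),
        st.floats(min_value=-180, max_value=180, allow_nan=False),
    )
    def test_roundtrip_stable_at_4dp(self, lat, lon):
        first = parse_coordinates((lat, lon))
        assert first is not None
        rendered = f"{format_dd(first[0])} {format_dd(first[1])}"
        second = parse_coordinates(rendered)
        assert second is not None
        assert format_dd(second[0]) == format_dd(first[0])
        assert format_dd(second[1]) == format_dd(first[1])


class TestDates:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("12-Jul-2019", (2019, "2019-07-12")),
            ("2019-07-12", (2019, "2019-07-12")),
            ("2019", (2019, "NA")),
            ("12-Jul-19", ("NA", "NA")),   # two-digit year is ambiguous
            ("summer 2019", ("NA", "NA")),
            ("31-Feb-2019", (2019, "NA")),  # year salvaged, date invalid
            ("", ("NA", "NA")),
        ],
    )
    def test_dialects(self, raw, expected):
        assert parse_collection_date(raw) == expected


def merged_record(ena_meta=None, bold_meta=None, seq="ACGT" * 50):
    ena = bold = None
    if ena_meta is not None:
        ena = SequenceRecord(
            "ACC1", Source.ENA, seq, accession="ACC1", raw_metadata=ena_meta
        )
    if bold_meta is not None:
        bold = SequenceRecord(
            "FIX001-21", Source.BOLD, seq, process_id="FIX001-21", raw_metadata=bold_meta
        )
    prov = "BOTH" if ena and bold else ("ENA_unique" if ena else "BOLD_unique")
    rid = "ACC1" if ena else "FIX001-21"
    return MergedRecord(rid, prov, seq, [rid], ena, bold)


class TestBuildMetadata:
    def test_country_qualifier_split_at_first_colon(self, store):
        rec = merged_record(ena_meta={"country": "Italy: Apulia, Bari"})
        meta = build_metadata(rec, lineage_from_taxid(7227, store), store)
        assert meta.country == "Italy" and meta.region == "Apulia, Bari"
        assert meta.mito_gencode == 5
        assert meta.permalink.endswith("/ACC1")

    def test_bold_numeric_coordinates_pass_through(self, store):
        rec = merged_record(bold_meta={"lat": "-12.1", "lon": "44.9", "country": "Comoros"})
        meta = build_metadata(rec, lineage_from_taxid(7955, store), store)
        assert (meta.lat_dd, meta.lon_dd) == (-12.1, 44.9)
        assert meta.mito_gencode == 2  # vertebrate mitochondrial via lineage
        assert "FIX001-21" in meta.permalink

    def test_host_and_dates(self, store):
        rec = merged_record(
            ena_meta={"host": "Apis mellifera", "collection_date": "12-Jul-2019"}
        )
        meta = build_metadata(rec, lineage_from_taxid(7227, store), store)
        assert meta.host == "Apis mellifera"
        assert (meta.collection_year, meta.collection_date) == (2019, "2019-07-12")

    def test_ena_fields_take_precedence_but_bold_fills_gaps(self, store):
        rec = merged_record(
            ena_meta={"country": "Italy: Apulia"},
            bold_meta={"country": "France", "region": "Bari old town",
                       "lat": "41.1", "lon": "16.8"},
        )
        meta = build_metadata(rec, lineage_from_taxid(7227, store), store)
        assert meta.country == "Italy"          # ENA wins
        assert meta.region == "Apulia"          # from the ENA qualifier
        assert (meta.lat_dd, meta.lon_dd) == (41.1, 16.8)  # BOLD fills missing

    def test_missing_everything_is_na(self, store):
        rec = merged_record(ena_meta={})
        meta = build_metadata(rec, lineage_from_taxid(7227, store), store)
        row = meta.as_row()
        for key in ("country", "region", "host", "collection_year", "collection_date",
                    "lat_dd", "lon_dd"):
            assert row[key] == "NA"
        assert row["seq_length"] == 200

    def test_row_has_exactly_the_nine_metadata_fields(self, store):
        meta = build_metadata(
            merged_record(ena_meta={}), lineage_from_taxid(7227, store), store
        )
        assert len(meta.as_row()) == 10  # nine fields; coordinates span two columns
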