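"""Extraction and normalization of the nine per-record metadata fields.

Fields: final sequence length, mitochondrial genetic code, sampling
country, sub-country address, host species, collection year, complete
collection date (ISO-8601), geographic coordinates in signed decimal
degrees, and a permanent link to the source-database entry. Anything
missing or unparseable becomes "NA" — never an exception.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date

from .integrate import MergedRecord
from .io_formats import TaxonomyStore
from .taxonomy import Lineage
from .translation import DEFAULT_MITO_TABLE

logger = logging.getLogger(__name__)

__all__ = [
    "MetadataRecord",
    "PermalinkTemplates",
    "parse_coordinates",
    "parse_collection_date",
    "build_metadata",
    "format_dd",
]

NA = "NA"


@dataclass(frozen=True)
class PermalinkTemplates:
    """URL templates per source; ``{id}`` is the accession or process ID."""

    ena: str = "https://www.ebi.ac.uk/ena/browser/view/{id}"
    bold: str = "http://www.boldsystems.org/index.php/Public_RecordView?processid={id}"


@dataclass
class MetadataRecord:
    """The nine normalized metadata fields of one collection entry."""

    seq_length: int
    mito_gencode: int
    country: str = NA
    region: str = NA
    host: str = NA
    collection_year: object = NA
    collection_date: str = NA
    lat_dd: float | None = None
    lon_dd: float | None = None
    permalink: str = NA

    def as_row(self) -> dict[str, object]:
        return {
            "seq_length": self.seq_length,
            "mito_gencode": self.mito_gencode,
            "country": self.country,
            "region": self.region,
            "host": self.host,
            "collection_year": self.collection_year,
            "collection_date": self.collection_date,
            "lat_dd": format_dd(self.lat_dd),
            "lon_dd": format_dd(self.lon_dd),
            "permalink": self.permalink,
        }


def format_dd(value: float | None) -> str:
    """Decimal degrees at fixed 4-decimal formatting; None -> "NA"."""
    return NA if value is None else f"{value:.4f}"


_DD_PAIR = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*([NS])[\s,]+(\d+(?:\.\d+)?)\s*([EW])\s*$", re.IGNORECASE
)
_DMS_PAIR = re.compile(
    r"^\s*(\d+)\s+(\d+(?:\.\d+)?)\s+(\d+(?:\.\d+)?)\s*([NS])"
    r"[\s,]+(\d+)\s+(\d+(?:\.\d+)?)\s+(\d+(?:\.\d+)?)\s*([EW])\s*$",
    re.IGNORECASE,
)
_SIGNED_PAIR = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?)[\s,]+([+-]?\d+(?:\.\d+)?)\s*$")


def _in_range(lat: float, lon: float):
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        logger.warning("coordinates out of range: lat=%s lon=%s", lat, lon)
        return None
    return lat, lon


def parse_coordinates(raw) -> tuple[float, float] | None:
    """Normalize coordinates to signed decimal degrees.

    Accepts the INSDC ``lat_lon`` dialect ("41.12 N 16.87 E"), a
    degrees-minutes-seconds string ("45 30 0 S 9 15 0 W"), a signed numeric
    string pair, or a (lat, lon) pair of numbers. S and W hemispheres are
    negative; DMS converts as deg + min/60 + sec/3600. Out-of-range or
    unparseable input yields None, never an exception.
    """
    if raw is None:
        return None
    if isinstance(raw, (tuple, list)) and len(raw) == 2:
        try:
            return _in_range(float(raw[0]), float(raw[1]))
        except (TypeError, ValueError):
            return None
    if not isinstance(raw, str) or not raw.strip():
        return None
    m = _DMS_PAIR.match(raw)
    if m:
        lat = int(m.group(1)) + float(m.group(2)) / 60 + float(m.group(3)) / 3600
        lon = int(m.group(5)) + float(m.group(6)) / 60 + float(m.group(7)) / 3600
        if m.group(4).upper() == "S":
            lat = -lat
        if m.group(8).upper() == "W":
            lon = -lon
        return _in_range(lat, lon)
    m = _DD_PAIR.match(raw)
    if m:
        lat = float(m.group(1)) * (-1 if m.group(2).upper() == "S" else 1)
        lon = float(m.group(3)) * (-1 if m.group(4).upper() == "W" else 1)
        return _in_range(lat, lon)
    m = _SIGNED_PAIR.match(raw)
    if m:
        return _in_range(float(m.group(1)), float(m.group(2)))
    return None


_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}
_DMY = re.compile(r"^\s*(\d{1,2})-([A-Za-z]{3})-(\d{4})\s*$")
_ISO = re.compile(r"^\s*(\d{4})-(\d{2})-(\d{2})\s*$")
_YEAR = re.compile(r"^\s*(\d{4})\s*$")


def parse_collection_date(raw) -> tuple[object, str]:
    """Extract (year, ISO date) from a collection-date string.

    Dialects: "DD-MMM-YYYY" (flat files), "YYYY-MM-DD", bare "YYYY".
    Two-digit years ("DD-MMM-YY") are rejected as ambiguous. The year is
    returned whenever any dialect matches; the complete ISO date only when
    day and month are present and valid. No match -> ("NA", "NA").
    """
    if not isinstance(raw, str) or not raw.strip():
        return NA, NA
    m = _DMY.match(raw)
    if m:
        day, mon, year = int(m.group(1)), _MONTHS.get(m.group(2).lower()), int(m.group(3))
        if mon:
            try:
                return year, date(year, mon, day).isoformat()
            except ValueError:
                return year, NA
        return NA, NA
    m = _ISO.match(raw)
    if m:
        year, mon, day = (int(g) for g in m.groups())
        try:
            return year, date(year, mon, day).isoformat()
        except ValueError:
            return year, NA
    m = _YEAR.match(raw)
    if m:
        return int(m.group(1)), NA
    return NA, NA


def _split_country(raw: str) -> tuple[str, str]:
    """INSDC country qualifier "Country: region, locality" -> (country, region)."""
    if ":" in raw:
        country, region = raw.split(":", 1)
        return country.strip(), region.strip() or NA
    return raw.strip(), NA


def build_metadata(
    record: MergedRecord,
    lineage: Lineage,
    store: TaxonomyStore,
    templates: PermalinkTemplates = PermalinkTemplates(),
    default_mito_table: int = DEFAULT_MITO_TABLE,
) -> MetadataRecord:
    """Assemble the normalized metadata for one merged record.

    ENA qualifiers take precedence; BOLD columns fill whatever is missing.
    The mitochondrial genetic code comes from the lowest resolved taxid of
    the harmonized lineage (default table for unresolved records).
    """
    ena_meta = dict(record.ena.raw_metadata) if record.ena is not None else {}
    bold_meta = dict(record.bold.raw_metadata) if record.bold is not None else {}

    country, region = NA, NA
    if "country" in ena_meta:
        country, region = _split_country(ena_meta["country"])
    elif "country" in bold_meta:
        country = bold_meta["country"].strip() or NA
    if region == NA and bold_meta.get("region", "").strip():
        region = bold_meta["region"].strip()

    host = ena_meta.get("host", "").strip() or NA

    coords = None
    if "lat_lon" in ena_meta:
        coords = parse_coordinates(ena_meta["lat_lon"])
    if coords is None and "lat" in bold_meta and "lon" in bold_meta:
        coords = parse_coordinates((bold_meta["lat"], bold_meta["lon"]))
    lat_dd, lon_dd = coords if coords is not None else (None, None)

    year, iso = NA, NA
    for raw_date in (ena_meta.get("collection_date"), bold_meta.get("collection_date")):
        if raw_date:
            year, iso = parse_collection_date(raw_date)
            if year != NA:
                break

    taxid = lineage.lowest_resolved_taxid()
    mito = store.mito_gencode_id(taxid) if taxid is not None else None
    if not mito:
        mito = default_mito_table

    if record.ena is not None:
        permalink = templates.ena.format(id=record.accession)
    else:
        link_id = record.bold.process_id or record.record_id
        permalink = templates.bold.format(id=link_id)

    return MetadataRecord(
        seq_length=len(record.sequence),
        mito_gencode=mito,
        country=country,
        region=region,
        host=host,
        collection_year=year,
        collection_date=iso,
        lat_dd=lat_dd,
        lon_dd=lon_dd,
        permalink=permalink,
    )
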