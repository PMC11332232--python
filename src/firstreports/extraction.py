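"""Extraction-record data model, the extraction prompt, and the bar-delimited table dialect.

An emerging-infectious-disease "first report" is an abstract-length note
announcing a plant pathogen's first detection on a host or in a region.  A
structured extraction from one report is a small table with eight columns
(pathogen, host, incidence percentage, year, location, country, latitude,
longitude), one row per pathogen x host x location combination.  Because the
extracting language model returns the whole table as a single text string,
the dialect uses a vertical bar as the column delimiter (locations may
contain commas) and the literal token ``NA`` for missing values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields as dataclass_fields
from typing import Callable, Optional, Sequence

__all__ = [
    "COLUMNS",
    "ExtractionRecord",
    "Report",
    "RowError",
    "FieldAnomaly",
    "ParseResult",
    "InvalidRecordError",
    "ExtractorError",
    "Extractor",
    "build_prompt",
    "parse_extraction_table",
    "write_extraction_table",
]

#: Canonical column order of the extraction-table dialect.
COLUMNS = (
    "Pathogen",
    "Host",
    "Percentage",
    "Year",
    "Location",
    "Country",
    "Latitude",
    "Longitude",
)

#: Maximum abstract length in characters (journal guideline for first reports).
MAX_ABSTRACT_CHARS = 2985

#: Missing-value token of the table dialect (exact, case-sensitive after trim).
NA_TOKEN = "NA"


class InvalidRecordError(ValueError):
    """An extraction record violates a field constraint.

    ``field`` names the offending column.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ExtractorError(RuntimeError):
    """Raised by an extractor when it cannot produce a table for a report."""


#: Extractor contract: a callable mapping (title, abstract) to one raw text
#: string in the bar-delimited dialect.  A live API adapter must satisfy this
#: signature; the package ships a deterministic mock (``synthetic.MockExtractor``).
Extractor = Callable[[str, str], str]


@dataclass(frozen=True)
class ExtractionRecord:
    """One row of the eight-column extraction table; every field is nullable.

    ``year`` is kept as text because reports sometimes give a span of years
    ("2019-2020"); numeric interpretation is deferred to field comparison.
    Coordinates are signed decimal degrees only -- degrees-minutes-seconds
    never reaches this type.
    """

    pathogen: Optional[str] = None
    host: Optional[str] = None
    percentage: Optional[float] = None
    year: Optional[str] = None
    location: Optional[str] = None
    country: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if all(getattr(self, f.name) is None for f in dataclass_fields(self)):
            raise InvalidRecordError("record", "all eight fields missing")
        for name in ("pathogen", "host", "year", "location", "country"):
            value = getattr(self, name)
            if value is None:
                continue
            if not isinstance(value, str) or not value.strip():
                raise InvalidRecordError(name, "must be non-empty text or missing")
            if "|" in value or "\n" in value:
                raise InvalidRecordError(name, "must not contain '|' or newline")
        if self.percentage is not None and not 0.0 <= float(self.percentage) <= 100.0:
            raise InvalidRecordError("percentage", f"{self.percentage} outside [0, 100]")
        if self.latitude is not None and not -90.0 <= float(self.latitude) <= 90.0:
            raise InvalidRecordError("latitude", f"{self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= float(self.longitude) <= 180.0:
            raise InvalidRecordError("longitude", f"{self.longitude} outside [-180, 180]")

    def coordinates(self) -> Optional[tuple[float, float]]:
        """(lat, lon) when both axes are present, else None."""
        if self.latitude is None or self.longitude is None:
            return None
        return (float(self.latitude), float(self.longitude))


@dataclass(frozen=True)
class Report:
    """One first-report text: identifier, title, abstract, optional ground truth.

    ``truth`` is populated by the synthetic generator; real corpus texts carry
    no truth and are validated against independently produced reference tables.
    """

    report_id: str
    title: str
    abstract: str
    truth: Optional[tuple[ExtractionRecord, ...]] = None

    def __post_init__(self) -> None:
        if not self.abstract or not self.abstract.strip():
            raise ValueError("abstract must be non-empty")
        if len(self.abstract) > MAX_ABSTRACT_CHARS:
            raise ValueError(
                f"abstract exceeds {MAX_ABSTRACT_CHARS} characters "
                f"({len(self.abstract)})"
            )
        if self.truth is not None and not isinstance(self.truth, tuple):
            object.__setattr__(self, "truth", tuple(self.truth))


# The extraction prompt sent ahead of each report.  Wording is fixed: the
# downstream parser and the matching rules assume exactly this output format
# (decimal-degree coordinates, NA for missing, vertical-bar delimiter).
PROMPT_TEMPLATE = """\
The following is an abstract describing a plant pathogen on a new host or in a new geographic area.

I’d like to know (i) what is the scientific name of the pathogen?

(ii) what is the scientific name of the host?

(iii) what percentage of hosts were infected by the pathogen?

(iv) what year was the pathogen sampled?

(v) where was the pathogen observed?

(vi) what country was the pathogen observed in? and

(vii) what are the latitude/longitude, in decimal degrees, of the location where the pathogen was observed.

For the coordinates, don’t include letters to indicate the cardinal directions, but use negative numbers to indicate west and south.

It is very important that the latitude and longitude be returned in decimal degrees.

If there are multiple pathogens, hosts, or locations, include each as a separate row.

If any of the information is not included in the abstract, use NA.

Use a vertical bar | to delimit the table. Use the column names: ‘Pathogen’ [scientific name of pathogen], ‘Host’ [scientific name of host], ‘Percentage’ [percent of hosts infected], ‘Year’ [year pathogen was sampled], ‘Location’ [location where the pathogen was observed], ‘Country’ [country where pathogen was observed], ‘Latitude’ [latitude in decimal degrees], ‘Longitude’ [longitude in decimal degrees].

Always use scientific names when possible. Do not summarize the abstract. Return only a table. Here is the title, followed by the abstract:"""


def build_prompt(title: str, abstract: str) -> str:
    """Assemble the full extraction prompt for one report.

    The fixed instruction block is followed by the title and then the
    abstract, each separated by a blank line.
    """
    if not title or not title.strip():
        raise ValueError("title must be non-empty")
    if not abstract or not abstract.strip():
        raise ValueError("abstract must be non-empty")
    return f"{PROMPT_TEMPLATE}\n\n{title}\n\n{abstract}"


@dataclass(frozen=True)
class RowError:
    """A table row that could not be turned into a record at all."""

    row_index: int  # 0-based index over data rows (header excluded)
    text: str
    reason: str


@dataclass(frozen=True)
class FieldAnomaly:
    """A single cell that was malformed; the field was set to missing."""

    row_index: int
    column: str
    value: str
    reason: str


@dataclass(frozen=True)
class ParseResult:
    """Outcome of parsing one raw table string.

    Invariant: ``rows_in == len(records) + len(row_errors)`` -- every data row
    is accounted for, never silently dropped.
    """

    records: tuple[ExtractionRecord, ...]
    row_errors: tuple[RowError, ...]
    field_anomalies: tuple[FieldAnomaly, ...]

    @property
    def rows_in(self) -> int:
        return len(self.records) + len(self.row_errors)


_NA_VARIANT_RE = re.compile(r"^(?:na|n/a|n\.a\.?)$", re.IGNORECASE)
_DMS_CHARS = set("°′″'\"NSEWnsew")


def _is_header(cells: Sequence[str]) -> bool:
    return len(cells) == len(COLUMNS) and all(
        c.strip().lower() == name.lower() for c, name in zip(cells, COLUMNS)
    )


def _parse_cell_text(
    cell: str, row_index: int, column: str, anomalies: list[FieldAnomaly]
) -> Optional[str]:
    if cell == NA_TOKEN:
        return None
    if cell == "":
        anomalies.append(FieldAnomaly(row_index, column, cell, "empty field"))
        return None
    if _NA_VARIANT_RE.match(cell):
        # Only the exact token "NA" denotes missing; variants are kept as
        # text but flagged so downstream audits can spot drift in the output
        # conventions.
        anomalies.append(
            FieldAnomaly(row_index, column, cell, "non-canonical NA variant kept as text")
        )
    return cell


def _parse_percentage(
    cell: str, row_index: int, anomalies: list[FieldAnomaly]
) -> Optional[float]:
    if cell == NA_TOKEN:
        return None
    if cell == "":
        anomalies.append(FieldAnomaly(row_index, "Percentage", cell, "empty field"))
        return None
    text = cell[:-1].strip() if cell.endswith("%") else cell
    try:
        value = float(text)
    except ValueError:
        anomalies.append(
            FieldAnomaly(row_index, "Percentage", cell, "unparseable number")
        )
        return None
    if not 0.0 <= value <= 100.0:
        anomalies.append(
            FieldAnomaly(row_index, "Percentage", cell, "outside [0, 100]")
        )
        return None
    return value


def _parse_coordinate(
    cell: str,
    row_index: int,
    column: str,
    bound: float,
    anomalies: list[FieldAnomaly],
) -> Optional[float]:
    if cell == NA_TOKEN:
        return None
    if cell == "":
        anomalies.append(FieldAnomaly(row_index, column, cell, "empty field"))
        return None
    try:
        value = float(cell)
    except ValueError:
        if any(ch in _DMS_CHARS for ch in cell):
            # The prompt demands plain signed decimals; DMS glyphs or
            # cardinal letters mean the conversion instruction was ignored.
            reason = "not a plain signed decimal (DMS?)"
        else:
            reason = "unparseable number"
        anomalies.append(FieldAnomaly(row_index, column, cell, reason))
        return None
    if not -bound <= value <= bound:
        anomalies.append(
            FieldAnomaly(row_index, column, cell, f"outside [-{bound}, {bound}]")
        )
        return None
    return value


def parse_extraction_table(raw: str) -> ParseResult:
    """Parse a raw bar-delimited table string into extraction records.

    A first row whose cells equal the canonical column names
    (case-insensitive) is consumed as a header.  Rows with a field count
    other than eight become :class:`RowError` entries; malformed numeric
    cells become :class:`FieldAnomaly` entries with the field set missing.
    Row order is preserved.
    """
    lines = [ln for ln in raw.replace("\r\n", "\n").split("\n") if ln.strip()]
    if lines and _is_header(lines[0].split("|")):
        lines = lines[1:]

    records: list[ExtractionRecord] = []
    row_errors: list[RowError] = []
    anomalies: list[FieldAnomaly] = []
    for idx, line in enumerate(lines):
        cells = [c.strip() for c in line.split("|")]
        if len(cells) != len(COLUMNS):
            row_errors.append(
                RowError(idx, line, f"expected 8 fields, found {len(cells)}")
            )
            continue
        pathogen = _parse_cell_text(cells[0], idx, "Pathogen", anomalies)
        host = _parse_cell_text(cells[1], idx, "Host", anomalies)
        percentage = _parse_percentage(cells[2], idx, anomalies)
        year = _parse_cell_text(cells[3], idx, "Year", anomalies)
        location = _parse_cell_text(cells[4], idx, "Location", anomalies)
        country = _parse_cell_text(cells[5], idx, "Country", anomalies)
        latitude = _parse_coordinate(cells[6], idx, "Latitude", 90.0, anomalies)
        longitude = _parse_coordinate(cells[7], idx, "Longitude", 180.0, anomalies)
        values = (pathogen, host, percentage, year, location, country, latitude, longitude)
        if all(v is None for v in values):
            row_errors.append(RowError(idx, line, "all eight fields missing"))
            continue
        records.append(ExtractionRecord(*values))
    return ParseResult(tuple(records), tuple(row_errors), tuple(anomalies))


def _format_value(value) -> str:
    if value is None:
        return NA_TOKEN
    if isinstance(value, float):
        return str(value)
    return str(value)


def write_extraction_table(
    records: Sequence[ExtractionRecord], include_header: bool = True
) -> str:
    """Serialize records to the bar-delimited dialect (inverse of the parser).

    ``parse_extraction_table(write_extraction_table(x)).records`` reproduces
    ``x`` field-for-field for any valid record list.
    """
    lines = ["|".join(COLUMNS)] if include_header else []
    for rec in records:
        if not isinstance(rec, ExtractionRecord):
            raise TypeError(f"not an ExtractionRecord: {rec!r}")
        lines.append(
            "|".join(
                _format_value(getattr(rec, name))
                for name in (
                    "pathogen",
                    "host",
                    "percentage",
                    "year",
                    "location",
                    "country",
                    "latitude",
                    "longitude",
                )
            )
        )
    return "\n".join(lines)
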