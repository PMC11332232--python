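"""Synthetic first-report corpus with known ground truth, plus an error model
that corrupts truth tables the way an imperfect extractor would.

Every abstract is templated prose embedding exactly its truth fields: one
pathogen scientific name, one to three hosts, a year or year span, one or
two named locations in a country, optionally a disease incidence and
optionally coordinates printed in degrees-minutes-seconds with cardinal
letters.  The truth table holds one row per pathogen x host x location.

The error model reproduces the characteristic extractor failure modes:
dropping all but the first host (omission), collapsing a year span to a
single year, inventing a 100% incidence where the report gave none,
perturbing coordinates slightly (conversion slips) or grossly (conversion
failures), appending a spurious row (commission), merging two coordinate
sets into one (conflation), and geocoding locations whose reports printed
no coordinates.  Each applied error is recorded in a ledger so downstream
classifications can be checked against what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .coordinates import (
    DMSCoordinate,
    builtin_boundary_provider,
    decimal_to_dms,
    dms_to_decimal,
    format_dms,
    random_point_within,
)
from .extraction import (
    ExtractionRecord,
    ExtractorError,
    MAX_ABSTRACT_CHARS,
    Report,
    write_extraction_table,
)

__all__ = [
    "CorpusSpec",
    "ErrorModel",
    "InjectedError",
    "CorruptionResult",
    "generate_corpus",
    "corrupt_truth",
    "MockExtractor",
    "DEFAULT_PATHOGENS",
    "DEFAULT_HOSTS",
    "DEFAULT_LOCATIONS",
    "DEFAULT_COUNTRIES",
]

DEFAULT_PATHOGENS = (
    "Fusarium circinatum",
    "Phytophthora ramorum",
    "Cryphonectria parasitica",
    "Ophiostoma novo-ulmi",
    "Hymenoscyphus fraxineus",
    "Ceratocystis platani",
    "Dothistroma septosporum",
    "Xylella fastidiosa",
    "Lecanosticta acicola",
    "Phytophthora sp.",
    "Armillaria mellea",
    "Erysiphe alphitoides",
)

DEFAULT_HOSTS = (
    "Pinus radiata",
    "Quercus robur",
    "Fraxinus excelsior",
    "Castanea sativa",
    "Platanus orientalis",
    "Ulmus minor",
    "Pinus sylvestris",
    "Fagus sylvatica",
    "Acer pseudoplatanus",
    "Alnus glutinosa",
    "Abies alba",
    "Larix decidua",
)

DEFAULT_LOCATIONS = (
    "Monte Verde forest",
    "Riverside nursery",
    "Mount Taro plantation",
    "Lakeview arboretum, east block",
    "Casa Blanca orchard",
    "Northern plateau woodland",
    "Harbor botanical garden",
    "Eastwood reserve",
    "Threeoaks experimental station",
    "Southbank shelterbelt",
)

#: Countries present in the bundled synthetic boundary fixture.
DEFAULT_COUNTRIES = ("Spain", "France", "Italy", "Japan", "Australia", "Chile")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a synthetic corpus.

    Defaults mirror the structure of a real first-report collection: about a
    third of reports print coordinates, about a quarter give an incidence,
    most describe a single host, and a small fraction report two survey
    locations (the precondition for coordinate conflation).
    """

    n_reports: int = 100
    hosts_per_report: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    p_coordinates: float = 0.34
    p_incidence: float = 0.26
    p_second_location: float = 0.08
    p_year_range: float = 0.15
    year_range: tuple[int, int] = (2015, 2023)
    pathogen_pool: Sequence[str] = DEFAULT_PATHOGENS
    host_pool: Sequence[str] = DEFAULT_HOSTS
    location_pool: Sequence[str] = DEFAULT_LOCATIONS
    country_pool: Sequence[str] = DEFAULT_COUNTRIES

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for name in ("p_coordinates", "p_incidence", "p_second_location", "p_year_range"):
            _check_prob(name, getattr(self, name))
        if not self.hosts_per_report or any(k not in (1, 2, 3) for k in self.hosts_per_report):
            raise ValueError("hosts_per_report must be a distribution over {1, 2, 3}")
        weight = sum(self.hosts_per_report.values())
        if abs(weight - 1.0) > 1e-9:
            raise ValueError("hosts_per_report probabilities must sum to 1")
        for pool_name in ("pathogen_pool", "host_pool", "location_pool", "country_pool"):
            if not getattr(self, pool_name):
                raise ValueError(f"{pool_name} must be non-empty")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be an inclusive (lo, hi) span")


@dataclass(frozen=True)
class ErrorModel:
    """Per-row error-injection rates (all probabilities in [0, 1]).

    Defaults approximate the per-case error frequencies observed when a
    temperature-zero generative model extracts this kind of corpus: year
    spans collapse on roughly a tenth of eligible rows, a missing incidence
    is overwhelmingly likely to be invented as 100%, coordinate conversion
    slips are common and outright failures rarer, spurious rows and
    conflations are rare, and nearly every location without printed
    coordinates gets geocoded anyway.
    """

    host_omission_rate: float = 0.08
    year_mismatch_rate: float = 0.10
    incidence_false_positive_rate: float = 0.90
    coord_minor_rate: float = 0.40
    coord_failure_rate: float = 0.20
    commission_rate: float = 0.01
    conflation_rate: float = 0.02
    geocode_rate: float = 1.0
    seed: int = 0
    minor_delta_range: tuple[float, float] = (0.001, 0.2)
    failure_delta_range: tuple[float, float] = (0.05, 2.0)
    geocode_radius: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "host_omission_rate",
            "year_mismatch_rate",
            "incidence_false_positive_rate",
            "coord_minor_rate",
            "coord_failure_rate",
            "commission_rate",
            "conflation_rate",
            "geocode_rate",
        ):
            _check_prob(name, getattr(self, name))
        if self.coord_minor_rate + self.coord_failure_rate > 1.0 + 1e-9:
            raise ValueError("coord_minor_rate + coord_failure_rate must be <= 1")

    @classmethod
    def none(cls, seed: int = 0) -> "ErrorModel":
        """A zero-noise model: output is identical to truth."""
        return cls(
            host_omission_rate=0.0,
            year_mismatch_rate=0.0,
            incidence_false_positive_rate=0.0,
            coord_minor_rate=0.0,
            coord_failure_rate=0.0,
            commission_rate=0.0,
            conflation_rate=0.0,
            geocode_rate=0.0,
            seed=seed,
        )


@dataclass(frozen=True)
class InjectedError:
    """One ledger entry: what was injected, into which truth row."""

    kind: str
    row_index: Optional[int]  # index into the truth table; None for row-level additions
    detail: Mapping = field(default_factory=dict)


@dataclass(frozen=True)
class CorruptionResult:
    records: tuple[ExtractionRecord, ...]
    ledger: tuple[InjectedError, ...]


def _round_seconds(c: DMSCoordinate) -> DMSCoordinate:
    # rounding 59.97" up to 60.0" must carry into minutes (and degrees)
    seconds = round(c.seconds, 1)
    minutes, degrees = int(c.minutes), c.degrees
    if seconds >= 60.0:
        seconds = 0.0
        minutes += 1
    if minutes >= 60:
        minutes = 0
        degrees += 1
    return DMSCoordinate(degrees, float(minutes), seconds, c.hemisphere)


def _quantized_point(lat: float, lon: float) -> tuple[float, float, str]:
    """Snap a decimal point to what its printed DMS form converts back to.

    Returns (lat, lon, printed DMS string); the truth table stores the
    snapped decimals so a faithful reader of the prose agrees with truth.
    """
    dms_lat = _round_seconds(decimal_to_dms(lat, "lat"))
    dms_lon = _round_seconds(decimal_to_dms(lon, "lon"))
    snapped_lat = round(dms_to_decimal(dms_lat), 6)
    snapped_lon = round(dms_to_decimal(dms_lon), 6)
    printed = f"{format_dms(dms_lat)}, {format_dms(dms_lon)}"
    return snapped_lat, snapped_lon, printed


def _host_phrase(hosts: Sequence[str]) -> str:
    if len(hosts) == 1:
        return hosts[0]
    if len(hosts) == 2:
        return f"{hosts[0]} and {hosts[1]}"
    return ", ".join(hosts[:-1]) + f", and {hosts[-1]}"


def _compose_abstract(
    pathogen: str,
    hosts: Sequence[str],
    year_text: str,
    locations: Sequence[tuple[str, Optional[str]]],  # (name, printed DMS or None)
    country: str,
    incidence: Optional[float],
) -> str:
    loc_phrases = []
    for name, printed in locations:
        loc_phrases.append(f"{name} ({printed})" if printed else name)
    sentences = [
        f"{pathogen} is reported for the first time causing disease on "
        f"{_host_phrase(hosts)} in {country}.",
        f"In {year_text}, symptomatic plants were observed at "
        f"{' and at '.join(loc_phrases)}.",
    ]
    if incidence is not None:
        sentences.append(
            f"Disease incidence reached {incidence:g}% of surveyed plants."
        )
    sentences.append(
        "Morphological examination and sequencing of the internal transcribed "
        "spacer region confirmed the identity of the pathogen. Voucher "
        "specimens were deposited in the regional herbarium. To our knowledge, "
        f"this is the first report of {pathogen} on these hosts in {country}."
    )
    return " ".join(sentences)


def generate_corpus(spec: CorpusSpec, seed: int) -> list[Report]:
    """Generate a seeded synthetic corpus; identical (spec, seed) gives
    identical reports.

    Each report's truth table holds one row per pathogen x host x location;
    incidence is shared across the report's rows, coordinates are shared by
    rows of the same location.
    """
    rng = np.random.default_rng(seed)
    provider = builtin_boundary_provider()
    known = set(provider.country_names)
    host_counts = sorted(spec.hosts_per_report)
    host_probs = [spec.hosts_per_report[k] for k in host_counts]
    reports: list[Report] = []
    for i in range(spec.n_reports):
        pathogen = spec.pathogen_pool[rng.integers(len(spec.pathogen_pool))]
        n_hosts = int(rng.choice(host_counts, p=host_probs))
        host_idx = rng.choice(len(spec.host_pool), size=n_hosts, replace=False)
        hosts = [spec.host_pool[j] for j in host_idx]
        country = spec.country_pool[rng.integers(len(spec.country_pool))]
        n_locs = 2 if rng.random() < spec.p_second_location else 1
        loc_idx = rng.choice(len(spec.location_pool), size=n_locs, replace=False)
        loc_names = [spec.location_pool[j] for j in loc_idx]
        y0, y1 = spec.year_range
        year_start = int(rng.integers(y0, y1 + 1))
        if rng.random() < spec.p_year_range and year_start < y1:
            year_text = f"{year_start}-{year_start + 1}"
        else:
            year_text = str(year_start)
        incidence = (
            float(int(rng.integers(1, 101))) if rng.random() < spec.p_incidence else None
        )
        with_coords = rng.random() < spec.p_coordinates

        locations: list[tuple[str, Optional[str], Optional[float], Optional[float]]] = []
        for name in loc_names:
            if with_coords and country in known:
                lat, lon = random_point_within(provider.country_polygon(country), rng)
                slat, slon, printed = _quantized_point(lat, lon)
                locations.append((name, printed, slat, slon))
            else:
                locations.append((name, None, None, None))

        truth = tuple(
            ExtractionRecord(
                pathogen=pathogen,
                host=host,
                percentage=incidence,
                year=year_text,
                location=loc_name,
                country=country,
                latitude=lat,
                longitude=lon,
            )
            for loc_name, _, lat, lon in locations
            for host in hosts
        )
        report_id = f"SR{i:04d}"
        title = (
            f"First report of {pathogen} causing disease of {hosts[0]} "
            f"in {country} ({report_id})"
        )
        abstract = _compose_abstract(
            pathogen,
            hosts,
            year_text,
            [(name, printed) for name, printed, _, _ in locations],
            country,
            incidence,
        )
        if len(abstract) > MAX_ABSTRACT_CHARS:
            raise RuntimeError("template produced an over-long abstract")
        reports.append(Report(report_id, title, abstract, truth))
    return reports


def _clamp(value: float, bound: float) -> float:
    return max(-bound, min(bound, value))


def corrupt_truth(
    truth: Sequence[ExtractionRecord],
    model: ErrorModel,
    rng: Optional[np.random.Generator] = None,
    country_centroids: Optional[Mapping[str, tuple[float, float]]] = None,
) -> CorruptionResult:
    """Apply the error model to one report's truth table.

    Each error type fires independently per eligible row with its configured
    rate (minor and failure coordinate perturbations are mutually exclusive
    per row).  ``rng`` overrides the model-seeded stream so a caller can
    decorrelate repeated per-report applications; with the default, identical
    (truth, model) inputs give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if country_centroids is None:
        provider = builtin_boundary_provider()
        country_centroids = {
            name: (
                provider.country_polygon(name).centroid.y,
                provider.country_polygon(name).centroid.x,
            )
            for name in provider.country_names
        }
    ledger: list[InjectedError] = []
    rows: list[tuple[int, ExtractionRecord]] = list(enumerate(truth))

    # host omission: any row whose host differs from the report's first host
    first_host = truth[0].host if truth else None
    kept: list[tuple[int, ExtractionRecord]] = []
    for idx, rec in rows:
        eligible = rec.host is not None and first_host is not None and rec.host != first_host
        if eligible and rng.random() < model.host_omission_rate:
            ledger.append(InjectedError("host_omission", idx, {"host": rec.host}))
            continue
        kept.append((idx, rec))
    rows = kept

    out: list[tuple[int, ExtractionRecord]] = []
    for idx, rec in rows:
        new = rec
        if new.year is not None and "-" in new.year and rng.random() < model.year_mismatch_rate:
            collapsed = new.year.split("-")[0].strip()
            ledger.append(
                InjectedError("year_mismatch", idx, {"from": new.year, "to": collapsed})
            )
            new = replace(new, year=collapsed)
        if new.percentage is None and rng.random() < model.incidence_false_positive_rate:
            ledger.append(InjectedError("incidence_false_positive", idx, {}))
            new = replace(new, percentage=100.0)
        if new.latitude is not None and new.longitude is not None:
            u = rng.random()
            if u < model.coord_minor_rate:
                axis = "lat" if rng.random() < 0.5 else "lon"
                delta = float(rng.uniform(*model.minor_delta_range)) * (
                    1 if rng.random() < 0.5 else -1
                )
                lat = _clamp(new.latitude + (delta if axis == "lat" else 0.0), 90.0)
                lon = _clamp(new.longitude + (delta if axis == "lon" else 0.0), 180.0)
                ledger.append(
                    InjectedError(
                        "coord_minor",
                        idx,
                        {"dlat": abs(lat - new.latitude), "dlon": abs(lon - new.longitude)},
                    )
                )
                new = replace(new, latitude=lat, longitude=lon)
            elif u < model.coord_minor_rate + model.coord_failure_rate:
                dlat = float(rng.uniform(*model.failure_delta_range)) * (
                    1 if rng.random() < 0.5 else -1
                )
                dlon = float(rng.uniform(*model.failure_delta_range)) * (
                    1 if rng.random() < 0.5 else -1
                )
                lat = _clamp(new.latitude + dlat, 90.0)
                lon = _clamp(new.longitude + dlon, 180.0)
                ledger.append(
                    InjectedError(
                        "coord_failure",
                        idx,
                        {"dlat": abs(lat - new.latitude), "dlon": abs(lon - new.longitude)},
                    )
                )
                new = replace(new, latitude=lat, longitude=lon)
        elif new.latitude is None and new.longitude is None:
            if rng.random() < model.geocode_rate and new.country in country_centroids:
                clat, clon = country_centroids[new.country]
                angle = rng.uniform(0.0, 2.0 * np.pi)
                radius = model.geocode_radius * np.sqrt(rng.random())
                lat = _clamp(clat + radius * np.sin(angle), 90.0)
                lon = _clamp(clon + radius * np.cos(angle), 180.0)
                ledger.append(
                    InjectedError("geocode", idx, {"lat": lat, "lon": lon})
                )
                new = replace(new, latitude=round(lat, 6), longitude=round(lon, 6))
        out.append((idx, new))

    # conflation: merge all coordinate sets of the report into the first one
    coord_rows = [k for k, (_, rec) in enumerate(out) if rec.coordinates() is not None]
    distinct = {out[k][1].coordinates() for k in coord_rows}
    if len(distinct) >= 2 and rng.random() < model.conflation_rate:
        keep = out[coord_rows[0]][1].coordinates()
        for k in coord_rows[1:]:
            idx, rec = out[k]
            if rec.coordinates() != keep:
                out[k] = (idx, replace(rec, latitude=keep[0], longitude=keep[1]))
        ledger.append(
            InjectedError(
                "conflation",
                None,
                {"kept": keep, "merged": len(distinct) - 1},
            )
        )

    # commission: append one spurious row echoing the report's context
    if truth and rng.random() < model.commission_rate:
        base = truth[0]
        lat = lon = None
        if base.latitude is not None and base.longitude is not None:
            lat = _clamp(base.latitude + 0.8, 90.0)
            lon = _clamp(base.longitude + 0.8, 180.0)
        spurious = ExtractionRecord(
            pathogen=base.pathogen,
            host=None,
            percentage=None,
            year=base.year,
            location="an adjacent roadside survey plot",
            country=base.country,
            latitude=lat,
            longitude=lon,
        )
        out.append((-1, spurious))
        ledger.append(InjectedError("commission", None, {}))

    return CorruptionResult(tuple(rec for _, rec in out), tuple(ledger))


class MockExtractor:
    """Deterministic extractor fulfilling the (title, abstract) -> text contract.

    Looks the report up by title in a corpus whose truth tables it holds,
    optionally corrupts the truth through an :class:`ErrorModel` (a fresh
    per-report RNG stream is derived from the model seed and the report's
    corpus position, so identical construction gives identical output), and
    serializes the result in the bar-delimited dialect.  Per-report injection
    ledgers accumulate in :attr:`ledgers`.
    """

    def __init__(
        self,
        corpus: Sequence[Report],
        error_model: Optional[ErrorModel] = None,
        include_header: bool = True,
        fail_report_ids: Sequence[str] = (),
    ):
        self._by_title: dict[str, tuple[int, Report]] = {}
        for i, rep in enumerate(corpus):
            if rep.truth is None:
                raise ValueError(f"report {rep.report_id} has no truth table")
            if rep.title in self._by_title:
                raise ValueError(f"duplicate title: {rep.title!r}")
            self._by_title[rep.title] = (i, rep)
        self.error_model = error_model
        self.include_header = include_header
        self._fail = frozenset(fail_report_ids)
        self.ledgers: dict[str, tuple[InjectedError, ...]] = {}

    def __call__(self, title: str, abstract: str) -> str:
        entry = self._by_title.get(title)
        if entry is None:
            raise ExtractorError(f"unknown report title: {title!r}")
        i, rep = entry
        if rep.report_id in self._fail:
            raise ExtractorError(f"simulated extractor failure for {rep.report_id}")
        records: Sequence[ExtractionRecord] = rep.truth
        if self.error_model is not None:
            rng = np.random.default_rng([self.error_model.seed, i])
            result = corrupt_truth(rep.truth, self.error_model, rng=rng)
            self.ledgers[rep.report_id] = result.ledger
            records = result.records
        return write_extraction_table(records, include_header=self.include_header)
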