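"""Degrees-minutes-seconds conversion, coordinate comparison, and country containment.

First reports print coordinates in DMS notation with cardinal letters
(e.g. 40°30′7.2″N); the extraction dialect demands signed decimal degrees.
This module converts between the two, compares a reference coordinate pair
against a candidate pair, classifies the discrepancy (exact within rounding,
minor conversion slip, outright conversion failure, omission, commission,
conflation), and checks whether a point falls inside the polygon of its
claimed country.

The minor/failure boundary is a magnitude threshold.  The underlying causes
(which conversion step went wrong) are not observable from the numbers, so
the distinction here is necessarily a declared rule, not a recovered one;
both thresholds are configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from shapely.geometry import Point, shape
from shapely.prepared import prep

__all__ = [
    "DMSCoordinate",
    "CoordinateThresholds",
    "DEFAULT_THRESHOLDS",
    "CoordinateDiscrepancy",
    "DiscrepancySummary",
    "DISCREPANCY_CATEGORIES",
    "dms_to_decimal",
    "decimal_to_dms",
    "format_dms",
    "classify_coordinate_pair",
    "summarize_discrepancies",
    "GeoJSONBoundaryProvider",
    "builtin_boundary_provider",
    "check_country_containment",
]

DISCREPANCY_CATEGORIES = (
    "exact_within_rounding",
    "minor_mismatch",
    "conversion_failure",
    "omission",
    "commission",
    "conflation",
)

LatLon = tuple[float, float]


@dataclass(frozen=True)
class DMSCoordinate:
    """One axis of a coordinate in degrees-minutes-seconds with a cardinal letter.

    The hemisphere implies the axis: N/S is latitude, E/W is longitude.
    Decimal value is ``degrees + minutes/60 + seconds/3600``, negated for S/W.
    """

    degrees: int
    minutes: float
    seconds: float
    hemisphere: str

    def __post_init__(self) -> None:
        if self.degrees < 0 or self.degrees != int(self.degrees):
            raise ValueError(f"degrees must be a non-negative integer: {self.degrees}")
        if not 0 <= self.minutes < 60:
            raise ValueError(f"minutes outside [0, 60): {self.minutes}")
        if not 0 <= self.seconds < 60:
            raise ValueError(f"seconds outside [0, 60): {self.seconds}")
        if self.hemisphere not in ("N", "S", "E", "W"):
            raise ValueError(f"hemisphere must be one of N/S/E/W: {self.hemisphere!r}")

    @property
    def axis(self) -> str:
        return "latitude" if self.hemisphere in ("N", "S") else "longitude"


def dms_to_decimal(c: DMSCoordinate) -> float:
    """Signed decimal degrees of a DMS coordinate (negative for S and W)."""
    magnitude = c.degrees + c.minutes / 60.0 + c.seconds / 3600.0
    bound = 90.0 if c.axis == "latitude" else 180.0
    if magnitude > bound:
        raise ValueError(f"{c.axis} magnitude {magnitude} exceeds {bound}")
    return -magnitude if c.hemisphere in ("S", "W") else magnitude


def decimal_to_dms(value: float, axis: str) -> DMSCoordinate:
    """Inverse of :func:`dms_to_decimal` for a given axis ("lat" or "lon")."""
    if axis in ("lat", "latitude"):
        bound, positive, negative = 90.0, "N", "S"
    elif axis in ("lon", "longitude"):
        bound, positive, negative = 180.0, "E", "W"
    else:
        raise ValueError(f"axis must be 'lat' or 'lon': {axis!r}")
    if not -bound <= value <= bound:
        raise ValueError(f"{axis} value {value} outside [-{bound}, {bound}]")
    hemisphere = negative if value < 0 else positive
    magnitude = abs(value)
    degrees = int(magnitude)
    rem_minutes = (magnitude - degrees) * 60.0
    minutes = int(rem_minutes)
    seconds = (rem_minutes - minutes) * 60.0
    # float drift can push seconds to 60-epsilon; carry upward
    if seconds >= 60.0 - 1e-9:
        seconds = 0.0
        minutes += 1
    if minutes >= 60:
        minutes = 0
        degrees += 1
    return DMSCoordinate(degrees, float(minutes), seconds, hemisphere)


def format_dms(c: DMSCoordinate, seconds_decimals: int = 1) -> str:
    """Human-readable DMS string, e.g. ``40°30′7.2″N``."""
    return (
        f"{c.degrees}°{int(c.minutes)}′"
        f"{c.seconds:.{seconds_decimals}f}″{c.hemisphere}"
    )


@dataclass(frozen=True)
class CoordinateThresholds:
    """Classification thresholds in decimal degrees.

    ``rounding_tolerance`` separates negligible decimal-rounding noise from a
    real discrepancy; ``minor_threshold`` separates a small conversion slip
    from an outright conversion failure.
    """

    rounding_tolerance: float = 0.001
    minor_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.rounding_tolerance < self.minor_threshold:
            raise ValueError("need 0 <= rounding_tolerance < minor_threshold")


DEFAULT_THRESHOLDS = CoordinateThresholds()


@dataclass(frozen=True)
class CoordinateDiscrepancy:
    """Classification of one reference/candidate coordinate comparison."""

    category: str
    abs_diff_lat: Optional[float] = None
    abs_diff_lon: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in DISCREPANCY_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _validate_latlon(point: LatLon, side: str) -> LatLon:
    lat, lon = float(point[0]), float(point[1])
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"{side} latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"{side} longitude {lon} outside [-180, 180]")
    return lat, lon


def classify_coordinate_pair(
    ref: Optional[LatLon],
    cand: Optional[LatLon],
    config: CoordinateThresholds = DEFAULT_THRESHOLDS,
) -> CoordinateDiscrepancy:
    """Classify one coordinate comparison.

    One-sided cases are omission (reference only) or commission (candidate
    only).  Two-sided cases are classified by the larger per-axis absolute
    difference against the thresholds; the per-axis differences are always
    reported for two-sided cases.  Conflation is a report-level pattern and
    is detected by the alignment layer, not here.
    """
    if ref is None and cand is None:
        raise ValueError("at least one side must be present")
    if cand is None:
        _validate_latlon(ref, "ref")
        return CoordinateDiscrepancy("omission")
    if ref is None:
        _validate_latlon(cand, "cand")
        return CoordinateDiscrepancy("commission")
    rlat, rlon = _validate_latlon(ref, "ref")
    clat, clon = _validate_latlon(cand, "cand")
    dlat, dlon = abs(rlat - clat), abs(rlon - clon)
    worst = max(dlat, dlon)
    if worst <= config.rounding_tolerance:
        category = "exact_within_rounding"
    elif worst <= config.minor_threshold:
        category = "minor_mismatch"
    else:
        category = "conversion_failure"
    return CoordinateDiscrepancy(category, dlat, dlon)


@dataclass(frozen=True)
class AxisStats:
    """Mean and range of absolute differences along one axis."""

    mean: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class DiscrepancySummary:
    """Per-category counts plus absolute-difference statistics.

    Difference statistics only exist for two-sided categories (exact, minor,
    failure); omission/commission/conflation cases carry no differences.
    The exact-match share is reported against two denominators because the
    natural denominator is ambiguous: all cases, and two-sided cases only.
    """

    counts: Mapping[str, int]
    total: int
    by_category: Mapping[str, tuple[AxisStats, AxisStats]]  # (lat, lon)
    overall_two_sided: Optional[tuple[AxisStats, AxisStats]]
    exact_share_of_all: float
    exact_share_of_two_sided: Optional[float]


def _axis_stats(values: Sequence[float]) -> AxisStats:
    return AxisStats(
        mean=sum(values) / len(values),
        min=min(values),
        max=max(values),
        n=len(values),
    )


def summarize_discrepancies(
    discrepancies: Sequence[CoordinateDiscrepancy],
) -> DiscrepancySummary:
    """Aggregate a discrepancy list: counts per category and per-axis stats."""
    if not discrepancies:
        raise ValueError("discrepancy list must be non-empty")
    counts = {cat: 0 for cat in DISCREPANCY_CATEGORIES}
    lat_by_cat: dict[str, list[float]] = {}
    lon_by_cat: dict[str, list[float]] = {}
    for d in discrepancies:
        counts[d.category] += 1
        if d.abs_diff_lat is not None and d.abs_diff_lon is not None:
            lat_by_cat.setdefault(d.category, []).append(d.abs_diff_lat)
            lon_by_cat.setdefault(d.category, []).append(d.abs_diff_lon)
    by_category = {
        cat: (_axis_stats(lat_by_cat[cat]), _axis_stats(lon_by_cat[cat]))
        for cat in lat_by_cat
    }
    all_lat = [v for vs in lat_by_cat.values() for v in vs]
    all_lon = [v for vs in lon_by_cat.values() for v in vs]
    overall = (_axis_stats(all_lat), _axis_stats(all_lon)) if all_lat else None
    total = len(discrepancies)
    n_two_sided = len(all_lat)
    n_exact = counts["exact_within_rounding"]
    return DiscrepancySummary(
        counts=counts,
        total=total,
        by_category=by_category,
        overall_two_sided=overall,
        exact_share_of_all=n_exact / total,
        exact_share_of_two_sided=(n_exact / n_two_sided) if n_two_sided else None,
    )


class GeoJSONBoundaryProvider:
    """Country polygons from a GeoJSON FeatureCollection (WGS84 decimal degrees).

    Features carry ``properties.name`` and optionally ``properties.kind``
    ("country", the default, or "water").  Name lookup is trimmed and
    case-insensitive.
    """

    def __init__(self, feature_collection: Mapping):
        self._countries: dict[str, object] = {}
        self._country_names: dict[str, str] = {}
        self._water: list[object] = []
        for feat in feature_collection.get("features", []):
            props = feat.get("properties", {}) or {}
            geom = shape(feat["geometry"])
            kind = (props.get("kind") or "country").lower()
            name = props.get("name", "")
            if kind == "water":
                self._water.append(geom)
            else:
                key = name.strip().casefold()
                self._countries[key] = geom
                self._country_names[key] = name
        self._prepared = {k: prep(g) for k, g in self._countries.items()}
        self._prepared_water = [prep(g) for g in self._water]

    @classmethod
    def from_text(cls, text: str) -> "GeoJSONBoundaryProvider":
        return cls(json.loads(text))

    @classmethod
    def from_path(cls, path) -> "GeoJSONBoundaryProvider":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    @property
    def country_names(self) -> tuple[str, ...]:
        return tuple(sorted(self._country_names.values()))

    def country_polygon(self, country: str):
        """Shapely geometry for the country, or None when unknown."""
        return self._countries.get(country.strip().casefold())

    def contains(self, country: str, lat: float, lon: float) -> Optional[bool]:
        prepared = self._prepared.get(country.strip().casefold())
        if prepared is None:
            return None
        return bool(prepared.covers(Point(lon, lat)))

    def in_water(self, lat: float, lon: float) -> bool:
        point = Point(lon, lat)
        return any(p.covers(point) for p in self._prepared_water)


def builtin_boundary_provider() -> GeoJSONBoundaryProvider:
    """The bundled synthetic rectangular country boxes (not real borders)."""
    text = (
        resources.files("firstreports")
        .joinpath("data/synthetic_country_boxes.geojson")
        .read_text(encoding="utf-8")
    )
    return GeoJSONBoundaryProvider.from_text(text)


def check_country_containment(
    point: LatLon, country: str, provider: GeoJSONBoundaryProvider
) -> str:
    """Verdict on whether a point lies inside its claimed country.

    Returns ``inside``, ``outside``, ``in_water`` (outside the country and
    within a known water body), or ``unknown`` when the provider has no
    polygon for the country.
    """
    lat, lon = _validate_latlon(point, "point")
    verdict = provider.contains(country, lat, lon)
    if verdict is None:
        return "unknown"
    if verdict:
        return "inside"
    if provider.in_water(lat, lon):
        return "in_water"
    return "outside"


def random_point_within(polygon, rng) -> LatLon:
    """Rejection-sample a (lat, lon) uniformly within a shapely polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    for _ in range(10_000):
        lon = float(rng.uniform(minx, maxx))
        lat = float(rng.uniform(miny, maxy))
        if polygon.covers(Point(lon, lat)):
            return (lat, lon)
    raise RuntimeError("failed to sample a point inside the polygon")
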