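"""Row alignment between reference and candidate extraction tables, and
classification of every field comparison into the error taxonomy.

For one report the reference (human) and candidate (model) tables are paired
one-to-one by a row-similarity score: the number of matching identity fields
among pathogen, host, location and country (scientific-name rules for the
first two, plain text normalization for the rest).  The pairing maximizes
the total score exactly, breaking ties deterministically in favour of
earlier rows; rows with no field in common never pair.  Reference rows left
over are omissions, candidate rows left over are commissions.

Each field of each aligned pair then yields exactly one outcome:

* ``true_positive``  -- both present and matching
* ``true_negative``  -- both missing (value fields only)
* ``false_positive`` -- reference missing, candidate invented a value
* ``mismatch``       -- both present, not matching
* ``omission``       -- reference value with no candidate counterpart
* ``commission``     -- candidate value with no reference counterpart
* ``conflation``     -- two distinct reference coordinate sets answered by a
  single candidate coordinate set (coordinate field only)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .coordinates import (
    CoordinateDiscrepancy,
    CoordinateThresholds,
    DEFAULT_THRESHOLDS,
    classify_coordinate_pair,
)
from .extraction import ExtractionRecord
from .names import DEFAULT_MATCH_CONFIG, MatchRuleConfig, names_match, normalize_plain

__all__ = [
    "FIELDS",
    "VALUE_FIELDS",
    "ComparisonOutcome",
    "AlignedReport",
    "row_similarity",
    "align_rows",
    "classify_fields",
]

#: Comparison fields; latitude/longitude are compared together as one field.
FIELDS = (
    "pathogen",
    "host",
    "percentage",
    "year",
    "location",
    "country",
    "latitude_longitude",
)

#: Fields for which "both missing" is a meaningful agreement (true negative).
#: Pathogen, host and country are always populated by the reference in this
#: corpus, so a true negative is never emitted for them.
VALUE_FIELDS = ("percentage", "year", "location", "latitude_longitude")


@dataclass(frozen=True)
class ComparisonOutcome:
    """Classification of one field comparison in one report."""

    report_id: str
    field: str
    category: str
    ref_value: Optional[str]
    cand_value: Optional[str]
    #: False when the outcome comes from an unmatched row (no counterpart row
    #: at all), True when both rows exist and a side merely answered NA.
    paired: bool = True


@dataclass
class AlignedReport:
    """Result of pairing one report's reference and candidate tables.

    Invariant: ``2 * len(pairs) + len(unmatched_ref) + len(unmatched_cand)``
    equals the total number of rows across both tables.
    """

    report_id: str
    pairs: list[tuple[ExtractionRecord, ExtractionRecord]]
    unmatched_ref: list[ExtractionRecord]
    unmatched_cand: list[ExtractionRecord]
    outcomes: list[ComparisonOutcome] = field(default_factory=list)
    coordinate_discrepancies: list[CoordinateDiscrepancy] = field(default_factory=list)


def _text_eq(a: Optional[str], b: Optional[str], config: MatchRuleConfig) -> bool:
    if a is None or b is None:
        return False
    return normalize_plain(a, config) == normalize_plain(b, config)


def _name_eq(a: Optional[str], b: Optional[str], config: MatchRuleConfig) -> bool:
    if a is None or b is None:
        return False
    return names_match(a, b, config)


def row_similarity(
    ref: ExtractionRecord, cand: ExtractionRecord, config: MatchRuleConfig = DEFAULT_MATCH_CONFIG
) -> int:
    """Count of matching identity fields (pathogen, host, location, country).

    All four fields weigh equally; a field counts only when present on both
    sides and matching.
    """
    score = 0
    if _name_eq(ref.pathogen, cand.pathogen, config):
        score += 1
    if _name_eq(ref.host, cand.host, config):
        score += 1
    if _text_eq(ref.location, cand.location, config):
        score += 1
    if _text_eq(ref.country, cand.country, config):
        score += 1
    return score


def _best_assignment(sim: list[list[int]]) -> list[tuple[int, int]]:
    """Exact maximum-score one-to-one assignment with deterministic ties.

    DFS over reference rows in order; for each, candidate columns are tried
    in ascending index before "leave unmatched", so among score-ties the
    first-found (lexicographically earliest) assignment wins.  Zero-score
    pairs are never taken.  A running upper bound prunes the search, which
    keeps it fast for the handful of rows a single report can hold.
    """
    n = len(sim)
    m = len(sim[0]) if n else 0
    best_score = -1
    best_pairs: list[tuple[int, int]] = []
    used = [False] * m
    # per-row maxima for the optimistic bound
    row_max = [max(row, default=0) for row in sim]
    suffix_bound = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_bound[i] = suffix_bound[i + 1] + row_max[i]

    current: list[tuple[int, int]] = []

    def rec(i: int, score: int) -> None:
        nonlocal best_score, best_pairs
        if score + suffix_bound[i] <= best_score:
            return  # cannot strictly improve; ties lose to the earlier find
        if i == n:
            if score > best_score:
                best_score = score
                best_pairs = list(current)
            return
        for j in range(m):
            if not used[j] and sim[i][j] > 0:
                used[j] = True
                current.append((i, j))
                rec(i + 1, score + sim[i][j])
                current.pop()
                used[j] = False
        rec(i + 1, score)

    rec(0, 0)
    return best_pairs


def align_rows(
    ref: Sequence[ExtractionRecord],
    cand: Sequence[ExtractionRecord],
    config: MatchRuleConfig = DEFAULT_MATCH_CONFIG,
    report_id: str = "",
) -> AlignedReport:
    """Pair reference and candidate rows of one report.

    Empty tables are allowed: every row on the populated side becomes an
    omission (reference) or commission (candidate).
    """
    sim = [[row_similarity(r, c, config) for c in cand] for r in ref]
    pairs_idx = _best_assignment(sim) if ref and cand else []
    paired_ref = {i for i, _ in pairs_idx}
    paired_cand = {j for _, j in pairs_idx}
    return AlignedReport(
        report_id=report_id,
        pairs=[(ref[i], cand[j]) for i, j in pairs_idx],
        unmatched_ref=[r for i, r in enumerate(ref) if i not in paired_ref],
        unmatched_cand=[c for j, c in enumerate(cand) if j not in paired_cand],
    )


def _display(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float):
        return str(value)
    return str(value)


def _coord_display(rec: ExtractionRecord) -> Optional[str]:
    coords = rec.coordinates()
    if coords is None:
        return None
    return f"{coords[0]},{coords[1]}"


def _classify_two_sided(
    field_name: str,
    ref_val,
    cand_val,
    matches: bool,
) -> str:
    if ref_val is None and cand_val is None:
        return "true_negative"
    if ref_val is None:
        return "false_positive"
    if cand_val is None:
        return "omission"
    return "true_positive" if matches else "mismatch"


def classify_fields(
    aligned: AlignedReport,
    config: MatchRuleConfig = DEFAULT_MATCH_CONFIG,
    thresholds: CoordinateThresholds = DEFAULT_THRESHOLDS,
) -> list[ComparisonOutcome]:
    """Emit one outcome per field per case and collect coordinate discrepancies.

    The outcome list is also stored on ``aligned.outcomes`` (and the
    coordinate discrepancies on ``aligned.coordinate_discrepancies``).
    Cases are: each aligned pair for every field, plus each unmatched row
    for the fields it actually populates.
    """
    outcomes: list[ComparisonOutcome] = []
    discrepancies: list[CoordinateDiscrepancy] = []
    rid = aligned.report_id

    # --- conflation detection (coordinate field only): a single candidate
    # coordinate set answering two or more distinct reference sets.
    def _key(coords):
        return (round(coords[0], 9), round(coords[1], 9))

    coord_groups: dict[tuple, list[int]] = {}
    for k, (r, c) in enumerate(aligned.pairs):
        if r.coordinates() is not None and c.coordinates() is not None:
            coord_groups.setdefault(_key(c.coordinates()), []).append(k)
    conflated_pairs: set[int] = set()
    for cand_key, members in coord_groups.items():
        ref_keys = {_key(aligned.pairs[k][0].coordinates()) for k in members}
        if len(members) >= 2 and len(ref_keys) >= 2:
            conflated_pairs.update(members)
            refs = "; ".join(
                sorted({_coord_display(aligned.pairs[k][0]) for k in members})
            )
            cand_disp = f"{cand_key[0]},{cand_key[1]}"
            outcomes.append(
                ComparisonOutcome(rid, "latitude_longitude", "conflation", refs, cand_disp)
            )
            discrepancies.append(CoordinateDiscrepancy("conflation"))

    for r, c in aligned.pairs:
        # identity/name fields
        for field_name, eq in (
            ("pathogen", _name_eq),
            ("host", _name_eq),
            ("location", _text_eq),
            ("country", _text_eq),
        ):
            rv, cv = getattr(r, field_name), getattr(c, field_name)
            category = _classify_two_sided(field_name, rv, cv, eq(rv, cv, config))
            if category == "true_negative" and field_name not in VALUE_FIELDS:
                # both sides silent on a field the reference normally always
                # populates; nothing to score
                continue
            outcomes.append(ComparisonOutcome(rid, field_name, category, rv, cv))
        # year: normalized text equality (a range vs a year within it still
        # mismatches)
        category = _classify_two_sided(
            "year", r.year, c.year, _text_eq(r.year, c.year, config)
        )
        outcomes.append(ComparisonOutcome(rid, "year", category, r.year, c.year))
        # percentage: numeric equality
        matches = (
            r.percentage is not None
            and c.percentage is not None
            and abs(r.percentage - c.percentage) < 1e-9
        )
        category = _classify_two_sided("percentage", r.percentage, c.percentage, matches)
        outcomes.append(
            ComparisonOutcome(
                rid, "percentage", category, _display(r.percentage), _display(c.percentage)
            )
        )

    # coordinates for non-conflated pairs
    for k, (r, c) in enumerate(aligned.pairs):
        if k in conflated_pairs:
            continue
        ref_coords, cand_coords = r.coordinates(), c.coordinates()
        if ref_coords is None and cand_coords is None:
            outcomes.append(
                ComparisonOutcome(rid, "latitude_longitude", "true_negative", None, None)
            )
            continue
        disc = classify_coordinate_pair(ref_coords, cand_coords, thresholds)
        discrepancies.append(disc)
        if disc.category == "exact_within_rounding":
            category = "true_positive"
        elif disc.category in ("minor_mismatch", "conversion_failure"):
            category = "mismatch"
        else:  # omission / commission within a pair
            category = disc.category
        outcomes.append(
            ComparisonOutcome(
                rid, "latitude_longitude", category, _coord_display(r), _coord_display(c)
            )
        )

    # unmatched rows: omission/commission outcomes for every present field
    for rec, category, side in (
        [(r, "omission", "ref") for r in aligned.unmatched_ref]
        + [(c, "commission", "cand") for c in aligned.unmatched_cand]
    ):
        for field_name in ("pathogen", "host", "location", "country", "year"):
            value = getattr(rec, field_name)
            if value is None:
                continue
            ref_v, cand_v = (value, None) if side == "ref" else (None, value)
            outcomes.append(
                ComparisonOutcome(rid, field_name, category, ref_v, cand_v, paired=False)
            )
        if rec.percentage is not None:
            ref_v, cand_v = (
                (_display(rec.percentage), None)
                if side == "ref"
                else (None, _display(rec.percentage))
            )
            outcomes.append(
                ComparisonOutcome(rid, "percentage", category, ref_v, cand_v, paired=False)
            )
        if rec.coordinates() is not None:
            disp = _coord_display(rec)
            ref_v, cand_v = (disp, None) if side == "ref" else (None, disp)
            outcomes.append(
                ComparisonOutcome(
                    rid, "latitude_longitude", category, ref_v, cand_v, paired=False
                )
            )
            discrepancies.append(CoordinateDiscrepancy(category))

    aligned.outcomes = outcomes
    aligned.coordinate_discrepancies = discrepancies
    return outcomes
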