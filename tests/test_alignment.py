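"""Row alignment and field-outcome classification."""

import itertools
from collections import Counter

import numpy as np
import pytest

from firstreports.alignment import (
    FIELDS,
    align_rows,
    classify_fields,
    row_similarity,
)
from firstreports.extraction import ExtractionRecord


def rec(pathogen="P a", host="H b", pct=None, year="2020", loc="L", country="Spain",
        lat=None, lon=None):
    return ExtractionRecord(pathogen, host, pct, year, loc, country, lat, lon)


def exhaustive_best(ref, cand):
    """Oracle: enumerate all one-to-one assignments, return (score, count_of_optima)."""
    n, m = len(ref), len(cand)
    sim = [[row_similarity(r, c) for c in cand] for r in ref]
    best, n_best = 0, 0
    best_assignments = []
    k = min(n, m)
    for size in range(k + 1):
        for ref_subset in itertools.combinations(range(n), size):
            for cand_perm in itertools.permutations(range(m), size):
                if any(sim[i][j] == 0 for i, j in zip(ref_subset, cand_perm)):
                    continue
                score = sum(sim[i][j] for i, j in zip(ref_subset, cand_perm))
                if score > best:
                    best, n_best = score, 1
                    best_assignments = [set(zip(ref_subset, cand_perm))]
                elif score == best and score > 0:
                    pairing = set(zip(ref_subset, cand_perm))
                    if pairing not in best_assignments:
                        n_best += 1
                        best_assignments.append(pairing)
    return best, n_best, best_assignments


class TestAlign:
    def test_identical_single_row_tables_pair(self):
        table = [rec()]
        aligned = align_rows(table, table)
        assert len(aligned.pairs) == 1
        assert not aligned.unmatched_ref and not aligned.unmatched_cand

    def test_missing_host_row_becomes_omission(self):
        ref = [rec(host="Pinus radiata"), rec(host="Quercus robur")]
        cand = [rec(host="Pinus radiata")]
        aligned = align_rows(ref, cand)
        assert len(aligned.pairs) == 1
        assert len(aligned.unmatched_ref) == 1
        assert aligned.unmatched_ref[0].host == "Quercus robur"

    def test_extra_candidate_row_becomes_commission(self):
        ref = [rec()]
        cand = [rec(), rec(loc="Elsewhere")]
        aligned = align_rows(ref, cand)
        assert len(aligned.unmatched_cand) == 1

    def test_zero_similarity_rows_never_pair(self):
        ref = [rec(pathogen="A a", host="B b", loc="X", country="Spain")]
        cand = [rec(pathogen="C c", host="D d", loc="Y", country="Japan")]
        aligned = align_rows(ref, cand)
        assert not aligned.pairs
        assert len(aligned.unmatched_ref) == 1
        assert len(aligned.unmatched_cand) == 1

    def test_row_count_conservation(self):
        ref = [rec(host=f"H {i}") for i in range(3)]
        cand = [rec(host="H 0"), rec(host="H 9"), rec(host="H 1"), rec(host="H 8")]
        aligned = align_rows(ref, cand)
        total = 2 * len(aligned.pairs) + len(aligned.unmatched_ref) + len(
            aligned.unmatched_cand
        )
        assert total == len(ref) + len(cand)

    def test_empty_tables_allowed(self):
        aligned = align_rows([], [rec()])
        assert not aligned.pairs and len(aligned.unmatched_cand) == 1
        aligned = align_rows([rec()], [])
        assert len(aligned.unmatched_ref) == 1

    def test_matches_exhaustive_assignment_on_random_small_tables(self):
        rng = np.random.default_rng(17)
        pathogens = ["P one", "P two"]
        hosts = ["H one", "H two", "H three"]
        locs = ["L1", "L2"]
        countries = ["Spain", "Japan"]
        checked_unique = 0
        for _ in range(150):
            n, m = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            def draw():
                return rec(
                    pathogen=pathogens[rng.integers(2)],
                    host=hosts[rng.integers(3)],
                    loc=locs[rng.integers(2)],
                    country=countries[rng.integers(2)],
                )
            ref = [draw() for _ in range(n)]
            cand = [draw() for _ in range(m)]
            best, n_best, best_assignments = exhaustive_best(ref, cand)
            aligned = align_rows(ref, cand)
            sim = [[row_similarity(r, c) for c in cand] for r in ref]
            ref_ids = {id(r): i for i, r in enumerate(ref)}
            cand_ids = {id(c): j for j, c in enumerate(cand)}
            pairing = {(ref_ids[id(r)], cand_ids[id(c)]) for r, c in aligned.pairs}
            achieved = sum(sim[i][j] for i, j in pairing)
            assert achieved == best
            if n_best == 1 and best > 0:
                checked_unique += 1
                assert pairing == best_assignments[0]
        assert checked_unique > 20  # the unique-optimum branch was exercised


class TestClassify:
    def _outcomes(self, ref, cand):
        aligned = align_rows(ref, cand, report_id="r1")
        return classify_fields(aligned), aligned

    def test_equal_years_true_positive(self):
        outcomes, _ = self._outcomes([rec(year="2020")], [rec(year="2020")])
        year = [o for o in outcomes if o.field == "year"]
        assert [o.category for o in year] == ["true_positive"]

    def test_invented_incidence_false_positive(self):
        outcomes, _ = self._outcomes([rec(pct=None)], [rec(pct=100.0)])
        pct = [o for o in outcomes if o.field == "percentage"]
        assert [o.category for o in pct] == ["false_positive"]

    def test_year_range_vs_single_year_mismatch(self):
        outcomes, _ = self._outcomes([rec(year="2019-2020")], [rec(year="2019")])
        year = [o for o in outcomes if o.field == "year"]
        assert [o.category for o in year] == ["mismatch"]

    def test_both_missing_value_field_true_negative(self):
        outcomes, _ = self._outcomes([rec(pct=None)], [rec(pct=None)])
        pct = [o for o in outcomes if o.field == "percentage"]
        assert [o.category for o in pct] == ["true_negative"]

    def test_value_level_omission_inside_pair(self):
        outcomes, _ = self._outcomes([rec(pct=12.0)], [rec(pct=None)])
        pct = [o for o in outcomes if o.field == "percentage"]
        assert [o.category for o in pct] == ["omission"]
        assert pct[0].paired

    def test_unmatched_ref_row_emits_omissions_for_present_fields(self):
        ref = [rec(host="H one"), rec(host="H two", pct=5.0)]
        cand = [rec(host="H one")]
        outcomes, _ = self._outcomes(ref, cand)
        omissions = [o for o in outcomes if o.category == "omission"]
        fields = sorted(o.field for o in omissions)
        assert fields == ["country", "host", "location", "pathogen", "percentage", "year"]
        assert all(not o.paired for o in omissions)

    def test_coordinate_categories_flow_through(self):
        ref = [rec(lat=40.5, lon=-3.5)]
        cand = [rec(lat=40.35, lon=-3.5)]
        outcomes, aligned = self._outcomes(ref, cand)
        coord = [o for o in outcomes if o.field == "latitude_longitude"]
        assert [o.category for o in coord] == ["mismatch"]
        assert aligned.coordinate_discrepancies[0].category == "minor_mismatch"

    def test_conflation_two_ref_sets_one_cand_set(self):
        ref = [
            rec(loc="L1", lat=40.5, lon=-3.5),
            rec(loc="L2", lat=41.5, lon=-2.5),
        ]
        cand = [
            rec(loc="L1", lat=40.5, lon=-3.5),
            rec(loc="L2", lat=40.5, lon=-3.5),
        ]
        outcomes, aligned = self._outcomes(ref, cand)
        coord = [o for o in outcomes if o.field == "latitude_longitude"]
        assert [o.category for o in coord] == ["conflation"]
        assert [d.category for d in aligned.coordinate_discrepancies] == ["conflation"]

    def test_shared_location_coordinates_are_not_conflation(self):
        # two hosts at the same location legitimately share one coordinate set
        ref = [rec(host="H one", lat=40.5, lon=-3.5), rec(host="H two", lat=40.5, lon=-3.5)]
        outcomes, _ = self._outcomes(ref, ref)
        coord = [o for o in outcomes if o.field == "latitude_longitude"]
        assert [o.category for o in coord] == ["true_positive", "true_positive"]

    def test_tally_conservation_per_field(self, small_corpus):
        # every case lands in exactly one category for its field
        from firstreports.synthetic import ErrorModel, MockExtractor
        from firstreports.extraction import parse_extraction_table

        extractor = MockExtractor(small_corpus, error_model=ErrorModel(seed=2))
        for rep in small_corpus:
            parsed = parse_extraction_table(extractor(rep.title, rep.abstract))
            aligned = align_rows(rep.truth, parsed.records, report_id=rep.report_id)
            outcomes = classify_fields(aligned)
            by_field = Counter(o.field for o in outcomes)
            for field_name, n_cases in by_field.items():
                cats = Counter(
                    o.category for o in outcomes if o.field == field_name
                )
                assert sum(cats.values()) == n_cases

    def test_self_alignment_yields_only_agreement(self, small_corpus):
        for rep in small_corpus:
            aligned = align_rows(rep.truth, rep.truth, report_id=rep.report_id)
            outcomes = classify_fields(aligned)
            assert not aligned.unmatched_ref and not aligned.unmatched_cand
            assert all(
                o.category in ("true_positive", "true_negative") for o in outcomes
            )
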