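"""Synthetic corpus generation, error injection, and the mock extractor."""

import math
import re

import numpy as np
import pytest

from firstreports.coordinates import builtin_boundary_provider
from firstreports.extraction import ExtractorError, parse_extraction_table
from firstreports.synthetic import (
    CorpusSpec,
    ErrorModel,
    MockExtractor,
    corrupt_truth,
    generate_corpus,
)


class TestGenerate:
    def test_seeded_generation_is_deterministic(self):
        spec = CorpusSpec(n_reports=20)
        assert generate_corpus(spec, 42) == generate_corpus(spec, 42)
        assert generate_corpus(spec, 42) != generate_corpus(spec, 43)

    def test_report_count_and_abstract_bound(self, small_corpus):
        assert len(small_corpus) == 25
        for rep in small_corpus:
            assert 0 < len(rep.abstract) <= 2985

    def test_no_coordinates_when_probability_zero(self):
        corpus = generate_corpus(CorpusSpec(n_reports=20, p_coordinates=0.0), 7)
        for rep in corpus:
            assert "°" not in rep.abstract
            assert not re.search(r"\d″[NSEW]", rep.abstract)
            for row in rep.truth:
                assert row.latitude is None and row.longitude is None

    def test_truth_has_one_row_per_host_and_location(self):
        spec = CorpusSpec(n_reports=15, hosts_per_report={2: 1.0}, p_second_location=0.0)
        for rep in generate_corpus(spec, 3):
            assert len(rep.truth) == 2
            assert len({r.host for r in rep.truth}) == 2
            assert len({r.location for r in rep.truth}) == 1

    def test_two_location_reports_expand_rows(self):
        spec = CorpusSpec(n_reports=10, hosts_per_report={2: 1.0}, p_second_location=1.0)
        for rep in generate_corpus(spec, 3):
            assert len(rep.truth) == 4  # 2 hosts x 2 locations

    def test_abstract_embeds_truth_fields(self, small_corpus):
        for rep in small_corpus:
            row = rep.truth[0]
            assert row.pathogen in rep.abstract
            assert row.country in rep.abstract
            assert row.year in rep.abstract
            for r in rep.truth:
                assert r.host in rep.abstract
                assert r.location in rep.abstract

    def test_printed_coordinates_are_inside_the_country(self):
        spec = CorpusSpec(n_reports=15, p_coordinates=1.0)
        provider = builtin_boundary_provider()
        for rep in generate_corpus(spec, 11):
            for row in rep.truth:
                assert provider.contains(row.country, row.latitude, row.longitude)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            CorpusSpec(pathogen_pool=())

    def test_bad_host_distribution_rejected(self):
        with pytest.raises(ValueError):
            CorpusSpec(hosts_per_report={1: 0.5, 2: 0.2})


class TestCorrupt:
    def test_all_rates_zero_is_identity(self, small_corpus, zero_noise_model):
        for rep in small_corpus:
            result = corrupt_truth(rep.truth, zero_noise_model)
            assert result.records == rep.truth
            assert result.ledger == ()

    def test_same_seed_same_output(self, small_corpus):
        model = ErrorModel(seed=9)
        a = corrupt_truth(small_corpus[0].truth, model)
        b = corrupt_truth(small_corpus[0].truth, model)
        assert a == b

    def test_certain_incidence_false_positive(self, small_corpus):
        model = ErrorModel.none()
        model = ErrorModel(**{**model.__dict__, "incidence_false_positive_rate": 1.0})
        for rep in small_corpus:
            eligible = sum(1 for r in rep.truth if r.percentage is None)
            result = corrupt_truth(rep.truth, model)
            assert all(r.percentage is not None for r in result.records)
            fp = [e for e in result.ledger if e.kind == "incidence_false_positive"]
            assert len(fp) == eligible
            for r, t in zip(result.records, rep.truth):
                if t.percentage is None:
                    assert r.percentage == 100.0

    def test_certain_host_omission_drops_non_first_hosts(self):
        spec = CorpusSpec(n_reports=5, hosts_per_report={2: 1.0}, p_second_location=0.0)
        model = ErrorModel(**{**ErrorModel.none().__dict__, "host_omission_rate": 1.0})
        for rep in generate_corpus(spec, 8):
            result = corrupt_truth(rep.truth, model)
            assert len(result.records) == 1
            assert result.records[0].host == rep.truth[0].host
            assert [e.kind for e in result.ledger] == ["host_omission"]

    def test_certain_year_collapse_on_ranges(self):
        spec = CorpusSpec(n_reports=20, p_year_range=1.0)
        model = ErrorModel(**{**ErrorModel.none().__dict__, "year_mismatch_rate": 1.0})
        for rep in generate_corpus(spec, 4):
            result = corrupt_truth(rep.truth, model)
            for orig, new in zip(rep.truth, result.records):
                if "-" in orig.year:
                    assert new.year == orig.year.split("-")[0]
                    assert new.year != orig.year

    def test_geocode_injection_near_country_centroid(self):
        spec = CorpusSpec(n_reports=10, p_coordinates=0.0)
        model = ErrorModel(**{**ErrorModel.none().__dict__, "geocode_rate": 1.0})
        provider = builtin_boundary_provider()
        for rep in generate_corpus(spec, 6):
            result = corrupt_truth(rep.truth, model)
            for row in result.records:
                assert row.latitude is not None and row.longitude is not None
                centroid = provider.country_polygon(row.country).centroid
                dist = math.hypot(row.latitude - centroid.y, row.longitude - centroid.x)
                assert dist <= model.geocode_radius + 1e-9
            assert sum(e.kind == "geocode" for e in result.ledger) == len(rep.truth)

    def test_conflation_merges_coordinate_sets(self, coord_corpus):
        model = ErrorModel(**{**ErrorModel.none().__dict__, "conflation_rate": 1.0})
        for rep in coord_corpus:
            n_sets = len({r.coordinates() for r in rep.truth})
            result = corrupt_truth(rep.truth, model)
            merged = {r.coordinates() for r in result.records}
            if n_sets >= 2:
                assert len(merged) == 1
                assert any(e.kind == "conflation" for e in result.ledger)

    def test_commission_appends_spurious_row(self, small_corpus):
        model = ErrorModel(**{**ErrorModel.none().__dict__, "commission_rate": 1.0})
        for rep in small_corpus:
            result = corrupt_truth(rep.truth, model)
            assert len(result.records) == len(rep.truth) + 1
            assert any(e.kind == "commission" for e in result.ledger)

    def test_coordinate_perturbation_magnitudes_in_declared_bands(self, coord_corpus):
        base = ErrorModel.none().__dict__
        minor = ErrorModel(**{**base, "coord_minor_rate": 1.0})
        fail = ErrorModel(**{**base, "coord_failure_rate": 1.0})
        for rep in coord_corpus:
            for model, lo, hi in ((minor, *minor.minor_delta_range),
                                  (fail, *fail.failure_delta_range)):
                result = corrupt_truth(rep.truth, model)
                for entry in result.ledger:
                    worst = max(entry.detail["dlat"], entry.detail["dlon"])
                    assert lo - 1e-9 <= worst <= hi + 1e-9

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(host_omission_rate=1.5)
        with pytest.raises(ValueError):
            ErrorModel(coord_minor_rate=0.7, coord_failure_rate=0.7)


class TestMockExtractor:
    def test_zero_noise_round_trip_reproduces_truth(self, small_corpus):
        extractor = MockExtractor(small_corpus)
        for rep in small_corpus:
            parsed = parse_extraction_table(extractor(rep.title, rep.abstract))
            assert parsed.records == rep.truth
            assert not parsed.row_errors

    def test_unknown_title_raises(self, small_corpus):
        extractor = MockExtractor(small_corpus)
        with pytest.raises(ExtractorError):
            extractor("no such title", "abstract")

    def test_simulated_failure(self, small_corpus):
        failing = small_corpus[0].report_id
        extractor = MockExtractor(small_corpus, fail_report_ids=[failing])
        with pytest.raises(ExtractorError):
            extractor(small_corpus[0].title, small_corpus[0].abstract)

    def test_corruption_is_reproducible_and_ledgered(self, small_corpus):
        model = ErrorModel(seed=13)
        first = MockExtractor(small_corpus, error_model=model)
        second = MockExtractor(small_corpus, error_model=model)
        for rep in small_corpus:
            assert first(rep.title, rep.abstract) == second(rep.title, rep.abstract)
        assert first.ledgers == second.ledgers
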