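"""End-to-end validation pipeline.

Generate or load a corpus of first reports, obtain a candidate extraction
table per report through the extractor contract, align each candidate table
against its reference (truth or reviewer) table, classify every field
comparison, and aggregate the per-field agreement statistics.  Outputs are a
delimited summary table, a flat outcome ledger for audit, and a
machine-readable JSON run report; re-running with the same configuration and
seed reproduces the delimited outputs byte for byte (mock extractor).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field as dc_field, asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import alignment
from .agreement import (
    ABSENT_CAND,
    ABSENT_REF,
    AgreementResult,
    KappaResult,
    OUTCOME_CATEGORIES,
    Tally,
    cohens_kappa,
    conditional_match_rate,
    overall_accuracy,
    percent,
)
from .alignment import ComparisonOutcome, align_rows, classify_fields
from .coordinates import (
    CoordinateThresholds,
    DEFAULT_THRESHOLDS,
    DiscrepancySummary,
    GeoJSONBoundaryProvider,
    builtin_boundary_provider,
    check_country_containment,
    summarize_discrepancies,
)
from .extraction import (
    Extractor,
    ExtractorError,
    ExtractionRecord,
    Report,
    parse_extraction_table,
    write_extraction_table,
)
from .names import DEFAULT_MATCH_CONFIG, MatchRuleConfig, normalize_name, normalize_plain
from .synthetic import CorpusSpec, ErrorModel, MockExtractor, generate_corpus

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "run_validation",
    "write_corpus",
    "load_corpus",
    "load_reference_tables",
]

logger = logging.getLogger("firstreports")


@dataclass
class PipelineConfig:
    """Configuration of one validation run.

    Exactly one corpus source must be set: a synthetic :class:`CorpusSpec`
    or a directory of report texts.  The reference source is "truth"
    (synthetic ground truth) or a directory of reviewer tables.  The
    extractor is "mock" (deterministic, reads the corpus truth, optionally
    corrupted through ``error_model``) or any callable satisfying the
    extractor contract.
    """

    corpus_spec: Optional[CorpusSpec] = None
    corpus_dir: Optional[str] = None
    reference: str = "truth"  # "truth" or a directory of reference tables
    extractor: object = "mock"
    error_model: Optional[ErrorModel] = None
    matching: MatchRuleConfig = dc_field(default_factory=MatchRuleConfig)
    thresholds: CoordinateThresholds = dc_field(default_factory=CoordinateThresholds)
    boundary: Optional[str] = "builtin"  # "builtin", a GeoJSON path, or None
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.corpus_spec is None) == (self.corpus_dir is None):
            raise ValueError("exactly one of corpus_spec / corpus_dir must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        corpus = raw.get("corpus", {}) or {}
        spec = None
        corpus_dir = corpus.get("dir")
        if "synthetic" in corpus:
            syn = dict(corpus["synthetic"] or {})
            if "hosts_per_report" in syn:
                syn["hosts_per_report"] = {
                    int(k): float(v) for k, v in syn["hosts_per_report"].items()
                }
            if "year_range" in syn:
                syn["year_range"] = tuple(syn["year_range"])
            spec = CorpusSpec(**syn)
        extractor_cfg = raw.get("extractor", {}) or {}
        error_model = None
        if isinstance(extractor_cfg, Mapping) and "error_model" in extractor_cfg:
            error_model = ErrorModel(**(extractor_cfg["error_model"] or {}))
        matching = MatchRuleConfig(**(raw.get("matching", {}) or {}))
        thresholds = CoordinateThresholds(**(raw.get("coordinates", {}) or {}))
        return cls(
            corpus_spec=spec,
            corpus_dir=corpus_dir,
            reference=raw.get("reference", "truth"),
            extractor="mock",
            error_model=error_model,
            matching=matching,
            thresholds=thresholds,
            boundary=raw.get("boundary", "builtin"),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


@dataclass
class ValidationReport:
    """Everything one run produced."""

    field_results: dict[str, AgreementResult]
    coordinate_summary: Optional[DiscrepancySummary]
    containment_counts: Optional[dict[str, int]]
    outcomes: list[ComparisonOutcome]
    n_reports: int
    unextracted: list[str]
    parse_row_errors: int
    injection_ledgers: dict[str, tuple]
    metadata: dict


_NAME_FIELDS = ("pathogen", "host")
_TEXT_FIELDS = ("year", "location", "country")


def _kappa_label(field_name: str, value: Optional[str], paired: bool, side: str,
                 config: MatchRuleConfig) -> str:
    if value is None:
        if paired:
            return "NA"
        return ABSENT_REF if side == "ref" else ABSENT_CAND
    if field_name in _NAME_FIELDS:
        return normalize_name(value, config)
    if field_name in _TEXT_FIELDS:
        return normalize_plain(value, config)
    return value  # percentage / coordinate display strings


def aggregate_outcomes(
    outcomes: Sequence[ComparisonOutcome], config: MatchRuleConfig = DEFAULT_MATCH_CONFIG
) -> dict[str, AgreementResult]:
    """Per-field tallies, accuracy, kappa and conditional match rate."""
    results: dict[str, AgreementResult] = {}
    for field_name in alignment.FIELDS:
        rows = [o for o in outcomes if o.field == field_name]
        if not rows:
            continue
        counts = Counter(o.category for o in rows)
        tally = Tally(**{cat: counts.get(cat, 0) for cat in OUTCOME_CATEGORIES})
        pairs = [
            (
                _kappa_label(field_name, o.ref_value, o.paired, "ref", config),
                _kappa_label(field_name, o.cand_value, o.paired, "cand", config),
            )
            for o in rows
            if o.category != "conflation"
        ]
        kappa = cohens_kappa(pairs) if len(pairs) >= 2 else None
        conditional = None
        if tally.true_positive + tally.mismatch > 0:
            conditional = conditional_match_rate(tally)
        results[field_name] = AgreementResult(
            field=field_name,
            tally=tally,
            accuracy=overall_accuracy(tally),
            kappa=kappa,
            conditional=conditional,
        )
    return results


def write_corpus(corpus: Sequence[Report], directory) -> None:
    """Write reports (and truth tables, when present) as plain text files."""
    directory = Path(directory)
    (directory / "reports").mkdir(parents=True, exist_ok=True)
    (directory / "truth").mkdir(parents=True, exist_ok=True)
    for rep in corpus:
        (directory / "reports" / f"{rep.report_id}.txt").write_text(
            f"{rep.title}\n\n{rep.abstract}\n", encoding="utf-8"
        )
        if rep.truth is not None:
            (directory / "truth" / f"{rep.report_id}.table.txt").write_text(
                write_extraction_table(rep.truth) + "\n", encoding="utf-8"
            )


def load_corpus(directory) -> list[Report]:
    """Load a corpus written by :func:`write_corpus` (truth optional)."""
    directory = Path(directory)
    reports_dir = directory / "reports"
    if not reports_dir.is_dir():
        raise FileNotFoundError(f"no reports/ directory under {directory}")
    corpus = []
    for path in sorted(reports_dir.glob("*.txt")):
        text = path.read_text(encoding="utf-8")
        title, _, abstract = text.partition("\n\n")
        truth_path = directory / "truth" / f"{path.stem}.table.txt"
        truth = None
        if truth_path.is_file():
            truth = parse_extraction_table(
                truth_path.read_text(encoding="utf-8")
            ).records
        corpus.append(Report(path.stem, title.strip(), abstract.strip(), truth))
    return corpus


def load_reference_tables(directory) -> dict[str, tuple[ExtractionRecord, ...]]:
    """Load reviewer reference tables: one ``<report_id>.table.txt`` per report."""
    directory = Path(directory)
    tables = {}
    for path in sorted(directory.glob("*.table.txt")):
        report_id = path.name[: -len(".table.txt")]
        tables[report_id] = parse_extraction_table(
            path.read_text(encoding="utf-8")
        ).records
    return tables


def _config_hash(config: PipelineConfig) -> str:
    def encode(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if callable(obj):
            return getattr(obj, "__name__", repr(type(obj).__name__))
        return obj

    blob = json.dumps(encode(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_validation(config: PipelineConfig) -> ValidationReport:
    """Run the whole pipeline and (optionally) write its outputs.

    Per-report extractor failures are never fatal: the report is marked
    unextracted and all its reference rows count as omissions.  Candidate
    rows lost to parse errors are likewise reflected as omissions of their
    reference counterparts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.corpus_spec is not None:
        corpus = generate_corpus(config.corpus_spec, config.seed)
    else:
        corpus = load_corpus(config.corpus_dir)
    timings["corpus"] = time.perf_counter() - t0

    if config.reference == "truth":
        missing = [r.report_id for r in corpus if r.truth is None]
        if missing:
            raise ValueError(f"reference='truth' but reports lack truth: {missing[:5]}")
        reference = {r.report_id: r.truth for r in corpus}
    else:
        reference = load_reference_tables(config.reference)
        missing = [r.report_id for r in corpus if r.report_id not in reference]
        if missing:
            raise ValueError(f"no reference table for reports: {missing[:5]}")

    if config.extractor == "mock":
        extractor: Extractor = MockExtractor(corpus, error_model=config.error_model)
    elif callable(config.extractor):
        extractor = config.extractor
    else:
        raise ValueError(f"extractor must be 'mock' or a callable: {config.extractor!r}")

    provider: Optional[GeoJSONBoundaryProvider] = None
    if config.boundary == "builtin":
        provider = builtin_boundary_provider()
    elif config.boundary:
        provider = GeoJSONBoundaryProvider.from_path(config.boundary)

    t0 = time.perf_counter()
    outcomes: list[ComparisonOutcome] = []
    discrepancies = []
    unextracted: list[str] = []
    parse_row_errors = 0
    containment: Optional[Counter] = Counter() if provider else None
    for rep in corpus:
        ref_records = reference[rep.report_id]
        try:
            raw = extractor(rep.title, rep.abstract)
        except ExtractorError as exc:
            logger.warning("extractor failed on %s: %s", rep.report_id, exc)
            unextracted.append(rep.report_id)
            cand_records: tuple[ExtractionRecord, ...] = ()
        else:
            parsed = parse_extraction_table(raw)
            for err in parsed.row_errors:
                logger.warning("%s row %d: %s", rep.report_id, err.row_index, err.reason)
            for anom in parsed.field_anomalies:
                logger.info(
                    "%s row %d %s: %s (%r)",
                    rep.report_id, anom.row_index, anom.column, anom.reason, anom.value,
                )
            parse_row_errors += len(parsed.row_errors)
            cand_records = parsed.records
        aligned = align_rows(ref_records, cand_records, config.matching, rep.report_id)
        classify_fields(aligned, config.matching, config.thresholds)
        outcomes.extend(aligned.outcomes)
        discrepancies.extend(aligned.coordinate_discrepancies)
        if containment is not None:
            for rec in cand_records:
                coords = rec.coordinates()
                if coords is not None and rec.country is not None:
                    verdict = check_country_containment(coords, rec.country, provider)
                    containment[verdict] += 1
                    if verdict in ("outside", "in_water"):
                        logger.warning(
                            "%s: coordinates %s fall %s the stated country %s",
                            rep.report_id, coords, verdict, rec.country,
                        )
    timings["extract_align_classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    field_results = aggregate_outcomes(outcomes, config.matching)
    coordinate_summary = summarize_discrepancies(discrepancies) if discrepancies else None
    timings["aggregate"] = time.perf_counter() - t0

    ledgers = dict(getattr(extractor, "ledgers", {}))
    report = ValidationReport(
        field_results=field_results,
        coordinate_summary=coordinate_summary,
        containment_counts=dict(containment) if containment is not None else None,
        outcomes=outcomes,
        n_reports=len(corpus),
        unextracted=unextracted,
        parse_row_errors=parse_row_errors,
        injection_ledgers=ledgers,
        metadata={
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "timings_s": timings,
            "n_reference_rows": sum(len(v) for v in reference.values()),
        },
    )
    if config.output_dir:
        _write_outputs(report, Path(config.output_dir))
    return report


def _format_summary(report: ValidationReport) -> str:
    header = (
        "field\tn_cases\ttrue_positive\ttrue_negative\tfalse_positive\tmismatch"
        "\tomission\tcommission\tconflation\taccuracy_pct\tconditional_pct"
        "\tkappa\tkappa_ci_low\tkappa_ci_high"
    )
    lines = [header]
    for field_name in alignment.FIELDS:
        res = report.field_results.get(field_name)
        if res is None:
            continue
        t = res.tally
        kappa = ci_lo = ci_hi = ""
        if res.kappa is not None and res.kappa.defined:
            kappa = f"{res.kappa.kappa:.4f}"
            ci_lo = f"{res.kappa.ci_lower:.4f}"
            ci_hi = f"{res.kappa.ci_upper:.4f}"
        cond = f"{percent(res.conditional)}" if res.conditional is not None else ""
        lines.append(
            f"{field_name}\t{t.total}\t{t.true_positive}\t{t.true_negative}"
            f"\t{t.false_positive}\t{t.mismatch}\t{t.omission}\t{t.commission}"
            f"\t{t.conflation}\t{res.accuracy_pct}\t{cond}\t{kappa}\t{ci_lo}\t{ci_hi}"
        )
    return "\n".join(lines) + "\n"


def _format_outcomes(outcomes: Sequence[ComparisonOutcome]) -> str:
    lines = ["report_id\tfield\tcategory\tref\tcand"]
    for o in outcomes:
        ref = "" if o.ref_value is None else str(o.ref_value)
        cand = "" if o.cand_value is None else str(o.cand_value)
        lines.append(f"{o.report_id}\t{o.field}\t{o.category}\t{ref}\t{cand}")
    return "\n".join(lines) + "\n"


def _json_safe(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _json_safe(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def _write_outputs(report: ValidationReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.tsv").write_text(_format_summary(report), encoding="utf-8")
    (outdir / "outcomes.tsv").write_text(_format_outcomes(report.outcomes), encoding="utf-8")
    machine = {
        "field_results": {k: _json_safe(v) for k, v in report.field_results.items()},
        "coordinate_summary": _json_safe(report.coordinate_summary),
        "containment_counts": report.containment_counts,
        "n_reports": report.n_reports,
        "unextracted": report.unextracted,
        "parse_row_errors": report.parse_row_errors,
        "metadata": report.metadata,
    }
    (outdir / "report.json").write_text(
        json.dumps(machine, indent=2, sort_keys=True), encoding="utf-8"
    )
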