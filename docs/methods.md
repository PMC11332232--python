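# Methods

This note documents the models, rules and numerical choices behind
`firstreports`, in the order data flows through the pipeline.

## The extraction task and the table dialect

A first report is a short note (≤ 2985 characters, the journal guideline
for such reports) announcing a plant pathogen's first detection on a host
or in a region. The extraction target is an 8-column table — pathogen,
host, incidence percentage, year, location, country, latitude, longitude —
with one row per pathogen × host × location combination. The prompt the
package builds instructs the extractor to delimit columns with a vertical
bar (locations may contain commas, so commas cannot delimit), to write the
literal token `NA` for anything the abstract does not state, and to return
coordinates as signed decimal degrees without cardinal letters.

The parser is strict about that dialect on purpose: a temperature-zero
extractor is highly conventionalized, so deviations are signal, not noise.
Only exact `NA` (after trimming) means missing; variants such as `n/a` are
kept as text and logged as field anomalies. A coordinate cell containing
degree/minute/second glyphs or cardinal letters is a field-level error (the
value becomes missing, the anomaly is logged) because it means the
decimal-conversion instruction was ignored. Rows with a field count other
than eight are collected as row errors, never silently dropped:
`rows_in == records_out + row_errors` always holds. A leading row equal to
the canonical column names is consumed as a header; both header and
headerless returns are accepted since either convention occurs in practice.

Percentages accept an optional trailing `%`. Years are kept as text because
year spans ("2019-2020") are common and a span versus a year inside it is a
real disagreement that numeric coercion would hide.

## Name matching

Two scientific names are considered the same when they differ only by
conventional decoration:

- subspecific rank markers (`subsp.`, `subsp`, `ssp.`, `ssp`, `var.`,
  `var`) are removed, keeping the epithet, so *Quercus robur* subsp.
  *robur* ≡ *Quercus robur* ssp *robur* ≡ *Quercus robur robur*;
- trailing genus-level placeholders (`sp.`, `sp`, `spp.`, `spp`) are
  removed, so *Phytophthora* sp. ≡ *Phytophthora* spp. ≡ *Phytophthora*;
- case is folded and internal whitespace collapsed.

Marker removal is token-based (whole words only), never substring, so
epithets containing the letters "sp" or "var" (*hispanica*, *varia*) are
untouched. `var.` is treated like `subsp.` although it is a botanical rank
of its own; a config flag turns it off if strictness is wanted. With every
flag off, matching degrades to strict equality after trimming.

No taxonomic backbone is consulted: synonymous but genuinely different
names (e.g. "Alder yellows phytoplasma" vs "Candidatus Phytoplasma alni")
do not match, which is the desired behaviour — the validation question is
whether the extractor returned what the reference reader returned, not
whether both point at the same taxon. Country, location and year fields use
only trim/case/whitespace normalization; author citations inside names, if
they ever occur, are treated as part of the name.

## Row alignment

Reference and candidate tables for one report are paired one-to-one. The
row-similarity score is the count of matching identity fields among
pathogen, host, location and country (names under the matcher above, the
rest under plain normalization); all four weigh equally, the least
informative choice in the absence of any reason to prefer one. The pairing
maximizes the total score *exactly* (a depth-first search with an
optimistic bound — report tables hold a handful of rows, so this is
microseconds), subject to two rules: rows with similarity 0 never pair, and
among equally good assignments the lexicographically earliest wins (the
first reference row takes the earliest best candidate row). A literal
greedy best-first pairing was considered and rejected: it cannot guarantee
agreement with the exhaustive optimum even when that optimum is unique,
and the exact search is just as cheap at this scale. Leftover reference
rows are omissions; leftover candidate rows are commissions.

## Outcome classification

Each aligned pair yields one outcome per field; each unmatched row yields
an omission or commission outcome for every field it populates. Within a
pair: both present and matching → true positive; both missing → true
negative (emitted only for the value fields — percentage, year, location,
coordinates — since the reference always populates pathogen, host and
country in this corpus); reference missing with a candidate value → false
positive; both present and different → mismatch; reference value answered
by `NA` → omission. Percentage comparison is numeric after unit stripping;
year comparison is normalized text equality.

Coordinates are compared as a single field. A pair of points is *exact
within rounding* when both axis differences are ≤ 0.001° (observed rounding
noise in decimal conversion sits around 0.0002–0.0004°, well below), a
*minor mismatch* up to 0.5°, and a *conversion failure* beyond. The
minor/failure boundary deserves honesty: the real-world distinction is
cause-based (which conversion step went wrong) and the magnitude
distributions of the two classes overlap, so no threshold can recover the
causal split exactly. The rule here is therefore declared configuration,
not an inferred fact. Conflation — two or more distinct reference
coordinate sets answered by one identical candidate set within a report —
is detected at the report level and replaces the per-pair coordinate
outcomes of the affected rows with a single conflation case. Two rows that
legitimately share one location (two hosts at the same site) share
coordinates on both sides and are *not* conflation.

Candidate coordinates are additionally audited for country containment
(point-in-polygon via shapely over a GeoJSON provider). Verdicts are
`inside`, `outside`, `in_water` (inside a known water body), or `unknown`
(no polygon for the country). Points outside their claimed country are
flagged in logs, never auto-corrected: the pipeline checks internal
consistency, it does not repair data. The bundled boundary file is a
deliberately synthetic set of rectangles (one per generator country plus a
lake), sufficient for exercising the containment logic; real analyses
should supply real boundaries through the same provider interface.

## Agreement statistics

Per field, over the case tally: overall accuracy (TP + TN) / N and, where
both sides returned values, the conditional match rate TP / (TP +
mismatch). Cohen's κ = (p_o − p_e) / (1 − p_e) is computed over
(reference label, candidate label) pairs: every distinct normalized value
is its own category, and an unmatched row contributes a reserved
pseudo-label on its absent side (distinct for each side, so absences never
agree). On open-class fields where nearly every label is unique, p_e ≈ 0
and κ tracks p_o, which is why accuracy and κ land close together on name
fields. The 95% CI is the normal interval with the Fleiss–Cohen–Everitt
(1969) asymptotic standard error, verified in the test suite against an
independent implementation to machine precision; a percentile bootstrap
(`ci_method="bootstrap"`) is available for small samples. κ is reported as
undefined when both raters are constant on the same single label
(p_e = 1). Percentages are reported to one decimal place throughout.

## The synthetic corpus and error model

The generator emulates the *structure* of first reports, not their prose:
each templated abstract embeds exactly one pathogen, 1–3 hosts, a year or
year span, one or (occasionally) two named locations with a country,
optionally an incidence, and optionally coordinates printed in DMS with
cardinal letters. Default condition parameters: 34% of reports print
coordinates, 26% print an incidence, hosts per report distributed
0.7/0.2/0.1 over 1/2/3, 8% of reports have a second location, 15% of years
are spans, years drawn from 2015–2023. Printed DMS is quantized to 0.1″ and
the truth table stores the decimals that the printed DMS converts back to,
so a faithful reader of the prose agrees with truth exactly.

The error model corrupts truth tables with one independent draw per
eligible row per error type: non-first-host rows dropped
(`host_omission_rate`), year spans collapsed to their first year
(`year_mismatch_rate`), missing incidences replaced by 100%
(`incidence_false_positive_rate` — the signature failure, default 0.9),
coordinates perturbed on one axis by |Δ| ∈ [0.001, 0.2]° (minor slips) or
on both axes by |Δ| ∈ [0.05, 2.0]° (failures; the two draws are mutually
exclusive per row and their magnitude bands deliberately bracket the
observed slip scales), spurious rows appended (`commission_rate`),
all of a report's coordinate sets merged into its first one
(`conflation_rate`, eligible only when ≥ 2 distinct sets exist), and
locations without printed coordinates geocoded to a uniform point within
0.5° of the country centroid (`geocode_rate`, default 1.0 — the mechanism
real extractors use is unknowable, so a disc around a country anchor is an
assumption, clearly labelled as such). Every injection is recorded in a
ledger (kind, truth-row index, magnitudes), which is what lets tests close
the loop between injected and recovered error rates.

The mock extractor satisfies the same `(title, abstract) → raw text`
contract a live API adapter would, by looking the report up by title and
serializing its (optionally corrupted) truth — per-report RNG streams are
derived from the model seed and corpus position so corruption is both
reproducible and independent across reports. What passing tests on this
corpus do **not** show: robustness to real linguistic variety, multilingual
reports, tables with unconventional column orders, or real country
borders. The generator validates the measurement machinery, not the
extractor.

## Pipeline determinism and failure handling

A run is fully determined by (configuration, seed): corpus generation,
corruption and aggregation share no hidden state, and the delimited outputs
(`summary.tsv`, `outcomes.tsv`) are byte-identical across reruns; wall-clock
timings appear only in `report.json` metadata. A report the extractor fails
on is marked unextracted and its reference rows all become omissions —
non-returns count against the candidate, they are not dropped. Candidate
rows lost to parse errors are counted and surface as omissions of their
reference counterparts. Inputs are never mutated.

## Problem sizes used in checks

The repeated checks use deliberately moderate sizes chosen to make the
statistics meaningful: zero-noise identity runs on 30–50 reports; error-rate
recovery on a ~1000-report corpus (≈ 2900 truth rows, ≈ 1200 rows eligible
for host omission) with injected rates 0.1 and 0.5, validated against
two-sided 99% binomial intervals; 100 randomized label sets for the κ
oracle comparison; 500 random points for DMS round-trips (tolerance 1e−9);
120 random small tables (≤ 4 rows a side) for the alignment-vs-exhaustive
check, asserting score equality always and pairing identity whenever the
optimum is unique.

## Known limitations

- The conflation detector requires the candidate coordinate sets to be
  bit-identical after the merge; a conflation followed by an independent
  perturbation of only some merged rows would be seen as ordinary
  mismatches.
- Injected commission rows share pathogen and country with their report, so
  at jointly extreme omission and commission rates a spurious row can pair
  with an orphaned reference row and surface as mismatches rather than one
  omission plus one commission; at realistic rates this is negligible.
- Kappa on open-class fields depends on the declared contingency
  construction (distinct normalized values as categories, reserved
  pseudo-labels for absences); other constructions are defensible and would
  shift κ slightly while leaving accuracy untouched.
- The incidence-invention failure mode is modelled per row, not per report;
  a report whose rows disagree on invented incidence cannot arise from real
  single-table extractors but is harmless for rate recovery.
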