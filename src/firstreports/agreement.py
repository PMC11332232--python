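"""Agreement statistics between a reference and a candidate extraction.

Two statistics summarize per-field agreement across a corpus:

* overall accuracy -- exact matches (true positives plus true negatives)
  divided by the total number of comparison cases for the field;
* Cohen's kappa, (p_o - p_e) / (1 - p_e), the chance-corrected agreement
  between the two raters, with a large-sample 95% confidence interval from
  the Fleiss-Cohen-Everitt asymptotic variance.

For open-class fields (scientific names, locations) every distinct
normalized value is its own kappa category and a row present on only one
side contributes a reserved pseudo-label on the absent side, which can never
agree.  With nearly unique labels the chance-agreement term p_e is close to
zero, so kappa tracks the raw agreement p_o -- which is why accuracy and
kappa land close together on such fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "OUTCOME_CATEGORIES",
    "Tally",
    "KappaResult",
    "AgreementResult",
    "ABSENT_REF",
    "ABSENT_CAND",
    "overall_accuracy",
    "conditional_match_rate",
    "cohens_kappa",
    "percent",
]

OUTCOME_CATEGORIES = (
    "true_positive",
    "true_negative",
    "false_positive",
    "mismatch",
    "omission",
    "commission",
    "conflation",
)

#: Pseudo-labels standing in for the absent side of an unpaired row when the
#: outcomes are coerced into rater-label pairs for kappa.  They are distinct,
#: so an omission and a commission never spuriously agree with anything.
ABSENT_REF = "__absent_ref__"
ABSENT_CAND = "__absent_cand__"


@dataclass(frozen=True)
class Tally:
    """Per-field counts over the comparison-outcome taxonomy."""

    true_positive: int = 0
    true_negative: int = 0
    false_positive: int = 0
    mismatch: int = 0
    omission: int = 0
    commission: int = 0
    conflation: int = 0

    def __post_init__(self) -> None:
        for cat in OUTCOME_CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"{cat} count must be >= 0")

    @property
    def total(self) -> int:
        return sum(getattr(self, cat) for cat in OUTCOME_CATEGORIES)

    def as_dict(self) -> dict[str, int]:
        return {cat: getattr(self, cat) for cat in OUTCOME_CATEGORIES}


def overall_accuracy(t: Tally) -> float:
    """Exact matches over all cases: (TP + TN) / total."""
    if t.total == 0:
        raise ValueError("accuracy undefined for an empty tally")
    return (t.true_positive + t.true_negative) / t.total


def conditional_match_rate(t: Tally) -> float:
    """Agreement restricted to cases where both sides returned a value.

    TP / (TP + mismatch): of the cases in which the reference holds a value
    and the candidate also returned one, the share extracted identically.
    """
    denom = t.true_positive + t.mismatch
    if denom == 0:
        raise ValueError("conditional match rate undefined: no two-sided value cases")
    return t.true_positive / denom


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its large-sample confidence interval.

    ``kappa`` is None when chance agreement is 1 (both raters constant on
    the same single label), where the statistic is undefined.
    """

    kappa: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    standard_error: Optional[float]
    p_observed: float
    p_expected: float
    n: int

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def _contingency(pairs: Sequence[tuple[Hashable, Hashable]]):
    labels = sorted({a for a, _ in pairs} | {b for _, b in pairs}, key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=float)
    for a, b in pairs:
        table[index[a], index[b]] += 1.0
    return table


def cohens_kappa(
    pairs: Sequence[tuple[Hashable, Hashable]],
    ci_level: float = 0.95,
    ci_method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int = 0,
) -> KappaResult:
    """Cohen's kappa over (reference label, candidate label) pairs.

    The point estimate is (p_o - p_e) / (1 - p_e) with p_o the observed
    agreement and p_e the chance agreement implied by the two marginal label
    distributions.  ``ci_method`` is "asymptotic" (normal interval with the
    Fleiss-Cohen-Everitt standard error, the default) or "bootstrap"
    (percentile interval over resampled pairs, for small samples).
    """
    if len(pairs) < 2:
        raise ValueError("kappa requires at least 2 pairs")
    table = _contingency(pairs)
    n = table.sum()
    p = table / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if 1.0 - pe < 1e-12:
        return KappaResult(None, None, None, None, po, pe, int(n))
    kappa = (po - pe) / (1.0 - pe)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pairs_arr = list(pairs)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(pairs_arr), size=len(pairs_arr))
            sample = [pairs_arr[i] for i in idx]
            t = _contingency(sample)
            q = t / t.sum()
            po_b = float(np.trace(q))
            pe_b = float(q.sum(axis=1) @ q.sum(axis=0))
            if 1.0 - pe_b > 1e-12:
                stats.append((po_b - pe_b) / (1.0 - pe_b))
        alpha = 1.0 - ci_level
        lower = float(np.quantile(stats, alpha / 2))
        upper = float(np.quantile(stats, 1 - alpha / 2))
        return KappaResult(kappa, lower, upper, None, po, pe, int(n))
    if ci_method != "asymptotic":
        raise ValueError(f"unknown ci_method {ci_method!r}")

    # Fleiss-Cohen-Everitt (1969) large-sample variance of kappa-hat.
    diag = np.diag(p)
    term_a = float(
        np.sum(diag * ((1.0 - pe) - (row + col) * (1.0 - po)) ** 2)
    )
    weights = (col[:, None] + row[None, :]) ** 2  # cell (i,j): (p_.i + p_j.)^2
    off = p * weights
    np.fill_diagonal(off, 0.0)
    term_b = (1.0 - po) ** 2 * float(off.sum())
    term_c = (po * pe - 2.0 * pe + po) ** 2
    var = (term_a + term_b - term_c) / (n * (1.0 - pe) ** 4)
    var = max(var, 0.0)
    se = math.sqrt(var)
    z = float(norm.ppf(1.0 - (1.0 - ci_level) / 2.0))
    lower = max(kappa - z * se, -1.0)
    upper = min(kappa + z * se, 1.0)
    return KappaResult(kappa, lower, upper, se, po, pe, int(n))


@dataclass(frozen=True)
class AgreementResult:
    """Corpus-level agreement summary for one field."""

    field: str
    tally: Tally
    accuracy: float
    kappa: Optional[KappaResult] = None
    conditional: Optional[float] = None

    @property
    def accuracy_pct(self) -> float:
        return percent(self.accuracy)


def percent(proportion: float, decimals: int = 1) -> float:
    """Proportion as a percentage rounded to the reporting precision."""
    return round(100.0 * proportion, decimals)
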