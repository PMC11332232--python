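"""Flexible equivalence rules for scientific names.

Two extractions of the same organism often differ only in conventional
decoration: the subspecific rank marker ("subsp.", "ssp", "var.") may or may
not be written before the epithet, a genus-only determination may or may not
carry an "sp."/"spp." placeholder, and case or spacing may vary.  Matching
here canonicalizes those variants; it performs no taxonomic resolution, so
genuinely different names ("Alder yellows phytoplasma" vs "Candidatus
Phytoplasma alni") never match.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MatchRuleConfig", "DEFAULT_MATCH_CONFIG", "normalize_name", "names_match", "normalize_plain"]

# Rank markers are matched token-wise (whole word only) so that epithets
# containing the letters "sp" or "var" (e.g. "hispanica") are never mangled.
_SUBSPECIFIC_MARKERS = frozenset({"subsp", "subsp.", "ssp", "ssp.", "var", "var."})
_GENUS_LEVEL_MARKERS = frozenset({"sp", "sp.", "spp", "spp."})


@dataclass(frozen=True)
class MatchRuleConfig:
    """Switches for the name-equivalence rules.

    With every flag off, matching degrades to strict string equality after
    trimming.
    """

    allow_subspecific_marker_variants: bool = True
    allow_sp_spp_variants: bool = True
    case_insensitive: bool = True
    collapse_whitespace: bool = True


DEFAULT_MATCH_CONFIG = MatchRuleConfig()


def normalize_name(name: str, config: MatchRuleConfig = DEFAULT_MATCH_CONFIG) -> str:
    """Canonical form of a scientific name under the configured rules.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    if not name or not name.strip():
        raise ValueError("name must be non-empty")
    text = name.strip()
    tokenized = (
        config.collapse_whitespace
        or config.allow_subspecific_marker_variants
        or config.allow_sp_spp_variants
    )
    if tokenized:
        tokens = text.split()
        if config.allow_subspecific_marker_variants:
            kept = [t for t in tokens if t.lower() not in _SUBSPECIFIC_MARKERS]
            if kept:
                tokens = kept
        if config.allow_sp_spp_variants:
            while len(tokens) > 1 and tokens[-1].lower() in _GENUS_LEVEL_MARKERS:
                tokens.pop()
        text = " ".join(tokens)
    if config.case_insensitive:
        text = text.casefold()
    return text


def names_match(a: str, b: str, config: MatchRuleConfig = DEFAULT_MATCH_CONFIG) -> bool:
    """True iff the two names share a canonical form (symmetric, reflexive)."""
    return normalize_name(a, config) == normalize_name(b, config)


def normalize_plain(text: str, config: MatchRuleConfig = DEFAULT_MATCH_CONFIG) -> str:
    """Trim/case/whitespace normalization for non-name text fields.

    Country, location and year comparison use only these rules; the rank-
    marker logic never applies to them.
    """
    if text is None:
        raise ValueError("text must be non-empty")
    out = text.strip()
    if config.collapse_whitespace:
        out = " ".join(out.split())
    if config.case_insensitive:
        out = out.casefold()
    return out
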